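"""Diffraction-peak detection and separable-Gaussian fitting.

Fiber diffraction from aligned filaments concentrates into discrete peaks,
so — in analogy with Bragg spots in crystallography — the merged pattern is
reduced to a list of fitted Gaussians.  Rendering those fits back onto a
clean grid produces an idealized noise-free pattern in which solution
background, panel-gap artefacts and bad pixels have been removed; that
rendered pattern is the preferred input to phase retrieval.

Peaks are modelled as separable ("horizontal and vertical") Gaussians
``A exp(-(x-cx)^2 / 2 sx^2) exp(-(y-cy)^2 / 2 sy^2) + b`` — elongated
equatorial streaks are captured by sx != sy, but the axes are not rotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

from .simulate import DetectorGeometry, DiffractionImage, q_of_pixel

__all__ = [
    "GaussianPeak",
    "PeakModel",
    "detect_peaks",
    "fit_peak",
    "fit_peaks",
    "render_fitted",
]


@dataclass
class GaussianPeak:
    amplitude: float
    center: tuple[float, float]  # (row, col), sub-pixel
    sigma_y: float  # rows, px
    sigma_x: float  # cols, px
    background_offset: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and (self.amplitude <= 0 or self.sigma_x <= 0
                               or self.sigma_y <= 0):
            raise ValueError("amplitude and sigmas must be > 0")


@dataclass
class PeakModel:
    peaks: list[GaussianPeak]
    shape: tuple[int, int]
    geometry: DetectorGeometry | None = None

    def to_table(self) -> pd.DataFrame:
        rows = []
        for p in self.peaks:
            q = (
                q_of_pixel(self.geometry, p.center[0], p.center[1])
                if self.geometry is not None
                else np.nan
            )
            rows.append(
                dict(center_row=p.center[0], center_col=p.center[1], q=q,
                     amplitude=p.amplitude, sigma_y=p.sigma_y,
                     sigma_x=p.sigma_x, offset=p.background_offset,
                     flag="ok" if p.converged else "failed")
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_peaks(
    merged: DiffractionImage,
    min_snr: float = 5.0,
    min_separation: int = 5,
    exclude_center_q: float = 0.03,
) -> np.ndarray:
    """Candidate peak centres as an (n, 2) array of (row, col).

    Local maxima whose residual over a median-filtered background exceeds
    ``min_snr`` times a MAD-based noise estimate, at least
    ``min_separation`` pixels apart.  Friedel pairing is enforced: accepting
    a peak at q also accepts its mate at -q (reflection through the beam
    centre), so the returned set is inversion-symmetric.

    The forward-scattering region (``q < exclude_center_q`` nm^-1) is not
    searched: the steep shoulder of the central lobe is not a diffraction
    peak, and the centre is modelled separately by the scaled featureless
    tube during phase retrieval.
    """
    img = np.where(merged.mask, merged.intensity, 0.0)
    if exclude_center_q > 0 and merged.geometry is not None:
        g = merged.geometry
        rows = np.arange(g.n_rows, dtype=float)
        q = q_of_pixel(g, rows[:, None],
                       np.arange(g.n_cols, dtype=float)[None, :])
        central = q < exclude_center_q
    else:
        central = np.zeros_like(img, dtype=bool)
    size = 2 * min_separation + 1
    bg = ndimage.median_filter(img, size=size)
    resid = img - bg
    vals = resid[merged.mask]
    noise = 1.4826 * np.median(np.abs(vals - np.median(vals))) + 1e-30
    is_max = img == ndimage.maximum_filter(img, size=min_separation)
    cand = np.argwhere(
        is_max & merged.mask & ~central & (resid > min_snr * noise)
    )
    if cand.size == 0:
        return np.zeros((0, 2))
    # greedy non-maximum suppression, brightest first
    heights = img[cand[:, 0], cand[:, 1]]
    order = np.argsort(-heights)
    kept: list[np.ndarray] = []
    for i in order:
        p = cand[i].astype(float)
        if all(np.hypot(*(p - k)) >= min_separation for k in kept):
            kept.append(p)
    # Friedel mates
    r0, c0 = merged.geometry.beam_center
    out = list(kept)
    for p in kept:
        mate = np.array([2 * r0 - p[0], 2 * c0 - p[1]])
        if not (0 <= mate[0] < img.shape[0] and 0 <= mate[1] < img.shape[1]):
            continue
        if all(np.hypot(*(mate - k)) >= min_separation for k in out):
            out.append(mate)
    return np.array(out)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _gauss2d(coords, amp, cy, cx, sy, sx, off):
    y, x = coords
    return (
        amp * np.exp(-0.5 * ((y - cy) / sy) ** 2 - 0.5 * ((x - cx) / sx) ** 2)
        + off
    )


def _two_gauss2d(coords, a1, cy1, cx1, sy1, sx1, a2, cy2, cx2, sy2, sx2, off):
    return (
        _gauss2d(coords, a1, cy1, cx1, sy1, sx1, 0.0)
        + _gauss2d(coords, a2, cy2, cx2, sy2, sx2, 0.0)
        + off
    )


def _window(shape: tuple[int, int], center, half: int):
    r, c = int(round(center[0])), int(round(center[1]))
    r0, r1 = max(r - half, 0), min(r + half + 1, shape[0])
    c0, c1 = max(c - half, 0), min(c + half + 1, shape[1])
    return slice(r0, r1), slice(c0, c1)


def _fit_single(
    intensity: np.ndarray,
    mask: np.ndarray,
    center: tuple[float, float],
    half: int,
    neighbor: tuple[float, float] | None = None,
) -> GaussianPeak | None:
    sr, sc = _window(intensity.shape, center, half)
    sub = intensity[sr, sc]
    msk = mask[sr, sc]
    if msk.sum() < 8:
        return None
    yy, xx = np.mgrid[sr, sc]
    y, x, z = yy[msk].astype(float), xx[msk].astype(float), sub[msk]
    off0 = float(np.percentile(z, 10))
    amp0 = float(z.max() - off0)
    if amp0 <= 0:
        return None
    p0 = [amp0, center[0], center[1], 2.0, 2.0, off0]
    lo = [1e-12, center[0] - half, center[1] - half, 0.3, 0.3, -np.inf]
    hi = [np.inf, center[0] + half, center[1] + half, 4 * half, 4 * half,
          np.inf]
    try:
        if neighbor is None:
            popt, _ = curve_fit(
                _gauss2d, (y, x), z, p0=p0, bounds=(lo, hi), maxfev=20000
            )
            amp, cy, cx, sy2, sx2, off = popt
        else:
            p0b = p0[:5] + [amp0, neighbor[0], neighbor[1], 2.0, 2.0, off0]
            lob = lo[:5] + [1e-12, neighbor[0] - half, neighbor[1] - half,
                            0.3, 0.3, -np.inf]
            hib = hi[:5] + [np.inf, neighbor[0] + half, neighbor[1] + half,
                            4 * half, 4 * half, np.inf]
            popt, _ = curve_fit(
                _two_gauss2d, (y, x), z, p0=p0b, bounds=(lob, hib),
                maxfev=40000,
            )
            amp, cy, cx, sy2, sx2, off = popt[0], popt[1], popt[2], popt[3], \
                popt[4], popt[10]
    except (RuntimeError, ValueError):
        return None
    if not np.all(np.isfinite([amp, cy, cx, sy2, sx2, off])):
        return None
    # a centre pinned to the window edge is a shoulder, not a peak
    if abs(cy - center[0]) > half - 1 or abs(cx - center[1]) > half - 1:
        return None
    return GaussianPeak(float(amp), (float(cy), float(cx)),
                        float(sy2), float(sx2), float(off))


def fit_peak(
    image: DiffractionImage,
    center: tuple[float, float],
    window_half: int = 8,
    neighbor: tuple[float, float] | None = None,
) -> GaussianPeak | None:
    """Least-squares separable-Gaussian fit around ``center``.

    Masked pixels are excluded.  If the fitted widths approach the window
    size the fit is repeated with a doubled window (elongated equatorial
    streaks need wide windows).  If ``neighbor`` (another candidate centre
    inside the window) is given, a simultaneous two-peak fit with a shared
    offset is used and the peak at ``center`` is returned.  A fit that does
    not converge, or whose centre runs to the window edge, returns ``None``.
    """
    half = max(window_half, 4)
    for _ in range(3):
        fit = _fit_single(image.intensity, image.mask, center, half, neighbor)
        if fit is None:
            return None
        if max(fit.sigma_x, fit.sigma_y) <= half / 2 or half >= 32:
            return fit
        half = min(2 * half, 32)
    return fit


def fit_peaks(
    merged: DiffractionImage,
    centers: np.ndarray | None = None,
    min_snr: float = 5.0,
    min_separation: int = 5,
    window_half: int = 8,
    exclude_center_q: float = 0.03,
) -> PeakModel:
    """Detect (unless ``centers`` given) and fit all diffraction peaks.

    Peaks are fitted brightest-first, and each accepted Gaussian is
    subtracted from a working copy of the image before the next fit, so
    overlapping peaks (adjacent equatorial lobes, split candidates) are not
    double-counted.  Non-converged or edge-pinned fits are dropped.
    """
    if centers is None:
        centers = detect_peaks(merged, min_snr, min_separation,
                               exclude_center_q)
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        return PeakModel([], merged.intensity.shape, merged.geometry)
    heights = merged.intensity[
        np.clip(np.round(centers[:, 0]).astype(int), 0,
                merged.intensity.shape[0] - 1),
        np.clip(np.round(centers[:, 1]).astype(int), 0,
                merged.intensity.shape[1] - 1),
    ]
    order = np.argsort(-heights)
    working = DiffractionImage(
        merged.intensity.copy(), merged.geometry, merged.mask,
        dict(merged.metadata),
    )
    peaks: list[GaussianPeak] = []
    for i in order:
        fit = fit_peak(working, tuple(centers[i]), window_half)
        if fit is None:
            continue
        peaks.append(fit)
        # deflate: remove this peak before fitting the rest
        half = int(np.ceil(6 * max(fit.sigma_x, fit.sigma_y)))
        sr, sc = _window(working.intensity.shape, fit.center, half)
        yy, xx = np.mgrid[sr, sc]
        working.intensity[sr, sc] -= _gauss2d(
            (yy.astype(float), xx.astype(float)), fit.amplitude,
            fit.center[0], fit.center[1], fit.sigma_y, fit.sigma_x, 0.0,
        )
    # Friedel completion: a real-valued density has an inversion-symmetric
    # pattern, so every fitted peak must have its mate at -q.  A mate whose
    # own fit failed is replaced by the mirrored Gaussian.
    if merged.geometry is not None:
        r0, c0 = merged.geometry.beam_center
        extra: list[GaussianPeak] = []
        for p in peaks:
            mate = (2 * r0 - p.center[0], 2 * c0 - p.center[1])
            if not (0 <= mate[0] < merged.intensity.shape[0]
                    and 0 <= mate[1] < merged.intensity.shape[1]):
                continue
            if any(
                np.hypot(q.center[0] - mate[0], q.center[1] - mate[1])
                < min_separation
                for q in peaks + extra
            ):
                continue
            extra.append(
                GaussianPeak(p.amplitude, mate, p.sigma_y, p.sigma_x,
                             p.background_offset)
            )
        peaks.extend(extra)
    return PeakModel(peaks, merged.intensity.shape, merged.geometry)


def render_fitted(model: PeakModel) -> DiffractionImage:
    """Idealized noise-free pattern: the fitted Gaussians on a zero
    background over the full grid, with no mask gaps.

    Offsets are deliberately dropped — between-peak intensity (solution
    background, tile seams) is exactly what this representation removes.
    Negative-amplitude artefacts cannot occur, so the image is >= 0.
    """
    out = np.zeros(model.shape)
    for p in model.peaks:
        half = int(np.ceil(6 * max(p.sigma_x, p.sigma_y)))
        sr, sc = _window(model.shape, p.center, half)
        yy, xx = np.mgrid[sr, sc]
        out[sr, sc] += _gauss2d(
            (yy.astype(float), xx.astype(float)),
            p.amplitude, p.center[0], p.center[1], p.sigma_y, p.sigma_x, 0.0,
        )
    geometry = model.geometry
    mask = np.ones(model.shape, dtype=bool)
    return DiffractionImage(out, geometry, mask, {"kind": "fitted"})
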