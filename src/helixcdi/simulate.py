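"""Synthetic serial-XFEL fiber-diffraction shot generator.

Renders single-shot detector images with the statistical structure of a
liquid-microjet XFEL experiment on flow-aligned helical filaments:

* ~20 filaments per exposed volume, incoherently summed (filaments sit at
  random relative positions much larger than any fringe of interest, so
  intensities add);
* a per-shot jet angle plus per-filament alignment jitter (~5 deg) and a
  random rotation of each filament about its own axis;
* a mixed 11-16 protofilament population;
* smooth isotropic solution background, Poisson photon noise, a cross-shaped
  panel-gap mask emulating tiled-detector seams, bad pixels, and an optional
  bright "jet-edge streak" artefact class for outlier-rejection tests.

Spatial frequency ``nu`` is reported as 1/d in nm^-1 (the 4 nm layer line
sits at 0.25 nm^-1).  The radial-analysis module converts to the SAXS
convention q = 2*pi/d where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.ndimage import map_coordinates

from .models import (
    GeometryError,
    Grid2D,
    ProjectionImage,
    SphereHelixModel,
    build_sphere_helix,
    project_model,
)

__all__ = [
    "HC_KEV_ANGSTROM",
    "DetectorGeometry",
    "ShotConfig",
    "DiffractionImage",
    "wavelength_from_energy",
    "photons_from_pulse_energy",
    "illuminated_volume",
    "q_of_pixel",
    "q_components",
    "radius_of_q",
    "fourier_intensity",
    "fourier_freqs",
    "simulate_pattern",
    "ShotSimulator",
    "simulate_shot",
    "crop_central_panels",
    "default_mixture",
]

#: h*c in keV * Angstrom.
HC_KEV_ANGSTROM = 12.398419843320026

#: Default protofilament mixture for taxol-stabilised in-vitro preparations:
#: dominated by the 13- and 14-pf forms with minor 11/12/15/16 populations.
def default_mixture() -> dict[int, float]:
    return {11: 0.02, 12: 0.08, 13: 0.40, 14: 0.35, 15: 0.10, 16: 0.05}


# ---------------------------------------------------------------------------
# Experiment-geometry helpers
# ---------------------------------------------------------------------------

def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in Angstrom from energy in keV (lambda = hc/E)."""
    if energy_kev <= 0:
        raise ValueError("photon energy must be > 0")
    return HC_KEV_ANGSTROM / energy_kev


def photons_from_pulse_energy(pulse_mj: float, energy_kev: float) -> float:
    """Number of photons in a pulse of ``pulse_mj`` mJ at ``energy_kev``."""
    if pulse_mj <= 0 or energy_kev <= 0:
        raise ValueError("pulse energy and photon energy must be > 0")
    kev_per_mj = 1e-3 / 1.602176634e-19 / 1e3  # mJ -> keV
    return pulse_mj * kev_per_mj / energy_kev


def illuminated_volume(focus_diameter_nm: float, jet_diameter_um: float) -> float:
    """Cylindrical beam-jet intersection volume in um^3."""
    if focus_diameter_nm <= 0 or jet_diameter_um <= 0:
        raise ValueError("focus and jet diameters must be > 0")
    r_um = focus_diameter_nm / 2.0 / 1000.0
    return float(np.pi * r_um**2 * jet_diameter_um)


# ---------------------------------------------------------------------------
# Detector geometry
# ---------------------------------------------------------------------------

@dataclass
class DetectorGeometry:
    """Monolithic detector grid with CXI-style geometry metadata.

    The default pixel pitch (520 um) corresponds to a 256x256 rebin of a
    CSPAD-like tiled detector; at 565 mm and 2.07 A it covers spatial
    frequencies past the 2 nm layer line along the detector axes.
    """

    n_rows: int = 256
    n_cols: int = 256
    pixel_pitch_um: float = 520.0
    distance_mm: float = 565.0
    wavelength_A: float = 2.07
    beam_center: tuple[float, float] | None = None
    panel_gap_mask: np.ndarray | None = None  # True = masked (gap)
    bad_pixel_mask: np.ndarray | None = None  # True = masked (bad)

    def __post_init__(self) -> None:
        if self.distance_mm <= 0 or self.wavelength_A <= 0:
            raise ValueError("distance and wavelength must be > 0")
        if self.beam_center is None:
            self.beam_center = ((self.n_rows - 1) / 2.0, (self.n_cols - 1) / 2.0)
        for name in ("panel_gap_mask", "bad_pixel_mask"):
            m = getattr(self, name)
            if m is not None and m.shape != (self.n_rows, self.n_cols):
                raise ValueError(f"{name} shape does not match detector")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the pixel is usable."""
        ok = np.ones(self.shape, dtype=bool)
        if self.panel_gap_mask is not None:
            ok &= ~self.panel_gap_mask
        if self.bad_pixel_mask is not None:
            ok &= ~self.bad_pixel_mask
        return ok

    def with_cross_gap(self, gap_pixels: int = 3) -> "DetectorGeometry":
        """Return a copy with a cross-shaped panel-gap mask through centre."""
        gap = np.zeros(self.shape, dtype=bool)
        r0 = int(round(self.beam_center[0]))
        c0 = int(round(self.beam_center[1]))
        h = gap_pixels // 2
        gap[max(r0 - h, 0) : r0 + h + 1, :] = True
        gap[:, max(c0 - h, 0) : c0 + h + 1] = True
        out = DetectorGeometry(
            self.n_rows, self.n_cols, self.pixel_pitch_um, self.distance_mm,
            self.wavelength_A, self.beam_center,
            panel_gap_mask=gap, bad_pixel_mask=self.bad_pixel_mask,
        )
        return out


def q_of_pixel(geometry: DetectorGeometry, row, col) -> np.ndarray | float:
    """Spatial frequency nu = 2 sin(theta)/lambda (= 1/d) of a pixel, nm^-1.

    Uses the exact (non-small-angle) scattering geometry:
    ``tan(2 theta) = r / D`` with r the in-plane radius from the beam centre.
    """
    row = np.asarray(row, dtype=float)
    col = np.asarray(col, dtype=float)
    pitch_mm = geometry.pixel_pitch_um / 1000.0
    r_mm = np.hypot(
        (row - geometry.beam_center[0]) * pitch_mm,
        (col - geometry.beam_center[1]) * pitch_mm,
    )
    two_theta = np.arctan2(r_mm, geometry.distance_mm)
    lam_nm = geometry.wavelength_A / 10.0
    out = 2.0 * np.sin(two_theta / 2.0) / lam_nm
    return out if out.ndim else float(out)


def radius_of_q(geometry: DetectorGeometry, q) -> np.ndarray | float:
    """Inverse of :func:`q_of_pixel`: detector radius in pixels for nu (nm^-1)."""
    q = np.asarray(q, dtype=float)
    lam_nm = geometry.wavelength_A / 10.0
    theta = np.arcsin(np.clip(q * lam_nm / 2.0, -1.0, 1.0))
    r_mm = geometry.distance_mm * np.tan(2.0 * theta)
    out = r_mm / (geometry.pixel_pitch_um / 1000.0)
    return out if out.ndim else float(out)


def q_components(geometry: DetectorGeometry) -> tuple[np.ndarray, np.ndarray]:
    """(nu_y, nu_x) components for every pixel, nm^-1.

    The magnitude follows the exact formula; the direction is the in-plane
    pixel direction from the beam centre (Ewald-sphere curvature of the
    out-of-plane component is negligible at these angles).
    """
    rows = np.arange(geometry.n_rows, dtype=float)
    cols = np.arange(geometry.n_cols, dtype=float)
    dr = rows[:, None] - geometry.beam_center[0]
    dc = cols[None, :] - geometry.beam_center[1]
    rr = np.hypot(dr, dc)
    q = q_of_pixel(geometry, rows[:, None], cols[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        qy = np.where(rr > 0, q * dr / rr, 0.0)
        qx = np.where(rr > 0, q * dc / rr, 0.0)
    return qy, qx


@dataclass
class DiffractionImage:
    """Detector intensity (photons) with geometry, validity mask, metadata.

    ``mask`` is True on usable pixels; masked pixels hold 0 and are excluded
    from every statistic downstream.
    """

    intensity: np.ndarray
    geometry: DetectorGeometry
    mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensity.shape != self.mask.shape:
            raise ValueError("intensity and mask shapes differ")


# ---------------------------------------------------------------------------
# Coherent single-filament patterns
# ---------------------------------------------------------------------------

def fourier_freqs(grid: Grid2D) -> tuple[np.ndarray, np.ndarray]:
    """Centred (nu_y, nu_x) axes of the FFT of a projection on ``grid``."""
    fy = np.fft.fftshift(np.fft.fftfreq(grid.n_rows, d=grid.pixel_size))
    fx = np.fft.fftshift(np.fft.fftfreq(grid.n_cols, d=grid.pixel_size))
    return fy, fx


def fourier_intensity(projection: ProjectionImage) -> np.ndarray:
    """Centred |FFT|^2 of the projected density.

    Satisfies Friedel symmetry I(q) = I(-q) exactly (real input) and
    Parseval's relation sum|F|^2 = N * sum|rho|^2.
    """
    F = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(projection.density)))
    return np.abs(F) ** 2


def _check_oversampled(projection: ProjectionImage) -> None:
    rows = np.flatnonzero(projection.density.sum(axis=1) > 0)
    cols = np.flatnonzero(projection.density.sum(axis=0) > 0)
    if rows.size and rows[-1] - rows[0] >= projection.grid.n_rows // 2:
        raise GeometryError("object spans >= half the field in y: undersampled")
    if cols.size and cols[-1] - cols[0] >= projection.grid.n_cols // 2:
        raise GeometryError("object spans >= half the field in x: undersampled")


def _detector_sample(
    intensity_grid: np.ndarray,
    grid: Grid2D,
    geometry: DetectorGeometry,
    rotation_deg: float = 0.0,
) -> np.ndarray:
    """Bilinear sample of a centred Fourier-intensity grid at detector pixels.

    ``rotation_deg`` rotates the pattern in the detector plane (the image of
    a filament whose axis is tilted by alpha rotates by alpha).
    """
    qy, qx = q_components(geometry)
    if rotation_deg:
        th = np.deg2rad(rotation_deg)
        c, s = np.cos(th), np.sin(th)
        qy, qx = c * qy - s * qx, s * qy + c * qx
    dq_y = 1.0 / (grid.n_rows * grid.pixel_size)
    dq_x = 1.0 / (grid.n_cols * grid.pixel_size)
    iy = qy / dq_y + grid.n_rows // 2
    ix = qx / dq_x + grid.n_cols // 2
    return map_coordinates(
        intensity_grid, [iy, ix], order=1, mode="constant", cval=0.0
    )


def simulate_pattern(
    projection: ProjectionImage,
    geometry: DetectorGeometry,
    photons: float,
) -> DiffractionImage:
    """Noise-free coherent diffraction of one projected object on a detector.

    Intensity is |FFT(projection)|^2 resampled at each detector pixel's
    (nu_y, nu_x) and scaled so the unmasked intensity sums to ``photons``.
    """
    _check_oversampled(projection)
    intens = fourier_intensity(projection)
    img = _detector_sample(intens, projection.grid, geometry)
    mask = geometry.valid_mask()
    img[~mask] = 0.0
    total = img[mask].sum()
    if photons > 0 and total > 0:
        img *= photons / total
    elif photons == 0:
        img[:] = 0.0
    return DiffractionImage(img, geometry, mask, {"kind": "pattern"})


# ---------------------------------------------------------------------------
# Shot simulation
# ---------------------------------------------------------------------------

@dataclass
class ShotConfig:
    """Statistical model of one experimental run.

    ``photons_per_pulse`` times ``scattering_fraction`` gives the expected
    number of detected photons per filament; the default pairs the nominal
    2e12-photon pulse with an effective scattering fraction of 1e-8 (a
    stand-in for the true cross-section, not a calibrated value).
    """

    n_filaments_mean: float = 20.0
    alignment_sigma: float = 5.0  # deg, filament-to-jet jitter
    jet_angle_mean: float = 0.0  # deg
    jet_angle_sigma: float = 10.0  # deg, shot-to-shot jet wander
    photons_per_pulse: float = 2e12
    scattering_fraction: float = 1e-8
    background_level: float = 0.5  # photons / unmasked pixel (mean)
    protofilament_mixture: dict[int, float] = field(default_factory=default_mixture)
    edge_streak_fraction: float = 0.0
    n_axial_rotations: int = 8
    random_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_filaments_mean, self.photons_per_pulse,
               self.background_level, self.scattering_fraction) < 0:
            raise ValueError("rates must be >= 0")
        w = sum(self.protofilament_mixture.values())
        if not np.isclose(w, 1.0):
            raise ValueError("protofilament mixture weights must sum to 1")

    @property
    def photons_per_filament(self) -> float:
        return self.photons_per_pulse * self.scattering_fraction


def _helix_for_pf(n_pf: int, reference_pf: int = 14,
                  reference_radius: float = 11.2) -> SphereHelixModel:
    """Sphere-helix wall for an n-protofilament tube.

    The centre-line radius scales linearly with protofilament count
    (constant lateral subunit spacing), anchored at 11.2 nm for 14 pf.
    """
    return SphereHelixModel(
        sphere_diameter=4.0,
        spheres_per_turn=n_pf,
        pitch_spheres_per_turn=3,
        helical_radius=reference_radius * n_pf / reference_pf,
        n_turns=60,
    )


def _background_profile(geometry: DetectorGeometry, level: float) -> np.ndarray:
    """Smooth isotropic solution background, mean ``level`` per unmasked px."""
    rows = np.arange(geometry.n_rows, dtype=float)
    cols = np.arange(geometry.n_cols, dtype=float)
    q = q_of_pixel(geometry, rows[:, None], cols[None, :])
    w = 1.0 / (1.0 + (q / 0.15) ** 2)  # featureless Lorentzian falloff
    mask = geometry.valid_mask()
    w *= level / w[mask].mean() if mask.any() else 0.0
    return w


def _edge_streak(geometry: DetectorGeometry, angle_deg: float,
                 amplitude: float) -> np.ndarray:
    """Bright narrow streak through the beam centre (jet-edge artefact)."""
    rows = np.arange(geometry.n_rows, dtype=float)[:, None]
    cols = np.arange(geometry.n_cols, dtype=float)[None, :]
    dr = rows - geometry.beam_center[0]
    dc = cols - geometry.beam_center[1]
    th = np.deg2rad(angle_deg)
    # distance from the line through centre at angle th (from +x/col axis)
    dist = np.abs(-np.sin(th) * dc + np.cos(th) * dr)
    return amplitude * np.exp(-0.5 * (dist / 1.5) ** 2)


class ShotSimulator:
    """Precomputes filament templates and renders seeded detector shots.

    One coherent Fourier-intensity template is computed per (protofilament
    count, axial rotation) pair; per shot, each filament samples a template
    at in-plane-rotated detector coordinates and intensities are summed
    incoherently before noise.
    """

    def __init__(
        self,
        config: ShotConfig,
        geometry: DetectorGeometry,
        grid: Grid2D | None = None,
    ) -> None:
        self.config = config
        self.geometry = geometry
        self.grid = grid or Grid2D()
        self._pf_values = sorted(config.protofilament_mixture)
        self._pf_weights = np.array(
            [config.protofilament_mixture[p] for p in self._pf_values]
        )
        rot_angles = np.arange(config.n_axial_rotations) * (
            360.0 / config.n_axial_rotations
        )
        self._templates: dict[int, list[np.ndarray]] = {}
        self._template_norm: dict[int, list[float]] = {}
        base_mask = geometry.valid_mask()
        needs_templates = (
            config.n_filaments_mean > 0 and config.photons_per_filament > 0
        )
        for pf in self._pf_values if needs_templates else []:
            model = _helix_for_pf(pf)
            centers = build_sphere_helix(model)
            tlist, nlist = [], []
            for ang in rot_angles:
                proj = project_model(centers, model.sphere_diameter, self.grid, ang)
                intens = fourier_intensity(proj)
                det = _detector_sample(intens, self.grid, geometry)
                norm = det[base_mask].sum()
                tlist.append(intens.astype(np.float32))
                nlist.append(norm)
            self._templates[pf] = tlist
            self._template_norm[pf] = nlist
        self._background = _background_profile(geometry, config.background_level)
        self._mask = base_mask
        self._qy, self._qx = q_components(geometry)
        self._dq = (1.0 / (self.grid.n_rows * self.grid.pixel_size),
                    1.0 / (self.grid.n_cols * self.grid.pixel_size))

    def reference_projection(self, n_steps: int = 60) -> ProjectionImage:
        """Mixture-weighted, axially averaged projection of the population.

        This is "the generating model's own projection": the expected
        real-space object underlying the simulated ensemble.
        """
        from .models import axially_averaged_projection

        density = np.zeros(self.grid.shape)
        for pf, w in zip(self._pf_values, self._pf_weights):
            avg = axially_averaged_projection(_helix_for_pf(pf), self.grid, n_steps)
            density += w * avg.density
        return ProjectionImage(grid=self.grid, density=density)

    def shot(self, index: int) -> DiffractionImage:
        """Render shot ``index`` (bit-reproducible given the config seed)."""
        cfg = self.config
        rng = np.random.default_rng([cfg.random_seed, index])
        jet_angle = rng.normal(cfg.jet_angle_mean, cfg.jet_angle_sigma)
        expected = self._background.copy()
        kind = "background"
        if cfg.edge_streak_fraction > 0 and rng.random() < cfg.edge_streak_fraction:
            kind = "edge"
            # jet-edge diffraction is very strong and dominates everything
            # else in the exposure; near detector saturation at the ridge
            streak_level = 5e4
            expected = expected + _edge_streak(
                self.geometry, rng.uniform(0.0, 180.0), streak_level
            )
            n_fil = 0
        else:
            n_fil = rng.poisson(cfg.n_filaments_mean)
            if n_fil > 0 and cfg.photons_per_filament > 0:
                kind = "filament"
            for _ in range(n_fil) if self._templates else []:
                pf = self._pf_values[
                    rng.choice(len(self._pf_values), p=self._pf_weights)
                ]
                irot = rng.integers(len(self._templates[pf]))
                alpha = jet_angle + rng.normal(0.0, cfg.alignment_sigma)
                th = np.deg2rad(alpha)
                cth, sth = np.cos(th), np.sin(th)
                qy = cth * self._qy - sth * self._qx
                qx = sth * self._qy + cth * self._qx
                det = map_coordinates(
                    self._templates[pf][irot],
                    [qy / self._dq[0] + self.grid.n_rows // 2,
                     qx / self._dq[1] + self.grid.n_cols // 2],
                    order=1, mode="constant", cval=0.0,
                )
                norm = self._template_norm[pf][irot]
                if norm > 0 and cfg.photons_per_filament > 0:
                    expected += det * (cfg.photons_per_filament / norm)
        counts = rng.poisson(expected).astype(float)
        counts[~self._mask] = 0.0
        meta = {
            "shot_id": index,
            "jet_angle": float(jet_angle % 180.0),
            "n_filaments": int(n_fil),
            "kind": kind,
            "seed": cfg.random_seed,
        }
        return DiffractionImage(counts, self.geometry, self._mask.copy(), meta)

    def shots(self, n: int, start: int = 0) -> Iterator[DiffractionImage]:
        for i in range(start, start + n):
            yield self.shot(i)


def simulate_shot(
    config: ShotConfig,
    geometry: DetectorGeometry,
    index: int = 0,
    grid: Grid2D | None = None,
) -> DiffractionImage:
    """One-off single shot (builds a :class:`ShotSimulator` internally)."""
    return ShotSimulator(config, geometry, grid).shot(index)


def crop_central_panels(image: DiffractionImage) -> DiffractionImage:
    """Central-quarter crop mirroring "only the central four of sixteen
    detector panels": half the rows and columns, centred on the beam."""
    g = image.geometry
    r0 = int(round(g.beam_center[0] - g.n_rows / 4))
    c0 = int(round(g.beam_center[1] - g.n_cols / 4))
    r1, c1 = r0 + g.n_rows // 2, c0 + g.n_cols // 2
    r0, c0 = max(r0, 0), max(c0, 0)
    sub_geom = DetectorGeometry(
        r1 - r0, c1 - c0, g.pixel_pitch_um, g.distance_mm, g.wavelength_A,
        beam_center=(g.beam_center[0] - r0, g.beam_center[1] - c0),
    )
    return DiffractionImage(
        image.intensity[r0:r1, c0:c1].copy(),
        sub_geom,
        image.mask[r0:r1, c0:c1].copy(),
        dict(image.metadata),
    )
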