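"""HDF5 shot-stack I/O (CXI-style layout), YAML configuration, pipeline
orchestration and run provenance.

Layout of a shot stack::

    /entry_1/data_1/data        (n_shots, rows, cols) float32 photon counts
    /entry_1/mask               (rows, cols) uint8, 1 = valid pixel
    /entry_1/geometry/...       distance_mm, pixel_pitch_um, wavelength_A,
                                beam_center
    /entry_1/metadata/...       per-shot jet angle, kind, filament count

Every pipeline stage appends one record to ``run_manifest.jsonl`` in the run
directory (stage name, inputs/outputs, counts, seeds, config hash,
timestamp, package version) and stamps its HDF5 outputs with the config
hash so an unchanged re-run is a no-op unless forced.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import Grid2D, TubeModel
from .simulate import DetectorGeometry, DiffractionImage, ShotConfig, ShotSimulator

__all__ = [
    "ConfigError",
    "FormatError",
    "StageError",
    "DEFAULT_CONFIG",
    "load_config",
    "config_hash",
    "write_shot_stack",
    "read_shot_stack",
    "stack_length",
    "save_image",
    "load_image",
    "save_density",
    "load_density",
    "run_pipeline",
    "PIPELINE_STAGES",
]


class ConfigError(ValueError):
    """Invalid or inconsistent configuration (CLI exit code 2)."""


class FormatError(ValueError):
    """A file does not follow the expected HDF5 layout (CLI exit code 3)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 4)."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Every tunable default of the pipeline, by stage.
DEFAULT_CONFIG: dict = {
    "grid": {"n_rows": 1024, "n_cols": 1024, "pixel_size": 0.5},
    "detector": {
        "n_rows": 256, "n_cols": 256, "pixel_pitch_um": 520.0,
        "distance_mm": 565.0, "wavelength_A": 2.07, "gap_pixels": 3,
    },
    "simulate": {
        "n_shots": 2000, "n_filaments_mean": 20.0, "alignment_sigma": 5.0,
        "jet_angle_mean": 0.0, "jet_angle_sigma": 10.0,
        "photons_per_pulse": 2.0e12, "scattering_fraction": 1.0e-8,
        "background_level": 0.5, "edge_streak_fraction": 0.0,
        "n_axial_rotations": 8, "random_seed": 0,
        "protofilament_mixture": {
            11: 0.02, 12: 0.08, 13: 0.40, 14: 0.35, 15: 0.10, 16: 0.05,
        },
    },
    "sort": {"keep_fraction": 0.4, "use_central_panels": True},
    "classify": {"block_size": 1000, "k": 5, "seed": 0},
    "merge": {"select_fraction": 69.0 / 186.0},
    "fitpeaks": {"enabled": True, "min_snr": 5.0, "min_separation": 5},
    "retrieve": {
        "n_cycles": 100, "symmetry_period": 10,
        "tube_inner_diameter": 17.4, "tube_outer_diameter": 25.4,
        "x_half_width": 15.6, "x_falloff_width": 11.8, "y_fwhm": 159.0,
        "falloff_convention": "fwhm", "central_fill_radius": None,
        "enforce_real": True, "enforce_positive": False,
    },
    "analyze": {"n_bins": None, "j01_search": [0.15, 0.50], "r13": 11.94},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise ConfigError(f"unknown config key: {path}{key}")
        if isinstance(base[key], dict) and key != "protofilament_mixture":
            if not isinstance(val, dict):
                raise ConfigError(f"{path}{key} must be a mapping")
            out[key] = _merge(base[key], val, f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file (unknown keys error)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    cfg["simulate"]["protofilament_mixture"] = {
        int(k): v for k, v in cfg["simulate"]["protofilament_mixture"].items()
    }
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
        cfg = _merge(cfg, user)
        mix = cfg["simulate"]["protofilament_mixture"]
        cfg["simulate"]["protofilament_mixture"] = {
            int(k): float(v) for k, v in mix.items()
        }
    return cfg


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _geometry_from_config(config: dict) -> DetectorGeometry:
    d = config["detector"]
    geom = DetectorGeometry(
        n_rows=d["n_rows"], n_cols=d["n_cols"],
        pixel_pitch_um=d["pixel_pitch_um"], distance_mm=d["distance_mm"],
        wavelength_A=d["wavelength_A"],
    )
    if d.get("gap_pixels", 0) > 0:
        geom = geom.with_cross_gap(d["gap_pixels"])
    return geom


def _grid_from_config(config: dict) -> Grid2D:
    g = config["grid"]
    return Grid2D(g["n_rows"], g["n_cols"], g["pixel_size"])


def _shot_config(config: dict, seed: int | None = None) -> ShotConfig:
    s = dict(config["simulate"])
    s.pop("n_shots")
    if seed is not None:
        s["random_seed"] = seed
    return ShotConfig(**s)


# ---------------------------------------------------------------------------
# HDF5 shot stacks
# ---------------------------------------------------------------------------

def _write_geometry(grp: h5py.Group, g: DetectorGeometry) -> None:
    grp["distance_mm"] = g.distance_mm
    grp["pixel_pitch_um"] = g.pixel_pitch_um
    grp["wavelength_A"] = g.wavelength_A
    grp["beam_center"] = np.asarray(g.beam_center)


def _read_geometry(entry: h5py.Group, shape: tuple[int, int]) -> DetectorGeometry:
    try:
        geo = entry["geometry"]
        return DetectorGeometry(
            n_rows=shape[0], n_cols=shape[1],
            pixel_pitch_um=float(geo["pixel_pitch_um"][()]),
            distance_mm=float(geo["distance_mm"][()]),
            wavelength_A=float(geo["wavelength_A"][()]),
            beam_center=tuple(geo["beam_center"][()]),
        )
    except KeyError as exc:
        raise FormatError(f"missing geometry dataset: {exc}") from exc


def write_shot_stack(
    path: str | Path,
    shots: Iterable[DiffractionImage],
    n_hint: int | None = None,
    extra_attrs: dict | None = None,
) -> int:
    """Stream shots into a CXI-style HDF5 stack; returns the shot count."""
    path = Path(path)
    it = iter(shots)
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("cannot write an empty shot stack")
    shape = first.intensity.shape
    with h5py.File(path, "w") as fh:
        data = fh.create_dataset(
            "/entry_1/data_1/data", shape=(n_hint or 1,) + shape,
            maxshape=(None,) + shape, dtype="f4", chunks=(1,) + shape,
        )
        fh["/entry_1/mask"] = first.mask.astype("u1")
        _write_geometry(fh.create_group("/entry_1/geometry"), first.geometry)
        jet, kind, nfil = [], [], []
        n = 0
        for img in _chain(first, it):
            if n >= data.shape[0]:
                data.resize(n + 1, axis=0)
            data[n] = img.intensity.astype("f4")
            jet.append(img.metadata.get("jet_angle", np.nan))
            kind.append(img.metadata.get("kind", ""))
            nfil.append(img.metadata.get("n_filaments", -1))
            n += 1
        data.resize(n, axis=0)
        meta = fh.create_group("/entry_1/metadata")
        meta["jet_angle"] = np.asarray(jet)
        meta["kind"] = np.asarray(kind, dtype=h5py.string_dtype())
        meta["n_filaments"] = np.asarray(nfil)
        for key, val in (extra_attrs or {}).items():
            fh.attrs[key] = val
    return n


def _chain(first, rest):
    yield first
    yield from rest


def stack_length(path: str | Path) -> int:
    with h5py.File(path, "r") as fh:
        try:
            return fh["/entry_1/data_1/data"].shape[0]
        except KeyError as exc:
            raise FormatError(
                "missing dataset /entry_1/data_1/data"
            ) from exc


def read_shot_stack(
    path: str | Path,
    selection: Sequence[int] | slice | None = None,
) -> Iterator[DiffractionImage]:
    """Lazily iterate shots; only one image is resident at a time.

    ``selection`` may be an index list or a slice; order is preserved.
    """
    with h5py.File(path, "r") as fh:
        try:
            data = fh["/entry_1/data_1/data"]
            mask = fh["/entry_1/mask"][()].astype(bool)
        except KeyError as exc:
            raise FormatError(f"missing dataset: {exc}") from exc
        geometry = _read_geometry(fh["/entry_1"], data.shape[1:])
        geometry.bad_pixel_mask = ~mask
        meta = fh.get("/entry_1/metadata")
        n = data.shape[0]
        if selection is None:
            indices = range(n)
        elif isinstance(selection, slice):
            indices = range(*selection.indices(n))
        else:
            indices = list(selection)
        for i in indices:
            md = {"shot_id": int(i)}
            if meta is not None:
                md["jet_angle"] = float(meta["jet_angle"][i])
                md["kind"] = meta["kind"][i].decode()
                md["n_filaments"] = int(meta["n_filaments"][i])
            yield DiffractionImage(data[i][()].astype(float), geometry,
                                   mask.copy(), md)


def save_image(path: str | Path, image: DiffractionImage,
               extra_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh["/entry_1/data_1/data"] = image.intensity.astype("f8")
        fh["/entry_1/mask"] = image.mask.astype("u1")
        _write_geometry(fh.create_group("/entry_1/geometry"), image.geometry)
        fh.attrs["metadata"] = json.dumps(image.metadata, default=str)
        for key, val in (extra_attrs or {}).items():
            fh.attrs[key] = val


def load_image(path: str | Path) -> DiffractionImage:
    with h5py.File(path, "r") as fh:
        try:
            data = fh["/entry_1/data_1/data"][()]
            mask = fh["/entry_1/mask"][()].astype(bool)
        except KeyError as exc:
            raise FormatError(f"missing dataset: {exc}") from exc
        geometry = _read_geometry(fh["/entry_1"], data.shape)
        md = json.loads(fh.attrs.get("metadata", "{}"))
    return DiffractionImage(data, geometry, mask, md)


def save_density(path: str | Path, result, extra_attrs: dict | None = None
                 ) -> None:
    """Persist a :class:`~helixcdi.phasing.ProjectionDensity` with its
    error history and support parameters."""
    with h5py.File(path, "w") as fh:
        fh["/density"] = result.density
        fh["/error_history"] = result.error_history
        if result.supported_object is not None:
            fh["/supported_object"] = result.supported_object
        g = result.grid
        fh.attrs.update(
            n_rows=g.n_rows, n_cols=g.n_cols, pixel_size=g.pixel_size,
            x_half_width=result.support.x_half_width,
            x_falloff_width=result.support.x_falloff_width,
            y_fwhm=result.support.y_fwhm,
            falloff_convention=result.support.falloff_convention,
            diverged=result.diverged,
        )
        for key, val in (extra_attrs or {}).items():
            fh.attrs[key] = val


def load_density(path: str | Path):
    from .phasing import ProjectionDensity, SupportMask

    with h5py.File(path, "r") as fh:
        density = fh["/density"][()]
        errors = fh["/error_history"][()]
        supported = (
            fh["/supported_object"][()] if "supported_object" in fh else None
        )
        a = fh.attrs
        grid = Grid2D(int(a["n_rows"]), int(a["n_cols"]), float(a["pixel_size"]))
        support = SupportMask(
            float(a["x_half_width"]), float(a["x_falloff_width"]),
            float(a["y_fwhm"]), str(a["falloff_convention"]),
        )
        return ProjectionDensity(grid, density, errors, support,
                                 bool(a["diverged"]), supported)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

PIPELINE_STAGES = (
    "simulate", "sort", "classify", "merge", "fitpeaks", "retrieve", "analyze",
)


def _manifest_append(workdir: Path, record: dict) -> None:
    record = dict(record, timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
                  version=__version__)
    with open(workdir / "run_manifest.jsonl", "a") as fh:
        fh.write(json.dumps(record, default=str) + "\n")


def _is_current(path: Path, chash: str) -> bool:
    if not path.exists():
        return False
    try:
        with h5py.File(path, "r") as fh:
            return fh.attrs.get("config_hash") == chash
    except OSError:
        return False


def run_pipeline(
    config: dict | None = None,
    workdir: str | Path = ".",
    seed: int | None = None,
    force: bool = False,
    input_stack: str | Path | None = None,
    through_stage: str = "analyze",
):
    """Execute the processing chain and return ``(density, summary)``.

    Stages: simulate (skipped when ``input_stack`` is given) -> sort ->
    classify/average -> merge -> fitpeaks (optional) -> retrieve -> analyze.
    Outputs are persisted per stage in ``workdir``; a stage whose output
    exists with the current config hash is skipped unless ``force``.
    Failure at any stage raises :class:`StageError`, leaving all upstream
    outputs in place.
    """
    from . import peaks as peaks_mod
    from . import phasing, radial, sorting

    config = config or load_config()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if through_stage not in PIPELINE_STAGES:
        raise ConfigError(f"unknown stage {through_stage!r}")
    last = PIPELINE_STAGES.index(through_stage)
    chash = config_hash(config)
    if seed is None:
        seed = config["simulate"]["random_seed"]
    geometry = _geometry_from_config(config)
    grid = _grid_from_config(config)

    def stage_enabled(name: str) -> bool:
        return PIPELINE_STAGES.index(name) <= last

    def run_stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ConfigError, FormatError):
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # --- simulate ---------------------------------------------------------
    stack_path = Path(input_stack) if input_stack else workdir / "shots.h5"
    if input_stack is None:
        if force or not _is_current(stack_path, chash):
            sim = ShotSimulator(_shot_config(config, seed), geometry, grid)
            n = run_stage(
                "simulate", write_shot_stack, stack_path,
                sim.shots(config["simulate"]["n_shots"]),
                n_hint=config["simulate"]["n_shots"],
                extra_attrs={"config_hash": chash, "seed": seed},
            )
            _manifest_append(workdir, dict(
                stage="simulate", inputs=[], outputs=[str(stack_path)],
                n_in=0, n_out=n, seed=seed, config_hash=chash,
            ))
    if not stage_enabled("sort"):
        return None, {"stack": str(stack_path)}
    n_shots = stack_length(stack_path)

    # --- sort -------------------------------------------------------------
    kept_path = workdir / "kept_indices.json"
    s_cfg = config["sort"]
    stats = [
        sorting.shot_statistics(img, s_cfg["use_central_panels"])
        for img in read_shot_stack(stack_path)
    ]
    kept = sorting.reject_outliers(stats, s_cfg["keep_fraction"])
    kept_path.write_text(json.dumps([int(i) for i in kept]))
    _manifest_append(workdir, dict(
        stage="sort", inputs=[str(stack_path)], outputs=[str(kept_path)],
        n_in=n_shots, n_out=len(kept), seed=seed, config_hash=chash,
    ))
    if not stage_enabled("classify"):
        return None, {"kept": len(kept)}

    # --- classify + class averaging --------------------------------------
    c_cfg = config["classify"]
    angles = np.array([
        sorting.estimate_equatorial_angle(img).angle
        for img in read_shot_stack(stack_path, kept)
    ])
    labels = sorting.classify_block(
        angles, c_cfg["block_size"], c_cfg["k"], c_cfg["seed"]
    )
    averages = []
    for lab in np.unique(labels):
        sel = labels == lab
        ids = kept[sel]
        members = list(read_shot_stack(stack_path, ids))
        averages.append(
            sorting.class_average(members, angles[sel], member_ids=ids)
        )
    pd.DataFrame({"shot": kept, "angle": angles, "label": labels}).to_csv(
        workdir / "classes.tsv", sep="\t", index=False
    )
    _manifest_append(workdir, dict(
        stage="classify", inputs=[str(stack_path)],
        outputs=[str(workdir / "classes.tsv")],
        n_in=len(kept), n_out=len(averages), seed=c_cfg["seed"],
        config_hash=chash,
    ))
    if not stage_enabled("merge"):
        return None, {"n_classes": len(averages)}

    # --- merge ------------------------------------------------------------
    merged = run_stage(
        "merge", sorting.select_align_merge, averages,
        config["merge"]["select_fraction"],
    )
    merged_path = workdir / "merged.h5"
    save_image(merged_path, merged, {"config_hash": chash})
    _manifest_append(workdir, dict(
        stage="merge", inputs=[str(workdir / "classes.tsv")],
        outputs=[str(merged_path)], n_in=len(averages),
        n_out=merged.metadata.get("n_classes"), seed=seed, config_hash=chash,
    ))
    if not stage_enabled("fitpeaks"):
        return None, {"merged": str(merged_path)}

    # --- fitpeaks (optional) ----------------------------------------------
    p_cfg = config["fitpeaks"]
    retrieval_input = merged
    if p_cfg["enabled"]:
        model = run_stage(
            "fitpeaks", peaks_mod.fit_peaks, merged,
            min_snr=p_cfg["min_snr"], min_separation=p_cfg["min_separation"],
        )
        model.to_table().to_csv(workdir / "peaks.tsv", sep="\t", index=False)
        rendered = peaks_mod.render_fitted(model)
        save_image(workdir / "fitted.h5", rendered, {"config_hash": chash})
        retrieval_input = rendered
        _manifest_append(workdir, dict(
            stage="fitpeaks", inputs=[str(merged_path)],
            outputs=[str(workdir / "peaks.tsv"), str(workdir / "fitted.h5")],
            n_in=1, n_out=len(model.peaks), seed=seed, config_hash=chash,
        ))
    if not stage_enabled("retrieve"):
        return None, {"merged": str(merged_path)}

    # --- retrieve ----------------------------------------------------------
    r_cfg = config["retrieve"]
    support = phasing.SupportMask(
        r_cfg["x_half_width"], r_cfg["x_falloff_width"], r_cfg["y_fwhm"],
        r_cfg["falloff_convention"],
    )
    tube = TubeModel(r_cfg["tube_inner_diameter"], r_cfg["tube_outer_diameter"])
    rconfig = phasing.RetrievalConfig(
        n_cycles=r_cfg["n_cycles"], symmetry_period=r_cfg["symmetry_period"],
        init_tube=tube, central_fill_radius=r_cfg["central_fill_radius"],
        enforce_real=r_cfg["enforce_real"],
        enforce_positive=r_cfg["enforce_positive"], seed=seed,
    )

    def _retrieve():
        amps, meas = phasing.detector_to_fourier(retrieval_input, grid)
        init = phasing.tube_initial_field(tube, grid, support)
        amps, meas, scale = phasing.fill_central_beam(
            amps, meas, init, grid, r_cfg["central_fill_radius"]
        )
        return phasing.retrieve(amps, meas, rconfig, support, grid,
                                initial_field=init)

    density = run_stage("retrieve", _retrieve)
    recon_path = workdir / "recon.h5"
    save_density(recon_path, density, {"config_hash": chash})
    _manifest_append(workdir, dict(
        stage="retrieve", inputs=[str(merged_path)],
        outputs=[str(recon_path)], n_in=1, n_out=1, seed=seed,
        config_hash=chash,
    ))
    if not stage_enabled("analyze"):
        return density, {"recon": str(recon_path)}

    # --- analyze ------------------------------------------------------------
    a_cfg = config["analyze"]
    profile = run_stage("analyze", radial.azimuthal_integrate, merged,
                        a_cfg["n_bins"])
    pd.DataFrame({
        "q_per_nm": profile.q_bins,
        "mean_intensity": profile.mean_intensity,
        "pixel_count": profile.pixel_counts,
    }).to_csv(workdir / "radial_profile.tsv", sep="\t", index=False)
    summary: dict = {"n_shots": int(n_shots), "n_kept": int(len(kept)),
                     "n_classes": int(len(averages)),
                     "n_merged_images": merged.metadata.get("n_images")}
    try:
        q01 = radial.find_J01(profile, tuple(a_cfg["j01_search"]))
        R = radial.helical_radius_from_J01(q01)
        summary.update(J01_q=q01, mean_helical_radius_nm=R,
                       protofilament_estimate=radial.protofilament_estimate(
                           R, a_cfg["r13"]))
    except ValueError as exc:
        summary["J01_error"] = str(exc)
    try:
        summary["peak_to_peak_nm"] = radial.peak_to_peak(density)
    except ValueError as exc:
        summary["peak_to_peak_error"] = str(exc)
    (workdir / "summary.json").write_text(json.dumps(summary, indent=2))
    _manifest_append(workdir, dict(
        stage="analyze", inputs=[str(merged_path), str(recon_path)],
        outputs=[str(workdir / "radial_profile.tsv"),
                 str(workdir / "summary.json")],
        n_in=1, n_out=1, seed=seed, config_hash=chash,
    ))
    return density, summary
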