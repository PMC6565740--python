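"""Shared fixtures.

The expensive end-to-end objects (the 2000-shot default-configuration
pipeline run and the generating model's reference projection) are
session-scoped so the full chain is simulated and processed exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from helixcdi.io import load_config, load_image, run_pipeline
from helixcdi.models import Grid2D
from helixcdi.simulate import DetectorGeometry, ShotConfig, ShotSimulator


@pytest.fixture(scope="session")
def grid() -> Grid2D:
    return Grid2D()


@pytest.fixture(scope="session")
def detector() -> DetectorGeometry:
    return DetectorGeometry().with_cross_gap(3)


@pytest.fixture(scope="session")
def small_detector() -> DetectorGeometry:
    """64x64 detector with the same q-range as the default (4x coarser)."""
    return DetectorGeometry(n_rows=64, n_cols=64, pixel_pitch_um=2080.0)


@pytest.fixture(scope="session")
def single_filament_sim(detector, grid) -> ShotSimulator:
    """One perfectly aligned 14-pf filament per shot, no background."""
    cfg = ShotConfig(
        n_filaments_mean=1.0, alignment_sigma=0.0, jet_angle_mean=30.0,
        jet_angle_sigma=0.0, background_level=0.0,
        scattering_fraction=1e-6, protofilament_mixture={14: 1.0},
        n_axial_rotations=4, random_seed=21,
    )
    return ShotSimulator(cfg, detector, grid)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Default-configuration end-to-end run: 2000 shots, seed 0.

    Returns a dict with the recovered density, stage summary, run directory
    and the configuration used.
    """
    workdir = tmp_path_factory.mktemp("full_pipeline")
    config = load_config()
    density, summary = run_pipeline(config, workdir=workdir, seed=0)
    return {
        "density": density,
        "summary": summary,
        "workdir": workdir,
        "config": config,
        "fitted": load_image(workdir / "fitted.h5"),
        "merged": load_image(workdir / "merged.h5"),
    }


@pytest.fixture(scope="session")
def reference_projection(detector, grid):
    """Mixture-weighted, rotation-averaged projection of the generating
    model population under the default shot configuration."""
    sim = ShotSimulator(ShotConfig(random_seed=0), detector, grid)
    return sim.reference_projection(n_steps=60)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
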