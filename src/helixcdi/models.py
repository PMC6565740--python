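"""Parametric microtubule stand-in models and their 2D projections.

Two model families are provided:

* :class:`TubeModel` — a featureless hollow cylinder, used for the initial
  phases of iterative phase retrieval and for filling the unmeasured central
  beam.  Its projection through the tube axis has a closed form (the line
  integral of an annulus), so it doubles as an analytic oracle.
* :class:`SphereHelixModel` — an oversimplified microtubule wall built from
  4 nm spheres: one turn of ``spheres_per_turn`` spheres with a stagger of
  ``pitch_spheres_per_turn`` monomer lengths per turn, replicated axially at
  the monomer repeat so that each protofilament is a chain of spheres spaced
  one sphere diameter apart.  This lattice reproduces the characteristic
  fiber-diffraction layer lines at the monomer repeat (4 nm) and its second
  order (2 nm).

All lengths are in nanometres.  Images use 0-based ``(row, col)`` indexing
with ``y`` = rows (the helical axis direction) and ``x`` = columns
(perpendicular to the axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "UndefinedResultError",
    "TubeModel",
    "SphereHelixModel",
    "Grid2D",
    "ProjectionImage",
    "tube_projection",
    "annulus_projection_profile",
    "build_sphere_helix",
    "project_model",
    "axially_averaged_projection",
    "com_radius",
    "annulus_com_radius",
    "tube_from_com_radius",
    "com_radius_from_structure",
]


class GeometryError(ValueError):
    """A model does not fit the requested grid / field of view."""


class UndefinedResultError(ValueError):
    """A quantity is undefined for the given input (e.g. zero total mass)."""


@dataclass(frozen=True)
class TubeModel:
    """Featureless hollow cylinder with uniform wall density.

    Parameters
    ----------
    inner_diameter, outer_diameter:
        Wall boundaries in nm; ``0 < inner < outer``.
    """

    inner_diameter: float
    outer_diameter: float

    def __post_init__(self) -> None:
        if not (0.0 < self.inner_diameter < self.outer_diameter):
            raise ValueError(
                "require 0 < inner_diameter < outer_diameter, got "
                f"{self.inner_diameter}, {self.outer_diameter}"
            )

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        return self.outer_diameter / 2.0

    @property
    def com_radius(self) -> float:
        """Radial centre of mass of the annular cross-section."""
        return annulus_com_radius(self.inner_radius, self.outer_radius)


@dataclass(frozen=True)
class SphereHelixModel:
    """Microtubule wall lattice built from spheres.

    ``spheres_per_turn`` spheres form one turn on a cylinder of radius
    ``helical_radius``; going once around, the lattice rises by
    ``pitch_spheres_per_turn`` sphere diameters (the 3-start stagger of the
    microtubule wall).  The turn is replicated ``n_turns`` times along the
    axis at a spacing of one sphere diameter — the 4 nm monomer repeat —
    so each protofilament is a vertical chain of touching spheres.
    """

    sphere_diameter: float = 4.0
    spheres_per_turn: int = 14
    pitch_spheres_per_turn: int = 3
    helical_radius: float = 11.2
    n_turns: int = 60

    def __post_init__(self) -> None:
        if self.sphere_diameter <= 0:
            raise ValueError("sphere_diameter must be > 0")
        if self.spheres_per_turn < 3:
            raise ValueError("spheres_per_turn must be >= 3")
        if self.helical_radius <= self.sphere_diameter / 2.0:
            raise ValueError("helical_radius must exceed the sphere radius")
        if self.n_turns < 1:
            raise ValueError("n_turns must be >= 1")

    @property
    def outer_diameter(self) -> float:
        """Outer envelope of the sphere lattice: 2 R + sphere diameter."""
        return 2.0 * self.helical_radius + self.sphere_diameter

    @property
    def axial_repeat(self) -> float:
        """Axial lattice repeat (= sphere diameter, the monomer length)."""
        return self.sphere_diameter


@dataclass(frozen=True)
class Grid2D:
    """Real-space raster: ``pixel_size`` nm per pixel, origin at ``center``."""

    n_rows: int = 1024
    n_cols: int = 1024
    pixel_size: float = 0.5
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must have at least 2x2 pixels")
        if self.center is None:
            object.__setattr__(
                self, "center", (self.n_rows / 2.0, self.n_cols / 2.0)
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def x_coords(self) -> np.ndarray:
        """x (nm) of each column centre, measured from the grid origin."""
        return (np.arange(self.n_cols) - self.center[1]) * self.pixel_size

    def y_coords(self) -> np.ndarray:
        """y (nm) of each row centre, measured from the grid origin."""
        return (np.arange(self.n_rows) - self.center[0]) * self.pixel_size

    @property
    def field_of_view(self) -> tuple[float, float]:
        """(y extent, x extent) of the grid in nm."""
        return (self.n_rows * self.pixel_size, self.n_cols * self.pixel_size)


@dataclass
class ProjectionImage:
    """Non-negative projected density on a :class:`Grid2D`."""

    grid: Grid2D
    density: np.ndarray
    orientation: float = 0.0  # deg, helical axis w.r.t. image y-axis

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != self.grid.shape:
            raise ValueError("density shape does not match grid")

    @property
    def total_mass(self) -> float:
        """Integrated density in (density unit) * nm^2."""
        return float(self.density.sum()) * self.grid.pixel_size**2


# ---------------------------------------------------------------------------
# Featureless tube
# ---------------------------------------------------------------------------

def annulus_projection_profile(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """Line integral of a unit-density annulus a <= r <= b along one axis.

    p(x) = 2 (sqrt(b^2 - x^2) - sqrt(max(a^2 - x^2, 0))) for |x| <= b.
    The profile peaks at |x| = a, where the chord grazes the inner bore.
    """
    x = np.asarray(x, dtype=float)
    outer = np.sqrt(np.clip(b * b - x * x, 0.0, None))
    inner = np.sqrt(np.clip(a * a - x * x, 0.0, None))
    return 2.0 * (outer - inner)


def tube_projection(model: TubeModel, grid: Grid2D) -> ProjectionImage:
    """Analytic projection of a featureless tube through its axis.

    The tube axis runs along y; the profile is replicated over all rows.

    Raises
    ------
    GeometryError
        If the tube is wider than the grid field of view.
    """
    _, fov_x = grid.field_of_view
    if model.outer_diameter >= fov_x:
        raise GeometryError(
            f"tube outer diameter {model.outer_diameter} nm exceeds the "
            f"{fov_x} nm field of view"
        )
    profile = annulus_projection_profile(
        grid.x_coords(), model.inner_radius, model.outer_radius
    )
    density = np.broadcast_to(profile, grid.shape).copy()
    return ProjectionImage(grid=grid, density=density)


# ---------------------------------------------------------------------------
# Sphere helix
# ---------------------------------------------------------------------------

def build_sphere_helix(model: SphereHelixModel) -> np.ndarray:
    """Sphere centres of the wall lattice as an (n, 3) array of (x, y, z) nm.

    y is the helical axis; the beam direction is z.  Within one turn,
    consecutive spheres advance by ``2*pi/spheres_per_turn`` azimuthally and
    by ``pitch_spheres_per_turn * d / spheres_per_turn`` axially; the turn is
    then repeated ``n_turns`` times at the axial monomer repeat ``d``.
    Centres are shifted so the lattice is centred on y = 0.
    """
    n = model.spheres_per_turn
    d = model.sphere_diameter
    j = np.arange(n)
    phi = 2.0 * np.pi * j / n
    z_turn = (model.pitch_spheres_per_turn * d / n) * j
    reps = np.arange(model.n_turns) * d
    y = (z_turn[:, None] + reps[None, :]).ravel()
    phi = np.repeat(phi, model.n_turns)
    centers = np.column_stack(
        [
            model.helical_radius * np.cos(phi),
            y - y.mean(),
            model.helical_radius * np.sin(phi),
        ]
    )
    return centers


def _stamp_spheres(
    density: np.ndarray, grid: Grid2D, xy: np.ndarray, radius: float
) -> None:
    """Accumulate projected chord-length profiles of spheres at (x, y) nm."""
    px = grid.pixel_size
    xs = grid.x_coords()
    ys = grid.y_coords()
    w = int(np.ceil(radius / px)) + 2
    for cx, cy in xy:
        ic = int(round(cx / px + grid.center[1]))
        jr = int(round(cy / px + grid.center[0]))
        if (
            ic - w < 0
            or ic + w >= grid.n_cols
            or jr - w < 0
            or jr + w >= grid.n_rows
        ):
            raise GeometryError(
                f"sphere at ({cx:.1f}, {cy:.1f}) nm falls outside the grid"
            )
        dx = xs[ic - w : ic + w + 1] - cx
        dy = ys[jr - w : jr + w + 1] - cy
        rho2 = dx[None, :] ** 2 + dy[:, None] ** 2
        chord = 2.0 * np.sqrt(np.clip(radius * radius - rho2, 0.0, None))
        # normalise so every sphere deposits exactly its volume, making the
        # projected mass independent of sub-pixel position (and rotation)
        total = chord.sum() * px * px
        if total > 0:
            chord *= (4.0 / 3.0) * np.pi * radius**3 / total
        density[jr - w : jr + w + 1, ic - w : ic + w + 1] += chord


def project_model(
    centers: np.ndarray,
    sphere_diameter: float,
    grid: Grid2D,
    rotation_about_helix_axis: float = 0.0,
) -> ProjectionImage:
    """Project spheres onto the (x, y) plane after rotating about the y axis.

    Each sphere of radius r contributes its chord-length profile
    ``2 sqrt(r^2 - rho^2)`` around its projected centre, so projected mass is
    exactly the sphere volume regardless of orientation.
    """
    centers = np.asarray(centers, dtype=float)
    theta = np.deg2rad(rotation_about_helix_axis)
    c, s = np.cos(theta), np.sin(theta)
    x = c * centers[:, 0] + s * centers[:, 2]
    xy = np.column_stack([x, centers[:, 1]])
    density = np.zeros(grid.shape)
    _stamp_spheres(density, grid, xy, sphere_diameter / 2.0)
    return ProjectionImage(
        grid=grid, density=density, orientation=0.0
    )


def axially_averaged_projection(
    model: SphereHelixModel, grid: Grid2D, n_steps: int = 360
) -> ProjectionImage:
    """Projection averaged over ``n_steps`` rotations spanning 360 degrees.

    Emulates an incoherent average over filaments with random rotation about
    their own axis (or, equivalently, a cylindrically averaged wall).
    """
    centers = build_sphere_helix(model)
    density = np.zeros(grid.shape)
    for ang in np.arange(n_steps) * (360.0 / n_steps):
        density += project_model(
            centers, model.sphere_diameter, grid, ang
        ).density
    return ProjectionImage(grid=grid, density=density / n_steps)


# ---------------------------------------------------------------------------
# Centre-of-mass radius
# ---------------------------------------------------------------------------

def com_radius(radii: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted mean radius: sum(r * m) / sum(m).

    Raises
    ------
    UndefinedResultError
        If the total mass is zero (or negative).
    """
    radii = np.asarray(radii, dtype=float)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise UndefinedResultError("COM radius undefined for zero total mass")
    return float((radii * masses).sum() / total)


def annulus_com_radius(a: float, b: float) -> float:
    """COM radius of a uniform annulus a <= r <= b: 2(b^3-a^3)/(3(b^2-a^2))."""
    if not 0 <= a < b:
        raise ValueError("require 0 <= a < b")
    return 2.0 * (b**3 - a**3) / (3.0 * (b**2 - a**2))


def tube_from_com_radius(com: float, wall_thickness: float = 4.0) -> TubeModel:
    """Tube of given wall thickness whose annulus COM radius equals ``com``.

    Inverts the closed-form annulus COM radius numerically; used to
    parameterise starting models for the phase-retrieval robustness scan.
    """
    from scipy.optimize import brentq

    t = wall_thickness
    if com <= t / 2.0:
        raise ValueError("COM radius must exceed half the wall thickness")

    def f(a: float) -> float:
        return annulus_com_radius(a, a + t) - com

    # annulus_com_radius(a, a+t) is increasing in a and > t/2 at a -> 0+
    hi = com + t
    a = brentq(f, 1e-9, hi)
    return TubeModel(2.0 * a, 2.0 * (a + t))


# Average atomic masses for the elements common in protein structures.
_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "MG": 24.305, "ZN": 65.38, "FE": 55.845, "CA": 40.078,
    "NA": 22.990, "K": 39.098, "CL": 35.45, "MN": 54.938,
}


def com_radius_from_structure(path: str, use_masses: bool = True) -> float:
    """COM radius of a PDB/mmCIF coordinate set about its own helical axis.

    The helical axis is taken as the principal axis (largest spread) of the
    centred coordinate set; radii are measured perpendicular to it.  Atomic
    masses are used when elements are present, otherwise unit masses.
    Distances are returned in nm (coordinates in such files are Angstrom).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    coords = []
    masses = []
    for atom in (
        a for mdl in st for ch in mdl for res in ch for a in res
    ):
        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        el = atom.element.name.upper()
        masses.append(_ATOMIC_MASS.get(el, 12.011) if use_masses else 1.0)
    if not coords:
        raise UndefinedResultError(f"no atoms found in {path}")
    coords = np.asarray(coords)
    masses = np.asarray(masses)
    center = (coords * masses[:, None]).sum(0) / masses.sum()
    coords = coords - center
    # principal axis = eigenvector of the largest eigenvalue of the
    # mass-weighted covariance (the direction of maximal extent)
    cov = (coords * masses[:, None]).T @ coords / masses.sum()
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    perp = coords - np.outer(coords @ axis, axis)
    radii_nm = np.linalg.norm(perp, axis=1) / 10.0
    return com_radius(radii_nm, masses)
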