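"""Scalar electrostatic-potential grids and cuboid sub-region averaging.

The Poisson–Boltzmann solve that produces real potential maps is external;
this module consumes its OpenDX output (via gridData/GridDataFormats, the
APBS dialect), provides an analytic Debye–Hückel generator for testing,
and implements the one computation the analysis owns: the mean potential
inside an oriented cuboid sub-region (sides 2.0 × 2.0 × 1.0 nm in the
interface analysis), by trilinear interpolation on a regular sample
lattice, with mean ± s.e.m. across frames.

Lengths are nm and potentials kJ/mol/e throughout (values are passed
through unchanged from the files; the unit is metadata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_FACTOR, KB

__all__ = ["PotentialGrid", "Cuboid", "read_dx", "write_dx",
           "dh_potential_grid", "debye_kappa", "cuboid_average",
           "cuboid_average_frames"]

AVOGADRO = 6.02214076e23
E_CHARGE = 1.602176634e-19  # C
EPS0 = 8.8541878128e-12  # F/m


@dataclass
class PotentialGrid:
    """Regular orthogonal 3D scalar grid (origin/spacing nm, values kJ/mol/e)."""

    origin: np.ndarray  # (3,)
    spacing: np.ndarray  # (3,) per-axis spacing (orthogonal axes only)
    values: np.ndarray  # (nx, ny, nz)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.spacing = np.asarray(self.spacing, float).reshape(3)
        self.values = np.asarray(self.values, float)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacings must be positive")
        if self.values.ndim != 3:
            raise ValueError("grid values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite values")

    def axes(self):
        return tuple(self.origin[k] + self.spacing[k] * np.arange(self.values.shape[k])
                     for k in range(3))


def read_dx(path) -> PotentialGrid:
    """Read an OpenDX scalar grid (APBS dialect).

    Only orthogonal (diagonal-delta) grids are supported; anything else
    raises ``ValueError``.
    """
    from gridData import Grid

    g = Grid(str(path))
    delta = np.asarray(g.delta)
    if delta.ndim == 2:
        if not np.allclose(delta, np.diag(np.diag(delta))):
            raise ValueError(f"{path}: non-orthogonal grid deltas are unsupported")
        delta = np.diag(delta)
    return PotentialGrid(np.asarray(g.origin), delta, np.asarray(g.grid),
                         {"source": str(path)})


def write_dx(grid: PotentialGrid, path) -> None:
    from gridData import Grid

    g = Grid(grid.values, origin=grid.origin, delta=grid.spacing)
    g.export(str(path), typequote='"')


def debye_kappa(ionic_strength_mm: float, eps_solvent: float = 78.4,
                temperature: float = 300.0) -> float:
    """Inverse Debye screening length κ in nm⁻¹ for a 1:1 electrolyte.

    κ² = 2·NA·e²·I / (ε0·εr·kB·T) with the ionic strength in mol/m³
    (numerically equal to mM).
    """
    if ionic_strength_mm < 0:
        raise ValueError("ionic strength must be non-negative")
    if ionic_strength_mm == 0:
        return 0.0
    i_si = ionic_strength_mm  # mM == mol/m^3
    kb_j = KB / AVOGADRO * 1000.0  # J/K
    kappa_m = math.sqrt(2.0 * AVOGADRO * E_CHARGE**2 * i_si
                        / (EPS0 * eps_solvent * kb_j * temperature))
    return kappa_m * 1e-9  # 1/m -> 1/nm


def dh_potential_grid(charges, origin, spacing, shape,
                      ionic_strength_mm: float = 150.0,
                      eps_solvent: float = 78.4, temperature: float = 300.0,
                      exclusion_radius: float = 1e-6) -> PotentialGrid:
    """Analytic screened-Coulomb (Debye–Hückel) potential of point charges.

    φ(r) = f/εr · Σ_i q_i·exp(−κ|r−r_i|)/|r−r_i| in kJ/mol/e, with
    f = e²·NA/(4π·ε0) in kJ·nm/mol and κ from the ionic strength.  Raises
    when any grid node lies within ``exclusion_radius`` nm of a charge.
    """
    kappa = debye_kappa(ionic_strength_mm, eps_solvent, temperature)
    ax = [np.asarray(origin, float)[k] + spacing[k] * np.arange(shape[k])
          for k in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    phi = np.zeros(xx.shape)
    for pos, q in charges:
        pos = np.asarray(pos, float)
        r = np.sqrt((xx - pos[0]) ** 2 + (yy - pos[1]) ** 2 + (zz - pos[2]) ** 2)
        if np.any(r < exclusion_radius):
            raise ValueError(
                f"grid node within {exclusion_radius} nm of charge at {pos}")
        phi += q * np.exp(-kappa * r) / r
    phi *= COULOMB_FACTOR / eps_solvent
    return PotentialGrid(np.asarray(origin, float), np.asarray(spacing, float),
                         phi, {"ionic_strength_mM": ionic_strength_mm,
                               "eps_solvent": eps_solvent,
                               "kappa_per_nm": kappa, "unit": "kJ/mol/e"})


@dataclass
class Cuboid:
    """Oriented box: center (nm), orthonormal axis triad, side lengths (nm)."""

    center: np.ndarray
    axes: np.ndarray = field(
        default_factory=lambda: np.eye(3))  # rows are unit vectors
    sides: tuple = (2.0, 2.0, 1.0)

    def __post_init__(self):
        self.center = np.asarray(self.center, float).reshape(3)
        self.axes = np.asarray(self.axes, float).reshape(3, 3)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("cuboid axes must be orthonormal (within 1e-8)")
        if any(s <= 0 for s in self.sides):
            raise ValueError("cuboid side lengths must be positive")

    def sample_lattice(self, n_per_axis: int = 21) -> np.ndarray:
        """Regular (n³, 3) lattice of points filling the cuboid."""
        offs = [np.linspace(-s / 2.0, s / 2.0, n_per_axis) for s in self.sides]
        aa, bb, cc = np.meshgrid(*offs, indexing="ij")
        pts = (aa.ravel()[:, None] * self.axes[0]
               + bb.ravel()[:, None] * self.axes[1]
               + cc.ravel()[:, None] * self.axes[2])
        return self.center + pts


def cuboid_average(grid: PotentialGrid, cuboid: Cuboid,
                   n_per_axis: int = 21) -> float:
    """Mean potential inside the cuboid (one frame).

    Trilinear interpolation of the grid at a regular ``n_per_axis``³
    lattice of points; raises with the overshoot when the cuboid pokes
    outside the grid.
    """
    from scipy.interpolate import RegularGridInterpolator

    pts = cuboid.sample_lattice(n_per_axis)
    ax = grid.axes()
    lo = np.array([a[0] for a in ax])
    hi = np.array([a[-1] for a in ax])
    under = np.minimum(pts.min(axis=0) - lo, 0.0)
    over = np.maximum(pts.max(axis=0) - hi, 0.0)
    if np.any(under < 0) or np.any(over > 0):
        raise ValueError(
            "cuboid extends outside the grid: undershoot (nm) "
            f"{(-under).tolist()}, overshoot (nm) {over.tolist()}")
    interp = RegularGridInterpolator(ax, grid.values, method="linear")
    return float(interp(pts).mean())


def cuboid_average_frames(grids, cuboid: Cuboid, n_per_axis: int = 21):
    """Mean ± s.e.m. of the cuboid average across frames (potential grids)."""
    vals = np.array([cuboid_average(g, cuboid, n_per_axis) for g in grids])
    if vals.size == 0:
        raise ValueError("no frames given")
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
    return float(vals.mean()), sem, vals
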