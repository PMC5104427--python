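"""Free-energy surface reconstruction from deposited hills.

The two-dimensional surface over (δ, τ) is rebuilt by summing the Gaussian
hills recorded during a well-tempered run,

    V(s) = Σ_i h_i · exp(−(δ−c_iδ)²/(2σ_iδ²) − d(τ, c_iτ)²/(2σ_iτ²)),

with d(·,·) the minimum-image angular difference, and rescaled by the
well-tempered estimator F = −γ/(γ−1)·V (min-shifted to zero).  One-
dimensional profiles follow by Boltzmann-weighted marginalization, and the
block machinery reproduces the cumulative 10-ns-interval convergence
analysis: profiles on [0, i·10 ns], mean/SEM over the last five, and the
RMS of consecutive profile values at a chosen position as the convergence
diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import kbt
from .io import HillSeries
from .potentials import angular_difference

__all__ = [
    "GridSpec", "FreeEnergyGrid", "Curve", "Profile1D", "Minimum",
    "sum_hills", "marginalize", "block_profiles", "profile_stats",
    "find_minima", "convergence_rms", "ConvergenceReport",
]

BLOCK_LENGTH_PS = 10_000.0  # 10 ns, the convergence-analysis block length
N_AVG_BLOCKS = 5


@dataclass(frozen=True)
class GridSpec:
    """Uniform (δ, τ) grid: δ spacing 0.035 nm; τ gets the same node count
    as δ by default (its printed 0.035° spacing would give ~10,000 bins,
    treated as a unit slip; override with ``tau_bins``)."""

    delta_min: float = 0.3
    delta_max: float = 1.4
    delta_spacing: float = 0.035
    tau_bins: int | None = None  # default: same count as the δ axis

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        n_d = int(round((self.delta_max - self.delta_min) / self.delta_spacing)) + 1
        delta = self.delta_min + self.delta_spacing * np.arange(n_d)
        n_t = self.tau_bins if self.tau_bins else n_d
        tau = -180.0 + 360.0 / n_t * np.arange(n_t)  # periodic, +180 excluded
        return delta, tau


@dataclass
class FreeEnergyGrid:
    """F(δ, τ) in kJ/mol on a uniform grid, min-shifted to zero."""

    delta: np.ndarray  # nm, axis nodes
    tau: np.ndarray  # deg, periodic axis nodes
    values: np.ndarray  # (n_delta, n_tau)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.delta.size, self.tau.size):
            raise ValueError("grid values shape does not match the axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("free-energy grid contains non-finite values")


@dataclass
class Curve:
    """A 1D free-energy curve over one CV axis."""

    coord: np.ndarray
    values: np.ndarray
    axis: str  # "delta" | "tau"


@dataclass
class Minimum:
    position: float | None  # grid-snapped coordinate, None if missing
    value: float | None  # ΔG on the mean curve, kJ/mol
    expected: float | None = None
    missing: bool = False


@dataclass
class Profile1D:
    """Block-averaged 1D profile: mean over the last five block curves,
    SEM = σ/√5 and CI95 half-width 1.96·SEM, all pointwise."""

    coord: np.ndarray
    axis: str
    blocks: list  # the averaged block curves (np.ndarray values)
    mean: np.ndarray
    sem: np.ndarray
    ci95: np.ndarray  # half-width
    minima: list = field(default_factory=list)


def sum_hills(hills: HillSeries, grid_spec: GridSpec = GridSpec(),
              time_cutoff: float | None = None,
              wt_rescale: bool = True) -> FreeEnergyGrid:
    """Rebuild the FES by summing Gaussian hills on the grid.

    ``time_cutoff`` (ps) keeps only hills with t ≤ cutoff.  With
    ``wt_rescale`` the well-tempered estimator F = −γ/(γ−1)·V is applied;
    without it F = −V (raw summation).  An empty series yields a flat zero
    grid with a warning.
    """
    if hills.bias_factor <= 1 and wt_rescale:
        raise ValueError("well-tempered rescaling requires bias factor γ > 1")
    if time_cutoff is not None:
        hills = hills.until(time_cutoff)
    delta, tau = grid_spec.axes()
    if len(hills) == 0:
        warnings.warn("empty hill series: returning a flat zero surface",
                      stacklevel=2)
        return FreeEnergyGrid(delta, tau, np.zeros((delta.size, tau.size)),
                              {"n_hills": 0})
    dd = delta[:, None] - hills.center_delta[None, :]  # (n_d, n_hills)
    dt = angular_difference(tau[:, None], hills.center_tau[None, :])  # (n_t, n_hills)
    ed = np.exp(-0.5 * (dd / hills.sigma_delta[None, :]) ** 2) * hills.height
    et = np.exp(-0.5 * (dt / hills.sigma_tau[None, :]) ** 2)
    v = ed @ et.T  # separable per hill: Σ_i h_i·ed[d,i]·et[t,i]
    prefactor = hills.bias_factor / (hills.bias_factor - 1.0) if wt_rescale else 1.0
    f = -prefactor * v
    f -= f.min()
    meta = {"n_hills": len(hills), "bias_factor": hills.bias_factor,
            "wt_rescale": wt_rescale,
            "time_range": (float(hills.time.min()), float(hills.time.max()))}
    return FreeEnergyGrid(delta, tau, f, meta)


def marginalize(grid: FreeEnergyGrid, keep_axis: str = "delta",
                temperature: float = 300.0, mode: str = "boltzmann") -> Curve:
    """Integrate one CV out of F(δ, τ).

    Boltzmann weighting at ``temperature`` (default), i.e.
    F(x) = −kB·T·ln Σ_y exp(−F(x,y)/kB·T)·Δy, evaluated with
    log-sum-exp; ``mode="min"`` projects by the minimum instead.  The
    result is min-shifted to zero.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if keep_axis == "delta":
        f, coord = grid.values, grid.delta
    elif keep_axis == "tau":
        f, coord = grid.values.T, grid.tau
    else:
        raise ValueError(f"keep_axis must be 'delta' or 'tau', got {keep_axis!r}")
    if mode == "min":
        prof = f.min(axis=1)
    elif mode == "boltzmann":
        beta = 1.0 / kbt(temperature)
        prof = -logsumexp(-beta * f, axis=1) / beta  # Δy constant: drops in shift
    else:
        raise ValueError(f"unknown marginalization mode {mode!r}")
    return Curve(coord.copy(), prof - prof.min(), keep_axis)


def block_profiles(hills: HillSeries, grid_spec: GridSpec = GridSpec(),
                   block_length: float = BLOCK_LENGTH_PS,
                   keep_axis: str = "delta", temperature: float = 300.0,
                   cumulative: bool = True, wt_rescale: bool = True) -> list[Curve]:
    """Profiles on successive time blocks of the hill series.

    With ``cumulative`` (default) curve i is built from hills in
    [0, i·block_length] — the convergence construction; otherwise from the
    i-th disjoint block alone.  The series must span at least one block.
    """
    if len(hills) == 0 or hills.time.max() < block_length:
        raise ValueError("hill series shorter than one block "
                         f"({block_length} ps)")
    n_blocks = int(hills.time.max() // block_length)
    curves = []
    for i in range(1, n_blocks + 1):
        if cumulative:
            sub = hills.until(i * block_length)
        else:
            keep = (hills.time > (i - 1) * block_length) & \
                   (hills.time <= i * block_length)
            sub = HillSeries(hills.time[keep], hills.center_delta[keep],
                             hills.center_tau[keep], hills.sigma_delta[keep],
                             hills.sigma_tau[keep], hills.height[keep],
                             hills.bias_factor)
        grid = sum_hills(sub, grid_spec, wt_rescale=wt_rescale)
        curves.append(marginalize(grid, keep_axis, temperature))
    return curves


def profile_stats(curves: list[Curve], n_avg: int = N_AVG_BLOCKS) -> Profile1D:
    """Mean/SEM/CI95 over the last ``n_avg`` block curves (pointwise).

    SEM uses the sample standard deviation across blocks (σ/√n, n = 5);
    the CI95 half-width is 1.96·SEM.  Raises when fewer than ``n_avg``
    curves are available.
    """
    if len(curves) < n_avg:
        raise ValueError(f"need at least {n_avg} block curves, got {len(curves)}")
    last = curves[-n_avg:]
    coord = last[0].coord
    for c in last[1:]:
        if c.axis != last[0].axis or not np.array_equal(c.coord, coord):
            raise ValueError("block curves are on different grids")
    stack = np.vstack([c.values for c in last])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n_avg)
    return Profile1D(coord.copy(), last[0].axis, [c.values for c in last],
                     mean - mean.min(), sem, 1.96 * sem)


def _smooth(values: np.ndarray, window: int = 3) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def find_minima(profile, expected_positions=None, window: float = 0.1,
                smooth_window: int = 3) -> list[Minimum]:
    """Locate local minima of a profile curve.

    The curve is smoothed by a 3-point moving average before the discrete
    neighborhood test; reported positions are snapped to grid nodes (ties
    toward smaller coordinate) and ΔG values read from the *unsmoothed*
    curve.  When ``expected_positions`` is given, the nearest local
    minimum within ``window`` of each is returned; a position with no
    local minimum nearby is flagged missing rather than substituted.
    """
    coord = profile.coord
    raw = profile.values if hasattr(profile, "values") else profile.mean
    s = _smooth(raw, smooth_window)
    is_min = np.zeros(coord.size, dtype=bool)
    for i in range(1, coord.size - 1):
        if s[i] <= s[i - 1] and s[i] <= s[i + 1] and (s[i] < s[i - 1] or s[i] < s[i + 1]):
            # plateau tie-break: only the first (smaller-coordinate) point
            if not (s[i] == s[i - 1] and is_min[i - 1]):
                is_min[i] = True
    idx = np.flatnonzero(is_min)
    if expected_positions is None:
        return [Minimum(float(coord[i]), float(raw[i])) for i in idx]
    out = []
    for pos in expected_positions:
        if idx.size:
            near = idx[np.argmin(np.abs(coord[idx] - pos))]
            if abs(coord[near] - pos) <= window:
                out.append(Minimum(float(coord[near]), float(raw[near]), pos))
                continue
        out.append(Minimum(None, None, pos, missing=True))
    return out


@dataclass
class ConvergenceReport:
    position: float
    values: np.ndarray  # profile value at the position, per block curve
    rms: np.ndarray  # |ΔG_i − ΔG_{i−1}| for consecutive curves
    converged: bool
    tolerance: float


def convergence_rms(curves: list[Curve], position: float,
                    tolerance: float = 1.0) -> ConvergenceReport:
    """RMS of consecutive block-profile values at a fixed position.

    The diagnostic of the time-block analysis: r_i = |ΔG_i − ΔG_{i−1}|
    evaluated (by linear interpolation) at ``position``, with the verdict
    "converged" when the last three r values all fall below ``tolerance``
    (kJ/mol).
    """
    if len(curves) < 2:
        raise ValueError("convergence analysis needs at least 2 block curves")
    coord = curves[0].coord
    if not (coord.min() <= position <= coord.max()):
        raise ValueError(f"position {position} outside the profile grid "
                         f"[{coord.min()}, {coord.max()}]")
    vals = np.array([np.interp(position, c.coord, c.values) for c in curves])
    rms = np.abs(np.diff(vals))
    tail = rms[-3:] if rms.size >= 3 else rms
    return ConvergenceReport(position, vals, rms,
                             bool(np.all(tail < tolerance)), tolerance)
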