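"""Joint CV densities and contour-volume-percentage state regions.

The closed (c) and open (o) reference regions of the hairpin are defined
on the (δ, τ) plane as the smallest set of highest-density cells whose
cumulative probability mass reaches a fraction χ (0.9 in the study): sort
cells by density f descending, take the cumulative sum C, and keep every
cell with C ≤ χ·Z where Z = Σf.  A cell straddling the threshold is
excluded (the rule is kept verbatim, so the enclosed mass is ≤ χ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fes import GridSpec
from .io import ColvarSeries
from .potentials import wrap_tau

__all__ = ["DensityGrid", "StateRegion", "joint_density",
           "contour_volume_mask", "classify_samples"]


@dataclass
class DensityGrid:
    """Normalized joint density f(δ, τ) on grid cells (cell centers stored).

    Σ f·Δδ·Δτ = 1 over in-bounds samples; ``n_out`` counts δ samples that
    fell outside the grid and were excluded from the normalization.
    """

    delta: np.ndarray  # cell centers, nm
    tau: np.ndarray  # cell centers, deg
    values: np.ndarray  # (n_delta, n_tau), ≥ 0
    n_samples: int = 0
    n_out: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def cell_area(self) -> float:
        return float((self.delta[1] - self.delta[0]) * (self.tau[1] - self.tau[0]))

    def cell_index(self, delta, tau):
        """(i, j) cell indices of samples; i = -1 marks out-of-bounds δ."""
        dd = self.delta[1] - self.delta[0]
        dt = self.tau[1] - self.tau[0]
        i = np.floor((np.asarray(delta, float) - (self.delta[0] - dd / 2)) / dd)
        j = np.floor((wrap_tau(tau) - (self.tau[0] - dt / 2)) / dt)
        j = j.astype(int) % self.tau.size  # τ periodic
        i = np.where((i < 0) | (i >= self.delta.size), -1, i).astype(int)
        return i, j


@dataclass
class StateRegion:
    """Top-density cells enclosing a fraction χ of the probability mass."""

    mask: np.ndarray  # boolean, same shape as the density grid
    chi: float
    label: str = ""
    enclosed_mass: float = 0.0  # as a fraction of the total


def joint_density(samples: ColvarSeries, grid_spec: GridSpec = GridSpec(),
                  estimator: str = "histogram",
                  kde_bandwidth=None) -> DensityGrid:
    """Estimate the joint density f(δ, τ) from unbiased CV samples.

    ``histogram`` (default) bins on the FES grid; ``kde`` evaluates a
    Gaussian kernel estimate (Scott bandwidth unless given) on the cell
    centers, with the τ axis handled periodically by ±360° image samples.
    Out-of-bounds δ samples are counted and excluded.
    """
    delta_nodes, tau_nodes = grid_spec.axes()
    dd = grid_spec.delta_spacing
    dt = 360.0 / tau_nodes.size
    d_edges = np.concatenate([delta_nodes - dd / 2, [delta_nodes[-1] + dd / 2]])
    t_edges = np.concatenate([tau_nodes - dt / 2, [tau_nodes[-1] + dt / 2]])

    d = np.asarray(samples.delta, float)
    t = wrap_tau(samples.tau)
    # fold τ samples in [tau_max + dt/2, 180) into the first periodic cell
    t = np.where(t >= t_edges[-1], t - 360.0, t)
    inside = (d >= d_edges[0]) & (d <= d_edges[-1])
    n_out = int(np.sum(~inside))
    d, t = d[inside], t[inside]
    if d.size == 0:
        raise ValueError("no samples fall inside the density grid")

    if estimator == "histogram":
        h, _, _ = np.histogram2d(d, t, bins=[d_edges, t_edges])
        f = h / (d.size * dd * dt)
    elif estimator == "kde":
        from scipy.stats import gaussian_kde
        pts = np.vstack([np.concatenate([d, d, d]),
                         np.concatenate([t - 360.0, t, t + 360.0])])
        kde = gaussian_kde(pts, bw_method=kde_bandwidth)
        cd, ct = np.meshgrid(delta_nodes, tau_nodes, indexing="ij")
        f = kde(np.vstack([cd.ravel(), ct.ravel()])).reshape(cd.shape)
        f /= f.sum() * dd * dt  # renormalize on the periodic window
    else:
        raise ValueError(f"unknown density estimator {estimator!r}")
    return DensityGrid(delta_nodes, tau_nodes, f, n_samples=int(d.size),
                       n_out=n_out, metadata={"estimator": estimator})


def contour_volume_mask(density: DensityGrid, chi: float,
                        label: str = "") -> StateRegion:
    """Smallest set of highest-density cells with cumulative mass ≤ χ·Z.

    Implements the contour-volume-percentage algorithm literally: sort
    cells by f in decreasing order (stable, so ties keep row-major order),
    cumulative-sum, and keep cells with C ≤ χ·Z.  Zero-density cells are
    never part of a region.
    """
    if not (0.0 < chi <= 1.0):
        raise ValueError(f"coverage fraction χ must be in (0, 1], got {chi}")
    f = density.values.ravel()
    order = np.argsort(-f, kind="stable")
    csum = np.cumsum(f[order])
    z = f.sum()
    keep_sorted = (csum <= chi * z) & (f[order] > 0)
    mask = np.zeros(f.size, dtype=bool)
    mask[order[keep_sorted]] = True
    mask = mask.reshape(density.values.shape)
    enclosed = float(density.values[mask].sum() / z) if z > 0 else 0.0
    return StateRegion(mask, chi, label, enclosed)


def classify_samples(samples: ColvarSeries, grid: DensityGrid,
                     regions: dict) -> np.ndarray:
    """Label each sample by state-region membership of its grid cell.

    ``regions`` maps labels (e.g. "c", "o") to :class:`StateRegion` masks
    defined on ``grid``; returns an array of labels, with samples in
    several regions labelled "both" and samples in none "neither".
    """
    items = list(regions.items())
    if not items:
        raise ValueError("no regions given")
    for _, reg in items:
        if reg.mask.shape != grid.values.shape:
            raise ValueError("state regions are defined on different grids")
    i, j = grid.cell_index(samples.delta, samples.tau)
    labels = np.empty(len(samples), dtype=object)
    for n in range(len(samples)):
        if i[n] < 0:
            labels[n] = "neither"
            continue
        hits = [lab for lab, reg in items if reg.mask[i[n], j[n]]]
        labels[n] = hits[0] if len(hits) == 1 else ("both" if hits else "neither")
    return labels
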