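"""Analytic model potentials on the (δ, τ) collective-variable plane.

The sampler runs on a two-dimensional landscape spanned by a distance-like
collective variable δ (nm) and a torsion-like collective variable τ
(degrees, periodic over 360°).  Every potential here has a closed-form
energy and gradient, so the free-energy surface a biased run should
recover is known exactly — that is the whole point of the module: the
downstream reconstruction machinery can be validated against ground truth.

Energies are in kJ/mol.  All evaluators broadcast over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

DELTA_DOMAIN = (0.2, 1.5)  # nm, finite-energy domain


def wrap_tau(tau):
    """Wrap a torsion (degrees) into [-180, 180)."""
    return (np.asarray(tau, dtype=float) + 180.0) % 360.0 - 180.0


def angular_difference(tau, tau0):
    """Minimum-image difference tau - tau0 in degrees, in [-180, 180)."""
    return wrap_tau(np.asarray(tau, dtype=float) - tau0)


@dataclass(frozen=True)
class Basin:
    """One attractive Gaussian basin of the model landscape."""

    center_delta: float  # nm
    center_tau: float  # deg
    depth: float  # kJ/mol, > 0
    width_delta: float = 0.10  # nm
    width_tau: float = 40.0  # deg


@dataclass
class ModelPotential:
    """Analytic potential U(δ, τ) with gradient, periodic in τ.

    Parameters
    ----------
    form
        Identifier of the functional form ("harmonic" or "basins").
    energy_fn, gradient_fn
        Vectorized evaluators; ``gradient_fn`` returns ``(dU/dδ, dU/dτ)``
        in kJ/mol/nm and kJ/mol/deg.
    params
        The parameters the potential was built from (provenance record).
    """

    form: str
    energy_fn: Callable
    gradient_fn: Callable
    params: dict = field(default_factory=dict)

    def energy(self, delta, tau):
        return self.energy_fn(np.asarray(delta, float), np.asarray(tau, float))

    def gradient(self, delta, tau):
        return self.gradient_fn(np.asarray(delta, float), np.asarray(tau, float))

    # ---- ground-truth surfaces -------------------------------------------
    def analytic_fes(self, delta_axis, tau_axis):
        """U on a grid, shifted so its minimum is zero (reference FES)."""
        dd, tt = np.meshgrid(delta_axis, tau_axis, indexing="ij")
        u = self.energy(dd, tt)
        return u - u.min()

    def analytic_fep(self, axis_values, keep_axis, temperature=300.0,
                     n_quad=721):
        """Reference 1D profile by Boltzmann quadrature over the other CV.

        ``keep_axis`` is "delta" or "tau"; the other variable is integrated
        out on ``n_quad`` points.  Returned profile is min-shifted to zero.
        """
        from scipy.special import logsumexp

        from .constants import kbt

        beta = 1.0 / kbt(temperature)
        axis_values = np.asarray(axis_values, float)
        if keep_axis == "delta":
            other = np.linspace(-180.0, 180.0, n_quad, endpoint=False)
            u = self.energy(axis_values[:, None], other[None, :])
        elif keep_axis == "tau":
            other = np.linspace(*DELTA_DOMAIN, n_quad)
            u = self.energy(other[None, :], axis_values[:, None]).T
        else:
            raise ValueError(f"keep_axis must be 'delta' or 'tau', got {keep_axis!r}")
        prof = -logsumexp(-beta * u, axis=1) / beta
        return prof - prof.min()


def _check_domain(center_delta: float, center_tau: float) -> None:
    lo, hi = DELTA_DOMAIN
    if not (lo <= center_delta <= hi):
        raise ValueError(
            f"basin center δ={center_delta} nm outside domain [{lo}, {hi}] nm")
    if not (-180.0 <= center_tau < 180.0):
        raise ValueError(
            f"basin center τ={center_tau}° outside [-180, 180)")


def _harmonic(center: tuple[float, float], k_delta: float, k_tau: float) -> ModelPotential:
    d0, t0 = center

    def energy(d, t):
        return 0.5 * k_delta * (d - d0) ** 2 + 0.5 * k_tau * angular_difference(t, t0) ** 2

    def gradient(d, t):
        return k_delta * (d - d0), k_tau * angular_difference(t, t0)

    return ModelPotential("harmonic", energy, gradient,
                          {"center": center, "k_delta": k_delta, "k_tau": k_tau})


def _basins(basins: Sequence[Basin], edge_kappa: float,
            edge_lo: float, edge_hi: float) -> ModelPotential:
    bs = list(basins)

    def energy(d, t):
        u = np.zeros(np.broadcast(d, t).shape)
        for b in bs:
            u = u - b.depth * np.exp(
                -0.5 * ((d - b.center_delta) / b.width_delta) ** 2
                - 0.5 * (angular_difference(t, b.center_tau) / b.width_tau) ** 2)
        u = u + np.where(d < edge_lo, edge_kappa * (d - edge_lo) ** 2, 0.0)
        u = u + np.where(d > edge_hi, edge_kappa * (d - edge_hi) ** 2, 0.0)
        return u

    def gradient(d, t):
        gd = np.zeros(np.broadcast(d, t).shape)
        gt = np.zeros(np.broadcast(d, t).shape)
        for b in bs:
            xd = (d - b.center_delta) / b.width_delta
            xt = angular_difference(t, b.center_tau) / b.width_tau
            g = b.depth * np.exp(-0.5 * xd**2 - 0.5 * xt**2)
            gd = gd + g * xd / b.width_delta
            gt = gt + g * xt / b.width_tau
        gd = gd + np.where(d < edge_lo, 2.0 * edge_kappa * (d - edge_lo), 0.0)
        gd = gd + np.where(d > edge_hi, 2.0 * edge_kappa * (d - edge_hi), 0.0)
        return gd, gt

    return ModelPotential("basins", energy, gradient,
                          {"basins": bs, "edge_kappa": edge_kappa,
                           "edge_lo": edge_lo, "edge_hi": edge_hi})


def make_potential(form: str, **params) -> ModelPotential:
    """Build a named analytic potential.

    Forms
    -----
    ``harmonic``
        Single well: ``center=(δ0, τ0)``, ``k_delta`` (kJ/mol/nm²),
        ``k_tau`` (kJ/mol/deg², default 0 for a δ-only well).
    ``basins``
        Sum of attractive Gaussian basins (``basins=[Basin, ...]`` or tuples
        ``(δ0, τ0, depth[, wδ, wτ])``) plus soft quadratic edges confining δ
        to ``[edge_lo, edge_hi]`` (``edge_kappa`` kJ/mol/nm², default 2000).

    Raises
    ------
    ValueError
        Unknown form, basin centers outside the domain, or non-positive
        depths/stiffnesses.
    """
    if form == "harmonic":
        center = params.get("center", (0.5, -150.0))
        k_delta = params.get("k_delta", 100.0)
        k_tau = params.get("k_tau", 0.0)
        _check_domain(*center)
        if k_delta <= 0 or k_tau < 0:
            raise ValueError("harmonic stiffness must be positive (k_tau may be 0)")
        return _harmonic(tuple(center), float(k_delta), float(k_tau))
    if form == "basins":
        raw = params.get("basins")
        if not raw:
            raise ValueError("'basins' form needs a non-empty basins list")
        basins = [b if isinstance(b, Basin) else Basin(*b) for b in raw]
        for b in basins:
            _check_domain(b.center_delta, b.center_tau)
            if b.depth <= 0 or b.width_delta <= 0 or b.width_tau <= 0:
                raise ValueError("basin depths and widths must be positive")
        return _basins(basins,
                       float(params.get("edge_kappa", 2000.0)),
                       float(params.get("edge_lo", 0.3)),
                       float(params.get("edge_hi", 1.4)))
    raise ValueError(f"unknown potential form {form!r}")


def hairpin_double_well() -> ModelPotential:
    """Default two-basin landscape emulating the hairpin closed/open states.

    Basins sit at (0.47 nm, -150°) and (0.81 nm, -60°) — the closed- and
    open-hairpin minima of the HFBI collective-variable plane — with depths
    14 and 10 kJ/mol and widths 0.10 nm / 40°.
    """
    return make_potential(
        "basins",
        basins=[Basin(0.47, -150.0, 14.0), Basin(0.81, -60.0, 10.0)],
    )


def wall_bias(delta, a: float = 1.3, kappa: float = 2000.0):
    """One-sided upper-wall energy κ·(δ−a)² for δ > a, else 0.

    PLUMED UPPER_WALLS convention (no ½ factor); continuous at δ = a.
    """
    if kappa < 0:
        raise ValueError("wall stiffness κ must be non-negative")
    d = np.asarray(delta, dtype=float)
    out = np.where(d > a, kappa * (d - a) ** 2, 0.0)
    return float(out) if np.isscalar(delta) else out


def wall_force(delta, a: float = 1.3, kappa: float = 2000.0):
    """dE/dδ of :func:`wall_bias` (2κ·(δ−a) above the wall, else 0)."""
    d = np.asarray(delta, dtype=float)
    out = np.where(d > a, 2.0 * kappa * (d - a), 0.0)
    return float(out) if np.isscalar(delta) else out
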