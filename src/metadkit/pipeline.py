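"""Declarative end-to-end pipeline: simulate → FES → profiles → states.

One YAML config drives the chain: a biased Langevin run on the model
landscape, hill summation to the 2D surface, block profiles with the
convergence diagnostic, joint densities with the contour-volume state
regions, and sample classification.  Each run writes a manifest recording
the effective parameters, input hashes and outputs, and identical
config + seed reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fes as fes_mod
from . import io as io_mod
from .density import classify_samples, contour_volume_mask, joint_density
from .potentials import hairpin_double_well
from .simulate import SimulationConfig, run_langevin_metad

log = logging.getLogger("metadkit.pipeline")

ALL_STAGES = ["simulate", "fes", "fep", "convergence", "density", "contour",
              "classify"]


@dataclass
class GridSection:
    delta_min: float = 0.3
    delta_max: float = 1.4
    spacing: float = 0.035
    tau_bins: int | None = None

    def to_spec(self) -> fes_mod.GridSpec:
        return fes_mod.GridSpec(self.delta_min, self.delta_max,
                                self.spacing, self.tau_bins)


@dataclass
class SimulateSection:
    n_steps: int = 500_000
    timestep: float = 0.2
    pace: int = 200
    temperature: float = 300.0
    bias_factor: float = 10.0
    hill_height: float | None = None
    sigma_delta: float = 0.1
    sigma_tau: float | None = None  # None -> 0.1 rad in degrees
    wall_a: float = 1.3
    wall_kappa: float = 2000.0
    colvar_stride: int = 25
    initial_delta: float = 0.47
    initial_tau: float = -150.0


@dataclass
class FepSection:
    axis: str = "delta"
    block_length_ns: float = 10.0
    n_avg_blocks: int = 5
    cumulative: bool = True
    temperature: float = 300.0
    wt_rescale: bool = True
    expected_minima: tuple = (0.47, 0.81, 1.25)
    minima_window: float = 0.1


@dataclass
class ConvergenceSection:
    position: float = 1.25
    tolerance: float = 1.0


@dataclass
class DensitySection:
    chi: float = 0.90
    estimator: str = "histogram"

    def __post_init__(self):
        if not (0.0 < self.chi <= 1.0):
            raise ValueError(f"density.chi must be in (0, 1], got {self.chi}")


@dataclass
class PipelineConfig:
    seed: int = 1
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    output_dir: str = "metadkit_out"
    hills: str | None = None  # external HILLS input (else from simulate)
    colvar: str | None = None
    grid: GridSection = field(default_factory=GridSection)
    simulate: SimulateSection = field(default_factory=SimulateSection)
    fep: FepSection = field(default_factory=FepSection)
    convergence: ConvergenceSection = field(default_factory=ConvergenceSection)
    density: DensitySection = field(default_factory=DensitySection)
    log_level: str = "INFO"


_SECTIONS = {"grid": GridSection, "simulate": SimulateSection,
             "fep": FepSection, "convergence": ConvergenceSection,
             "density": DensitySection}


def _build(cls, mapping: dict, path: str):
    known = {f.name: f for f in dc_fields(cls)}
    kwargs = {}
    for key, value in mapping.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {path}{key!r}{extra}")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ValueError(f"bad value under {path!r}: {exc}") from exc


def validate_config(raw) -> PipelineConfig:
    """Parse and validate a pipeline config (YAML text, dict, or path).

    Unknown keys are rejected with a nearest-key suggestion; omitted keys
    take the study defaults (grid spacing 0.035 nm, χ = 0.90, γ = 10,
    wall 1.3 nm / 2000 kJ/mol/nm², 10 ns blocks averaged over the last 5).
    """
    if (isinstance(raw, (str, Path)) and str(raw).strip()
            and "\n" not in str(raw) and Path(raw).is_file()):
        raw = Path(raw).read_text()
    data = yaml.safe_load(raw) if isinstance(raw, (str, Path)) else raw
    data = {} if data is None else dict(data)
    top = {f.name: f for f in dc_fields(PipelineConfig)}
    kwargs = {}
    for key, value in data.items():
        if key not in top:
            hint = difflib.get_close_matches(key, top, n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{extra}")
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            kwargs[key] = _build(_SECTIONS[key], value, f"{key}.")
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    for stage in cfg.stages:
        if stage not in ALL_STAGES:
            hint = difflib.get_close_matches(stage, ALL_STAGES, n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown stage {stage!r}{extra}")
    if cfg.seed is None:
        raise ValueError("an explicit seed is required")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; returns the manifest."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid_spec = config.grid.to_spec()
    manifest = {"config": json.loads(json.dumps(config, default=vars)),
                "inputs": {}, "outputs": []}
    stages = [s for s in ALL_STAGES if s in config.stages]

    # pre-run validation of external inputs
    for name in ("hills", "colvar"):
        path = getattr(config, name)
        if path is not None:
            if not Path(path).exists():
                raise FileNotFoundError(f"configured {name} input not found: {path}")
            manifest["inputs"][name] = {"path": str(path),
                                        "sha256": _sha256(Path(path))}
    needs_hills = any(s in stages for s in ("fes", "fep", "convergence"))
    if needs_hills and "simulate" not in stages and config.hills is None:
        raise ValueError("fes/fep stages need either a simulate stage or a "
                         "hills input path")
    needs_colvar = any(s in stages for s in ("density", "contour", "classify"))
    if needs_colvar and "simulate" not in stages and config.colvar is None:
        raise ValueError("density stages need either a simulate stage or a "
                         "colvar input path")

    hills = colvar = None
    if "simulate" in stages:
        log.info("simulate: %d steps, seed %d", config.simulate.n_steps, config.seed)
        sim = config.simulate
        sim_cfg = SimulationConfig(
            seed=config.seed, temperature=sim.temperature,
            bias_factor=sim.bias_factor, hill_height=sim.hill_height,
            sigma_delta=sim.sigma_delta,
            **({} if sim.sigma_tau is None else {"sigma_tau": sim.sigma_tau}),
            pace=sim.pace, wall_a=sim.wall_a, wall_kappa=sim.wall_kappa,
            timestep=sim.timestep, n_steps=sim.n_steps,
            colvar_stride=sim.colvar_stride, initial_delta=sim.initial_delta,
            initial_tau=sim.initial_tau)
        colvar, hills = run_langevin_metad(hairpin_double_well(), sim_cfg)
        io_mod.write_hills(hills, out / "HILLS")
        io_mod.write_colvar(colvar, out / "COLVAR")
        manifest["outputs"] += ["HILLS", "COLVAR"]
    if hills is None and config.hills:
        hills = io_mod.read_hills(config.hills)
    if colvar is None and config.colvar:
        colvar = io_mod.read_colvar(config.colvar)

    if "fes" in stages:
        log.info("fes: summing %d hills", len(hills))
        grid = fes_mod.sum_hills(hills, grid_spec,
                                 wt_rescale=config.fep.wt_rescale)
        header = ("delta_nm tau_deg F_kJ_mol")
        dd, tt = np.meshgrid(grid.delta, grid.tau, indexing="ij")
        np.savetxt(out / "fes.dat",
                   np.column_stack([dd.ravel(), tt.ravel(), grid.values.ravel()]),
                   header=header, fmt="%.10g")
        manifest["outputs"].append("fes.dat")

    curves = None
    if "fep" in stages or "convergence" in stages:
        curves = fes_mod.block_profiles(
            hills, grid_spec, config.fep.block_length_ns * 1000.0,
            config.fep.axis, config.fep.temperature, config.fep.cumulative,
            config.fep.wt_rescale)
    if "fep" in stages:
        prof = fes_mod.profile_stats(curves, config.fep.n_avg_blocks)
        prof.minima = fes_mod.find_minima(prof, config.fep.expected_minima,
                                          config.fep.minima_window)
        _write_csv(pd.DataFrame({
            "coord": prof.coord, "mean": prof.mean, "sem": prof.sem,
            "ci_lo": prof.mean - prof.ci95, "ci_hi": prof.mean + prof.ci95}),
            out / "fep.csv")
        _write_csv(pd.DataFrame([
            {"expected": m.expected, "position": m.position,
             "delta_g": m.value, "missing": m.missing} for m in prof.minima]),
            out / "fep_minima.csv")
        manifest["outputs"] += ["fep.csv", "fep_minima.csv"]
    if "convergence" in stages:
        rep = fes_mod.convergence_rms(curves, config.convergence.position,
                                      config.convergence.tolerance)
        _write_csv(pd.DataFrame({
            "block": np.arange(1, len(rep.values) + 1),
            "value": rep.values,
            "rms_prev": np.concatenate([[np.nan], rep.rms])}),
            out / "convergence.csv")
        manifest["outputs"].append("convergence.csv")
        manifest["converged"] = rep.converged
        log.info("convergence at %.3f nm: %s", rep.position, rep.converged)

    density = None
    if "density" in stages or "contour" in stages or "classify" in stages:
        density = joint_density(colvar, grid_spec, config.density.estimator)
    if "density" in stages:
        dd, tt = np.meshgrid(density.delta, density.tau, indexing="ij")
        _write_csv(pd.DataFrame({"delta": dd.ravel(), "tau": tt.ravel(),
                                 "f": density.values.ravel()}),
                   out / "density.csv")
        manifest["outputs"].append("density.csv")
    region = None
    if "contour" in stages or "classify" in stages:
        region = contour_volume_mask(density, config.density.chi, label="c")
    if "contour" in stages:
        dd, tt = np.meshgrid(density.delta, density.tau, indexing="ij")
        di, ti = np.meshgrid(np.arange(density.delta.size),
                             np.arange(density.tau.size), indexing="ij")
        _write_csv(pd.DataFrame({
            "delta_index": di.ravel(), "tau_index": ti.ravel(),
            "delta": dd.ravel(), "tau": tt.ravel(),
            "f": density.values.ravel(),
            "in_region": region.mask.ravel().astype(int)}),
            out / "mask.csv")
        manifest["outputs"].append("mask.csv")
        manifest["enclosed_mass"] = region.enclosed_mass
    if "classify" in stages:
        labels = classify_samples(colvar, density, {"c": region})
        _write_csv(pd.DataFrame({"time": colvar.time, "delta": colvar.delta,
                                 "tau": colvar.tau, "label": labels}),
                   out / "labels.csv")
        manifest["outputs"].append("labels.csv")

    manifest["seed"] = config.seed
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
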