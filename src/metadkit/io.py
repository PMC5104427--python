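"""Readers and writers for PLUMED-dialect HILLS/COLVAR files and multi-model PDB.

HILLS and COLVAR are whitespace-separated text tables whose column order is
declared by a leading ``#! FIELDS ...`` header; ``#! SET key value`` lines
carry scalar metadata.  Numeric output uses 12 significant digits so a
write/read cycle is the identity on the stored records.

PDB reading goes through Biopython (altloc disorder, insertion codes);
writing emits standard fixed-column ATOM/HETATM records with MODEL/ENDMDL
blocks.  Files ending in ``.gz`` are handled transparently.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .potentials import wrap_tau

__all__ = [
    "MetadFormatError", "HillSeries", "ColvarSeries",
    "read_hills", "write_hills", "read_colvar", "write_colvar",
    "StructureModel", "TrajectoryFrames", "read_pdb_models", "write_pdb_models",
]


class MetadFormatError(ValueError):
    """Raised when an input file does not follow the expected format."""


HILLS_FIELDS = ["time", "delta", "tau", "sigma_delta", "sigma_tau", "height", "biasf"]
COLVAR_FIELDS = ["time", "delta", "tau"]
_FMT = "%.11e"  # 12 significant digits


@dataclass
class HillSeries:
    """Deposited Gaussian bias hills.

    Arrays are parallel; times are ps, centers (nm, deg), widths (nm, deg),
    heights kJ/mol.  ``bias_factor`` is the (constant) well-tempered γ.
    """

    time: np.ndarray
    center_delta: np.ndarray
    center_tau: np.ndarray
    sigma_delta: np.ndarray
    sigma_tau: np.ndarray
    height: np.ndarray
    bias_factor: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("time", "center_delta", "center_tau",
                     "sigma_delta", "sigma_tau", "height"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self) and (np.any(self.sigma_delta <= 0) or np.any(self.sigma_tau <= 0)):
            raise ValueError("hill widths must be positive")
        if len(self) and np.any(self.height < 0):
            raise ValueError("hill heights must be non-negative")
        if len(self) and np.any(np.diff(self.time) < 0):
            warnings.warn("hill times are not non-decreasing", stacklevel=2)

    def __len__(self) -> int:
        return self.time.size

    @classmethod
    def empty(cls, bias_factor: float = 10.0) -> "HillSeries":
        z = np.empty(0)
        return cls(z, z, z, z, z, z, bias_factor)

    def until(self, time_cutoff: float) -> "HillSeries":
        """Hills deposited at t ≤ time_cutoff (ps)."""
        keep = self.time <= time_cutoff
        return HillSeries(self.time[keep], self.center_delta[keep],
                         self.center_tau[keep], self.sigma_delta[keep],
                         self.sigma_tau[keep], self.height[keep],
                         self.bias_factor, dict(self.metadata))


@dataclass
class ColvarSeries:
    """Time series of collective-variable samples (time ps, δ nm, τ deg)."""

    time: np.ndarray
    delta: np.ndarray
    tau: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.tau = wrap_tau(self.tau)

    def __len__(self) -> int:
        return self.time.size


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_plumed(path, expected_fields):
    """Parse a PLUMED-style table; returns (columns dict, metadata dict)."""
    fields = None
    meta = {}
    rows = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#!"):
                parts = line.split()
                if len(parts) >= 2 and parts[1] == "FIELDS":
                    fields = parts[2:]
                elif len(parts) >= 4 and parts[1] == "SET":
                    meta[parts[2]] = " ".join(parts[3:])
                continue
            if line.startswith("#"):
                continue
            if fields is None:
                raise MetadFormatError(
                    f"{path}: data on line {lineno} before '#! FIELDS' header")
            vals = line.split()
            if len(vals) != len(fields):
                raise MetadFormatError(
                    f"{path}: line {lineno} has {len(vals)} values, "
                    f"FIELDS declares {len(fields)}")
            rows.append([float(v) for v in vals])
    if fields is None:
        raise MetadFormatError(f"{path}: missing '#! FIELDS' header line")
    missing = [f for f in expected_fields if f not in fields]
    if missing:
        raise MetadFormatError(f"{path}: FIELDS is missing column(s) {missing}")
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(fields))
    cols = {f: data[:, i] for i, f in enumerate(fields)}
    return cols, meta


def read_hills(path) -> HillSeries:
    """Read a PLUMED-dialect HILLS file (column order per its FIELDS line)."""
    cols, meta = _parse_plumed(path, HILLS_FIELDS)
    t = cols["time"]
    if t.size and np.any(np.diff(t) < 0):
        warnings.warn(f"{path}: hill times are not non-decreasing", stacklevel=2)
    biasf = cols["biasf"]
    if biasf.size:
        if not np.allclose(biasf, biasf[0]):
            raise MetadFormatError(f"{path}: bias factor varies within the series")
        gamma = float(biasf[0])
    else:
        gamma = float(meta.get("biasfactor", 10.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # monotonicity already reported above
        return HillSeries(t, cols["delta"], cols["tau"], cols["sigma_delta"],
                          cols["sigma_tau"], cols["height"], gamma, meta)


def write_hills(hills: HillSeries, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("#! FIELDS " + " ".join(HILLS_FIELDS) + "\n")
        for k, v in hills.metadata.items():
            fh.write(f"#! SET {k} {v}\n")
        for i in range(len(hills)):
            row = (hills.time[i], hills.center_delta[i], hills.center_tau[i],
                   hills.sigma_delta[i], hills.sigma_tau[i], hills.height[i],
                   hills.bias_factor)
            fh.write(" ".join(_FMT % v for v in row) + "\n")


def read_colvar(path) -> ColvarSeries:
    """Read a COLVAR file; τ is wrapped into [-180, 180) on read."""
    cols, meta = _parse_plumed(path, COLVAR_FIELDS)
    return ColvarSeries(cols["time"], cols["delta"], cols["tau"], meta)


def write_colvar(colvar: ColvarSeries, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("#! FIELDS " + " ".join(COLVAR_FIELDS) + "\n")
        for k, v in colvar.metadata.items():
            fh.write(f"#! SET {k} {v}\n")
        for i in range(len(colvar)):
            fh.write(" ".join(_FMT % v for v in
                              (colvar.time[i], colvar.delta[i], colvar.tau[i])) + "\n")


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """One coordinate frame: parallel per-atom arrays, coordinates in Å."""

    chain_ids: np.ndarray  # str
    resids: np.ndarray  # int, PDB numbering (1-based)
    icodes: np.ndarray  # str, insertion codes ('' if none)
    resnames: np.ndarray  # str
    atom_names: np.ndarray  # str
    elements: np.ndarray  # str
    coords: np.ndarray  # (n, 3) float, Å
    is_hetero: np.ndarray  # bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure model")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def mask(self, keep: np.ndarray) -> "StructureModel":
        return StructureModel(self.chain_ids[keep], self.resids[keep],
                              self.icodes[keep], self.resnames[keep],
                              self.atom_names[keep], self.elements[keep],
                              self.coords[keep], self.is_hetero[keep])

    def select_chains(self, chains) -> "StructureModel":
        chains = {chains} if isinstance(chains, str) else set(chains)
        return self.mask(np.isin(self.chain_ids, sorted(chains)))

    def find_atom(self, chain: str, resid: int, atom_name: str) -> int:
        """Index of the (chain, residue, atom-name) atom; raises if absent."""
        hit = np.flatnonzero((self.chain_ids == chain) & (self.resids == resid)
                             & (self.atom_names == atom_name))
        if hit.size == 0:
            raise KeyError(f"atom {atom_name} of residue {resid} chain {chain} not found")
        return int(hit[0])


@dataclass
class TrajectoryFrames:
    """A sequence of structure models (e.g. models of a multi-model PDB)."""

    frames: list
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> StructureModel:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name.lstrip("0123456789")
    if name[:2].upper() in ("CL", "BR", "ZN", "NA", "MG", "FE", "MN") and len(name) >= 2:
        return name[:2].capitalize()
    return name[:1].upper()


def read_pdb_models(path, include_waters: bool = True) -> TrajectoryFrames:
    """Read a (multi-model) PDB file into trajectory frames.

    Disordered atoms keep the highest-occupancy altloc (ties: the first
    listed).  Raises :class:`MetadFormatError` when no ATOM/HETATM records
    are present.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    if str(path).endswith(".gz"):
        with _open(path) as fh:
            structure = parser.get_structure("m", fh)
    else:
        structure = parser.get_structure("m", str(path))

    frames = []
    for model in structure:
        chain_ids, resids, icodes, resnames = [], [], [], []
        atom_names, elements, coords, het = [], [], [], []
        for chain in model:
            for residue in chain:
                hetfield, resseq, icode = residue.id
                is_het = hetfield.strip() != ""
                is_water = residue.resname.strip() in ("HOH", "WAT", "SOL")
                if is_water and not include_waters:
                    continue
                for atom in residue:
                    # Bio.PDB yields DisorderedAtom wrappers; pick the
                    # highest-occupancy altloc, first-listed on ties.
                    if atom.is_disordered():
                        alts = atom.disordered_get_list()
                        occ = [a.get_occupancy() or 0.0 for a in alts]
                        atom = alts[int(np.argmax(occ))]
                    chain_ids.append(chain.id)
                    resids.append(resseq)
                    icodes.append(icode.strip())
                    resnames.append(residue.resname.strip())
                    atom_names.append(atom.get_name())
                    elem = (atom.element or "").strip() or _guess_element(atom.get_name())
                    elements.append(elem.capitalize())
                    coords.append(atom.get_coord())
                    het.append(is_het)
        if chain_ids:
            frames.append(StructureModel(
                np.asarray(chain_ids), np.asarray(resids, dtype=int),
                np.asarray(icodes), np.asarray(resnames),
                np.asarray(atom_names), np.asarray(elements),
                np.asarray(coords, dtype=float), np.asarray(het, dtype=bool)))
    if not frames:
        raise MetadFormatError(f"{path}: no ATOM/HETATM records found")
    return TrajectoryFrames(frames)


def _pdb_atom_line(serial, name, resname, chain, resid, icode, xyz, element, het):
    record = "HETATM" if het else "ATOM  "
    # PDB atom-name column convention: 1-2 char element names start in col 14
    name = name if len(name) >= 4 else f" {name:<3s}"
    return (f"{record}{serial:5d} {name:<4.4s} {resname:<3.3s} {chain:1.1s}"
            f"{resid:4d}{icode:1.1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2.2s}\n")


def write_pdb_models(frames: TrajectoryFrames, path) -> None:
    """Write frames as a multi-model PDB (MODEL/ENDMDL per frame)."""
    multi = len(frames) > 1
    with _open(path, "wt") as fh:
        for imodel, m in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for i in range(m.n_atoms):
                fh.write(_pdb_atom_line(
                    (i + 1) % 100000, str(m.atom_names[i]), str(m.resnames[i]),
                    str(m.chain_ids[i]), int(m.resids[i]),
                    str(m.icodes[i]) or " ", m.coords[i],
                    str(m.elements[i]), bool(m.is_hetero[i])))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
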