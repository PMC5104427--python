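"""Per-structure and per-trajectory analytics.

Covers the geometric collective variables (the CA30–CA65 distance δ and
the C59–N60–CA60–C60 torsion τ), hydrogen-bond detection and persistence
with the four-group decomposition around the hairpin (residues 60–66),
Shrake–Rupley solvent-accessible surface area, the interface-area formula
SASA_i + SASA_j − SASA_{i,j}, residue minimum-distance maps and the
0.45 nm contact rule, the nonpolar solvation model G = γ·SASA + b,
Welch's t-test, and block-averaged RMSF.

Distances are handled in Å internally (PDB native) and reported in nm
where the corresponding convention is nm (CVs, H-bond cutoffs, distance
maps); SASA is reported in Å² as the solvation coefficients expect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import StructureModel, TrajectoryFrames

__all__ = [
    "compute_delta", "compute_tau", "detect_hbonds", "hbond_persistence",
    "classify_hbond_group", "HBondStat", "sasa", "interface_area",
    "InterfaceReport", "distance_map", "contact_residues",
    "nonpolar_solvation", "welch_t", "rmsf",
    "GAMMA_SURF", "B_SURF", "BONDI_RADII",
]

# Nonpolar solvation model coefficients (g_mmpbsa SASA model):
# G_nonpolar = γ·SASA + b with SASA in Å².
GAMMA_SURF = 0.0226778  # kJ mol^-1 Å^-2
B_SURF = 3.84982  # kJ/mol

#: Bondi van der Waals radii, Å.
BONDI_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
               "P": 1.80, "F": 1.47, "Cl": 1.75, "Zn": 1.39}
DEFAULT_RADIUS = 1.50

WATER_RESNAMES = {"HOH", "WAT", "SOL"}
HAIRPIN_RANGE = (60, 66)


# ---------------------------------------------------------------------------
# collective variables
# ---------------------------------------------------------------------------

def compute_delta(model: StructureModel, chain: str,
                  resid_a: int = 30, resid_b: int = 65) -> float:
    """CA–CA distance between two residues of a chain, in nm.

    Defaults to the hairpin-opening coordinate CA30–CA65.
    """
    i = model.find_atom(chain, resid_a, "CA")
    j = model.find_atom(chain, resid_b, "CA")
    return float(np.linalg.norm(model.coords[i] - model.coords[j])) / 10.0


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees, IUPAC sign convention, in (-180, 180]."""
    b0, b2 = p0 - p1, p3 - p2
    b1 = (p2 - p1) / np.linalg.norm(p2 - p1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def compute_tau(model: StructureModel, chain: str, resid: int = 60) -> float:
    """Backbone torsion C(i−1)–N(i)–CA(i)–C(i) in degrees (default i = 60)."""
    atoms = [(resid - 1, "C"), (resid, "N"), (resid, "CA"), (resid, "C")]
    pts = [model.coords[model.find_atom(chain, r, a)] for r, a in atoms]
    return _dihedral(*pts)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

AtomId = tuple  # (chain, resid, atom_name)


def _donor_hydrogens(model: StructureModel, bond_cut: float = 1.25):
    """Map each N/O donor atom index to its covalently attached H indices
    (same residue, within ``bond_cut`` Å)."""
    donors = {}
    h_idx = np.flatnonzero(model.elements == "H")
    heavy = np.flatnonzero(np.isin(model.elements, ["N", "O"]))
    if h_idx.size == 0 or heavy.size == 0:
        return donors
    tree = cKDTree(model.coords[h_idx])
    for d in heavy:
        near = tree.query_ball_point(model.coords[d], bond_cut)
        attached = [int(h_idx[k]) for k in near
                    if model.chain_ids[h_idx[k]] == model.chain_ids[d]
                    and model.resids[h_idx[k]] == model.resids[d]]
        if attached:
            donors[int(d)] = attached
    return donors


def detect_hbonds(model: StructureModel, d_cut: float = 0.35,
                  angle_cut: float = 30.0) -> list:
    """Geometric hydrogen bonds in one frame (GROMACS-style criterion).

    A bond is an N/O donor with an attached hydrogen and an N/O acceptor
    with donor–acceptor distance ≤ ``d_cut`` (nm) and H–donor–acceptor
    angle ≤ ``angle_cut`` (degrees); both boundaries closed.  Donor and
    acceptor in the same residue are excluded (no topology available for
    finer bonded exclusions).  Returns ``(donor AtomId, acceptor AtomId)``
    pairs.
    """
    d_cut_a = d_cut * 10.0  # nm -> Å
    donors = _donor_hydrogens(model)
    acceptors = np.flatnonzero(np.isin(model.elements, ["N", "O"]))
    if not donors or acceptors.size == 0:
        return []
    tree = cKDTree(model.coords[acceptors])
    events = []
    for d, hs in donors.items():
        pd = model.coords[d]
        for k in tree.query_ball_point(pd, d_cut_a):
            a = int(acceptors[k])
            if (model.chain_ids[a] == model.chain_ids[d]
                    and model.resids[a] == model.resids[d]):
                continue
            va = model.coords[a] - pd
            ra = np.linalg.norm(va)
            # closed boundaries with a small slack so that geometries built
            # exactly at the cutoffs are detected despite float rounding
            if ra > d_cut_a + 1e-9 or ra == 0.0:
                continue
            for h in hs:
                vh = model.coords[h] - pd
                cosang = float(np.dot(vh, va) / (np.linalg.norm(vh) * ra))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if ang <= angle_cut + 1e-9:
                    events.append((
                        (str(model.chain_ids[d]), int(model.resids[d]),
                         str(model.atom_names[d])),
                        (str(model.chain_ids[a]), int(model.resids[a]),
                         str(model.atom_names[a]))))
                    break  # one event per donor-acceptor pair and frame
    return events


@dataclass
class HBondStat:
    donor: AtomId
    acceptor: AtomId
    persistence: float  # fraction of frames, (0.05, 1]
    group: str = ""


def hbond_persistence(frames: TrajectoryFrames, d_cut: float = 0.35,
                      angle_cut: float = 30.0,
                      min_persistence: float = 0.05):
    """Per-pair H-bond persistence over a trajectory.

    Persistence is the number of frames in which a (donor, acceptor) pair
    is bonded divided by the total number of frames; only pairs with
    persistence strictly above ``min_persistence`` (5%) are retained.
    Returns ``(stats, mean_per_frame)`` where ``mean_per_frame`` is the
    average number of detected H-bonds per frame before filtering.
    """
    if len(frames) == 0:
        raise ValueError("H-bond persistence needs at least one frame")
    counts: dict = {}
    total_events = 0
    for m in frames:
        events = detect_hbonds(m, d_cut, angle_cut)
        total_events += len(events)
        for pair in events:
            counts[pair] = counts.get(pair, 0) + 1
    n = len(frames)
    stats = [HBondStat(d, a, c / n) for (d, a), c in sorted(counts.items())
             if c / n > min_persistence]
    return stats, total_events / n


def classify_hbond_group(stat: HBondStat, subject_chain: str,
                         facing_chain: str | None = None,
                         hairpin_range: tuple = HAIRPIN_RANGE,
                         water_resnames=frozenset(WATER_RESNAMES),
                         donor_resname: str = "", acceptor_resname: str = "") -> str:
    """Assign an H-bond to one of the four hairpin-centred groups.

    intra-hairpin: both partners inside residues 60–66 of the subject
    chain; intra-chain: hairpin to the rest of the same chain;
    inter-chain: hairpin to the facing chain; hairpin-solvent: hairpin to
    water.  Bonds touching neither hairpin nor solvent are "unclassified".
    """
    lo, hi = hairpin_range

    def in_hairpin(atom):
        chain, resid, _ = atom
        return chain == subject_chain and lo <= resid <= hi

    d_hp, a_hp = in_hairpin(stat.donor), in_hairpin(stat.acceptor)
    d_wat = donor_resname in water_resnames
    a_wat = acceptor_resname in water_resnames
    if (d_hp and a_wat) or (a_hp and d_wat):
        return "hairpin-solvent"
    if d_hp and a_hp:
        return "intra-hairpin"
    if d_hp or a_hp:
        other = stat.acceptor if d_hp else stat.donor
        if other[0] == subject_chain:
            return "intra-chain"
        if facing_chain is None or other[0] == facing_chain:
            return "inter-chain"
    return "unclassified"


def hairpin_solvent_profile(frames: TrajectoryFrames, subject_chain: str,
                            hairpin_range: tuple = HAIRPIN_RANGE,
                            d_cut: float = 0.35, angle_cut: float = 30.0):
    """Mean H-bonds per frame between each hairpin residue and water."""
    lo, hi = hairpin_range
    counts = {r: 0 for r in range(lo, hi + 1)}
    for m in frames:
        resname_of = {}
        for c, r, nm in zip(m.chain_ids, m.resids, m.resnames):
            resname_of[(c, r)] = nm
        for don, acc in detect_hbonds(m, d_cut, angle_cut):
            for hp_atom, other in ((don, acc), (acc, don)):
                if (hp_atom[0] == subject_chain and lo <= hp_atom[1] <= hi
                        and resname_of[(other[0], other[1])] in WATER_RESNAMES):
                    counts[hp_atom[1]] += 1
    n = max(len(frames), 1)
    return {r: c / n for r, c in counts.items()}


# ---------------------------------------------------------------------------
# SASA and interfaces
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral)."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(model: StructureModel, probe_radius: float = 1.4,
         n_points: int = 960, radii: dict | None = None,
         strict_elements: bool = False):
    """Shrake–Rupley solvent-accessible surface area, Å².

    Rolls a probe of ``probe_radius`` Å over Bondi van der Waals spheres
    sampled with ``n_points`` deterministic test points per atom.  Returns
    ``(total, per_atom)``.  Unknown elements fall back to 1.5 Å unless
    ``strict_elements`` is set.
    """
    table = BONDI_RADII if radii is None else radii
    r = np.empty(model.n_atoms)
    for i, el in enumerate(model.elements):
        if el in table:
            r[i] = table[el]
        elif strict_elements:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        else:
            r[i] = DEFAULT_RADIUS
    r = r + probe_radius
    pts = _sphere_points(n_points)
    coords = model.coords
    tree = cKDTree(coords)
    per_atom = np.zeros(model.n_atoms)
    max_r = r.max()
    for i in range(model.n_atoms):
        test = coords[i] + r[i] * pts
        # exactly coincident equal-radius spheres are degenerate duplicates:
        # only the first-listed one keeps surface (deterministic tie-break)
        neighbors = []
        for j in tree.query_ball_point(coords[i], r[i] + max_r):
            if j == i:
                continue
            if r[j] == r[i] and np.array_equal(coords[j], coords[i]):
                if j < i:
                    neighbors = None  # fully occluded by its earlier twin
                    break
                continue
            neighbors.append(j)
        if neighbors is None:
            continue
        if neighbors:
            d2 = ((test[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(-1)
            exposed = np.all(d2 > (r[neighbors] ** 2)[None, :], axis=1)
            frac = float(np.sum(exposed)) / n_points
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * math.pi * r[i] ** 2
    return float(per_atom.sum()), per_atom


@dataclass
class InterfaceReport:
    chain_i: str
    chain_j: str
    series: np.ndarray  # per-frame interface area, Å²
    mean: float
    ci95: float  # half-width, 1.96·SEM over frames


def interface_area(frames: TrajectoryFrames, chain_i: str, chain_j: str,
                   **sasa_kwargs) -> InterfaceReport:
    """Interface area SASA_i + SASA_j − SASA_{i,j} per frame, Å².

    Isolated-chain SASA is computed with the partner (and any other
    chains) removed; the pair term on the two chains together.  The full
    difference is kept (no ½ factor), i.e. the solvent area the pair
    loses on contact.  The mean comes with a 95% confidence half-width
    (1.96·SEM over frames).
    """
    vals = np.empty(len(frames))
    for k, m in enumerate(frames):
        for ch in (chain_i, chain_j):
            if not np.any(m.chain_ids == ch):
                raise ValueError(f"chain {ch!r} missing in frame {k}")
        s_i, _ = sasa(m.select_chains(chain_i), **sasa_kwargs)
        s_j, _ = sasa(m.select_chains(chain_j), **sasa_kwargs)
        s_ij, _ = sasa(m.select_chains([chain_i, chain_j]), **sasa_kwargs)
        vals[k] = s_i + s_j - s_ij
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return InterfaceReport(chain_i, chain_j, vals, mean, 1.96 * sem)


def distance_map(frames: TrajectoryFrames, chain_i: str, chain_j: str):
    """Residue-pair mean minimum heavy-atom distances, nm.

    For every frame the smallest heavy-atom distance of each residue pair
    is found, then averaged over frames.  Returns a dict keyed by
    ``(resid_i, resid_j)``.
    """
    if len(frames) == 0:
        raise ValueError("distance map needs at least one frame")
    sums: dict = {}
    for m in frames:
        a = m.select_chains(chain_i)
        b = m.select_chains(chain_j)
        a = a.mask(a.elements != "H")
        b = b.mask(b.elements != "H")
        if a.n_atoms == 0 or b.n_atoms == 0:
            raise ValueError("empty chain in distance map")
        d = np.sqrt(((a.coords[:, None, :] - b.coords[None, :, :]) ** 2).sum(-1))
        res_a = np.unique(a.resids)
        res_b = np.unique(b.resids)
        for ra in res_a:
            rows = a.resids == ra
            for rb in res_b:
                dmin = d[rows][:, b.resids == rb].min() / 10.0  # Å -> nm
                sums[(int(ra), int(rb))] = sums.get((int(ra), int(rb)), 0.0) + dmin
    return {k: v / len(frames) for k, v in sums.items()}


def contact_residues(dist_map: dict, cutoff: float = 0.45) -> list:
    """Residue pairs whose mean minimum distance is ≤ ``cutoff`` nm."""
    return sorted(pair for pair, d in dist_map.items() if d <= cutoff)


# ---------------------------------------------------------------------------
# solvation, statistics, fluctuations
# ---------------------------------------------------------------------------

def nonpolar_solvation(sasa_a2, gamma: float = GAMMA_SURF,
                       b: float = B_SURF):
    """Nonpolar solvation free energy G = γ·SASA + b, kJ/mol (SASA in Å²)."""
    s = np.asarray(sasa_a2, dtype=float)
    if np.any(s < 0):
        raise ValueError("SASA must be non-negative")
    out = gamma * s + b
    return float(out) if np.isscalar(sasa_a2) else out


def welch_t(x, y):
    """Welch's unequal-variance t-test: returns (t, df, two-sided p).

    df by the Welch–Satterthwaite approximation; undefined when both
    samples have zero variance.
    """
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch's t-test needs at least two values per sample")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise ValueError("both samples have zero variance: t is undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                      fit_mobile: np.ndarray, fit_reference: np.ndarray):
    """Least-squares superposition of ``mobile`` using the fit subsets."""
    from scipy.spatial.transform import Rotation

    mc = fit_mobile.mean(axis=0)
    rc = fit_reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(fit_reference - rc, fit_mobile - mc)
    return rot.apply(mobile - mc) + rc


def rmsf(frames: TrajectoryFrames, n_blocks: int = 5, chain: str | None = None,
         superpose: bool = True):
    """Block-averaged per-residue RMSF (standard deviation of positions).

    The trajectory is split into ``n_blocks`` disjoint blocks; within each
    block frames are superposed onto the block's first frame by a CA-only
    least-squares fit, the per-atom fluctuation about the block-mean
    position is computed and residue-averaged, and the blocks give the
    mean ± SEM.  Returns ``(resids, mean, sem)`` in Å.
    """
    if len(frames) < n_blocks:
        raise ValueError(f"need at least {n_blocks} frames, got {len(frames)}")
    models = [m.select_chains(chain) if chain else m for m in frames]
    resids = models[0].resids
    uniq = np.unique(resids)
    per_block = []
    edges = np.linspace(0, len(models), n_blocks + 1).astype(int)
    for b in range(n_blocks):
        block = models[edges[b]:edges[b + 1]]
        ref = block[0]
        ca = np.flatnonzero(ref.atom_names == "CA")
        stack = []
        for m in block:
            xyz = m.coords
            if superpose and ca.size >= 3:
                xyz = _kabsch_superpose(xyz, ref.coords, m.coords[ca], ref.coords[ca])
            stack.append(xyz)
        stack = np.asarray(stack)  # (n_frames, n_atoms, 3)
        mean_pos = stack.mean(axis=0)
        fluct = np.sqrt(((stack - mean_pos) ** 2).sum(-1).mean(axis=0))  # per atom
        per_block.append([fluct[resids == r].mean() for r in uniq])
    per_block = np.asarray(per_block)  # (n_blocks, n_residues)
    mean = per_block.mean(axis=0)
    sem = per_block.std(axis=0, ddof=1) / math.sqrt(n_blocks)
    return uniq, mean, sem
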