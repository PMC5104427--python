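"""Designed small-structure fixtures with controllable H-bonds and interfaces.

Builds multi-model peptide-like structures from a declarative spec: chains
of minimal backbone residues (N, H, CA, C, O) laid out on a line, plus a
list of designed donor→acceptor hydrogen bonds, each present in a stated
fraction of frames at a stated geometry.  Because every coordinate is
placed analytically, the expected outcome of the downstream analytics
(H-bond persistence, group decomposition, interface area, distance maps)
is known by construction.

In a frame where a designed bond is "present" the acceptor residue's
carbonyl O is moved onto the donor's N–H axis at the requested distance
and angle; otherwise the O sits at its home position pointing away from
the backbone, where the detection criterion cannot fire.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import StructureModel, TrajectoryFrames

__all__ = ["ChainSpec", "HBondDesign", "WaterSpec", "FixtureSpec",
           "make_structure_fixture"]

RESIDUE_PITCH = 3.8  # Å between consecutive residues along x

# local atom positions within a residue (Å); the carbonyl O points to -z so
# that no accidental H-bond forms with the next residue's amide
_LOCAL = {
    "N": np.array([0.0, 0.0, 0.0]),
    "H": np.array([0.0, 0.0, 1.0]),
    "CA": np.array([1.45, 0.0, 0.0]),
    "C": np.array([2.40, 0.50, 0.0]),
    "O": np.array([2.40, 0.50, -1.23]),
}
_ELEMENTS = {"N": "N", "H": "H", "CA": "C", "C": "C", "O": "O"}


@dataclass(frozen=True)
class ChainSpec:
    chain_id: str
    n_residues: int
    start_resid: int = 1
    origin: tuple = (0.0, 0.0, 0.0)  # Å


@dataclass(frozen=True)
class HBondDesign:
    """A donor(N–H)→acceptor(O) bond present in a fraction of frames."""

    donor: tuple  # (chain_id, resid)
    acceptor: tuple  # (chain_id, resid)
    fraction: float = 1.0
    distance: float = 2.9  # donor-acceptor, Å
    angle: float = 10.0  # H-donor-acceptor, deg
    present_frames: tuple | None = None  # explicit override


@dataclass(frozen=True)
class WaterSpec:
    chain_id: str
    resid: int
    center: tuple  # O position, Å


@dataclass
class FixtureSpec:
    chains: list
    n_frames: int = 1
    hbonds: list = field(default_factory=list)
    waters: list = field(default_factory=list)


def _residue_atoms(resid: int, origin: np.ndarray):
    base = origin + np.array([RESIDUE_PITCH * resid, 0.0, 0.0])
    return {name: base + off for name, off in _LOCAL.items()}


def _present_set(design: HBondDesign, n_frames: int) -> set:
    if design.present_frames is not None:
        bad = [i for i in design.present_frames if not 0 <= i < n_frames]
        if bad:
            raise ValueError(f"present_frames indices out of range: {bad}")
        return set(design.present_frames)
    if not 0.0 <= design.fraction <= 1.0:
        raise ValueError(f"H-bond fraction must be in [0, 1], got {design.fraction}")
    return set(range(int(round(design.fraction * n_frames))))


def make_structure_fixture(spec: FixtureSpec) -> TrajectoryFrames:
    """Build the multi-model trajectory described by ``spec``.

    Raises ``ValueError`` for geometrically unsatisfiable specs: a donor or
    acceptor residue that does not exist, donor and acceptor in the same
    residue (excluded by the detector), two designs steering the same
    acceptor O in the same frame, or a non-positive bond distance.
    """
    chain_of = {}
    for c in spec.chains:
        if c.n_residues < 1:
            raise ValueError(f"chain {c.chain_id} has no residues")
        for r in range(c.start_resid, c.start_resid + c.n_residues):
            chain_of[(c.chain_id, r)] = c
    for w in spec.waters:
        if (w.chain_id, w.resid) in chain_of:
            raise ValueError(f"water {(w.chain_id, w.resid)} collides with a chain residue")

    presence = []
    for hb in spec.hbonds:
        if hb.donor not in chain_of:
            raise ValueError(f"donor residue {hb.donor} not in any chain")
        if hb.acceptor not in chain_of and not any(
                (w.chain_id, w.resid) == tuple(hb.acceptor) for w in spec.waters):
            raise ValueError(f"acceptor residue {hb.acceptor} not in any chain or water")
        if tuple(hb.donor) == tuple(hb.acceptor):
            raise ValueError("donor and acceptor must be different residues")
        if hb.distance <= 0:
            raise ValueError("bond distance must be positive")
        presence.append(_present_set(hb, spec.n_frames))

    frames = []
    for iframe in range(spec.n_frames):
        # steer acceptor O positions for bonds present in this frame
        steered: dict = {}
        for hb, frames_on in zip(spec.hbonds, presence):
            if iframe not in frames_on:
                continue
            donor_atoms = _residue_atoms(hb.donor[1] - chain_of[hb.donor].start_resid,
                                         np.asarray(chain_of[hb.donor].origin, float))
            theta = math.radians(hb.angle)
            target = donor_atoms["N"] + hb.distance * np.array(
                [math.sin(theta), 0.0, math.cos(theta)])
            key = tuple(hb.acceptor)
            if key in steered and not np.allclose(steered[key], target):
                raise ValueError(
                    f"unsatisfiable spec: acceptor {key} steered to two "
                    f"different positions in frame {iframe}")
            steered[key] = target

        chain_ids, resids, resnames, atom_names, elements, coords, het = \
            [], [], [], [], [], [], []
        for c in spec.chains:
            origin = np.asarray(c.origin, float)
            for k in range(c.n_residues):
                resid = c.start_resid + k
                atoms = _residue_atoms(k, origin)
                if (c.chain_id, resid) in steered:
                    atoms["O"] = steered[(c.chain_id, resid)]
                for name, pos in atoms.items():
                    chain_ids.append(c.chain_id)
                    resids.append(resid)
                    resnames.append("ALA")
                    atom_names.append(name)
                    elements.append(_ELEMENTS[name])
                    coords.append(pos)
                    het.append(False)
        for w in spec.waters:
            pos_o = steered.get((w.chain_id, w.resid),
                                np.asarray(w.center, float))
            for name, off in (("O", np.zeros(3)),
                              ("H1", np.array([0.96, 0.0, 0.0])),
                              ("H2", np.array([-0.24, 0.93, 0.0]))):
                chain_ids.append(w.chain_id)
                resids.append(w.resid)
                resnames.append("HOH")
                atom_names.append(name)
                elements.append("H" if name.startswith("H") else "O")
                coords.append(pos_o + off)
                het.append(True)
        frames.append(StructureModel(
            np.asarray(chain_ids), np.asarray(resids, int),
            np.asarray([""] * len(resids)), np.asarray(resnames),
            np.asarray(atom_names), np.asarray(elements),
            np.asarray(coords, float), np.asarray(het, bool)))
    return TrajectoryFrames(frames, {"n_frames": spec.n_frames})
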