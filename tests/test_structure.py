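"""Structural analytics: CVs, H-bonds, SASA, interfaces, statistics, RMSF."""

import math

import numpy as np
import pytest

from metadkit.fixtures import (ChainSpec, FixtureSpec, HBondDesign,
                               make_structure_fixture)
from metadkit.io import StructureModel, TrajectoryFrames
from metadkit.structure import (BONDI_RADII, classify_hbond_group,
                                compute_delta, compute_tau, contact_residues,
                                detect_hbonds, distance_map, hbond_persistence,
                                HBondStat, interface_area, nonpolar_solvation,
                                rmsf, sasa, welch_t)


def model_from(atoms):
    """atoms: list of (chain, resid, resname, name, element, xyz)."""
    return StructureModel(
        np.array([a[0] for a in atoms]),
        np.array([a[1] for a in atoms], dtype=int),
        np.array(["" for _ in atoms]),
        np.array([a[2] for a in atoms]),
        np.array([a[3] for a in atoms]),
        np.array([a[4] for a in atoms]),
        np.array([a[5] for a in atoms], dtype=float),
        np.zeros(len(atoms), dtype=bool))


class TestCollectiveVariables:
    def test_delta_axis_distance(self):
        m = model_from([("A", 30, "ASP", "CA", "C", (0, 0, 0)),
                        ("A", 65, "GLN", "CA", "C", (0, 0, 10.0))])
        assert compute_delta(m, "A") == pytest.approx(1.0)

    def test_delta_zero_for_coincident(self):
        m = model_from([("A", 30, "ASP", "CA", "C", (1, 2, 3)),
                        ("A", 65, "GLN", "CA", "C", (1, 2, 3))])
        assert compute_delta(m, "A") == 0.0

    def test_delta_missing_atom_named_error(self):
        m = model_from([("A", 30, "ASP", "CA", "C", (0, 0, 0))])
        with pytest.raises(KeyError, match="residue 65"):
            compute_delta(m, "A")

    def _torsion_model(self, tau_deg):
        # C(59)-N(60)-CA(60)-C(60) chain built so the dihedral is tau_deg
        t = math.radians(tau_deg)
        return model_from([
            ("A", 59, "VAL", "C", "C", (1.0, 1.0, 0.0)),
            ("A", 60, "ALA", "N", "N", (0.0, 1.0, 0.0)),
            ("A", 60, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            ("A", 60, "ALA", "C", "C",
             (math.cos(t), 0.0, math.sin(t))),
        ])

    def test_planar_cis_is_zero(self):
        assert compute_tau(self._torsion_model(0.0), "A") == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        assert abs(compute_tau(self._torsion_model(180.0), "A")) == \
            pytest.approx(180.0, abs=1e-9)

    @pytest.mark.parametrize("tau", [-150.0, -60.0, 45.0, 120.0])
    def test_constructed_torsions_recovered_with_sign(self, tau):
        assert compute_tau(self._torsion_model(tau), "A") == \
            pytest.approx(tau, abs=1e-9)


def hbond_model(d_a=2.9, angle=10.0, acceptor_chain="B"):
    """Donor N-H (chain A res 1) and acceptor O (res 2) at given geometry."""
    t = math.radians(angle)
    return model_from([
        ("A", 1, "ALA", "N", "N", (0.0, 0.0, 0.0)),
        ("A", 1, "ALA", "H", "H", (0.0, 0.0, 1.0)),
        (acceptor_chain, 2, "ALA", "O", "O",
         (d_a * math.sin(t), 0.0, d_a * math.cos(t))),
    ])


class TestDetectHbonds:
    def test_inside_both_cuts_detected(self):
        events = detect_hbonds(hbond_model(2.9, 10.0))
        assert events == [(("A", 1, "N"), ("B", 2, "O"))]

    def test_distance_beyond_cut_not_detected(self):
        assert detect_hbonds(hbond_model(4.0, 10.0)) == []

    def test_closed_boundaries(self):
        assert len(detect_hbonds(hbond_model(3.5, 30.0))) == 1
        assert len(detect_hbonds(hbond_model(3.51, 10.0))) == 0
        assert len(detect_hbonds(hbond_model(2.9, 30.1))) == 0

    def test_same_residue_pairs_excluded(self):
        m = model_from([
            ("A", 1, "ALA", "N", "N", (0.0, 0.0, 0.0)),
            ("A", 1, "ALA", "H", "H", (0.0, 0.0, 1.0)),
            ("A", 1, "ALA", "O", "O", (0.0, 0.0, 2.9)),
        ])
        assert detect_hbonds(m) == []


class TestPersistence:
    def _frames(self, present, total):
        spec = FixtureSpec(
            chains=[ChainSpec("A", 2), ChainSpec("B", 2, origin=(0, 10, 0))],
            n_frames=total,
            hbonds=[HBondDesign(("A", 1), ("B", 1), fraction=present / total)])
        return make_structure_fixture(spec)

    def test_always_present_persistence_one(self):
        stats, _ = hbond_persistence(self._frames(20, 20))
        assert len(stats) == 1
        assert stats[0].persistence == pytest.approx(1.0)

    def test_30_of_300_retained_at_010(self):
        stats, _ = hbond_persistence(self._frames(30, 300))
        assert len(stats) == 1
        assert stats[0].persistence == pytest.approx(0.10)

    def test_10_of_300_dropped_by_5pct_filter(self):
        stats, _ = hbond_persistence(self._frames(10, 300))
        assert stats == []

    def test_invariant_under_frame_reordering(self):
        frames = self._frames(7, 20)
        rev = TrajectoryFrames(list(frames)[::-1])
        s1, _ = hbond_persistence(frames)
        s2, _ = hbond_persistence(rev)
        assert [(s.donor, s.acceptor, s.persistence) for s in s1] == \
            [(s.donor, s.acceptor, s.persistence) for s in s2]

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            hbond_persistence(TrajectoryFrames([]))


class TestHbondGroups:
    def _stat(self, donor, acceptor):
        return HBondStat(donor, acceptor, 0.5)

    def test_intra_hairpin(self):
        s = self._stat(("D", 62, "N"), ("D", 64, "O"))
        assert classify_hbond_group(s, "D") == "intra-hairpin"

    def test_intra_chain(self):
        s = self._stat(("D", 62, "N"), ("D", 30, "O"))
        assert classify_hbond_group(s, "D") == "intra-chain"

    def test_inter_chain(self):
        s = self._stat(("D", 62, "N"), ("C", 40, "O"))
        assert classify_hbond_group(s, "D", facing_chain="C") == "inter-chain"

    def test_hairpin_solvent(self):
        s = self._stat(("D", 62, "N"), ("W", 501, "O"))
        assert classify_hbond_group(s, "D", acceptor_resname="HOH") == \
            "hairpin-solvent"

    def test_untouched_bond_unclassified(self):
        s = self._stat(("D", 10, "N"), ("D", 20, "O"))
        assert classify_hbond_group(s, "D") == "unclassified"


class TestSasa:
    def test_single_oxygen_closed_form(self):
        m = model_from([("A", 1, "HOH", "O", "O", (0, 0, 0))])
        total, per_atom = sasa(m, probe_radius=1.4, n_points=960)
        expected = 4 * math.pi * (BONDI_RADII["O"] + 1.4) ** 2
        assert expected == pytest.approx(107.14, abs=0.01)
        assert total == pytest.approx(expected, rel=0.005)

    def test_two_separated_atoms_additive(self):
        m1 = model_from([("A", 1, "HOH", "O", "O", (0, 0, 0))])
        m2 = model_from([("A", 1, "HOH", "O", "O", (0, 0, 0)),
                         ("A", 2, "HOH", "O", "O", (50, 0, 0))])
        assert sasa(m2)[0] == pytest.approx(2 * sasa(m1)[0], rel=1e-9)

    def test_coincident_atoms_fully_occlude(self):
        m1 = model_from([("A", 1, "HOH", "O", "O", (0, 0, 0))])
        m2 = model_from([("A", 1, "HOH", "O", "O", (0, 0, 0)),
                         ("A", 2, "HOH", "O", "O", (0, 0, 0))])
        # each test point of one sphere lies on (not inside) the twin; with
        # strict interior occlusion the pair counts once in total
        assert sasa(m2)[0] == pytest.approx(sasa(m1)[0], rel=0.01)

    def test_unknown_element_strict_mode(self):
        m = model_from([("A", 1, "UNK", "X", "Xx", (0, 0, 0))])
        with pytest.raises(KeyError):
            sasa(m, strict_elements=True)

    def test_cross_check_against_biotite(self):
        # independent Shrake-Rupley (biotite) with identical Bondi radii
        biotite_struc = pytest.importorskip("biotite.structure")
        frames = make_structure_fixture(FixtureSpec(
            chains=[ChainSpec("A", 3), ChainSpec("B", 2, origin=(2.0, 6.0, 1.0))]))
        m = frames[0]
        total, _ = sasa(m, probe_radius=1.4, n_points=960)
        arr = biotite_struc.AtomArray(m.n_atoms)
        arr.coord = m.coords
        arr.chain_id = m.chain_ids
        arr.res_id = m.resids
        arr.res_name = m.resnames
        arr.atom_name = m.atom_names
        arr.element = np.char.upper(m.elements.astype(str))
        radii = np.array([BONDI_RADII[e] for e in m.elements])
        ref = float(np.nansum(biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=960, vdw_radii=radii)))
        assert total == pytest.approx(ref, rel=0.02)


class TestInterface:
    def test_far_apart_chains_zero_area(self):
        frames = make_structure_fixture(FixtureSpec(
            chains=[ChainSpec("A", 2), ChainSpec("B", 2, origin=(0, 50.0, 0))]))
        rep = interface_area(frames, "A", "B")
        assert rep.mean == pytest.approx(0.0, abs=1e-6)

    def test_two_sphere_cap_oracle(self):
        # two single-atom chains at distance d < 2(r+probe): buried area is
        # twice the spherical cap 2πR(R − d/2), R = r + probe
        d = 3.0
        m = model_from([("A", 1, "HOH", "O", "O", (0, 0, 0)),
                        ("B", 1, "HOH", "O", "O", (d, 0, 0))])
        rep = interface_area(TrajectoryFrames([m]), "A", "B")
        r_eff = BONDI_RADII["O"] + 1.4
        expected = 2 * (2 * math.pi * r_eff * (r_eff - d / 2))
        assert rep.mean == pytest.approx(expected, rel=0.02)

    def test_symmetric_in_chain_order(self):
        frames = make_structure_fixture(FixtureSpec(
            chains=[ChainSpec("A", 2), ChainSpec("B", 2, origin=(0, 4.0, 0))]))
        a = interface_area(frames, "A", "B")
        b = interface_area(frames, "B", "A")
        assert a.mean == pytest.approx(b.mean, rel=1e-12)

    def test_nonnegative_on_randomized_fixtures(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            off = rng.uniform(-2, 6, 3)
            frames = make_structure_fixture(FixtureSpec(
                chains=[ChainSpec("A", 2), ChainSpec("B", 2, origin=tuple(off))]))
            rep = interface_area(frames, "A", "B")
            assert rep.series.min() >= -1e-9

    def test_missing_chain_rejected(self):
        frames = make_structure_fixture(FixtureSpec(chains=[ChainSpec("A", 2)]))
        with pytest.raises(ValueError, match="chain 'B'"):
            interface_area(frames, "A", "B")


class TestDistanceMap:
    def test_constant_040_is_contact(self):
        m = model_from([("A", 1, "ALA", "CA", "C", (0, 0, 0)),
                        ("B", 1, "ALA", "CA", "C", (4.0, 0, 0))])
        dmap = distance_map(TrajectoryFrames([m]), "A", "B")
        assert dmap[(1, 1)] == pytest.approx(0.40)
        assert contact_residues(dmap) == [(1, 1)]

    def test_mean_over_frames_046_not_contact(self):
        m1 = model_from([("A", 1, "ALA", "CA", "C", (0, 0, 0)),
                         ("B", 1, "ALA", "CA", "C", (4.0, 0, 0))])
        m2 = model_from([("A", 1, "ALA", "CA", "C", (0, 0, 0)),
                         ("B", 1, "ALA", "CA", "C", (5.2, 0, 0))])
        dmap = distance_map(TrajectoryFrames([m1, m2]), "A", "B")
        assert dmap[(1, 1)] == pytest.approx(0.46)
        assert contact_residues(dmap) == []

    def test_hydrogens_excluded_from_search(self):
        m = model_from([("A", 1, "ALA", "CA", "C", (0, 0, 0)),
                        ("B", 1, "ALA", "H", "H", (1.0, 0, 0)),
                        ("B", 1, "ALA", "CA", "C", (6.0, 0, 0))])
        dmap = distance_map(TrajectoryFrames([m]), "A", "B")
        assert dmap[(1, 1)] == pytest.approx(0.60)


class TestNonpolarSolvation:
    def test_zero_area_gives_intercept(self):
        assert nonpolar_solvation(0.0) == pytest.approx(3.84982, abs=1e-9)

    def test_100_A2(self):
        assert nonpolar_solvation(100.0) == pytest.approx(6.11760, abs=1e-5)

    def test_affine_linearity(self):
        s = 321.0
        assert nonpolar_solvation(2 * s) - nonpolar_solvation(s) == \
            pytest.approx(nonpolar_solvation(s) - nonpolar_solvation(0.0))

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            nonpolar_solvation(-1.0)


class TestWelch:
    def test_identical_samples_t_zero_p_one(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_worked_example(self):
        t, df, p = welch_t([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert t == pytest.approx(-1.8974, abs=1e-4)
        assert df == pytest.approx(5.882, abs=1e-3)

    def test_antisymmetry(self):
        x, y = [1.0, 2.0, 4.0], [2.0, 5.0, 9.0, 11.0]
        t1, _, p1 = welch_t(x, y)
        t2, _, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_direct_formula_oracle_50_random_pairs(self):
        from scipy.stats import t as student_t
        rng = np.random.default_rng(17)
        for _ in range(50):
            x = rng.normal(0, 1.0, rng.integers(3, 40))
            y = rng.normal(0.3, 2.0, rng.integers(3, 40))
            t, df, p = welch_t(x, y)
            vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
            t_ref = (x.mean() - y.mean()) / math.sqrt(vx + vy)
            df_ref = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
            p_ref = 2 * student_t.sf(abs(t_ref), df_ref)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert df == pytest.approx(df_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            welch_t([2.0, 2.0], [3.0, 3.0])


class TestRmsf:
    def _static(self, n=10):
        m = model_from([("A", 1, "ALA", "CA", "C", (0, 0, 0)),
                        ("A", 2, "ALA", "CA", "C", (3.8, 0, 0))])
        return TrajectoryFrames([m] * n)

    def test_static_trajectory_zero(self):
        resids, mean, sem = rmsf(self._static())
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)

    def test_oscillating_atom_two_point_std(self):
        a = 0.7
        frames = []
        for i in range(10):
            x = a if i % 2 == 0 else -a
            frames.append(model_from([("A", 1, "ALA", "O", "O", (x, 0, 0))]))
        resids, mean, sem = rmsf(TrajectoryFrames(frames), n_blocks=5,
                                 superpose=False)
        assert mean[0] == pytest.approx(a, rel=1e-9)
        assert sem[0] == pytest.approx(0.0, abs=1e-12)

    def test_unit_scaling_linearity(self):
        frames = []
        for i in range(10):
            x = 0.5 if i % 2 == 0 else -0.5
            frames.append(model_from([("A", 1, "ALA", "O", "O", (x, 0, 0))]))
        scaled = TrajectoryFrames([
            StructureModel(f.chain_ids, f.resids, f.icodes, f.resnames,
                           f.atom_names, f.elements, f.coords * 10.0,
                           f.is_hetero) for f in frames])
        _, m1, _ = rmsf(TrajectoryFrames(frames), superpose=False)
        _, m2, _ = rmsf(scaled, superpose=False)
        assert m2[0] == pytest.approx(10 * m1[0], rel=1e-9)

    def test_fewer_frames_than_blocks_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            rmsf(self._static(n=3))
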