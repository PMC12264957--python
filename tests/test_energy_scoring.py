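"""Nonbonded terms, surface areas, desolvation and the composite score."""

import numpy as np
import pytest

import airdock.energy as en
from airdock.forcefield import Topology, build_topology
from airdock.scoring import (EnergyReport, WEIGHT_PROFILES,
                             composite_score, desolvation_energy,
                             emscoring, sasascore, score_complex)


def two_atom_pairs(eps=0.2, rmin=4.0, q1=0.0, q2=0.0):
    t = Topology(np.array([eps, eps]), np.array([rmin, rmin]),
                 np.array([q1, q2]), np.zeros(2), np.array([1.9, 1.9]),
                 np.empty((0, 2), dtype=int), np.empty(0), np.empty(0),
                 np.empty((0, 3), dtype=int), np.empty(0), np.empty(0))
    return t, en.PairTerms.build(np.array([0]), np.array([1]), t)


class TestLennardJones:
    def test_minimum_is_minus_epsilon_at_rmin(self):
        _, pairs = two_atom_pairs(eps=0.2, rmin=4.0)
        coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        assert en.lj_energy(coords, pairs) == pytest.approx(-0.2)

    def test_twice_rmin_negative_and_shallow(self):
        _, pairs = two_atom_pairs(eps=0.2, rmin=4.0)
        coords = np.array([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0]])
        e = en.lj_energy(coords, pairs, cutoff=100.0)
        assert -0.2 < e < 0.0

    def test_beyond_cutoff_is_zero(self):
        _, pairs = two_atom_pairs()
        coords = np.array([[0.0, 0.0, 0.0], [9.0, 0.0, 0.0]])
        assert en.lj_energy(coords, pairs) == 0.0

    def test_softcore_cap_bounds_clash(self):
        _, pairs = two_atom_pairs(eps=0.2, rmin=4.0)
        coords = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
        assert en.lj_energy(coords, pairs, softcore_cap=10.0) == 10.0

    def test_gradient_matches_finite_difference(self):
        _, pairs = two_atom_pairs(eps=0.3, rmin=3.5)
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.4, -0.2]])
        grad = np.zeros_like(coords)
        en.lj_energy(coords, pairs, grad=grad)
        h = 1e-6
        for k in range(3):
            c1 = coords.copy()
            c1[1, k] += h
            num = (en.lj_energy(c1, pairs) -
                   en.lj_energy(coords, pairs)) / h
            assert grad[1, k] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestCoulomb:
    def test_plug_in_value_without_shift(self):
        _, pairs = two_atom_pairs(q1=1.0, q2=-1.0)
        coords = np.array([[0.0, 0.0, 0.0], [3.320636, 0.0, 0.0]])
        e = en.coulomb_energy(coords, pairs, shift=False, dielectric=10.0)
        assert e == pytest.approx(-10.0, rel=1e-6)

    def test_equal_charges_positive(self):
        _, pairs = two_atom_pairs(q1=0.5, q2=0.5)
        coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        assert en.coulomb_energy(coords, pairs) > 0.0

    def test_beyond_cutoff_zero_and_shift_continuous(self):
        _, pairs = two_atom_pairs(q1=1.0, q2=-1.0)
        far = np.array([[0.0, 0.0, 0.0], [8.6, 0.0, 0.0]])
        assert en.coulomb_energy(far, pairs) == 0.0
        near_cut = np.array([[0.0, 0.0, 0.0], [8.49, 0.0, 0.0]])
        assert abs(en.coulomb_energy(near_cut, pairs)) < 1e-4


class TestSasa:
    def test_isolated_atom_is_solvent_sphere(self):
        area = en.shrake_rupley(np.zeros((1, 3)), np.array([1.9]))
        expected = 4 * np.pi * (1.9 + 1.4) ** 2
        assert area[0] == pytest.approx(expected, rel=0.01)

    def test_fully_buried_atom_is_zero(self):
        # central atom caged by 14 large neighbors
        shell = []
        for x in (-1, 1):
            for y in (-1, 1):
                for z in (-1, 1):
                    shell.append([1.6 * x, 1.6 * y, 1.6 * z])
        for axis in range(3):
            for s in (-1, 1):
                v = [0.0, 0.0, 0.0]
                v[axis] = 2.6 * s
                shell.append(v)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.full(len(coords), 1.9)
        areas = en.shrake_rupley(coords, radii)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_probe_monotonicity(self, toy, toy_topology):
        # a larger probe grows every exposed sphere; for a packed model the
        # per-atom value need not grow (neighbor occlusion grows too), but
        # the total does, and a two-atom system grows atom-wise
        pair = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        r = np.array([1.9, 1.9])
        a1 = en.shrake_rupley(pair, r, probe=1.4)
        a2 = en.shrake_rupley(pair, r, probe=2.8)
        assert (a2 > a1).all()
        coords = toy.reference.coords()
        t1 = en.shrake_rupley(coords, toy_topology.radius, probe=1.4).sum()
        t2 = en.shrake_rupley(coords, toy_topology.radius, probe=2.8).sum()
        assert t2 > t1

    def test_matches_independent_implementation(self, tripeptide):
        biotite_struct = pytest.importorskip("biotite.structure")
        top = build_topology(tripeptide)
        coords = tripeptide.coords()
        ours = en.shrake_rupley(coords, top.radius, n_points=960)
        import biotite.structure as struc
        arr = struc.AtomArray(len(coords))
        arr.coord = coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = [a.resseq for a in tripeptide.atoms()]
        arr.atom_name[:] = [a.name for a in tripeptide.atoms()]
        arr.res_name[:] = [a.resname for a in tripeptide.atoms()]
        arr.element[:] = [a.element for a in tripeptide.atoms()]
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960,
                            vdw_radii=top.radius.astype(np.float32))
        np.testing.assert_allclose(ours, theirs, rtol=0.06, atol=2.0)


class TestDesolvationAndBsa:
    def test_far_separated_partners_zero(self, toy, toy_topology):
        apart = toy.reference.copy()
        coords = apart.coords()
        n_rec = sum(len(r.atoms) for r in apart.chain_residues("A"))
        coords[n_rec:] += np.array([100.0, 0.0, 0.0])
        apart.set_coords(coords)
        e, bsa = desolvation_energy(apart, toy_topology, [["A"], ["B"]])
        assert e == pytest.approx(0.0, abs=1e-9)
        assert bsa == pytest.approx(0.0, abs=1e-9)

    def test_contacting_pose_buries_surface(self, toy, toy_topology):
        e, bsa = desolvation_energy(toy.reference, toy_topology,
                                    [["A"], ["B"]])
        assert bsa > 0.0

    def test_sign_matches_direct_summation(self, toy, toy_topology):
        e, _ = desolvation_energy(toy.reference, toy_topology,
                                  [["A"], ["B"]])
        coords = toy.reference.coords()
        sasa_c = en.shrake_rupley(coords, toy_topology.radius)
        n_rec = sum(len(r.atoms)
                    for r in toy.reference.chain_residues("A"))
        free = np.concatenate([
            en.shrake_rupley(coords[:n_rec], toy_topology.radius[:n_rec]),
            en.shrake_rupley(coords[n_rec:], toy_topology.radius[n_rec:])])
        direct = float(np.sum(toy_topology.asp * (sasa_c - free)))
        assert e == pytest.approx(direct)
        assert np.sign(e) == np.sign(direct)


class TestCompositeScore:
    def test_worked_arithmetic(self):
        report = EnergyReport(e_vdw=-40.0, e_elec=-100.0, e_desolv=-8.0,
                              e_air=20.0, bsa=0.0)
        assert composite_score(report, "refined") == pytest.approx(-66.0)

    def test_all_zero_components(self):
        assert composite_score(EnergyReport(), "refined") == 0.0

    def test_custom_unit_weights_select_components(self):
        report = EnergyReport(e_vdw=-7.0, e_elec=3.0, e_desolv=1.0,
                              e_air=2.0, bsa=100.0)
        assert composite_score(report, {"vdw": 1.0}) == pytest.approx(-7.0)
        assert composite_score(report, {"bsa": 1.0}) == pytest.approx(100.0)

    def test_exact_linearity(self, rng):
        w = WEIGHT_PROFILES["rigidbody"]
        r1 = EnergyReport(*rng.normal(size=5))
        r2 = EnergyReport(*rng.normal(size=5))
        both = EnergyReport(*(np.array(list(r1.components().values())) +
                              np.array(list(r2.components().values()))))
        assert composite_score(both, w) == pytest.approx(
            composite_score(r1, w) + composite_score(r2, w))

    def test_unknown_profile_raises(self):
        with pytest.raises(ValueError):
            composite_score(EnergyReport(), "nonsense")


class TestScoreComplexInvariances:
    def test_rigid_motion_invariance(self, toy, toy_topology, rng):
        from scipy.spatial.transform import Rotation
        rep1 = score_complex(toy.reference, toy_topology,
                             partners=[["A"], ["B"]], with_sasa=False)
        moved = toy.reference.copy()
        R = Rotation.random(rng=rng).as_matrix()
        moved.set_coords(toy.reference.coords() @ R.T + [5.0, -3.0, 2.0])
        rep2 = score_complex(moved, toy_topology, partners=[["A"], ["B"]],
                             with_sasa=False)
        assert rep1.e_vdw == pytest.approx(rep2.e_vdw, abs=1e-8)
        assert rep1.e_elec == pytest.approx(rep2.e_elec, abs=1e-8)

    def test_partner_swap_symmetry(self, toy, toy_topology):
        rep1 = score_complex(toy.reference, toy_topology,
                             partners=[["A"], ["B"]], with_sasa=False)
        rep2 = score_complex(toy.reference, toy_topology,
                             partners=[["B"], ["A"]], with_sasa=False)
        assert rep1.e_vdw == pytest.approx(rep2.e_vdw)
        assert rep1.e_elec == pytest.approx(rep2.e_elec)


class TestEmscoring:
    def test_duplicate_models_score_identically(self, toy):
        models = [toy.reference.copy(), toy.reference.copy()]
        _, table = emscoring(models, em_steps=5)
        assert table["score"].iloc[0] == pytest.approx(
            table["score"].iloc[1])
        # stable order on ties
        assert list(table["model_index"]) == [0, 1]

    def test_clashed_model_ranks_last_without_em(self, toy):
        clashed = toy.reference.copy()
        coords = clashed.coords()
        n_rec = sum(len(r.atoms) for r in clashed.chain_residues("A"))
        # ram the ligand 3 Å into the receptor
        coords[n_rec:] -= np.array([3.0, 0.0, 0.0])
        clashed.set_coords(coords)
        _, table = emscoring([toy.reference.copy(), clashed], em_steps=0)
        assert table.iloc[-1]["model_index"] == 1

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            emscoring([])


class TestSasascore:
    def test_empty_expectations_zero(self, toy, toy_topology):
        v, _ = sasascore(toy.reference, topology=toy_topology)
        assert v == 0

    def test_exposed_residue_compliance_and_complement(self, toy,
                                                       toy_topology):
        # receptor residue on the face opposite the interface: exposed
        exposed = ("A", 14, "")
        v_ok, _ = sasascore(toy.reference, accessible_expected=[exposed],
                            topology=toy_topology)
        assert v_ok == 0
        v_bad, table = sasascore(toy.reference, buried_expected=[exposed],
                                 topology=toy_topology)
        assert v_bad == 1
        assert table["rel_accessibility"].iloc[0] > 0.15

    def test_unknown_residue_raises(self, toy, toy_topology):
        with pytest.raises(KeyError):
            sasascore(toy.reference, buried_expected=[("A", 999, "")],
                      topology=toy_topology)
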