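"""Rigid poses, restraint-driven sampling and Cartesian refinement."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from airdock.docking import (RefinementSettings, RigidPose, energy_minimize,
                             flexible_refine, rigid_transform,
                             sample_rigidbody)
from airdock.forcefield import Topology, build_topology
from airdock.pdbio import AtomRecord, Model, Residue
from airdock.restraints import (AmbiguousRestraint, ResidueTag,
                                RestraintSet, effective_distance)


def single_atom_model(chain, resseq, xyz, name="CA"):
    rec = AtomRecord(1, name, "GLY", chain, resseq, "",
                     np.asarray(xyz, dtype=float), "C")
    return Model([Residue("GLY", chain, resseq, "", [rec])])


def bare_topology(n, eps=0.0, rmin=4.0, charge=0.0):
    return Topology(np.full(n, eps), np.full(n, rmin), np.full(n, charge),
                    np.zeros(n), np.full(n, 1.9),
                    np.empty((0, 2), dtype=int), np.empty(0), np.empty(0),
                    np.empty((0, 3), dtype=int), np.empty(0), np.empty(0))


class TestRigidPose:
    def test_identity_pose_is_identity(self, toy):
        coords = toy.ligand.coords()
        out = rigid_transform(coords, RigidPose.identity())
        np.testing.assert_allclose(out, coords)

    def test_half_turn_applied_twice_is_identity(self, toy):
        pose = RigidPose.from_rotvec(np.array([np.pi, 0.0, 0.0]),
                                     np.zeros(3))
        coords = toy.ligand.coords()
        twice = rigid_transform(rigid_transform(coords, pose), pose)
        np.testing.assert_allclose(twice, coords, atol=1e-9)

    def test_internal_distances_preserved(self, toy, rng):
        pose = RigidPose.from_rotvec(rng.normal(size=3),
                                     rng.normal(size=3) * 10)
        coords = toy.ligand.coords()
        out = rigid_transform(coords, pose)
        np.testing.assert_allclose(pdist(out), pdist(coords), atol=1e-6)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidPose(np.eye(3) * 2.0, np.zeros(3))


class TestSampleRigidbody:
    def test_single_air_reaches_flat_region(self, toy):
        # two 1-atom partners, only the AIR term active: the optimizer
        # must bring the effective distance inside the 2 Å upper bound
        rec = single_atom_model("A", 1, [0.0, 0.0, 0.0])
        lig = single_atom_model("B", 1, [30.0, 0.0, 0.0])
        air = AmbiguousRestraint(
            ResidueTag("A", 1),
            frozenset([ResidueTag("B", 1, role="passive")]), 2.0, 0.0)
        rset = RestraintSet("one", ambiguous=[air])
        models, _ = sample_rigidbody(
            rec, bare_topology(1), lig, bare_topology(1), [rset],
            n_models=1, seed=5, weights={"vdw": 0.0, "elec": 0.0,
                                         "air": 1.0},
            removal_fraction=0.0, max_evals=400)
        out = models[0]
        d = effective_distance(out.coords()[:1], out.coords()[1:])
        assert d <= 2.0 + 1e-3

    def test_determinism_same_seed(self, toy):
        from airdock.fixtures import make_epitope_restraints
        rset = make_epitope_restraints(toy, "true")
        rt = build_topology(toy.receptor)
        lt = build_topology(toy.ligand)
        m1, t1 = sample_rigidbody(toy.receptor, rt, toy.ligand, lt,
                                  [rset], n_models=4, seed=11)
        m2, t2 = sample_rigidbody(toy.receptor, rt, toy.ligand, lt,
                                  [rset], n_models=4, seed=11)
        assert list(t1["score"]) == list(t2["score"])
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.coords(), b.coords())

    def test_rigid_stage_preserves_internal_geometry(self, toy):
        from airdock.fixtures import make_epitope_restraints
        rset = make_epitope_restraints(toy, "true")
        rt = build_topology(toy.receptor)
        lt = build_topology(toy.ligand)
        models, _ = sample_rigidbody(toy.receptor, rt, toy.ligand, lt,
                                     [rset], n_models=2, seed=3)
        n_rec = toy.receptor.n_atoms
        for m in models:
            lig_out = m.coords()[n_rec:]
            np.testing.assert_allclose(pdist(lig_out),
                                       pdist(toy.ligand.coords()),
                                       atol=1e-6)

    def test_every_model_carries_a_set_id(self, toy):
        from airdock.fixtures import make_epitope_restraints
        sets = [make_epitope_restraints(toy, "true"),
                make_epitope_restraints(toy, "decoy_1")]
        rt = build_topology(toy.receptor)
        lt = build_topology(toy.ligand)
        models, table = sample_rigidbody(toy.receptor, rt, toy.ligand, lt,
                                         sets, n_models=4, seed=2)
        assert all(m.provenance.restraint_set_id in ("true", "decoy_1")
                   for m in models)
        assert set(table["set_id"]) == {"true", "decoy_1"}


class TestEnergyMinimize:
    def test_zero_steps_is_identity_with_energies(self, toy,
                                                  toy_topology):
        out, report = energy_minimize(toy.reference, toy_topology,
                                      n_steps=0)
        np.testing.assert_array_equal(out.coords(),
                                      toy.reference.coords())
        assert report.extras["e_total"] is not None

    def test_lj_pushes_overlapping_atoms_apart(self):
        rec = single_atom_model("A", 1, [0.0, 0.0, 0.0])
        lig = single_atom_model("B", 2, [3.2, 0.0, 0.0])   # 0.8 * rmin
        combined = Model([rec.residues[0], lig.residues[0]])
        top = bare_topology(2, eps=0.2, rmin=4.0)
        out, _ = energy_minimize(combined, top, n_steps=100)
        d = np.linalg.norm(out.coords()[1] - out.coords()[0])
        assert d > 3.2

    def test_minimization_does_not_increase_energy(self, toy,
                                                   toy_topology):
        _, rep0 = energy_minimize(toy.reference, toy_topology, n_steps=0)
        _, rep1 = energy_minimize(toy.reference, toy_topology, n_steps=50)
        assert rep1.extras["e_total"] <= rep0.extras["e_total"] + 1e-9


class TestFlexibleRefine:
    def test_zero_cutoff_leaves_coordinates_unchanged(self, toy,
                                                      toy_topology):
        settings = RefinementSettings(n_steps=50, flexible_cutoff=0.0)
        out, _ = flexible_refine(toy.reference, toy_topology,
                                 settings=settings)
        np.testing.assert_array_equal(out.coords(),
                                      toy.reference.coords())

    def test_tether_bounds_distal_backbone_motion(self, toy,
                                                  toy_topology):
        # clash at the interface: push the ligand 1 Å into the receptor
        clashed = toy.reference.copy()
        coords = clashed.coords()
        n_rec = toy.receptor.n_atoms
        coords[n_rec:] -= np.array([1.0, 0.0, 0.0])
        clashed.set_coords(coords)
        settings = RefinementSettings(n_steps=100, flexible_cutoff=5.0,
                                      tether_k=10.0)
        out, _ = flexible_refine(clashed, toy_topology, settings=settings)
        moved = np.linalg.norm(out.coords() - clashed.coords(), axis=1)
        # distal (non-interface) CA atoms barely move
        from airdock.docking import _flexible_atom_mask
        flex = _flexible_atom_mask(clashed, 5.0)
        names = [a.name for a in clashed.atoms()]
        distal_ca = [i for i in range(len(names))
                     if names[i] == "CA" and not flex[i]]
        assert len(distal_ca) > 0
        assert max(moved[i] for i in distal_ca) < 0.5
        # something at the interface did move
        assert moved[flex].max() > moved[~flex].max()

    def test_everything_flexible_equals_plain_minimization(self, toy,
                                                           toy_topology):
        settings = RefinementSettings(n_steps=30, flexible_cutoff=1e6)
        out1, _ = flexible_refine(toy.reference, toy_topology,
                                  settings=settings)
        out2, _ = energy_minimize(toy.reference, toy_topology,
                                  settings=settings)
        np.testing.assert_allclose(out1.coords(), out2.coords(),
                                   atol=1e-8)
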