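"""Selection, filtering, mutation, alanine scanning and contact maps."""

import numpy as np
import pytest

from airdock.analysis import (UnsupportedMutationError, alascan,
                              contact_map, filter_models,
                              interface_residues, mutate_residue,
                              residue_class, seletop, seletopclusts)
from airdock.clustering import Clustering


def scored(model, score, name=None):
    m = model.copy()
    m.provenance.score = score
    if name:
        m.provenance.name = name
    return m


class TestSeletop:
    def test_keeps_n_lowest_scores(self, toy):
        models = [scored(toy.reference, s) for s in [3.0, -1.0, 0.5, -2.0]]
        kept = seletop(models, 2)
        assert [m.provenance.score for m in kept] == [-2.0, -1.0]

    def test_output_is_sorted_prefix_of_score_multiset(self, toy, rng):
        scores = list(rng.normal(size=9))
        models = [scored(toy.reference, s) for s in scores]
        kept = seletop(models, 5)
        assert [m.provenance.score for m in kept] == sorted(scores)[:5]

    def test_ties_keep_input_order(self, toy):
        models = [scored(toy.reference, 1.0, name=f"m{i}")
                  for i in range(3)]
        kept = seletop(models, 2)
        assert [m.provenance.name for m in kept] == ["m0", "m1"]

    def test_n_larger_than_input_warns_and_keeps_all(self, toy):
        models = [scored(toy.reference, 0.0)]
        with pytest.warns(UserWarning):
            assert len(seletop(models, 10)) == 1

    def test_nonpositive_n_rejected(self, toy):
        with pytest.raises(ValueError):
            seletop([scored(toy.reference, 0.0)], 0)


class TestSeletopclusts:
    def _models(self, toy, n):
        return [scored(toy.reference, float(i), name=f"m{i}")
                for i in range(n)]

    def test_two_clusters_default_four_each(self, toy):
        models = self._models(toy, 16)
        clustering = Clustering(
            labels=[1] * 8 + [2] * 8,
            clusters=[list(range(8)), list(range(8, 16))])
        kept = seletopclusts(models, clustering)
        assert len(kept) == 8
        assert {m.provenance.cluster_id for m in kept} == {1, 2}
        ranks = [m.provenance.cluster_rank for m in kept]
        assert ranks == [1, 2, 3, 4, 1, 2, 3, 4]

    def test_small_cluster_kept_whole(self, toy):
        models = self._models(toy, 3)
        clustering = Clustering(labels=[1, 1, 1], clusters=[[0, 1, 2]])
        assert len(seletopclusts(models, clustering,
                                 n_per_cluster=10)) == 3

    def test_no_clusters_raises(self, toy):
        with pytest.raises(ValueError):
            seletopclusts(self._models(toy, 2),
                          Clustering(labels=[None, None]))


class TestFilterModels:
    def test_infinite_threshold_is_identity(self, toy):
        models = [scored(toy.reference, s) for s in (-5.0, -1.0)]
        assert len(filter_models(models, np.inf)) == 2

    def test_threshold_below_min_warns_empty(self, toy):
        models = [scored(toy.reference, s) for s in (-5.0, -1.0)]
        with pytest.warns(UserWarning):
            assert filter_models(models, -10.0) == []

    def test_threshold_between_scores(self, toy):
        models = [scored(toy.reference, s) for s in (-5.0, -1.0)]
        kept = filter_models(models, -2.0)
        assert [m.provenance.score for m in kept] == [-5.0]


class TestInterfaceResidues:
    def test_separated_partners_empty(self, toy):
        far = toy.reference.copy()
        coords = far.coords()
        n_rec = toy.receptor.n_atoms
        coords[n_rec:] += 100.0
        far.set_coords(coords)
        iface = interface_residues(far)
        assert all(len(v) == 0 for v in iface.values())

    def test_boundary_inclusion(self):
        from airdock.pdbio import AtomRecord, Model, Residue

        def dimer_at(d):
            a = AtomRecord(1, "CA", "GLY", "A", 1, "", np.zeros(3), "C")
            b = AtomRecord(2, "CA", "GLY", "B", 9, "",
                           np.array([d, 0.0, 0.0]), "C")
            return Model([Residue("GLY", "A", 1, "", [a]),
                          Residue("GLY", "B", 9, "", [b])])

        assert interface_residues(dimer_at(4.9))["A"] == [(1, "")]
        assert interface_residues(dimer_at(5.1))["A"] == []


class TestMutateResidue:
    def test_leu_to_ala_leaves_five_atoms(self, toy):
        mut = mutate_residue(toy.reference, "A", 2, "ALA")  # LEU 2
        res = mut.residue("A", 2)
        assert res.resname == "ALA"
        assert sorted(a.name for a in res.atoms) == \
            ["C", "CA", "CB", "N", "O"]

    def test_ala_to_ala_is_identity(self, toy):
        mut = mutate_residue(toy.reference, "A", 3, "ALA")  # ALA 3
        np.testing.assert_array_equal(mut.coords(),
                                      toy.reference.coords())

    def test_gly_to_ala_grows_cb_at_bond_length(self):
        from airdock.build import EXTENDED, build_peptide
        pep = build_peptide(["ALA", "GLY", "ALA"], conformation=EXTENDED)
        mut = mutate_residue(pep, "A", 2, "ALA")
        res = mut.residue("A", 2)
        d = np.linalg.norm(res.atom("CB").xyz - res.atom("CA").xyz)
        assert d == pytest.approx(1.53, abs=0.01)

    def test_proline_unsupported(self, toy):
        with pytest.raises(UnsupportedMutationError):
            mutate_residue(toy.reference, "A", 2, "PRO")

    def test_growth_mutation_gets_template_atoms(self, toy):
        mut = mutate_residue(toy.reference, "A", 3, "LYS")  # ALA 3
        res = mut.residue("A", 3)
        assert sorted(a.name for a in res.atoms) == \
            ["C", "CA", "CB", "CD", "CE", "CG", "N", "NZ", "O"]


@pytest.fixture(scope="module")
def scan(toy):
    return alascan(toy.reference, em_steps=15, partners=[["A"], ["B"]])


class TestAlascan:

    def test_only_interface_residues_scanned(self, toy, scan):
        iface = interface_residues(toy.reference)
        expected = {(c, r) for c in iface for r, _ in iface[c]}
        assert {(row["chain"], row["resseq"])
                for _, row in scan.iterrows()} == expected

    def test_target_residues_skipped_with_zero_delta(self, scan):
        ala_rows = scan[scan["resname"] == "ALA"]
        if len(ala_rows):
            assert ala_rows["skipped"].all()
            assert (ala_rows["delta_score"] == 0.0).all()

    def test_salt_bridge_dominates_electrostatic_delta(self, scan):
        ok = scan[~scan["skipped"]]
        best = ok.loc[ok["delta_elec"].abs().idxmax()]
        assert (best["chain"], best["resseq"]) in \
            [("A", 12), ("A", 16), ("B", 1), ("B", 5)]
        assert best["resname"] in ("LYS", "GLU", "ASP")


class TestContactMap:
    def test_far_dimer_has_intrachain_but_no_interchain(self, toy):
        far = toy.reference.copy()
        coords = far.coords()
        coords[toy.receptor.n_atoms:] += 100.0
        far.set_coords(coords)
        table, chord = contact_map(far)
        inter = table[table["interchain"]]
        intra = table[~table["interchain"]]
        assert not inter["contact"].any()
        assert intra["contact"].any()
        assert len(chord) == 0

    def test_salt_bridge_typed_charged_charged(self, toy):
        table, chord = contact_map(toy.reference)
        row = chord[(chord["resseq_a"] == 12) & (chord["resseq_b"] == 5)]
        assert len(row) == 1
        assert row.iloc[0]["class_pair"] == "charged-charged"

    def test_no_duplicate_symmetric_pairs(self, toy):
        table, _ = contact_map(toy.reference)
        keys = set()
        for _, row in table.iterrows():
            k = ((row["chain_a"], row["resseq_a"]),
                 (row["chain_b"], row["resseq_b"]))
            assert k not in keys and (k[1], k[0]) not in keys
            keys.add(k)

    def test_cluster_frequency_counting(self, toy):
        moved = toy.reference.copy()
        coords = moved.coords()
        coords[toy.receptor.n_atoms:] += np.array([2.5, 0.0, 0.0])
        moved.set_coords(coords)
        table, _ = contact_map([toy.reference, moved])
        inter = table[table["interchain"] & (table["contact_frequency"]
                                             > 0)]
        assert set(inter["contact_frequency"].round(2)) <= {0.5, 1.0}
        assert (inter["contact_frequency"] == 0.5).any()
        assert (inter["contact_frequency"] == 1.0).any()

    def test_residue_class_partition(self):
        assert residue_class("LYS") == "charged"
        assert residue_class("SER") == "polar"
        assert residue_class("LEU") == "apolar"
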