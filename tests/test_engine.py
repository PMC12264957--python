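"""Workflow configuration, execution, provenance and traceback."""

import shutil

import numpy as np
import pandas as pd
import pytest

import airdock as ad
from airdock.engine import (ConfigError, cfg_query, load_config,
                            parse_config, report, run_workflow,
                            traceback_table, validate_config)

CLASSIC_STEPS = ["topoaa", "rigidbody", "seletop", "flexref", "emref",
              "caprieval", "clustfcc", "seletopclusts", "caprieval"]


def write_inputs(d, seed=0):
    toy = ad.make_toy_dimer(seed)
    ad.write_pdb(toy.receptor, d / "receptor.pdb")
    ad.write_pdb(toy.ligand, d / "ligand.pdb")
    ad.write_pdb(toy.reference, d / "reference.pdb")
    ad.make_epitope_restraints(toy, "true", d / "airs.tbl")
    return toy


CLASSIC_CONFIG = """\
run_dir = "{run_dir}"
molecules = ["receptor.pdb", "ligand.pdb"]
seed = 42

[topoaa]
[rigidbody]
ambig_fname = "airs.tbl"
sampling = 10
max_evals = 60
[seletop]
select = 6
[flexref]
ambig_fname = "airs.tbl"
n_steps = 5
[emref]
n_steps = 5
[caprieval]
reference_fname = "reference.pdb"
[clustfcc]
min_size = 1
[seletopclusts]
top_models = 2
[caprieval]
reference_fname = "reference.pdb"
"""


@pytest.fixture(scope="module")
def tiny_run(tmp_path_factory):
    """One small full pipeline run shared by the execution tests."""
    d = tmp_path_factory.mktemp("wf")
    write_inputs(d)
    (d / "wf.toml").write_text(CLASSIC_CONFIG.format(run_dir="run1"))
    record = run_workflow(d / "wf.toml")
    return d, record


class TestParseConfig:
    def test_pipeline_config_steps_in_order(self, tmp_path):
        write_inputs(tmp_path)
        (tmp_path / "wf.toml").write_text(
            CLASSIC_CONFIG.format(run_dir="r"))
        cfg = parse_config(tmp_path / "wf.toml")
        assert [s.module for s in cfg.steps] == CLASSIC_STEPS

    def test_repeated_sections_get_distinct_step_ids(self, tmp_path):
        write_inputs(tmp_path)
        (tmp_path / "wf.toml").write_text(
            CLASSIC_CONFIG.format(run_dir="r"))
        cfg = parse_config(tmp_path / "wf.toml")
        capri = [s.step_id for s in cfg.steps if s.module == "caprieval"]
        assert capri == ["caprieval", "caprieval__2"]

    def test_empty_steps_rejected(self, tmp_path):
        p = tmp_path / "e.toml"
        write_inputs(tmp_path)
        p.write_text('run_dir = "r"\nmolecules = ["receptor.pdb"]\n')
        with pytest.raises(ConfigError, match="no steps"):
            validate_config(parse_config(p))

    def test_syntax_error_reported(self, tmp_path):
        p = tmp_path / "bad.toml"
        p.write_text('run_dir = = "r"\n')
        with pytest.raises(ConfigError):
            parse_config(p)

    def test_duplicate_global_key_rejected(self, tmp_path):
        p = tmp_path / "dup.toml"
        p.write_text('run_dir = "a"\nrun_dir = "b"\n[topoaa]\n')
        with pytest.raises(ConfigError):
            parse_config(p)


class TestValidateConfig:
    def _config(self, tmp_path, body):
        write_inputs(tmp_path)
        p = tmp_path / "wf.toml"
        p.write_text('run_dir = "r"\n'
                     'molecules = ["receptor.pdb", "ligand.pdb"]\n'
                     + body)
        return p

    def test_misspelled_module_suggestion(self, tmp_path):
        p = self._config(tmp_path, "[topoaa]\n[rigidbdy]\n")
        with pytest.raises(ConfigError, match="rigidbody"):
            load_config(p)

    def test_unknown_parameter_suggestion(self, tmp_path):
        p = self._config(tmp_path,
                         '[topoaa]\n[rigidbody]\nambigfname = "x.tbl"\n')
        with pytest.raises(ConfigError, match="ambig_fname"):
            load_config(p)

    def test_first_step_must_build_topology(self, tmp_path):
        p = self._config(tmp_path, "[seletop]\n")
        with pytest.raises(ConfigError, match="topology"):
            load_config(p)

    def test_missing_restraint_file_rejected_before_run(self, tmp_path):
        p = self._config(tmp_path,
                         '[topoaa]\n[rigidbody]\n'
                         'ambig_fname = "missing.tbl"\n')
        with pytest.raises(ConfigError, match="missing.tbl"):
            load_config(p)

    def test_missing_molecule_rejected(self, tmp_path):
        write_inputs(tmp_path)
        p = tmp_path / "wf.toml"
        p.write_text('run_dir = "r"\nmolecules = ["nope.pdb"]\n'
                     "[topoaa]\n")
        with pytest.raises(ConfigError, match="nope.pdb"):
            load_config(p)

    def test_defaults_injected(self, tmp_path):
        p = self._config(tmp_path,
                         '[topoaa]\n[rigidbody]\n'
                         'ambig_fname = "airs.tbl"\n')
        cfg = load_config(p)
        rigid = cfg.steps[1]
        assert rigid.params["sampling"] == 1000
        assert rigid.params["w_vdw"] == pytest.approx(0.01)


class TestRunWorkflow:
    def test_numbered_step_directories(self, tiny_run):
        d, record = tiny_run
        names = [p.name for p in record.step_dirs]
        assert names == [f"{i}_{m}" for i, m in enumerate(CLASSIC_STEPS)]
        assert (record.run_dir / "data").is_dir()

    def test_model_counts_follow_selections(self, tiny_run):
        _, record = tiny_run
        assert len(record.manifest(1)) == 10     # rigidbody sampling
        assert len(record.manifest(2)) == 6      # seletop
        assert len(record.manifest(3)) == 6      # flexref

    def test_every_manifest_file_exists(self, tiny_run):
        _, record = tiny_run
        for i, step_dir in enumerate(record.step_dirs):
            mf = record.manifest(i)
            for fname in mf["file"]:
                assert (step_dir / fname).exists()

    def test_restraint_set_id_propagates_to_every_step(self, tiny_run):
        _, record = tiny_run
        for i in range(1, len(record.step_dirs)):
            mf = record.manifest(i)
            assert (mf["set_id"] == "airs").all()

    def test_existing_nonempty_run_dir_rejected(self, tiny_run):
        d, _ = tiny_run
        with pytest.raises(ConfigError, match="exists"):
            run_workflow(d / "wf.toml")

    def test_rerun_same_seed_byte_identical_manifests(self, tmp_path):
        write_inputs(tmp_path)
        cfg = CLASSIC_CONFIG.replace('sampling = 10', 'sampling = 4') \
                         .replace('select = 6', 'select = 3')
        for run_dir in ("runA", "runB"):
            (tmp_path / f"{run_dir}.toml").write_text(
                cfg.format(run_dir=run_dir))
            run_workflow(tmp_path / f"{run_dir}.toml")
        for i, module in enumerate(CLASSIC_STEPS):
            a = (tmp_path / "runA" / f"{i}_{module}" /
                 "manifest.tsv").read_bytes()
            b = (tmp_path / "runB" / f"{i}_{module}" /
                 "manifest.tsv").read_bytes()
            assert a == b, f"step {i}_{module} differs"


class TestTraceback:
    def test_survivors_have_full_chains(self, tiny_run):
        _, record = tiny_run
        table = traceback_table(record.run_dir)
        final = table[table["8_caprieval"] != "-"]
        # every survivor traces through every step
        for col in [f"{i}_{m}" for i, m in enumerate(CLASSIC_STEPS)][1:]:
            assert (final[col] != "-").all()
        assert (final["set_id"] == "airs").all()

    def test_dropped_models_truncated_at_seletop(self, tiny_run):
        _, record = tiny_run
        table = traceback_table(record.run_dir)
        dropped = table[table["2_seletop"] == "-"]
        assert len(dropped) == 4                 # 10 sampled - 6 kept
        assert (dropped["3_flexref"] == "-").all()
        assert (dropped["1_rigidbody"] != "-").all()

    def test_missing_manifest_raises(self, tiny_run, tmp_path):
        d, record = tiny_run
        broken = tmp_path / "broken"
        shutil.copytree(record.run_dir, broken)
        (broken / "2_seletop" / "manifest.tsv").unlink()
        with pytest.raises(FileNotFoundError, match="2_seletop"):
            traceback_table(broken)


class TestReportAndCfg:
    def test_report_writes_summary_and_scatter(self, tiny_run):
        _, record = tiny_run
        out = report(record.run_dir, make_plots=False)
        assert (out / "steps.tsv").exists()
        scatter = pd.read_csv(out / "score_vs_metrics.tsv", sep="\t")
        assert {"score", "irmsd", "dockq"} <= set(scatter.columns)

    def test_report_without_metrics_warns(self, tmp_path):
        write_inputs(tmp_path)
        (tmp_path / "wf.toml").write_text(
            'run_dir = "r"\n'
            'molecules = ["receptor.pdb", "ligand.pdb"]\n'
            'seed = 1\n[topoaa]\n[rigidbody]\n'
            'ambig_fname = "airs.tbl"\nsampling = 2\nmax_evals = 10\n')
        record = run_workflow(tmp_path / "wf.toml")
        with pytest.warns(UserWarning, match="caprieval"):
            report(record.run_dir, make_plots=False)

    def test_cfg_query_single_module(self):
        text = cfg_query("rigidbody")
        assert "ambig_fname" in text
        assert "sampling" in text

    def test_cfg_query_all_covers_registry(self):
        from airdock.engine import MODULE_REGISTRY
        text = cfg_query("all")
        for name in MODULE_REGISTRY:
            assert f"[{name}]" in text

    def test_cfg_query_unknown_module(self):
        with pytest.raises(KeyError):
            cfg_query("frobnicate")


class TestScoringOnlyWorkflow:
    def test_ensemble_rescoring_pipeline(self, tmp_path):
        """A single multi-model PDB is rescored (topology + short EM +
        score) and evaluated against the best-scored model."""
        toy = write_inputs(tmp_path)
        ens = ad.make_decoys(toy, [0.0, 3.0, 8.0], n_per_level=1, seed=5,
                             include_wrong_epitope=False)
        ad.write_pdb(ens, tmp_path / "ensemble.pdb")
        (tmp_path / "wf.toml").write_text(
            'run_dir = "score_run"\n'
            'molecules = ["ensemble.pdb"]\n'
            'seed = 3\n'
            "[topoaa]\n[emscoring]\nn_steps = 10\n[caprieval]\n")
        record = run_workflow(tmp_path / "wf.toml")
        scores = pd.read_csv(record.step_dirs[1] / "scores.tsv", sep="\t")
        assert len(scores) == 3
        assert (scores["error"].fillna("") == "").all()
        assert list(scores["score"]) == sorted(scores["score"])
        ss = pd.read_csv(record.step_dirs[2] / "capri_ss.tsv", sep="\t")
        # best-scored model compared against itself
        assert ss.iloc[0]["dockq"] == pytest.approx(1.0)


class TestAnalysisModulesInWorkflow:
    def test_matrix_clustering_filter_maps_and_scan(self, tmp_path):
        toy = write_inputs(tmp_path)
        (tmp_path / "wf.toml").write_text(
            'run_dir = "an_run"\n'
            'molecules = ["receptor.pdb", "ligand.pdb"]\n'
            'seed = 5\n'
            "[topoaa]\n"
            '[rigidbody]\nambig_fname = "airs.tbl"\nsampling = 6\n'
            "max_evals = 60\n"
            "[rmsdmatrix]\n"
            "[clustrmsd]\nn_clusters = 2\nmin_size = 1\n"
            "[seletopclusts]\ntop_models = 2\n"
            "[sasascore]\naccessible = [\"A:14\"]\n"
            "[filter]\nthreshold = 1e6\n"
            "[contactmap]\n"
            "[alascan]\nem_steps = 3\n")
        record = run_workflow(tmp_path / "wf.toml")
        mat = pd.read_csv(record.step_dirs[2] / "rmsd_matrix.tsv",
                          sep="\t")
        assert len(mat) == 6 * 5               # off-diagonal entries
        clusters = pd.read_csv(record.step_dirs[3] / "clusters.tsv",
                               sep="\t")
        assert clusters["cluster_id"].nunique() <= 2
        sasa = pd.read_csv(record.step_dirs[5] / "scores.tsv", sep="\t")
        assert (sasa["violations"] == 0).all()  # A:14 faces the solvent
        scan = pd.read_csv(record.step_dirs[8] / "alascan.tsv", sep="\t")
        assert {"delta_score", "delta_elec"} <= set(scan.columns)
        chords = list(record.step_dirs[7].glob("chord_*.tsv"))
        assert chords
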