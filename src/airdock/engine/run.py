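"""Workflow execution: numbered step directories, manifests, traceback.

A run directory looks like::

    run_dir/
      data/            copies of the input files
      0_topoaa/        one directory per step, 0-based, "<i>_<module>"
      1_rigidbody/
        manifest.tsv   model name, file, score, restraint set, parent ...
        *.pdb          the step's output models
      ...
      analysis/        summary tables and plots (written by `report`)

Each step consumes the previous step's model list and writes its own
manifest; model names chain through ``parent`` fields, so the full
lineage of every final model — including which restraint set produced it
— can be reconstructed (``traceback_table``).  Manifests contain no
timestamps: identical config + seed reruns are byte-identical.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .. import analysis as an
from .. import capri as cp
from .. import clustering as cl
from ..docking import (RefinementSettings, energy_minimize, flexible_refine,
                       sample_rigidbody)
from ..forcefield import build_topology
from ..pdbio import Ensemble, Model, read_pdb, write_pdb
from ..restraints import RestraintSet, parse_tbl
from ..scoring import emscoring as run_emscoring
from ..scoring import sasascore as run_sasascore
from .config import ConfigError, WorkflowConfig, load_config
from .registry import MODULE_REGISTRY

logger = logging.getLogger(__name__)

__all__ = ["RunRecord", "StepError", "run_workflow", "traceback_table",
           "report"]

_FLOAT_FMT = "%.4f"


class StepError(RuntimeError):
    """A workflow step failed; the partial run directory is retained."""


@dataclass
class RunRecord:
    run_dir: Path
    step_dirs: list[Path]
    config: WorkflowConfig

    def manifest(self, index: int) -> pd.DataFrame:
        return pd.read_csv(self.step_dirs[index] / "manifest.tsv",
                           sep="\t", keep_default_na=False)


@dataclass
class _State:
    config: WorkflowConfig
    base: Path                        # directory config paths resolve from
    molecules: list[Ensemble] = field(default_factory=list)
    molecule_names: list[str] = field(default_factory=list)
    models: list[Model] = field(default_factory=list)
    partners: list[list[str]] | None = None
    clustering: cl.Clustering | None = None
    matrix: np.ndarray | None = None
    matrix_n: int = 0
    charged_termini: bool = True


def _resolve(state: _State, p: str | Path) -> Path:
    p = Path(p)
    return p if p.is_absolute() else state.base / p


def _load_restraint_sets(state: _State, params: dict
                         ) -> list[RestraintSet]:
    ambig = params.get("ambig_fname") or []
    if isinstance(ambig, str):
        ambig = [ambig] if ambig else []
    sets = [parse_tbl(_resolve(state, p)) for p in ambig]
    unambig = params.get("unambig_fname") or ""
    if unambig:
        extra = parse_tbl(_resolve(state, unambig))
        if not sets:
            sets = [RestraintSet("unambig")]
        for s in sets:
            s.unambiguous.extend(extra.unambiguous)
            s.ambiguous.extend(extra.ambiguous)
    return sets


def _set_for_model(model: Model, sets: list[RestraintSet]
                   ) -> RestraintSet | None:
    """The restraint set a model must keep using (never mixed)."""
    if not sets:
        return None
    sid = model.provenance.restraint_set_id
    by_id = {s.set_id: s for s in sets}
    if sid is not None and sid in by_id:
        return by_id[sid]
    if len(sets) == 1:
        return sets[0]
    return None


def _write_models(state: _State, step_dir: Path, step_name: str) -> None:
    """Rename models to <step>_<k>, write PDBs and the step manifest."""
    rows = []
    for k, model in enumerate(state.models, start=1):
        prov = model.provenance
        prov.parent = prov.name
        prov.name = f"{step_name}_{k}"
        fname = f"{prov.name}.pdb"
        write_pdb(model, step_dir / fname)
        rows.append({
            "model": prov.name, "file": fname,
            "score": "" if prov.score is None
            else _FLOAT_FMT % prov.score,
            "set_id": prov.restraint_set_id or "",
            "parent": prov.parent or "",
            "cluster_id": "" if prov.cluster_id is None
            else prov.cluster_id,
            "cluster_rank": "" if prov.cluster_rank is None
            else prov.cluster_rank,
        })
    pd.DataFrame(rows).to_csv(step_dir / "manifest.tsv", sep="\t",
                              index=False)


def _save_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _save_matrix(mat: np.ndarray, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        for i in range(mat.shape[0]):
            for j in range(mat.shape[1]):
                if i != j:
                    fh.write(f"{i + 1}\t{j + 1}\t{mat[i, j]:.4f}\n")


# ---------------------------------------------------------------------------
# step runners
# ---------------------------------------------------------------------------

def _run_topoaa(state: _State, params: dict, step_dir: Path) -> None:
    state.charged_termini = params["charged_termini"]
    rows = []
    for mi, mol_path in enumerate(state.config.molecules, start=1):
        ens = read_pdb(_resolve(state, mol_path))
        build_topology(ens[0], charged_termini=state.charged_termini)
        state.molecules.append(ens)
        name = f"topoaa_{mi}_1"
        state.molecule_names.append(name)
        for k, model in enumerate(ens, start=1):
            mname = f"topoaa_{mi}_{k}"
            model.provenance.name = mname
            model.provenance.parent = Path(mol_path).name
            fname = f"{mname}.pdb"
            write_pdb(model, step_dir / fname)
            rows.append({"model": mname, "file": fname, "score": "",
                         "set_id": "", "parent": Path(mol_path).name,
                         "cluster_id": "", "cluster_rank": ""})
    pd.DataFrame(rows).to_csv(step_dir / "manifest.tsv", sep="\t",
                              index=False)
    if len(state.molecules) == 1:
        # scoring-only workflow: the ensemble members are the models
        state.models = [m.copy() for m in state.molecules[0]]
        state.partners = [[c] for c in state.models[0].chains]


def _run_rigidbody(state: _State, params: dict, step_dir: Path) -> None:
    if len(state.molecules) != 2:
        raise StepError("rigidbody needs exactly two input molecules")
    sets = _load_restraint_sets(state, params)
    if not sets:
        raise StepError("rigidbody needs ambig_fname (or unambig_fname)")
    receptor = state.molecules[0][0]
    ligand = state.molecules[1][0]
    rec_top = build_topology(receptor,
                             charged_termini=state.charged_termini)
    lig_top = build_topology(ligand, charged_termini=state.charged_termini)
    seed = params["seed"] if params["seed"] >= 0 else state.config.seed
    models, table = sample_rigidbody(
        receptor, rec_top, ligand, lig_top, sets,
        n_models=params["sampling"], seed=seed,
        weights={"vdw": params["w_vdw"], "elec": params["w_elec"],
                 "air": params["w_air"]},
        removal_fraction=params["removal_fraction"],
        max_evals=params["max_evals"])
    parent = "+".join(state.molecule_names)
    for m in models:
        m.provenance.name = parent      # becomes `parent` on write
    state.models = models
    state.partners = [list(receptor.chains), list(ligand.chains)]
    _save_table(table, step_dir / "scores.tsv")
    _write_models(state, step_dir, "rigidbody")


def _refine(state: _State, params: dict, step_dir: Path,
            step_name: str, flexible: bool) -> None:
    if not state.models:
        raise StepError(f"{step_name}: no models from the previous step")
    sets = _load_restraint_sets(state, params)
    settings = RefinementSettings(
        n_steps=params["n_steps"],
        flexible_cutoff=params.get("flexible_cutoff", 5.0),
        tether_k=params.get("tether_k", 10.0))
    out: list[Model] = []
    for model in state.models:
        topology = build_topology(model,
                                  charged_termini=state.charged_termini)
        rset = _set_for_model(model, sets)
        if flexible:
            refined, report = flexible_refine(model, topology, rset,
                                              settings,
                                              partners=state.partners)
        else:
            refined, report = energy_minimize(model, topology, rset,
                                              settings=settings,
                                              partners=state.partners)
        # keep lineage/set identity; the score is the refined score
        prov = model.provenance.copy()
        prov.score = report.score
        refined.provenance = prov
        out.append(refined)
    # refinement re-ranks by the refined score
    order = sorted(range(len(out)),
                   key=lambda i: (out[i].provenance.score
                                  if out[i].provenance.score is not None
                                  else np.inf, i))
    state.models = [out[i] for i in order]
    _write_models(state, step_dir, step_name)


def _run_flexref(state: _State, params: dict, step_dir: Path) -> None:
    _refine(state, params, step_dir, "flexref", flexible=True)


def _run_emref(state: _State, params: dict, step_dir: Path) -> None:
    _refine(state, params, step_dir, "emref", flexible=False)


def _run_seletop(state: _State, params: dict, step_dir: Path) -> None:
    state.models = an.seletop(state.models, params["select"])
    state.clustering = None
    _write_models(state, step_dir, "seletop")


def _run_emscoring(state: _State, params: dict, step_dir: Path) -> None:
    if not state.models:
        raise StepError("emscoring: no models to score")
    refined, table = run_emscoring(state.models, partners=state.partners,
                                   em_steps=params["n_steps"],
                                   charged_termini=state.charged_termini)
    failed = table[table["error"] != ""]
    for _, row in failed.iterrows():
        logger.warning("emscoring: model %s failed: %s", row["model"],
                       row["error"])
    # keep ranked order; re-attach provenance names
    by_index = {int(r["model_index"]): r
                for _, r in table.iterrows() if r["error"] == ""}
    out = []
    for mi, model in enumerate(state.models):
        if mi not in by_index:
            continue
        ref_model = refined[[int(r["model_index"])
                             for _, r in table.iterrows()
                             if r["error"] == ""].index(mi)]
        ref_model.provenance = model.provenance.copy()
        ref_model.provenance.score = float(by_index[mi]["score"])
        out.append(ref_model)
    out.sort(key=lambda m: m.provenance.score)
    state.models = out
    _save_table(table.drop(columns=["model_index"]),
                step_dir / "scores.tsv")
    _write_models(state, step_dir, "emscoring")


def _parse_residue_list(items) -> list[tuple[str, int, str]]:
    out = []
    for item in items:
        chain, _, resseq = str(item).partition(":")
        out.append((chain, int(resseq), ""))
    return out


def _run_sasascore(state: _State, params: dict, step_dir: Path) -> None:
    if not state.models:
        raise StepError("sasascore: no models to score")
    buried = _parse_residue_list(params["buried"])
    accessible = _parse_residue_list(params["accessible"])
    rows = []
    for model in state.models:
        topology = build_topology(model,
                                  charged_termini=state.charged_termini)
        violations, _ = run_sasascore(model, buried, accessible,
                                      params["rel_cutoff"], topology)
        model.provenance.score = float(violations)
        rows.append({"model": model.provenance.name,
                     "violations": violations})
    state.models.sort(key=lambda m: m.provenance.score)
    _save_table(pd.DataFrame(rows), step_dir / "scores.tsv")
    _write_models(state, step_dir, "sasascore")


def _run_caprieval(state: _State, params: dict, step_dir: Path) -> None:
    if not state.models:
        raise StepError("caprieval: no models to evaluate")
    reference = None
    if params["reference_fname"]:
        reference = read_pdb(_resolve(state,
                                      params["reference_fname"]))[0]
    ss, clt = cp.caprieval(state.models, reference=reference,
                           clustering=state.clustering,
                           partners=state.partners,
                           top_n=params["top_n"])
    _save_table(ss, step_dir / "capri_ss.tsv")
    _save_table(clt, step_dir / "capri_clt.tsv")
    _write_models(state, step_dir, "caprieval")


def _run_clustfcc(state: _State, params: dict, step_dir: Path) -> None:
    if not state.models:
        raise StepError("clustfcc: no models to cluster")
    mat = cl.fcc_matrix(state.models, cutoff=params["contact_cutoff"])
    scores = [m.provenance.score if m.provenance.score is not None
              else np.inf for m in state.models]
    state.clustering = cl.cluster_fcc(mat, threshold=params["threshold"],
                                      min_size=params["min_size"],
                                      scores=scores)
    _finish_clustering(state, step_dir, "clustfcc", mat, "fcc")


def _run_rmsdmatrix(state: _State, params: dict, step_dir: Path) -> None:
    if not state.models:
        raise StepError("rmsdmatrix: no models")
    state.matrix = cl.rmsd_matrix(state.models)
    state.matrix_n = len(state.models)
    _save_matrix(state.matrix, step_dir / "rmsd_matrix.tsv")
    _write_models(state, step_dir, "rmsdmatrix")


def _run_ilrmsdmatrix(state: _State, params: dict, step_dir: Path) -> None:
    if not state.models:
        raise StepError("ilrmsdmatrix: no models")
    state.matrix = cl.ilrmsd_matrix(state.models, partners=state.partners,
                                    interface_cutoff=params[
                                        "interface_cutoff"])
    state.matrix_n = len(state.models)
    _save_matrix(state.matrix, step_dir / "ilrmsd_matrix.tsv")
    _write_models(state, step_dir, "ilrmsdmatrix")


def _run_clustrmsd(state: _State, params: dict, step_dir: Path) -> None:
    if not state.models:
        raise StepError("clustrmsd: no models to cluster")
    cutoff = params["cutoff"] or None
    n_clusters = params["n_clusters"] or None
    if cutoff is not None and n_clusters is not None:
        raise StepError("clustrmsd: give either cutoff or n_clusters, "
                        "not both")
    if cutoff is None and n_clusters is None:
        cutoff = 7.5            # Å, default dendrogram cut
    if state.matrix is not None and state.matrix_n == len(state.models):
        mat = state.matrix
    else:
        mat = cl.rmsd_matrix(state.models)
    scores = [m.provenance.score if m.provenance.score is not None
              else np.inf for m in state.models]
    state.clustering = cl.cluster_rmsd(mat, cutoff=cutoff,
                                       n_clusters=n_clusters,
                                       min_size=params["min_size"],
                                       scores=scores)
    _finish_clustering(state, step_dir, "clustrmsd", mat, "rmsd")


def _finish_clustering(state: _State, step_dir: Path, step_name: str,
                       mat: np.ndarray, kind: str) -> None:
    for i, model in enumerate(state.models):
        model.provenance.cluster_id = state.clustering.labels[i]
    _save_matrix(mat, step_dir / f"{kind}_matrix.tsv")
    rows = [{"model": m.provenance.name,
             "cluster_id": state.clustering.labels[i] or ""}
            for i, m in enumerate(state.models)]
    _save_table(pd.DataFrame(rows), step_dir / "clusters.tsv")
    _write_models(state, step_dir, step_name)


def _run_seletopclusts(state: _State, params: dict, step_dir: Path) -> None:
    if state.clustering is None:
        raise StepError("seletopclusts requires a preceding clustering "
                        "step")
    state.models = an.seletopclusts(state.models, state.clustering,
                                    n_clusters=params["top_clusters"],
                                    n_per_cluster=params["top_models"])
    state.clustering = None        # indices no longer aligned
    _write_models(state, step_dir, "seletopclusts")


def _run_filter(state: _State, params: dict, step_dir: Path) -> None:
    state.models = an.filter_models(state.models, params["threshold"])
    state.clustering = None
    _write_models(state, step_dir, "filter")


def _run_alascan(state: _State, params: dict, step_dir: Path) -> None:
    if not state.models:
        raise StepError("alascan: no models")
    best = state.models[0]
    table = an.alascan(best, target_aa=params["target"],
                       em_steps=params["em_steps"],
                       partners=state.partners)
    _save_table(table, step_dir / "alascan.tsv")
    _write_models(state, step_dir, "alascan")


def _run_contactmap(state: _State, params: dict, step_dir: Path) -> None:
    if not state.models:
        raise StepError("contactmap: no models")
    groups: list[tuple[str, list[Model]]]
    if params["per_cluster"] and state.clustering is not None \
            and state.clustering.n_clusters:
        groups = [(f"cluster_{cid}",
                   [state.models[i]
                    for i in state.clustering.members(cid)])
                  for cid in range(1, state.clustering.n_clusters + 1)]
    else:
        groups = [("best_model", [state.models[0]])]
    for label, members in groups:
        table, chord = an.contact_map(members, cutoff=params["cutoff"])
        _save_table(table, step_dir / f"contacts_{label}.tsv")
        _save_table(chord, step_dir / f"chord_{label}.tsv")
    _write_models(state, step_dir, "contactmap")


_RUNNERS = {
    "topoaa": _run_topoaa,
    "rigidbody": _run_rigidbody,
    "seletop": _run_seletop,
    "flexref": _run_flexref,
    "emref": _run_emref,
    "emscoring": _run_emscoring,
    "sasascore": _run_sasascore,
    "caprieval": _run_caprieval,
    "clustfcc": _run_clustfcc,
    "rmsdmatrix": _run_rmsdmatrix,
    "ilrmsdmatrix": _run_ilrmsdmatrix,
    "clustrmsd": _run_clustrmsd,
    "seletopclusts": _run_seletopclusts,
    "filter": _run_filter,
    "alascan": _run_alascan,
    "contactmap": _run_contactmap,
}


def run_workflow(config: WorkflowConfig | str | Path) -> RunRecord:
    """Validate and execute a workflow; returns the run record.

    Step i writes into ``<i>_<module>`` (0-based).  A failing step aborts
    the run with a :class:`StepError`; the partial run directory is kept
    for inspection.
    """
    if not isinstance(config, WorkflowConfig):
        config = load_config(config)
    base = config.source.parent if config.source else Path(".")
    run_dir = config.run_dir
    if not run_dir.is_absolute():
        run_dir = base / run_dir
    if run_dir.exists() and any(run_dir.iterdir()):
        raise ConfigError(f"run directory {run_dir} already exists and is "
                          f"not empty")
    run_dir.mkdir(parents=True, exist_ok=True)
    data_dir = run_dir / "data"
    data_dir.mkdir()
    for mol in config.molecules:
        shutil.copy(base / mol if not mol.is_absolute() else mol, data_dir)
    for step in config.steps:
        for key in ("ambig_fname", "unambig_fname", "reference_fname"):
            val = step.params.get(key)
            if not val:
                continue
            for p in (val if isinstance(val, list) else [val]):
                src = Path(p) if Path(p).is_absolute() else base / p
                if src.exists():
                    shutil.copy(src, data_dir)

    state = _State(config=config, base=base)
    step_dirs: list[Path] = []
    for i, step in enumerate(config.steps):
        step_dir = run_dir / f"{i}_{step.module}"
        step_dir.mkdir()
        step_dirs.append(step_dir)
        logger.info("step %d: %s", i, step.step_id)
        try:
            _RUNNERS[step.module](state, step.params, step_dir)
        except StepError:
            raise
        except Exception as exc:
            raise StepError(f"step {i} ({step.step_id}) failed: "
                            f"{exc}") from exc
    return RunRecord(run_dir=run_dir, step_dirs=step_dirs, config=config)


# ---------------------------------------------------------------------------
# traceback and reporting
# ---------------------------------------------------------------------------

def _step_manifests(run_dir: Path) -> list[tuple[str, pd.DataFrame]]:
    run_dir = Path(run_dir)
    steps = sorted((d for d in run_dir.iterdir()
                    if d.is_dir() and d.name[0].isdigit()),
                   key=lambda d: int(d.name.split("_", 1)[0]))
    out = []
    for d in steps:
        mpath = d / "manifest.tsv"
        if not mpath.exists():
            raise FileNotFoundError(f"missing manifest for step {d.name}")
        out.append((d.name, pd.read_csv(mpath, sep="\t",
                                        keep_default_na=False)))
    return out


def traceback_table(run_dir: Path) -> pd.DataFrame:
    """Lineage of every model: its name at every step it survived.

    One row per terminal model (dropped models are truncated at the step
    that dropped them); columns are the step directories, plus the
    restraint-set id of the lineage.
    """
    manifests = _step_manifests(Path(run_dir))
    step_names = [name for name, _ in manifests]
    parent_of: dict[tuple[int, str], str] = {}
    info: dict[tuple[int, str], dict] = {}
    has_child: set[tuple[int, str]] = set()
    for si, (_, mf) in enumerate(manifests):
        for _, row in mf.iterrows():
            key = (si, row["model"])
            parent_of[key] = str(row["parent"])
            info[key] = dict(row)
    for (si, name), parent in parent_of.items():
        for back in range(si - 1, -1, -1):
            for pname in parent.split("+"):
                if (back, pname) in info:
                    has_child.add((back, pname))
            if any((back, p) in info for p in parent.split("+")):
                break
    rows = []
    for key in sorted(info, key=lambda k: (k[0], k[1])):
        if key in has_child:
            continue
        si, name = key
        chain: dict[str, str] = {s: "-" for s in step_names}
        cur: tuple[int, str] | None = key
        while cur is not None:
            ci, cname = cur
            chain[step_names[ci]] = cname
            parent = parent_of.get(cur, "")
            nxt = None
            for back in range(ci - 1, -1, -1):
                hits = [p for p in parent.split("+") if (back, p) in info]
                if hits:
                    nxt = (back, hits[0])
                    if len(hits) > 1:
                        chain[step_names[back]] = "+".join(hits)
                        nxt = None
                    break
            cur = nxt
        rows.append({**chain, "set_id": info[key].get("set_id", ""),
                     "score": info[key].get("score", "")})
    return pd.DataFrame(rows)


def report(run_dir: Path, make_plots: bool = True) -> Path:
    """Summary tables (and optional static plots) for a finished run.

    Writes ``analysis/`` inside the run directory: per-step score
    distributions and, when a caprieval step exists, score-vs-metric
    scatter data grouped by cluster.  Without metrics the report is
    limited to scores (with a warning).
    """
    import warnings

    run_dir = Path(run_dir)
    manifests = _step_manifests(run_dir)
    if not manifests:
        raise ValueError(f"{run_dir} contains no step manifests")
    out_dir = run_dir / "analysis"
    out_dir.mkdir(exist_ok=True)

    rows = []
    for name, mf in manifests:
        scores = pd.to_numeric(mf["score"], errors="coerce").dropna()
        rows.append({"step": name, "n_models": len(mf),
                     "best_score": scores.min() if len(scores) else "",
                     "mean_score": scores.mean() if len(scores) else ""})
    _save_table(pd.DataFrame(rows), out_dir / "steps.tsv")

    capri_dirs = [run_dir / name for name, _ in manifests
                  if name.endswith("_caprieval")
                  and (run_dir / name / "capri_ss.tsv").exists()]
    if not capri_dirs:
        warnings.warn("no caprieval output: report limited to scores",
                      stacklevel=2)
        return out_dir
    ss = pd.read_csv(capri_dirs[-1] / "capri_ss.tsv", sep="\t",
                     keep_default_na=False)
    _save_table(ss, out_dir / "score_vs_metrics.tsv")
    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 4))
        cid = ss["cluster_id"].replace("", "noise")
        for label, sub in ss.groupby(cid):
            ax.scatter(sub["irmsd"], sub["score"], s=14, label=str(label))
        ax.set_xlabel("interface RMSD (Å)")
        ax.set_ylabel("score")
        ax.legend(title="cluster", fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / "score_vs_irmsd.png", dpi=120)
        plt.close(fig)
    return out_dir
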