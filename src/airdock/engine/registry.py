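"""Module registry: every workflow step, its category and its parameters.

Modules fall into exactly five categories — topology, sampling,
refinement, scoring and analysis.  Each registry entry declares a typed
parameter schema with defaults and descriptions; the ``cfg`` CLI renders
it, and config validation checks user parameters against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["Param", "ModuleSpec", "MODULE_REGISTRY", "CATEGORIES",
           "cfg_query"]

CATEGORIES = ("topology", "sampling", "refinement", "scoring", "analysis")


@dataclass(frozen=True)
class Param:
    type: type
    default: Any
    description: str
    choices: tuple | None = None

    def check(self, value: Any) -> bool:
        if self.type is float and isinstance(value, int) \
                and not isinstance(value, bool):
            return True
        if self.type is list:
            return isinstance(value, (list, str))
        if self.type is int and isinstance(value, bool):
            return False
        ok = isinstance(value, self.type)
        if ok and self.choices is not None:
            ok = value in self.choices
        return ok


@dataclass(frozen=True)
class ModuleSpec:
    name: str
    category: str
    description: str
    params: dict[str, Param] = field(default_factory=dict)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")


_RESTRAINT_PARAMS = {
    "ambig_fname": Param(list, "", "ambiguous restraint file(s), .tbl "
                         "(a list means one restraint set per file)"),
    "unambig_fname": Param(str, "", "unambiguous restraint file, .tbl "
                           "(applied on top of every set)"),
}

MODULE_REGISTRY: dict[str, ModuleSpec] = {s.name: s for s in [
    ModuleSpec("topoaa", "topology", "all-atom (heavy-atom) topology "
               "generation for every input molecule", {
        "charged_termini": Param(bool, True, "apply +1/-1 charge patches "
                                 "to free chain termini"),
    }),
    ModuleSpec("rigidbody", "sampling", "restraint-driven rigid-body "
               "docking of two molecules", {
        **_RESTRAINT_PARAMS,
        "sampling": Param(int, 1000, "number of rigid-body models to "
                          "generate"),
        "seed": Param(int, -1, "stage seed; -1 inherits the global seed"),
        "w_vdw": Param(float, 0.01, "van der Waals weight in the rigid "
                       "search energy"),
        "w_elec": Param(float, 1.0, "electrostatic weight in the rigid "
                        "search energy"),
        "w_air": Param(float, 0.1, "restraint weight in the rigid search "
                       "energy"),
        "removal_fraction": Param(float, 0.5, "fraction of ambiguous "
                                  "restraints randomly removed per model"),
        "max_evals": Param(int, 300, "simplex energy evaluations per "
                           "model"),
    }),
    ModuleSpec("seletop", "analysis", "keep the n best-scored models", {
        "select": Param(int, 200, "number of models to keep"),
    }),
    ModuleSpec("flexref", "refinement", "semiflexible interface "
               "refinement (restrained Cartesian minimization)", {
        **_RESTRAINT_PARAMS,
        "n_steps": Param(int, 100, "maximum minimization iterations"),
        "flexible_cutoff": Param(float, 5.0, "Å; residues within this "
                                 "distance of the partner move freely"),
        "tether_k": Param(float, 10.0, "kcal/mol/Å² positional restraint "
                          "on non-interface atoms"),
    }),
    ModuleSpec("emref", "refinement", "unrestrained energy-minimization "
               "refinement", {
        **_RESTRAINT_PARAMS,
        "n_steps": Param(int, 200, "maximum minimization iterations"),
    }),
    ModuleSpec("emscoring", "scoring", "topology + short energy "
               "minimization + composite score per model", {
        "n_steps": Param(int, 100, "minimization iterations before "
                         "scoring"),
    }),
    ModuleSpec("sasascore", "scoring", "accessibility-compliance scoring "
               "against expected buried/accessible residues", {
        "buried": Param(list, [], "residues expected buried, as "
                        "'CHAIN:RESSEQ' strings"),
        "accessible": Param(list, [], "residues expected accessible, as "
                            "'CHAIN:RESSEQ' strings"),
        "rel_cutoff": Param(float, 0.15, "relative-accessibility "
                            "threshold"),
    }),
    ModuleSpec("caprieval", "analysis", "CAPRI metrics vs a reference or "
               "the best-scored model", {
        "reference_fname": Param(str, "", "reference complex PDB; empty "
                                 "= use the best-scored model"),
        "top_n": Param(int, 4, "members per cluster entering cluster "
                       "statistics"),
    }),
    ModuleSpec("clustfcc", "analysis", "fraction-of-common-contacts "
               "clustering", {
        "threshold": Param(float, 0.6, "mutual FCC similarity threshold"),
        "min_size": Param(int, 4, "smallest cluster kept"),
        "contact_cutoff": Param(float, 5.0, "Å heavy-atom contact rule"),
    }),
    ModuleSpec("rmsdmatrix", "analysis", "pairwise backbone RMSD matrix", {
    }),
    ModuleSpec("ilrmsdmatrix", "analysis", "pairwise interface-ligand "
               "RMSD matrix", {
        "interface_cutoff": Param(float, 10.0, "Å interface residue "
                                  "rule"),
    }),
    ModuleSpec("clustrmsd", "analysis", "hierarchical (average-linkage) "
               "clustering of an RMSD matrix", {
        "cutoff": Param(float, 0.0, "dendrogram distance cut in Å "
                        "(0 = unset)"),
        "n_clusters": Param(int, 0, "number of clusters to cut into "
                            "(0 = unset)"),
        "min_size": Param(int, 4, "smallest cluster kept"),
    }),
    ModuleSpec("seletopclusts", "analysis", "keep the top models of the "
               "top clusters", {
        "top_clusters": Param(int, 10, "number of clusters to keep"),
        "top_models": Param(int, 4, "models kept per cluster"),
    }),
    ModuleSpec("filter", "analysis", "filter models on a score "
               "threshold", {
        "threshold": Param(float, 0.0, "keep models with score <= "
                           "threshold"),
    }),
    ModuleSpec("alascan", "analysis", "point-mutation scan of interface "
               "residues", {
        "target": Param(str, "ALA", "target residue of the scan"),
        "em_steps": Param(int, 50, "minimization iterations per mutant"),
    }),
    ModuleSpec("contactmap", "analysis", "residue-residue contact map "
               "and chord data", {
        "cutoff": Param(float, 5.0, "Å heavy-atom contact rule"),
        "per_cluster": Param(bool, True, "one map per cluster when a "
                             "clustering exists"),
    }),
]}


def cfg_query(module: str | None = None) -> str:
    """Human-readable parameter documentation for one module or all."""
    if module is not None and module != "all":
        if module not in MODULE_REGISTRY:
            raise KeyError(f"unknown module {module!r}; available: "
                           f"{sorted(MODULE_REGISTRY)}")
        specs = [MODULE_REGISTRY[module]]
    else:
        specs = [MODULE_REGISTRY[k] for k in MODULE_REGISTRY]
    lines: list[str] = []
    for spec in specs:
        lines.append(f"[{spec.name}] ({spec.category}) — "
                     f"{spec.description}")
        if not spec.params:
            lines.append("  (no parameters)")
        for name, p in spec.params.items():
            lines.append(f"  {name} ({p.type.__name__}, default "
                         f"{p.default!r}): {p.description}")
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"
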