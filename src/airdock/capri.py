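"""CAPRI-style quality assessment of docked models against a reference.

Metrics
-------
fnat
    Fraction of the reference's intermolecular residue contacts (5 Å
    heavy-atom rule) reproduced by the model.
L-RMSD
    Ligand backbone RMSD after superposition on the receptor backbone.
i-RMSD
    Backbone RMSD over the reference interface residues (10 Å rule) after
    superposition on those same atoms.
IL-RMSD
    Ligand-interface heavy-atom RMSD after superposition on the receptor
    interface backbone.
DockQ
    ``(fnat + 1/(1+(irmsd/1.5)^2) + 1/(1+(lrmsd/8.5)^2)) / 3``.

Quality classes follow the community thresholds: high / medium /
acceptable / incorrect.  Residue correspondence is by identifier
(chain, residue number, insertion code) — **not** by sequence alignment;
models must be numbered consistently with the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import (CONTACT_CUTOFF, Clustering,
                         ILRMSD_INTERFACE_CUTOFF, contacts,
                         interface_residue_keys)
from .pdbio import BACKBONE_ATOMS, Model
from .superpose import superposed_rmsd

__all__ = [
    "CapriMetrics",
    "fnat",
    "lrmsd",
    "irmsd",
    "ilrmsd",
    "dockq",
    "capri_class",
    "evaluate_model",
    "caprieval",
    "CLUSTER_TOP_N",
]

CLUSTER_TOP_N = 4   # members per cluster entering cluster statistics


@dataclass(frozen=True)
class CapriMetrics:
    fnat: float
    lrmsd: float
    irmsd: float
    ilrmsd: float
    dockq: float
    capri_class: str


class CorrespondenceError(ValueError):
    """Model and reference share too few atoms to compare."""


def _atom_table(model: Model, kind: str,
                chains: set[str] | None = None,
                residues: set | None = None) -> dict[tuple, np.ndarray]:
    out: dict[tuple, np.ndarray] = {}
    for res in model.residues:
        if chains is not None and res.chain not in chains:
            continue
        if residues is not None and res.key not in residues:
            continue
        for a in res.atoms:
            if kind == "backbone" and a.name not in BACKBONE_ATOMS:
                continue
            if a.element == "H":
                continue
            out[(res.chain, res.resseq, res.icode, a.name)] = a.xyz
    return out


def _paired(model: Model, reference: Model, kind: str,
            chains: set[str] | None = None,
            residues: set | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms shared (by identifier) between both structures.

    Atoms missing on either side are excluded; more than 50% of the
    reference side missing is an error.
    """
    dm = _atom_table(model, kind, chains, residues)
    dr = _atom_table(reference, kind, chains, residues)
    common = sorted(set(dm) & set(dr))
    if not dr:
        raise CorrespondenceError("reference selection is empty")
    if len(common) < 0.5 * len(dr):
        raise CorrespondenceError(
            f"only {len(common)} of {len(dr)} reference atoms have a "
            f"counterpart in the model")
    return (np.array([dm[k] for k in common]),
            np.array([dr[k] for k in common]))


def _partner_chains(model: Model,
                    partners: list[list[str]] | None) -> tuple[set, set]:
    if partners is None:
        chains = model.chains
        return {chains[0]}, set(chains[1:])
    return set(partners[0]), {c for g in partners[1:] for c in g}


def fnat(model: Model, reference: Model,
         cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of reference intermolecular contacts kept by the model."""
    ref_contacts = contacts(reference, cutoff)
    if len(ref_contacts) == 0:
        raise ValueError("reference has no intermolecular contacts")
    mod_contacts = contacts(model, cutoff)
    return len(mod_contacts.pairs & ref_contacts.pairs) / len(ref_contacts)


def lrmsd(model: Model, reference: Model,
          partners: list[list[str]] | None = None) -> float:
    """Ligand backbone RMSD after receptor-backbone superposition."""
    rec, lig = _partner_chains(reference, partners)
    fit_m, fit_r = _paired(model, reference, "backbone", chains=rec)
    over_m, over_r = _paired(model, reference, "backbone", chains=lig)
    return superposed_rmsd(fit_m, fit_r, over_m, over_r)


def irmsd(model: Model, reference: Model,
          partners: list[list[str]] | None = None,
          interface_cutoff: float = ILRMSD_INTERFACE_CUTOFF) -> float:
    """Interface backbone RMSD (reference-defined interface, 10 Å rule)."""
    iface = interface_residue_keys(reference, interface_cutoff)
    fit_m, fit_r = _paired(model, reference, "backbone", residues=iface)
    return superposed_rmsd(fit_m, fit_r)


def ilrmsd(model: Model, reference: Model,
           partners: list[list[str]] | None = None,
           interface_cutoff: float = ILRMSD_INTERFACE_CUTOFF) -> float:
    """Ligand-interface heavy-atom RMSD after receptor-interface fit."""
    rec, lig = _partner_chains(reference, partners)
    iface = interface_residue_keys(reference, interface_cutoff)
    rec_iface = {k for k in iface if k[0] in rec}
    lig_iface = {k for k in iface if k[0] in lig}
    fit_m, fit_r = _paired(model, reference, "backbone", residues=rec_iface)
    over_m, over_r = _paired(model, reference, "heavy", residues=lig_iface)
    return superposed_rmsd(fit_m, fit_r, over_m, over_r)


def dockq(fnat_value: float, irmsd_value: float, lrmsd_value: float) -> float:
    """DockQ = (fnat + s(irmsd, 1.5) + s(lrmsd, 8.5)) / 3, s = 1/(1+(x/d)²)."""
    if not (0.0 <= fnat_value <= 1.0):
        raise ValueError(f"fnat {fnat_value} outside [0, 1]")
    s_i = 1.0 / (1.0 + (irmsd_value / 1.5) ** 2)
    s_l = 1.0 / (1.0 + (lrmsd_value / 8.5) ** 2)
    return (fnat_value + s_i + s_l) / 3.0


def capri_class(fnat_value: float, irmsd_value: float,
                lrmsd_value: float) -> str:
    """CAPRI quality class; the highest satisfied class wins."""
    if fnat_value >= 0.5 and (irmsd_value <= 1.0 or lrmsd_value <= 1.0):
        return "high"
    if fnat_value >= 0.3 and (irmsd_value <= 2.0 or lrmsd_value <= 5.0):
        return "medium"
    if fnat_value >= 0.1 and (irmsd_value <= 4.0 or lrmsd_value <= 10.0):
        return "acceptable"
    return "incorrect"


def evaluate_model(model: Model, reference: Model,
                   partners: list[list[str]] | None = None) -> CapriMetrics:
    """All CAPRI metrics of one model against a reference."""
    f = fnat(model, reference)
    lr = lrmsd(model, reference, partners)
    ir = irmsd(model, reference, partners)
    ilr = ilrmsd(model, reference, partners)
    q = dockq(f, ir, lr)
    return CapriMetrics(f, lr, ir, ilr, q, capri_class(f, ir, lr))


def caprieval(models: list[Model], reference: Model | None = None,
              clustering: Clustering | None = None,
              partners: list[list[str]] | None = None,
              top_n: int = CLUSTER_TOP_N
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-model and per-cluster CAPRI tables.

    Without a reference, models are compared against the best-scored model
    (ties broken by input index).  Cluster statistics are mean ± std
    (population) of score and metrics over each cluster's ``top_n``
    best-scored members.
    """
    if not models:
        raise ValueError("no models to evaluate")
    if reference is None:
        scored = [(m.provenance.score if m.provenance.score is not None
                   else np.inf, i) for i, m in enumerate(models)]
        reference = models[min(scored)[1]]

    # cluster labels: an explicit clustering, else provenance (which is
    # how cluster identity survives a selection step)
    if clustering is not None:
        labels = list(clustering.labels)
    else:
        labels = [m.provenance.cluster_id for m in models]

    rows = []
    for i, m in enumerate(models):
        met = evaluate_model(m, reference, partners)
        cid = labels[i]
        rows.append({
            "model": m.provenance.name or f"model_{i + 1}",
            "score": m.provenance.score,
            "fnat": met.fnat, "lrmsd": met.lrmsd, "irmsd": met.irmsd,
            "ilrmsd": met.ilrmsd, "dockq": met.dockq,
            "capri_class": met.capri_class,
            "cluster_id": cid,
            "set_id": m.provenance.restraint_set_id,
        })
    ss = pd.DataFrame(rows)
    order = ss["score"].fillna(np.inf).argsort(kind="stable")
    ss = ss.iloc[order].reset_index(drop=True)
    ss.insert(0, "rank", np.arange(1, len(ss) + 1))

    metric_cols = ["score", "fnat", "lrmsd", "irmsd", "ilrmsd", "dockq"]
    clusters: dict[int, list[int]] = {}
    for i, cid in enumerate(labels):
        if cid is not None and not pd.isna(cid):
            clusters.setdefault(int(cid), []).append(i)
    crows = []
    for cid in sorted(clusters):
        members = clusters[cid]
        ranked = sorted(
            members,
            key=lambda i: (models[i].provenance.score
                           if models[i].provenance.score is not None
                           else np.inf, i))[:top_n]
        sub = pd.DataFrame([rows[i] for i in ranked])
        row = {"cluster_id": cid, "n": len(members),
               "n_used": len(ranked)}
        for col in metric_cols:
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_std"] = float(sub[col].std(ddof=0))
        crows.append(row)
    clt = pd.DataFrame(crows)
    if len(clt):
        # clusters ranked by the mean score of their best members
        clt = clt.sort_values("score_mean", kind="stable").reset_index(
            drop=True)
        clt.insert(0, "cluster_rank", np.arange(1, len(clt) + 1))
    return ss, clt
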