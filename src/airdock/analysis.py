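"""Model selection, alanine scanning and contact-map analysis.

Interface residues follow the 5 Å heavy-atom rule throughout: a residue is
interfacial when any of its heavy atoms lies within 5 Å of a heavy atom of
another chain.  The alanine scan mutates each interface residue in turn,
re-minimizes briefly and reports the score difference

    Δscore = score(wild type) - score(mutant)

so a positive Δ means the mutation worsens the score (a hot-spot
candidate), together with per-component deltas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .build import place_sidechain
from .clustering import CONTACT_CUTOFF, Clustering, contacts
from .forcefield import TEMPLATES, build_topology
from .pdbio import Model
from .scoring import EnergyReport, score_complex

logger = logging.getLogger(__name__)

__all__ = [
    "seletop",
    "seletopclusts",
    "filter_models",
    "interface_residues",
    "mutate_residue",
    "alascan",
    "contact_map",
    "residue_class",
    "UnsupportedMutationError",
]

# residue classes for contact typing
_CHARGED = {"ASP", "GLU", "LYS", "ARG", "HIS"}
_POLAR = {"SER", "THR", "ASN", "GLN", "TYR", "TRP", "CYS"}

# grafting arbitrary ring geometry is out of scope for v1
_RING_RESIDUES = {"PHE", "TYR", "TRP", "HIS"}


class UnsupportedMutationError(ValueError):
    """Mutation target or site not supported (PRO and ring targets, v1)."""


def _score_of(model: Model, index: int) -> float:
    s = model.provenance.score
    return s if s is not None else np.inf


def seletop(models: list[Model], n: int) -> list[Model]:
    """The n lowest-score models (stable tie-break on input index)."""
    if n <= 0:
        raise ValueError(f"seletop needs n > 0, got {n}")
    if n > len(models):
        warnings.warn(f"seletop: requested {n} of {len(models)} models; "
                      f"keeping all", stacklevel=2)
        n = len(models)
    order = sorted(range(len(models)),
                   key=lambda i: (_score_of(models[i], i), i))
    return [models[i] for i in order[:n]]


def seletopclusts(models: list[Model], clustering: Clustering,
                  n_clusters: int = 10,
                  n_per_cluster: int = 4) -> list[Model]:
    """Top ``n_per_cluster`` models of the best ``n_clusters`` clusters.

    Cluster order comes from the clustering (size, then best score);
    within a cluster models are taken by ascending score.  Selected models
    record their cluster id and rank-in-cluster in provenance.
    """
    if clustering.n_clusters == 0:
        raise ValueError("no clusters to select from")
    out: list[Model] = []
    for cid in range(1, min(n_clusters, clustering.n_clusters) + 1):
        members = sorted(clustering.members(cid),
                         key=lambda i: (_score_of(models[i], i), i))
        for rank, mi in enumerate(members[:n_per_cluster], start=1):
            m = models[mi]
            m.provenance.cluster_id = cid
            m.provenance.cluster_rank = rank
            out.append(m)
    return out


def filter_models(models: list[Model], threshold: float) -> list[Model]:
    """Keep models with score <= threshold (lower is better)."""
    kept = [m for i, m in enumerate(models)
            if _score_of(m, i) <= threshold]
    if not kept:
        warnings.warn(f"filter: no model at or below score {threshold}",
                      stacklevel=2)
    return kept


def interface_residues(model: Model, cutoff: float = CONTACT_CUTOFF
                       ) -> dict[str, list[tuple[int, str]]]:
    """Interface residues per chain: any intermolecular heavy atom < cutoff."""
    cset = contacts(model, cutoff)
    per_chain: dict[str, set[tuple[int, str]]] = {c: set()
                                                  for c in model.chains}
    for a, b in cset.pairs:
        per_chain[a[0]].add((a[1], a[2]))
        per_chain[b[0]].add((b[1], b[2]))
    return {c: sorted(v) for c, v in per_chain.items()}


def mutate_residue(model: Model, chain: str, resseq: int, target_aa: str,
                   icode: str = "") -> Model:
    """Return a copy of the model with one residue mutated.

    Alanine (the default scan target) truncates the side chain at CB;
    GLY→ALA grows a CB along the N-CA-C bisector at 1.53 Å.  Other targets
    graft an ideal template side chain aligned on the N/CA/C frame (a
    short minimization afterwards resolves clashes).  PRO — as site or
    target — and ring targets are not supported in v1.
    """
    target_aa = target_aa.upper()
    if target_aa not in TEMPLATES:
        raise KeyError(f"no template for target residue {target_aa!r}")
    if target_aa in _RING_RESIDUES:
        raise UnsupportedMutationError(
            f"mutation to ring residue {target_aa} is not supported")
    out = model.copy()
    res = out.residue(chain, resseq, icode)
    if res.resname == "PRO" or target_aa == "PRO":
        raise UnsupportedMutationError(
            "mutations involving proline are not supported")
    if res.resname == target_aa:
        return out

    n = res.atom("N").xyz
    ca = res.atom("CA").xyz
    c = res.atom("C").xyz
    keep = {"N", "CA", "C", "O", "OXT"}
    backbone = [a for a in res.atoms if a.name in keep]
    new_side = place_sidechain(target_aa, n, ca, c)
    if res.has_atom("CB"):        # keep the native CB position
        new_side["CB"] = res.atom("CB").xyz.copy()
        # re-anchor atoms grown from CB onto the native CB
        shift = res.atom("CB").xyz - place_sidechain(target_aa, n, ca,
                                                     c)["CB"]
        for name in new_side:
            if name != "CB":
                new_side[name] = new_side[name] + shift
    res.atoms = backbone
    tpl = TEMPLATES[target_aa]
    serial = max((a.serial for a in out.atoms()), default=0)
    for name in tpl.atoms:
        if name in keep:
            continue
        serial += 1
        rec = backbone[0].copy()
        rec.serial = serial
        rec.name = name
        rec.xyz = np.asarray(new_side[name], dtype=float)
        rec.element = name[0] if name[0] in "NOS" else "C"
        res.atoms.append(rec)
    res.resname = target_aa
    for a in res.atoms:
        a.resname = target_aa
    return out


def alascan(model: Model, target_aa: str = "ALA", em_steps: int = 50,
            partners: list[list[str]] | None = None,
            profile: str | dict = "refined",
            cutoff: float = CONTACT_CUTOFF) -> pd.DataFrame:
    """Mutational scan of all interface residues (5 Å rule).

    Each interface residue is mutated to ``target_aa`` starting from the
    same wild-type coordinates, the complex is briefly re-minimized and
    rescored; the table reports Δscore = score_wt − score_mut and the
    per-component deltas.  Residues already equal to the target are
    reported with Δ = 0 and flagged as skipped, as are per-residue
    failures (the scan continues).
    """
    from .docking import energy_minimize

    def _score(m: Model) -> EnergyReport:
        top = build_topology(m)
        _, report = energy_minimize(m, top, n_steps=em_steps,
                                    partners=partners, profile=profile)
        return report

    wt = _score(model)
    iface = interface_residues(model, cutoff)
    rows = []
    for chain_id in model.chains:
        for resseq, icode in iface[chain_id]:
            res = model.residue(chain_id, resseq, icode)
            row = {"chain": chain_id, "resseq": resseq, "icode": icode,
                   "resname": res.resname, "target": target_aa,
                   "delta_score": 0.0, "delta_vdw": 0.0, "delta_elec": 0.0,
                   "delta_desolv": 0.0, "delta_bsa": 0.0,
                   "skipped": False, "error": ""}
            if res.resname == target_aa:
                row["skipped"] = True
                rows.append(row)
                continue
            try:
                mut = mutate_residue(model, chain_id, resseq, target_aa,
                                     icode)
                rep = _score(mut)
                row.update({
                    "delta_score": wt.score - rep.score,
                    "delta_vdw": wt.e_vdw - rep.e_vdw,
                    "delta_elec": wt.e_elec - rep.e_elec,
                    "delta_desolv": wt.e_desolv - rep.e_desolv,
                    "delta_bsa": wt.bsa - rep.bsa,
                })
            except Exception as exc:   # noqa: BLE001 - per-residue isolation
                logger.warning("alascan %s %s%s failed: %s",
                               res.resname, chain_id, resseq, exc)
                row["skipped"] = True
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def residue_class(resname: str) -> str:
    """Contact-typing class: charged / polar / apolar."""
    if resname in _CHARGED:
        return "charged"
    if resname in _POLAR:
        return "polar"
    return "apolar"


def contact_map(models: Model | list[Model],
                cutoff: float = CONTACT_CUTOFF
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residue-residue distance/contact table plus interchain chord data.

    For a single model the table holds every residue pair (intra- and
    interchain) with its minimal heavy-atom distance, a contact flag and
    the residue-class pair.  For a cluster of models the contact flag
    becomes a frequency over members.  The chord table lists interchain
    contacts only.
    """
    model_list = [models] if isinstance(models, Model) else list(models)
    first = model_list[0]

    residues = first.residues
    keys = [r.key for r in residues]
    names = {r.key: r.resname for r in residues}

    # minimal heavy-atom distance per pair, averaged contact over models
    n = len(residues)
    freq = np.zeros((n, n))
    mindist = np.full((n, n), np.inf)
    for m in model_list:
        blocks = []
        for r in m.residues:
            blocks.append(np.array([a.xyz for a in r.atoms
                                    if a.element != "H"]))
        for i in range(n):
            for j in range(i + 1, n):
                diff = blocks[i][:, None, :] - blocks[j][None, :, :]
                d = float(np.sqrt((diff ** 2).sum(axis=2).min()))
                mindist[i, j] = min(mindist[i, j], d)
                if d < cutoff:
                    freq[i, j] += 1.0
    freq /= len(model_list)

    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            ki, kj = keys[i], keys[j]
            rows.append({
                "chain_a": ki[0], "resseq_a": ki[1], "resname_a": names[ki],
                "chain_b": kj[0], "resseq_b": kj[1], "resname_b": names[kj],
                "min_distance": mindist[i, j],
                "contact_frequency": freq[i, j],
                "contact": freq[i, j] > 0.0,
                "interchain": ki[0] != kj[0],
                "class_pair": "-".join(sorted([
                    residue_class(names[ki]), residue_class(names[kj])])),
            })
    table = pd.DataFrame(rows)
    chord = table[table["interchain"] & table["contact"]].reset_index(
        drop=True)
    return table, chord
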