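"""Contact extraction, similarity matrices and model clustering.

Two clustering routes are provided:

* **FCC clustering** — models are compared by the fraction of common
  intermolecular residue contacts (a *directed* similarity:
  ``fcc(a, b) = |a ∩ b| / |a|``) and grouped Taylor-Butina style with a
  mutual-neighbor rule.
* **RMSD clustering** — agglomerative average-linkage on a pairwise
  backbone-RMSD (or interface-ligand-RMSD) matrix, cut either at a
  distance threshold or into a fixed number of clusters.

Cluster ordering is deterministic: by size (descending), then by the best
member score, then by lowest member index; cluster ids are contiguous
from 1 and undersized clusters dissolve to noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import cdist, squareform

from .pdbio import Model, select_atoms
from .superpose import kabsch, superposed_rmsd

__all__ = [
    "ContactSet",
    "Clustering",
    "contacts",
    "fcc",
    "fcc_matrix",
    "cluster_fcc",
    "rmsd_matrix",
    "ilrmsd_matrix",
    "cluster_rmsd",
    "interface_residue_keys",
    "CONTACT_CUTOFF",
    "ILRMSD_INTERFACE_CUTOFF",
]

CONTACT_CUTOFF = 5.0            # Å, heavy-atom residue contact rule
ILRMSD_INTERFACE_CUTOFF = 10.0  # Å, interface residues for IL-RMSD

ResKey = tuple[str, int, str]


@dataclass(frozen=True)
class ContactSet:
    """Intermolecular residue-pair contacts of one model."""

    pairs: frozenset[tuple[ResKey, ResKey]]
    cutoff: float = CONTACT_CUTOFF

    def __len__(self) -> int:
        return len(self.pairs)


def _residue_blocks(model: Model, heavy: bool = True
                    ) -> tuple[list, np.ndarray, np.ndarray]:
    """Residues with their heavy-atom coordinate slices."""
    keys, starts, coords = [], [], []
    n = 0
    for res in model.residues:
        atoms = [a for a in res.atoms if not heavy or a.element != "H"]
        if not atoms:
            continue
        keys.append(res)
        starts.append(n)
        coords.extend(a.xyz for a in atoms)
        n += len(atoms)
    starts.append(n)
    return keys, np.array(starts), np.array(coords, dtype=float)


def contacts(model: Model, cutoff: float = CONTACT_CUTOFF) -> ContactSet:
    """Intermolecular residue contacts: any heavy-atom pair closer than
    ``cutoff`` between residues of different chains.

    Pairs are keyed receptor-first, i.e. ordered by chain position in the
    model.
    """
    if len(model.chains) < 2:
        raise ValueError("contacts need a model with at least two chains")
    chain_rank = {c: i for i, c in enumerate(model.chains)}
    residues, starts, coords = _residue_blocks(model)
    d = cdist(coords, coords)
    pairs: set[tuple[ResKey, ResKey]] = set()
    for i, ri in enumerate(residues):
        for j in range(i + 1, len(residues)):
            rj = residues[j]
            if ri.chain == rj.chain:
                continue
            block = d[starts[i]:starts[i + 1], starts[j]:starts[j + 1]]
            if np.min(block) < cutoff:
                a, b = ri.key, rj.key
                if chain_rank[rj.chain] < chain_rank[ri.chain]:
                    a, b = b, a
                pairs.add((a, b))
    return ContactSet(frozenset(pairs), cutoff)


def fcc(a: ContactSet, b: ContactSet) -> float:
    """Directed fraction of common contacts, |a ∩ b| / |a| (0 if a empty)."""
    if len(a) == 0:
        return 0.0
    return len(a.pairs & b.pairs) / len(a.pairs)


def fcc_matrix(models: list[Model],
               cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Directed n×n FCC matrix (diagonal 1 by convention)."""
    sets = [contacts(m, cutoff) for m in models]
    n = len(sets)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                mat[i, j] = fcc(sets[i], sets[j])
    return mat


@dataclass
class Clustering:
    """Cluster id per model (None = noise); clusters ordered and 1-based."""

    labels: list[int | None]
    clusters: list[list[int]] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def members(self, cluster_id: int) -> list[int]:
        return self.clusters[cluster_id - 1]


def _order_clusters(raw: list[list[int]], scores: list[float] | None,
                    n_models: int, min_size: int) -> Clustering:
    kept = [sorted(c) for c in raw if len(c) >= min_size]

    def best(c: list[int]) -> float:
        if scores is None:
            return 0.0
        return min(scores[i] for i in c)

    kept.sort(key=lambda c: (-len(c), best(c), c[0]))
    if scores is not None:
        kept = [sorted(c, key=lambda i: (scores[i], i)) for c in kept]
    labels: list[int | None] = [None] * n_models
    for cid, members in enumerate(kept, start=1):
        for i in members:
            labels[i] = cid
    return Clustering(labels, kept)


def cluster_fcc(matrix: np.ndarray, threshold: float = 0.6,
                min_size: int = 4,
                scores: list[float] | None = None) -> Clustering:
    """Taylor-Butina clustering on a directed FCC matrix.

    Models i, j are neighbors iff ``fcc(i,j) >= threshold`` **and**
    ``fcc(j,i) >= threshold`` (mutual rule).  Repeatedly the unassigned
    model with the most unassigned neighbors becomes a cluster centre and
    claims them; clusters below ``min_size`` dissolve to noise.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("FCC matrix must be square")
    neighbor = (matrix >= threshold) & (matrix.T >= threshold)
    np.fill_diagonal(neighbor, False)
    unassigned = np.ones(n, dtype=bool)
    raw: list[list[int]] = []
    while np.any(unassigned):
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        centre = int(np.argmax(counts))      # ties: lowest index
        members = [centre] + [int(j) for j in np.where(
            neighbor[centre] & unassigned)[0] if j != centre]
        if counts[centre] <= 0 and min_size > 1:
            # remaining models are all isolated; they become singletons
            members = [centre]
        for m in members:
            unassigned[m] = False
        raw.append(members)
    return _order_clusters(raw, scores, n, min_size)


def rmsd_matrix(models: list[Model], kind: str = "backbone") -> np.ndarray:
    """Symmetric pairwise RMSD matrix after optimal (Kabsch) superposition.

    All models must share atom composition; the RMSD is computed over the
    backbone (default) or all heavy atoms.
    """
    sel = "backbone" if kind == "backbone" else "heavy"
    coords = []
    ref_comp = models[0].composition()
    for m in models:
        if m.composition() != ref_comp:
            raise ValueError("models differ in atom composition")
        xyz, _ = select_atoms(m, kind=sel)
        coords.append(xyz)
    n = len(models)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = superposed_rmsd(coords[j], coords[i])
            mat[i, j] = mat[j, i] = v
    return mat


def interface_residue_keys(model: Model,
                           cutoff: float = ILRMSD_INTERFACE_CUTOFF
                           ) -> set[ResKey]:
    """Residues with any intermolecular heavy-atom pair within ``cutoff``."""
    cset = contacts(model, cutoff)
    keys: set[ResKey] = set()
    for a, b in cset.pairs:
        keys.add(a)
        keys.add(b)
    return keys


def _partner_chains(model: Model,
                    partners: list[list[str]] | None) -> tuple[set, set]:
    if partners is None:
        chains = model.chains
        return {chains[0]}, set(chains[1:])
    return set(partners[0]), {c for g in partners[1:] for c in g}


def ilrmsd_matrix(models: list[Model],
                  partners: list[list[str]] | None = None,
                  interface_cutoff: float = ILRMSD_INTERFACE_CUTOFF
                  ) -> np.ndarray:
    """Pairwise interface-ligand RMSD matrix (reference-free).

    For each pair the interface is taken from the pair's first model
    (``cutoff`` Å heavy-atom rule); models are superposed on the receptor
    interface backbone and the RMSD evaluated over ligand interface heavy
    atoms.  Receptor = first partner group (first chain by default).
    """
    rec_chains, lig_chains = _partner_chains(models[0], partners)
    ref_comp = models[0].composition()
    for m in models[1:]:
        if m.composition() != ref_comp:
            raise ValueError("models differ in atom composition")
    n = len(models)
    mat = np.zeros((n, n))
    for i in range(n):
        iface = interface_residue_keys(models[i], interface_cutoff)
        rec_iface = {k for k in iface if k[0] in rec_chains}
        lig_iface = {k for k in iface if k[0] in lig_chains}
        if not rec_iface or not lig_iface:
            raise ValueError(
                f"model {i} has no interface within {interface_cutoff} Å")
        fit_i, _ = select_atoms(models[i], residues=rec_iface,
                                kind="backbone")
        over_i, _ = select_atoms(models[i], residues=lig_iface, kind="heavy")
        for j in range(i + 1, n):
            fit_j, _ = select_atoms(models[j], residues=rec_iface,
                                    kind="backbone")
            over_j, _ = select_atoms(models[j], residues=lig_iface,
                                     kind="heavy")
            v = superposed_rmsd(fit_j, fit_i, over_j, over_i)
            mat[i, j] = mat[j, i] = v
    return mat


def cluster_rmsd(matrix: np.ndarray, cutoff: float | None = None,
                 n_clusters: int | None = None, min_size: int = 4,
                 linkage: str = "average",
                 scores: list[float] | None = None) -> Clustering:
    """Agglomerative clustering of an RMSD matrix.

    Exactly one cut criterion must be given: a dendrogram distance
    ``cutoff`` (Å) or a target ``n_clusters``.
    """
    if (cutoff is None) == (n_clusters is None):
        raise ValueError("give exactly one of cutoff= or n_clusters=")
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n == 1:
        return _order_clusters([[0]], scores, 1, min_size)
    Z = scipy_linkage(squareform(matrix, checks=False), method=linkage)
    if cutoff is not None:
        flat = fcluster(Z, t=cutoff, criterion="distance")
    else:
        flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    raw: dict[int, list[int]] = {}
    for i, cid in enumerate(flat):
        raw.setdefault(int(cid), []).append(i)
    return _order_clusters(list(raw.values()), scores, n, min_size)
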