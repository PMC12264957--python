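"""Energy terms and their gradients.

Nonbonded model
---------------
* van der Waals: Lennard-Jones 12-6, ``eps_ij*((rmin_ij/r)^12 - 2*(rmin_ij/r)^6)``
  with geometric-mean epsilon and arithmetic-mean rmin combination rules,
  8.5 Å cutoff, optional per-pair soft-core energy cap (used at the rigid
  stage so restraint attraction can bring partners into contact).
* electrostatics: Coulomb ``332.0636*qi*qj/(eps_r*r)`` with a constant
  relative dielectric (default 10) and a smooth ``(1-(r/rc)^2)^2`` shift
  to zero at the cutoff.
* desolvation: ``sum_i asp_i * (SASA_complex,i - SASA_free,i)`` where the
  free state is each partner in isolation at its complex coordinates.

Surface areas use the Shrake-Rupley method with a deterministic
golden-spiral point set (960 points/atom by default, probe 1.4 Å).

Bonded terms (harmonic bonds and angles) and flat-bottom distance
restraints provide analytic gradients for L-BFGS minimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial.distance import cdist

from .forcefield import Topology
from .pdbio import Model
from .restraints import RestraintSet

__all__ = [
    "COULOMB_CONSTANT",
    "NONBONDED_CUTOFF",
    "DIELECTRIC",
    "PROBE_RADIUS",
    "SASA_POINTS",
    "lj_energy",
    "coulomb_energy",
    "sphere_points",
    "shrake_rupley",
    "bonded_energy",
    "nonbonded_pairlist",
    "intermolecular_pairs",
    "PairTerms",
    "RestraintTerms",
    "resolve_restraint_terms",
    "MinimizationError",
]

COULOMB_CONSTANT = 332.0636   # kcal·Å/(mol·e²)
NONBONDED_CUTOFF = 8.5        # Å
DIELECTRIC = 10.0             # constant relative dielectric
PROBE_RADIUS = 1.4            # Å
SASA_POINTS = 960


class MinimizationError(RuntimeError):
    """Raised when an energy evaluation turns non-finite."""


# ---------------------------------------------------------------------------
# pairwise nonbonded terms
# ---------------------------------------------------------------------------

@dataclass
class PairTerms:
    """Precomputed pair indices and combined parameters for fast evaluation."""

    i: np.ndarray          # (np,) atom indices
    j: np.ndarray
    eps_ij: np.ndarray     # geometric mean
    rmin_ij: np.ndarray    # arithmetic mean
    qq: np.ndarray         # qi*qj

    @classmethod
    def build(cls, idx_i: np.ndarray, idx_j: np.ndarray,
              top_i: Topology, top_j: Topology | None = None) -> "PairTerms":
        if top_j is None:
            top_j = top_i
        eps = np.sqrt(top_i.epsilon[idx_i] * top_j.epsilon[idx_j])
        rmin = 0.5 * (top_i.rmin[idx_i] + top_j.rmin[idx_j])
        qq = top_i.charge[idx_i] * top_j.charge[idx_j]
        return cls(np.asarray(idx_i, dtype=int), np.asarray(idx_j, dtype=int),
                   eps, rmin, qq)


def nonbonded_pairlist(topology: Topology) -> PairTerms:
    """All unique atom pairs of one system minus 1-2/1-3 exclusions."""
    n = topology.n_atoms
    iu, ju = np.triu_indices(n, k=1)
    if topology.excluded:
        excl = np.array(sorted(topology.excluded), dtype=int)
        keys = iu.astype(np.int64) * n + ju
        ekeys = excl[:, 0].astype(np.int64) * n + excl[:, 1]
        mask = ~np.isin(keys, ekeys)
        iu, ju = iu[mask], ju[mask]
    return PairTerms.build(iu, ju, topology)


def intermolecular_pairs(n_a: int, n_b: int, top_a: Topology,
                         top_b: Topology) -> PairTerms:
    """All cross pairs between two partners (j indices local to partner B)."""
    ii, jj = np.meshgrid(np.arange(n_a), np.arange(n_b), indexing="ij")
    return PairTerms.build(ii.ravel(), jj.ravel(), top_a, top_b)


def _pair_geometry(coords_i: np.ndarray, coords_j: np.ndarray,
                   pairs: PairTerms) -> tuple[np.ndarray, np.ndarray]:
    diff = coords_i[pairs.i] - coords_j[pairs.j]
    r = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    return diff, r


def lj_energy(coords_i: np.ndarray, pairs: PairTerms,
              coords_j: np.ndarray | None = None,
              cutoff: float = NONBONDED_CUTOFF,
              softcore_cap: float | None = None,
              grad: np.ndarray | None = None,
              grad_j: np.ndarray | None = None) -> float:
    """Lennard-Jones 12-6 over a pair list; optionally accumulate gradient.

    A capped pair contributes a flat (zero-gradient) energy plateau, which
    is what lets the rigid stage tolerate clashes.
    """
    same = coords_j is None
    if same:
        coords_j = coords_i
    diff, r = _pair_geometry(coords_i, coords_j, pairs)
    mask = (r < cutoff) & (r > 1e-12)
    if not np.any(mask):
        return 0.0
    r, diff = r[mask], diff[mask]
    eps, rmin = pairs.eps_ij[mask], pairs.rmin_ij[mask]
    s6 = (rmin / r) ** 6
    e = eps * (s6 * s6 - 2.0 * s6)
    capped = np.zeros(len(e), dtype=bool)
    if softcore_cap is not None:
        capped = e > softcore_cap
        e = np.minimum(e, softcore_cap)
    if grad is not None:
        dEdr = -12.0 * eps / r * (s6 * s6 - s6)
        dEdr[capped] = 0.0
        g = (dEdr / r)[:, None] * diff
        np.add.at(grad, pairs.i[mask], g)
        tgt = grad if same else grad_j
        if tgt is not None:
            np.add.at(tgt, pairs.j[mask], -g)
    return float(np.sum(e))


COULOMB_CLAMP = 2.8   # Å; below this the Coulomb term plateaus
# (2.8 Å is a genuine salt-bridge N-O contact: clamping there removes
# any incentive to interpenetrate charged groups)


def coulomb_energy(coords_i: np.ndarray, pairs: PairTerms,
                   coords_j: np.ndarray | None = None,
                   cutoff: float = NONBONDED_CUTOFF,
                   dielectric: float = DIELECTRIC,
                   shift: bool = True,
                   clamp: float = COULOMB_CLAMP,
                   grad: np.ndarray | None = None,
                   grad_j: np.ndarray | None = None) -> float:
    """Shifted Coulomb energy over a pair list; optional gradient.

    Distances below ``clamp`` are evaluated at the clamp (flat plateau)
    so opposite charges cannot collapse to unbounded energies in the
    heavy-atom representation.
    """
    same = coords_j is None
    if same:
        coords_j = coords_i
    diff, r = _pair_geometry(coords_i, coords_j, pairs)
    mask = (r < cutoff) & (r > 1e-12) & (pairs.qq != 0.0)
    if not np.any(mask):
        return 0.0
    r, diff = r[mask], diff[mask]
    clamped = r < clamp
    r = np.maximum(r, clamp)
    qq = pairs.qq[mask]
    pref = COULOMB_CONSTANT * qq / dielectric
    if shift:
        s = (r / cutoff) ** 2
        f = (1.0 - s) ** 2
        e = pref / r * f
        if grad is not None:
            dEdr = pref * (-f / r**2 + (1.0 / r) * 2.0 * (1.0 - s)
                           * (-2.0 * r / cutoff**2))
    else:
        e = pref / r
        if grad is not None:
            dEdr = -pref / r**2
    if grad is not None:
        dEdr[clamped] = 0.0
        g = (dEdr / r)[:, None] * diff
        np.add.at(grad, pairs.i[mask], g)
        tgt = grad if same else grad_j
        if tgt is not None:
            np.add.at(tgt, pairs.j[mask], -g)
    return float(np.sum(e))


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def bonded_energy(coords: np.ndarray, topology: Topology,
                  grad: np.ndarray | None = None) -> float:
    """Harmonic bond + angle energy; optional in-place gradient."""
    e = 0.0
    if len(topology.bonds):
        bi, bj = topology.bonds[:, 0], topology.bonds[:, 1]
        diff = coords[bi] - coords[bj]
        r = np.linalg.norm(diff, axis=1)
        dr = r - topology.bond_r0
        e += float(np.sum(topology.bond_k * dr * dr))
        if grad is not None:
            g = (2.0 * topology.bond_k * dr / np.maximum(r, 1e-12))[:, None] \
                * diff
            np.add.at(grad, bi, g)
            np.add.at(grad, bj, -g)
    if len(topology.angles):
        ai, aj, ak = (topology.angles[:, 0], topology.angles[:, 1],
                      topology.angles[:, 2])
        u = coords[ai] - coords[aj]
        v = coords[ak] - coords[aj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.einsum("ij,ij->i", u, v) / (nu * nv)
        cos_t = np.clip(cos_t, -1.0, 1.0)
        theta = np.arccos(cos_t)
        dth = theta - topology.angle_theta0
        e += float(np.sum(topology.angle_k * dth * dth))
        if grad is not None:
            sin_t = np.maximum(np.sqrt(1.0 - cos_t**2), 1e-8)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            dti = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
            dtk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
            pref = (2.0 * topology.angle_k * dth)[:, None]
            np.add.at(grad, ai, pref * dti)
            np.add.at(grad, ak, pref * dtk)
            np.add.at(grad, aj, -pref * (dti + dtk))
    return e


# ---------------------------------------------------------------------------
# restraint terms on a coordinate array
# ---------------------------------------------------------------------------

@dataclass
class RestraintTerms:
    """Restraints resolved to atom indices of one coordinate array."""

    # ambiguous: per restraint, (source idx array, target idx array, lo, hi)
    airs: list[tuple[np.ndarray, np.ndarray, float, float]]
    # unambiguous: (i, j, lo, hi)
    pairs: list[tuple[int, int, float, float]]
    k: float
    ceiling: float

    def energy(self, coords: np.ndarray,
               grad: np.ndarray | None = None) -> float:
        e = 0.0
        for src, tgt, lo, hi in self.airs:
            e += _air_term(coords, src, tgt, lo, hi, self.k, self.ceiling,
                           grad)
        for i, j, lo, hi in self.pairs:
            diff = coords[i] - coords[j]
            r = float(np.linalg.norm(diff))
            if r > hi:
                viol, sgn = r - hi, 1.0
            elif r < lo:
                viol, sgn = lo - r, -1.0
            else:
                continue
            term = self.k * viol * viol
            if term >= self.ceiling:
                e += self.ceiling
                continue
            e += term
            if grad is not None and r > 1e-12:
                g = sgn * 2.0 * self.k * viol / r * diff
                grad[i] += g
                grad[j] -= g
        return e


def _air_term(coords: np.ndarray, src: np.ndarray, tgt: np.ndarray,
              lo: float, hi: float, k: float, ceiling: float,
              grad: np.ndarray | None) -> float:
    a = coords[src]
    b = coords[tgt]
    diff = a[:, None, :] - b[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    if np.any(d2 < 1e-12):
        d_eff = 0.0
    else:
        s = float(np.sum(d2 ** -3))
        d_eff = s ** (-1.0 / 6.0)
    if d_eff > hi:
        viol, sgn = d_eff - hi, 1.0
    elif d_eff < lo:
        viol, sgn = lo - d_eff, -1.0
    else:
        return 0.0
    term = k * viol * viol
    if term >= ceiling or d_eff == 0.0:
        return min(term, ceiling)
    if grad is not None:
        # dE/d(d_eff) * d(d_eff)/dS * dS/dx
        dEdd = sgn * 2.0 * k * viol
        dddS = (-1.0 / 6.0) * s ** (-7.0 / 6.0)
        # dS/dx_i = sum_j -6 d_ij^-8 (x_i - x_j)
        w = -6.0 * d2 ** -4
        gsrc = np.einsum("ij,ijk->ik", w, diff)
        gtgt = -np.einsum("ij,ijk->jk", w, diff)
        np.add.at(grad, src, dEdd * dddS * gsrc)
        np.add.at(grad, tgt, dEdd * dddS * gtgt)
    return term


def resolve_restraint_terms(model: Model, rset: RestraintSet,
                            k: float, ceiling: float) -> RestraintTerms:
    """Map a restraint set onto heavy-atom indices of one model."""
    amap: dict[tuple[str, int, str], list[int]] = {}
    atom_map: dict[tuple[str, int, str, str], int] = {}
    for gi, atom in enumerate(model.atoms()):
        key = (atom.chain, atom.resseq, atom.icode)
        if atom.element != "H":
            amap.setdefault(key, []).append(gi)
        atom_map[(atom.chain, atom.resseq, atom.icode, atom.name)] = gi

    airs = []
    for r in rset.ambiguous:
        skey = (r.source.chain, r.source.resseq, r.source.icode)
        if skey not in amap:
            raise KeyError(f"restraint source residue {skey} not in model")
        tidx: list[int] = []
        for t in sorted(r.targets, key=lambda t: (t.chain, t.resseq,
                                                  t.icode)):
            tkey = (t.chain, t.resseq, t.icode)
            if tkey not in amap:
                raise KeyError(f"restraint target residue {tkey} not in "
                               f"model")
            tidx.extend(amap[tkey])
        airs.append((np.array(amap[skey], dtype=int),
                     np.array(tidx, dtype=int),
                     r.lower_bound, r.upper_bound))
    pairs = []
    for r in rset.unambiguous:
        ka = (r.atom_a.chain, r.atom_a.resseq, r.atom_a.icode, r.atom_a.name)
        kb = (r.atom_b.chain, r.atom_b.resseq, r.atom_b.icode, r.atom_b.name)
        if ka not in atom_map or kb not in atom_map:
            missing = ka if ka not in atom_map else kb
            raise KeyError(f"restraint atom {missing} not in model")
        pairs.append((atom_map[ka], atom_map[kb],
                      r.distance - r.dminus, r.distance + r.dplus))
    return RestraintTerms(airs, pairs, k, ceiling)


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def sphere_points(n: int = SASA_POINTS) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe: float = PROBE_RADIUS,
                  n_points: int = SASA_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Å²), Shrake-Rupley.

    Each atom's accessible fraction is the share of ``n_points`` test
    points on its solvent sphere (radius + probe) not inside any
    neighbor's solvent sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    ext = radii + probe
    pts = sphere_points(n_points)
    d = cdist(coords, coords)
    areas = np.zeros(n)
    for i in range(n):
        nbrs = np.where((d[i] < ext[i] + ext) & (np.arange(n) != i))[0]
        if len(nbrs):
            sphere = coords[i] + ext[i] * pts
            d2 = cdist(sphere, coords[nbrs], "sqeuclidean")
            buried = np.any(d2 < ext[nbrs] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    return areas
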