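"""Rigid-body docking and Cartesian refinement.

The rigid stage samples ligand orientations on a sphere around the
receptor and locally minimizes a soft rigid-body energy

    E = w_vdw*E_vdw(softcore) + w_elec*E_elec + w_air*E_air

over the six rigid degrees of freedom (rotation vector + translation)
with a derivative-free Nelder-Mead simplex.  Ambiguous restraints are the
driving force: the soft-core, down-weighted van der Waals term tolerates
clashes so that restraint attraction can bring the partners into contact.

Refinement is restrained Cartesian minimization (L-BFGS with analytic
gradients).  ``flexible_refine`` frees the residues within a cutoff of
the partner and tethers everything else to its input position — a
deliberate, simplified Cartesian analogue of semiflexible interface
refinement protocols that anneal in torsion-angle space.

Every stochastic draw is keyed to ``seed + model index`` so per-model
work is order-independent and reruns are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

from . import energy as en
from .forcefield import Topology
from .pdbio import Model, Provenance
from .restraints import (AIR_ENERGY_CEILING, AIR_FORCE_CONSTANT,
                         RestraintSet, assign_restraint_sets, random_removal)
from .scoring import (EnergyReport, WEIGHT_PROFILES, composite_score,
                      score_complex)

logger = logging.getLogger(__name__)

__all__ = [
    "RigidPose",
    "RefinementSettings",
    "rigid_transform",
    "sample_rigidbody",
    "energy_minimize",
    "flexible_refine",
]

RIGID_SOFTCORE_CAP = 500.0  # kcal/mol per-pair LJ plateau at the rigid stage
# (0.01-weighted: 5 score units per deeply clashed pair, enough to make
# interpenetration unprofitable while tolerating surface clashes)
SPHERE_MARGIN = 9.0         # Å added to receptor+ligand bounding radii


@dataclass(frozen=True)
class RigidPose:
    """Proper rotation + translation applied about the mobile centroid."""

    rotation: np.ndarray     # (3,3) orthonormal, det +1
    translation: np.ndarray  # (3,) Å

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("pose needs a 3x3 rotation and a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
                or not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation matrix is not a proper rotation")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec: np.ndarray,
                    translation: np.ndarray) -> "RigidPose":
        return cls(Rotation.from_rotvec(rotvec).as_matrix(),
                   np.asarray(translation, dtype=float))


def rigid_transform(coords: np.ndarray, pose: RigidPose) -> np.ndarray:
    """Apply a rigid pose about the centroid; preserves internal distances."""
    coords = np.asarray(coords, dtype=float)
    c = coords.mean(axis=0)
    return (coords - c) @ pose.rotation.T + c + pose.translation


@dataclass
class RefinementSettings:
    n_steps: int = 100
    gtol: float = 1e-4              # gradient-norm stop tolerance
    flexible_cutoff: float = 5.0    # Å, interface residue cutoff
    tether_k: float = 10.0          # kcal/mol/Å² positional restraint

    def __post_init__(self):
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.flexible_cutoff < 0:
            raise ValueError("flexible_cutoff must be >= 0")


# ---------------------------------------------------------------------------
# Cartesian minimization
# ---------------------------------------------------------------------------

def _closest_pair(coords: np.ndarray) -> tuple[int, int]:
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    return tuple(int(v) for v in np.unravel_index(np.argmin(d), d.shape))


class _System:
    """Total energy + gradient of a model under one topology."""

    def __init__(self, model: Model, topology: Topology,
                 restraints: RestraintSet | None,
                 tether_idx: np.ndarray | None = None,
                 tether_ref: np.ndarray | None = None,
                 tether_k: float = 0.0,
                 softcore_cap: float | None = None):
        if model.n_atoms != topology.n_atoms:
            raise ValueError("model/topology atom count mismatch")
        self.model = model
        self.topology = topology
        self.pairs = en.nonbonded_pairlist(topology)
        self.softcore_cap = softcore_cap
        self.rterms = None
        if restraints is not None and len(restraints):
            self.rterms = en.resolve_restraint_terms(
                model, restraints, AIR_FORCE_CONSTANT, AIR_ENERGY_CEILING)
        self.tether_idx = tether_idx
        self.tether_ref = tether_ref
        self.tether_k = tether_k

    def energy_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        coords = x.reshape(-1, 3)
        grad = np.zeros_like(coords)
        e = en.bonded_energy(coords, self.topology, grad)
        e += en.lj_energy(coords, self.pairs,
                          softcore_cap=self.softcore_cap, grad=grad)
        e += en.coulomb_energy(coords, self.pairs, grad=grad)
        if self.rterms is not None:
            e += self.rterms.energy(coords, grad)
        if self.tether_idx is not None and len(self.tether_idx):
            dx = coords[self.tether_idx] - self.tether_ref
            e += float(self.tether_k * np.sum(dx * dx))
            grad[self.tether_idx] += 2.0 * self.tether_k * dx
        if not np.isfinite(e):
            i, j = _closest_pair(coords)
            raise en.MinimizationError(
                f"non-finite energy; closest atom pair is ({i}, {j})")
        return e, grad.ravel()


def _minimize_system(system: _System, settings: RefinementSettings
                     ) -> tuple[np.ndarray, float]:
    x0 = system.model.coords().ravel()
    if settings.n_steps == 0:
        e0, _ = system.energy_grad(x0)
        return x0.reshape(-1, 3), e0
    res = scipy_minimize(system.energy_grad, x0, jac=True, method="L-BFGS-B",
                         options={"maxiter": settings.n_steps,
                                  "gtol": settings.gtol})
    if not np.all(np.isfinite(res.x)):
        raise en.MinimizationError("minimizer produced non-finite coordinates")
    return res.x.reshape(-1, 3), float(res.fun)


def _post_report(model: Model, topology: Topology,
                 restraints: RestraintSet | None,
                 partners: list[list[str]] | None,
                 profile: str | dict) -> EnergyReport:
    if len(model.chains) >= 2:
        return score_complex(model, topology, partners=partners,
                             restraints=restraints, profile=profile)
    return EnergyReport()


def energy_minimize(model: Model, topology: Topology,
                    restraints: RestraintSet | None = None,
                    n_steps: int = 100,
                    settings: RefinementSettings | None = None,
                    partners: list[list[str]] | None = None,
                    profile: str | dict = "refined"
                    ) -> tuple[Model, EnergyReport]:
    """Energy-minimize a model (bonded + nonbonded + restraints).

    Runs at most ``n_steps`` quasi-Newton iterations or stops at the
    gradient tolerance; the total energy is non-increasing.  Returns the
    minimized model and its component-energy report.
    """
    if settings is None:
        settings = RefinementSettings(n_steps=n_steps)
    system = _System(model, topology, restraints)
    coords, e_total = _minimize_system(system, settings)
    out = model.copy()
    out.set_coords(coords)
    report = _post_report(out, topology, restraints, partners, profile)
    report.extras["e_total"] = e_total
    out.provenance.score = report.score
    return out, report


def _flexible_atom_mask(model: Model, cutoff: float) -> np.ndarray:
    """True for atoms of residues within ``cutoff`` of another chain."""
    coords = model.coords()
    chains = np.array([a.chain for a in model.atoms()])
    mask = np.zeros(len(coords), dtype=bool)
    if cutoff <= 0:
        return mask
    gi = 0
    spans = []
    for res in model.residues:
        spans.append((res, gi, gi + len(res.atoms)))
        gi += len(res.atoms)
    for res, lo, hi in spans:
        other = chains != res.chain
        if not np.any(other):
            continue
        d = cdist(coords[lo:hi], coords[other])
        if np.min(d) < cutoff:
            mask[lo:hi] = True
    return mask


def flexible_refine(model: Model, topology: Topology,
                    restraints: RestraintSet | None = None,
                    settings: RefinementSettings | None = None,
                    partners: list[list[str]] | None = None,
                    profile: str | dict = "refined"
                    ) -> tuple[Model, EnergyReport]:
    """Semiflexible interface refinement (Cartesian analogue).

    Atoms of residues within ``settings.flexible_cutoff`` (default 5 Å) of
    the partner move freely; all other atoms are tethered to their input
    positions with harmonic restraints of ``settings.tether_k``.  With a
    zero cutoff nothing is flexible and the model is returned unchanged
    (infinite-tether limit).
    """
    if settings is None:
        settings = RefinementSettings()
    flex = _flexible_atom_mask(model, settings.flexible_cutoff)
    if not np.any(flex):
        report = _post_report(model, topology, restraints, partners, profile)
        out = model.copy()
        out.provenance.score = report.score
        return out, report
    tether_idx = np.where(~flex)[0]
    tether_ref = model.coords()[tether_idx]
    system = _System(model, topology, restraints,
                     tether_idx=tether_idx, tether_ref=tether_ref,
                     tether_k=settings.tether_k)
    coords, e_total = _minimize_system(system, settings)
    out = model.copy()
    out.set_coords(coords)
    report = _post_report(out, topology, restraints, partners, profile)
    report.extras["e_total"] = e_total
    out.provenance.score = report.score
    return out, report


# ---------------------------------------------------------------------------
# rigid-body sampling
# ---------------------------------------------------------------------------

class _RigidEnergy:
    """Cross-partner energies on a receptor×ligand distance matrix.

    All parameter combinations and restraint index slices are precomputed;
    one evaluation is a single ``cdist`` plus vectorized term sums, which
    is what makes thousands of simplex evaluations affordable.
    """

    def __init__(self, rec_coords: np.ndarray, top_rec: Topology,
                 n_lig: int, top_lig: Topology,
                 softcore_cap: float, cutoff: float = en.NONBONDED_CUTOFF,
                 dielectric: float = en.DIELECTRIC):
        self.rec = rec_coords
        self.cutoff2 = cutoff * cutoff
        self.cutoff = cutoff
        self.cap = softcore_cap
        self.dielectric = dielectric
        self.EPS = np.sqrt(np.outer(top_rec.epsilon, top_lig.epsilon))
        self.RMIN2 = (0.5 * (top_rec.rmin[:, None]
                             + top_lig.rmin[None, :])) ** 2
        self.QQ = np.outer(top_rec.charge, top_lig.charge)
        self.n_rec = len(rec_coords)
        self.airs: list[tuple[np.ndarray, np.ndarray, float, float]] = []
        self.air_k = AIR_FORCE_CONSTANT

    def set_restraints(self, template: Model, rset: RestraintSet) -> None:
        """Resolve restraints into (receptor rows, ligand cols) slices."""
        self.airs = []
        if rset is None or not len(rset):
            return
        terms = en.resolve_restraint_terms(template, rset,
                                           AIR_FORCE_CONSTANT, np.inf)
        for src, tgt, lo, hi in terms.airs:
            rows = np.concatenate([src[src < self.n_rec],
                                   tgt[tgt < self.n_rec]])
            cols = np.concatenate([src[src >= self.n_rec],
                                   tgt[tgt >= self.n_rec]]) - self.n_rec
            if not len(rows) or not len(cols):
                raise ValueError("rigid-stage restraints must be "
                                 "cross-partner")
            self.airs.append((rows, cols, lo, hi))
        for i, j, lo, hi in terms.pairs:
            a, b = sorted((i, j))
            if a >= self.n_rec or b < self.n_rec:
                raise ValueError("rigid-stage restraints must be "
                                 "cross-partner")
            self.airs.append((np.array([a]), np.array([b - self.n_rec]),
                              lo, hi))

    def terms(self, lig_coords: np.ndarray, air_ceiling: float = np.inf
              ) -> tuple[float, float, float]:
        """(E_vdw, E_elec, E_air) for one ligand placement."""
        d2 = cdist(self.rec, lig_coords, "sqeuclidean")
        m = d2 < self.cutoff2
        e_vdw = 0.0
        e_elec = 0.0
        if np.any(m):
            s6 = (self.RMIN2[m] / np.maximum(d2[m], 1e-12)) ** 3
            lj = self.EPS[m] * (s6 * s6 - 2.0 * s6)
            if self.cap is not None:
                lj = np.minimum(lj, self.cap)
            e_vdw = float(lj.sum())
            qm = m & (self.QQ != 0.0)
            if np.any(qm):
                r = np.sqrt(d2[qm])
                r = np.maximum(r, en.COULOMB_CLAMP)
                f = (1.0 - (r / self.cutoff) ** 2) ** 2
                e_elec = float(np.sum(
                    en.COULOMB_CONSTANT * self.QQ[qm] / self.dielectric
                    / r * f))
        e_air = 0.0
        for rows, cols, lo, hi in self.airs:
            s = float(np.sum(d2[np.ix_(rows, cols)] ** -3))
            d_eff = s ** (-1.0 / 6.0)
            if d_eff > hi:
                viol = d_eff - hi
            elif d_eff < lo:
                viol = lo - d_eff
            else:
                continue
            e_air += min(self.air_k * viol * viol, air_ceiling)
        return e_vdw, e_elec, e_air

def _combine(receptor: Model, ligand: Model) -> Model:
    overlap = set(receptor.chains) & set(ligand.chains)
    if overlap:
        raise ValueError(f"receptor and ligand share chain id(s) {overlap}")
    return Model([r.copy() for r in receptor.residues] +
                 [r.copy() for r in ligand.residues])


def _merge_topologies(top_a: Topology, top_b: Topology) -> Topology:
    """Concatenate two partner topologies into one complex topology."""
    off = top_a.n_atoms
    return Topology(
        np.concatenate([top_a.epsilon, top_b.epsilon]),
        np.concatenate([top_a.rmin, top_b.rmin]),
        np.concatenate([top_a.charge, top_b.charge]),
        np.concatenate([top_a.asp, top_b.asp]),
        np.concatenate([top_a.radius, top_b.radius]),
        np.vstack([top_a.bonds, top_b.bonds + off]),
        np.concatenate([top_a.bond_r0, top_b.bond_r0]),
        np.concatenate([top_a.bond_k, top_b.bond_k]),
        np.vstack([top_a.angles, top_b.angles + off]),
        np.concatenate([top_a.angle_theta0, top_b.angle_theta0]),
        np.concatenate([top_a.angle_k, top_b.angle_k]),
        {(i, j) for i, j in top_a.excluded} |
        {(i + off, j + off) for i, j in top_b.excluded},
    )


def sample_rigidbody(receptor: Model, receptor_top: Topology,
                     ligand: Model, ligand_top: Topology,
                     sets: list[RestraintSet],
                     n_models: int = 1000,
                     seed: int = 42,
                     weights: dict[str, float] | None = None,
                     removal_fraction: float = 0.5,
                     max_evals: int = 300,
                     softcore_cap: float = RIGID_SOFTCORE_CAP,
                     rank_profile: str | dict = "rigidbody"
                     ) -> tuple[list[Model], pd.DataFrame]:
    """Restraint-driven rigid-body docking.

    Generates ``n_models`` complexes (default 1000).  Each model draws a
    restraint set round-robin, applies seeded random removal of half the
    ambiguous restraints, starts from a random ligand orientation on a
    sphere of radius ``R_rec + R_lig + 9 Å`` and locally minimizes the
    soft rigid energy over the 6 rigid degrees of freedom.  Output models
    carry pose, energies and restraint-set id and are ranked by the
    rigid-body score.
    """
    if not sets:
        raise ValueError("rigid-body docking needs at least one restraint "
                         "set")
    if weights is None:
        weights = {"vdw": WEIGHT_PROFILES["rigidbody"]["vdw"],
                   "elec": WEIGHT_PROFILES["rigidbody"]["elec"],
                   "air": WEIGHT_PROFILES["rigidbody"]["air"]}
    set_by_id = {s.set_id: s for s in sets}
    assignment = assign_restraint_sets(n_models, sets)

    rec_coords = receptor.coords()
    lig_coords0 = ligand.coords()
    rec_centroid = rec_coords.mean(axis=0)
    lig_centroid0 = lig_coords0.mean(axis=0)
    r_rec = float(np.linalg.norm(rec_coords - rec_centroid, axis=1).max())
    r_lig = float(np.linalg.norm(lig_coords0 - lig_centroid0, axis=1).max())
    sphere_r = r_rec + r_lig + SPHERE_MARGIN

    template = _combine(receptor, ligand)
    n_rec = len(rec_coords)
    rigid = _RigidEnergy(rec_coords, receptor_top, len(lig_coords0),
                         ligand_top, softcore_cap)
    # free-partner SASA is pose-independent: compute once
    radius_all = np.concatenate([receptor_top.radius, ligand_top.radius])
    asp_all = np.concatenate([receptor_top.asp, ligand_top.asp])
    sasa_free = np.concatenate([
        en.shrake_rupley(rec_coords, receptor_top.radius),
        en.shrake_rupley(lig_coords0, ligand_top.radius)])
    rank_w = (WEIGHT_PROFILES[rank_profile]
              if isinstance(rank_profile, str) else rank_profile)

    lig_centered = lig_coords0 - lig_centroid0
    models: list[Model] = []
    rows = []
    for mi in range(n_models):
        rng = np.random.default_rng(seed + mi)
        set_id = assignment[mi]
        rset = random_removal(set_by_id[set_id], removal_fraction,
                              seed=seed + mi)
        if len(rset) == 0:
            logger.warning("model %d: all restraints removed; docking "
                           "without the restraint term", mi + 1)
        # no ceiling during optimization: the quadratic tail is the
        # long-range funnel that pulls the ligand onto the epitope
        rigid.set_restraints(template, rset)

        # random start: orientation uniform, centroid on the sphere
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        start_centroid = rec_centroid + sphere_r * direction
        R0 = Rotation.random(rng=rng).as_matrix()

        def place(x: np.ndarray) -> np.ndarray:
            R = Rotation.from_rotvec(x[:3]).as_matrix()
            return lig_centered @ (R @ R0).T + start_centroid + x[3:]

        def objective(x: np.ndarray) -> float:
            e_vdw, e_elec, e_air = rigid.terms(place(x))
            return (weights["vdw"] * e_vdw + weights["elec"] * e_elec
                    + weights["air"] * e_air)

        # initial simplex spans ~0.8 rad rotations and ~12 Å translations;
        # the default (tiny steps around zero) cannot cross the gap to the
        # receptor within the evaluation budget
        x0 = np.zeros(6)
        steps = np.array([0.8, 0.8, 0.8, 12.0, 12.0, 12.0])
        simplex = np.vstack([x0, x0 + np.diag(steps)])
        res = scipy_minimize(objective, x0, method="Nelder-Mead",
                             options={"maxfev": max_evals,
                                      "initial_simplex": simplex,
                                      "xatol": 1e-3, "fatol": 1e-3})
        lig_final = place(res.x)

        # rigid-body score with the stage profile (capped terms, AIR
        # ceiling restored, desolvation/BSA from cached free SASA)
        e_vdw, e_elec, e_air = rigid.terms(lig_final,
                                           air_ceiling=AIR_ENERGY_CEILING)
        all_coords = np.vstack([rec_coords, lig_final])
        sasa_cplx = en.shrake_rupley(all_coords, radius_all)
        e_desolv = float(np.sum(asp_all * (sasa_cplx - sasa_free)))
        bsa = float(np.sum(sasa_free) - np.sum(sasa_cplx))
        report = EnergyReport(e_vdw, e_elec, e_desolv, e_air, bsa)
        report.score = composite_score(report, rank_w)

        model = template.copy()
        model.set_coords(all_coords)
        model.model_id = mi + 1
        model.provenance = Provenance(
            origin_step="rigidbody", restraint_set_id=set_id,
            name=f"rigidbody_{mi + 1}", score=report.score)
        models.append(model)
        rows.append({"model_index": mi, "model": model.provenance.name,
                     "set_id": set_id, "score": report.score,
                     "e_vdw": report.e_vdw, "e_elec": report.e_elec,
                     "e_desolv": report.e_desolv, "e_air": report.e_air,
                     "bsa": report.bsa})

    table = pd.DataFrame(rows).sort_values(
        ["score", "model_index"], kind="stable").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    ranked = [models[i] for i in table["model_index"]]
    return ranked, table
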