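"""Composite scoring of docked complexes.

The score is a weighted linear combination of intermolecular component
energies,

    score = w_vdw*E_vdw + w_elec*E_elec + w_desolv*E_desolv
          + w_air*E_air + w_bsa*BSA,

lower is better.  Three named weight profiles are shipped (all weights
config-exposed):

============  =====  ======  ========  =====  ======
profile       vdw    elec    desolv    air    bsa
============  =====  ======  ========  =====  ======
``rigidbody`` 0.01   1.0     1.0       0.1    -0.01
``refined``   1.0    0.2     1.0       0.1    0.0
``scoring``   1.0    0.2     1.0       0.0    0.0
============  =====  ======  ========  =====  ======

The rigid-body profile down-weights van der Waals (soft-core stage) and
rewards buried surface; the ``scoring`` profile drops the restraint term
for scoring-only workflows without restraints.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import energy as en
from .forcefield import Topology, build_topology
from .pdbio import Ensemble, Model
from .restraints import RestraintSet

__all__ = [
    "EnergyReport",
    "WEIGHT_PROFILES",
    "composite_score",
    "score_complex",
    "desolvation_energy",
    "buried_surface",
    "emscoring",
    "sasascore",
    "default_partners",
]

WEIGHT_PROFILES: dict[str, dict[str, float]] = {
    "rigidbody": {"vdw": 0.01, "elec": 1.0, "desolv": 1.0, "air": 0.1,
                  "bsa": -0.01},
    "refined": {"vdw": 1.0, "elec": 0.2, "desolv": 1.0, "air": 0.1,
                "bsa": 0.0},
    "scoring": {"vdw": 1.0, "elec": 0.2, "desolv": 1.0, "air": 0.0,
                "bsa": 0.0},
}


@dataclass
class EnergyReport:
    """Component energies (kcal/mol), buried surface (Å²) and the score."""

    e_vdw: float = 0.0
    e_elec: float = 0.0
    e_desolv: float = 0.0
    e_air: float = 0.0
    bsa: float = 0.0
    score: float = 0.0
    extras: dict = field(default_factory=dict)

    def components(self) -> dict[str, float]:
        return {"vdw": self.e_vdw, "elec": self.e_elec,
                "desolv": self.e_desolv, "air": self.e_air, "bsa": self.bsa}


def _weights(profile: str | dict[str, float]) -> dict[str, float]:
    if isinstance(profile, str):
        if profile not in WEIGHT_PROFILES:
            raise ValueError(
                f"unknown weight profile {profile!r}; choose from "
                f"{sorted(WEIGHT_PROFILES)} or pass explicit weights")
        return WEIGHT_PROFILES[profile]
    w = dict.fromkeys(("vdw", "elec", "desolv", "air", "bsa"), 0.0)
    unknown = set(profile) - set(w)
    if unknown:
        raise ValueError(f"unknown weight component(s) {sorted(unknown)}")
    w.update(profile)
    return w


def composite_score(report: EnergyReport,
                    profile: str | dict[str, float] = "refined") -> float:
    """Linear combination of the report's components under a profile."""
    w = _weights(profile)
    comp = report.components()
    return float(sum(w[name] * comp[name] for name in w))


def default_partners(model: Model) -> list[list[str]]:
    """One partner per chain (the two-body case is chains [A],[B])."""
    return [[c] for c in model.chains]


def _partner_atom_indices(model: Model,
                          partners: list[list[str]]) -> list[np.ndarray]:
    chains = [set(g) for g in partners]
    idx: list[list[int]] = [[] for _ in partners]
    for gi, atom in enumerate(model.atoms()):
        for pi, cset in enumerate(chains):
            if atom.chain in cset:
                idx[pi].append(gi)
                break
    return [np.array(g, dtype=int) for g in idx]


def desolvation_energy(model: Model, topology: Topology,
                       partners: list[list[str]] | None = None,
                       probe: float = en.PROBE_RADIUS,
                       n_points: int = en.SASA_POINTS
                       ) -> tuple[float, float]:
    """(desolvation energy, buried surface area) of a complex.

    The free state is each partner in isolation at its complex
    coordinates; ``e_desolv = sum_i asp_i*(SASA_complex,i - SASA_free,i)``
    and ``bsa = sum_partners SASA_free - SASA_complex``.
    """
    if partners is None:
        partners = default_partners(model)
    coords = model.coords()
    if len(coords) != topology.n_atoms:
        raise ValueError("model/topology atom count mismatch")
    sasa_complex = en.shrake_rupley(coords, topology.radius, probe, n_points)
    sasa_free = np.zeros_like(sasa_complex)
    for idx in _partner_atom_indices(model, partners):
        sasa_free[idx] = en.shrake_rupley(coords[idx], topology.radius[idx],
                                          probe, n_points)
    e_desolv = float(np.sum(topology.asp * (sasa_complex - sasa_free)))
    bsa = float(np.sum(sasa_free) - np.sum(sasa_complex))
    return e_desolv, bsa


def buried_surface(model: Model, topology: Topology,
                   partners: list[list[str]] | None = None) -> float:
    """Buried surface area (Å²) of a complex."""
    return desolvation_energy(model, topology, partners)[1]


def score_complex(model: Model, topology: Topology,
                  partners: list[list[str]] | None = None,
                  restraints: RestraintSet | None = None,
                  profile: str | dict[str, float] = "refined",
                  softcore_cap: float | None = None,
                  with_sasa: bool = True,
                  air_k: float | None = None,
                  air_ceiling: float | None = None) -> EnergyReport:
    """Full component-energy report for one complex.

    vdW and electrostatic terms are intermolecular only (between partner
    groups); the restraint term is the flat-bottom AIR/pair penalty of
    ``restraints`` when given.
    """
    from .restraints import AIR_ENERGY_CEILING, AIR_FORCE_CONSTANT
    if partners is None:
        partners = default_partners(model)
    if len(partners) < 2:
        raise ValueError("scoring a complex needs at least two partners")
    coords = model.coords()
    groups = _partner_atom_indices(model, partners)

    e_vdw = 0.0
    e_elec = 0.0
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            ii, jj = np.meshgrid(groups[a], groups[b], indexing="ij")
            pairs = en.PairTerms.build(ii.ravel(), jj.ravel(),
                                       topology, topology)
            e_vdw += en.lj_energy(coords, pairs, softcore_cap=softcore_cap)
            e_elec += en.coulomb_energy(coords, pairs)

    e_air = 0.0
    if restraints is not None and len(restraints):
        terms = en.resolve_restraint_terms(
            model, restraints,
            k=air_k if air_k is not None else AIR_FORCE_CONSTANT,
            ceiling=air_ceiling if air_ceiling is not None
            else AIR_ENERGY_CEILING)
        e_air = terms.energy(coords)

    e_desolv, bsa = (0.0, 0.0)
    if with_sasa:
        e_desolv, bsa = desolvation_energy(model, topology, partners)

    report = EnergyReport(e_vdw, e_elec, e_desolv, e_air, bsa)
    report.score = composite_score(report, profile)
    return report


def emscoring(ensemble: Ensemble | list[Model],
              partners: list[list[str]] | None = None,
              em_steps: int = 100,
              profile: str | dict[str, float] = "refined",
              charged_termini: bool = True
              ) -> tuple[list[Model], pd.DataFrame]:
    """Topology + short energy minimization + scoring for an ensemble.

    Returns the refined models and a table ranked ascending by score with
    a stable tie-break on model index.  Per-model failures are reported in
    the table (``error`` column) and do not abort the remaining models.
    """
    from .docking import energy_minimize

    models = list(ensemble)
    if not models:
        raise ValueError("empty ensemble")
    rows = []
    refined: list[Model] = []
    for mi, model in enumerate(models):
        try:
            topology = build_topology(model, charged_termini=charged_termini)
            out, report = energy_minimize(model, topology, restraints=None,
                                          n_steps=em_steps,
                                          partners=partners,
                                          profile=profile)
            refined.append(out)
            rows.append({"model_index": mi,
                         "model": model.provenance.name or f"model_{mi + 1}",
                         "score": report.score,
                         **{f"e_{k}": v
                            for k, v in report.components().items()
                            if k != "bsa"},
                         "bsa": report.bsa, "error": ""})
        except Exception as exc:   # noqa: BLE001 - per-model isolation
            rows.append({"model_index": mi,
                         "model": model.provenance.name or f"model_{mi + 1}",
                         "score": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    table = table.sort_values(["score", "model_index"], kind="stable",
                              na_position="last").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return refined, table


_REF_SASA_CACHE: dict[str, float] = {}


def reference_residue_sasa() -> dict[str, float]:
    """Free-residue reference SASA (Å²) from packaged Gly-X-Gly values."""
    if not _REF_SASA_CACHE:
        text = resources.files("airdock.data").joinpath(
            "ref_sasa.tsv").read_text()
        rows = [ln for ln in text.splitlines()
                if ln.strip() and not ln.startswith("#")]
        for row in csv.reader(rows, delimiter="\t"):
            _REF_SASA_CACHE[row[0]] = float(row[1])
    return _REF_SASA_CACHE


def residue_relative_accessibility(model: Model, topology: Topology
                                   ) -> dict[tuple[str, int, str], float]:
    """Per-residue SASA in the complex over the free-residue reference."""
    ref = reference_residue_sasa()
    areas = en.shrake_rupley(model.coords(), topology.radius)
    out: dict[tuple[str, int, str], float] = {}
    gi = 0
    for res in model.residues:
        total = float(areas[gi:gi + len(res.atoms)].sum())
        gi += len(res.atoms)
        denom = ref.get(res.resname)
        if denom is None:
            raise KeyError(f"no reference SASA for residue {res.resname}")
        out[res.key] = total / denom
    return out


def sasascore(model: Model,
              buried_expected: list[tuple[str, int, str]] = (),
              accessible_expected: list[tuple[str, int, str]] = (),
              rel_cutoff: float = 0.15,
              topology: Topology | None = None) -> tuple[int, pd.DataFrame]:
    """Accessibility-compliance score: count of violated expectations.

    A violation is an ``accessible_expected`` residue whose relative
    accessibility falls below ``rel_cutoff``, or a ``buried_expected``
    residue above it.  Lower is better.
    """
    if topology is None:
        topology = build_topology(model)
    rel = residue_relative_accessibility(model, topology)

    def norm(key) -> tuple[str, int, str]:
        if len(key) == 2:
            return (key[0], key[1], "")
        return tuple(key)

    rows = []
    violations = 0
    for key, expect in [(k, "buried") for k in buried_expected] + \
                       [(k, "accessible") for k in accessible_expected]:
        key = norm(key)
        if key not in rel:
            raise KeyError(f"residue {key} not in model")
        acc = rel[key]
        bad = acc > rel_cutoff if expect == "buried" else acc < rel_cutoff
        violations += int(bad)
        rows.append({"chain": key[0], "resseq": key[1], "icode": key[2],
                     "expected": expect, "rel_accessibility": acc,
                     "violation": bool(bad)})
    return violations, pd.DataFrame(rows)
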