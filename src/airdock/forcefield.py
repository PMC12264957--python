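"""Heavy-atom force field: per-atom parameters and covalent topology.

A united-type, heavy-atom representation: each amino acid residue is a
template of heavy atoms with explicit bonds; hydrogens are implicit.
Per-atom physical parameters (Lennard-Jones epsilon/rmin, partial charge,
atomic solvation parameter, SASA radius) are shipped as a plain-text table
``data/forcefield.tsv`` with one row per (residue, atom); see that file's
header for column semantics.

Charges are formal: zero everywhere except charged side-chain termini
(ASP/GLU carboxylates at -0.5 per oxygen, LYS NZ +1, ARG NH1/NH2 +0.5 each)
and, optionally, charged chain termini (+1 on the N-terminal nitrogen,
-1 spread over the C-terminal carboxylate).  Histidine is neutral.

Bond equilibrium lengths come from the residue templates; angle equilibria
are taken from the input conformation (the minimizer preserves local
geometry rather than idealizing it).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .pdbio import Model, Residue

__all__ = [
    "AtomParams",
    "Topology",
    "ResidueTemplate",
    "TEMPLATES",
    "UnparameterizedResidueError",
    "MissingAtomError",
    "load_param_table",
    "build_topology",
    "peptide_links",
    "PEPTIDE_BOND_LENGTH",
    "PEPTIDE_LINK_CUTOFF",
]

PEPTIDE_BOND_LENGTH = 1.329   # Å, C(i)-N(i+1)
PEPTIDE_LINK_CUTOFF = 2.0     # Å, max C-N distance counted as a link
BOND_K = 300.0                # kcal/mol/Å², harmonic bond force constant
ANGLE_K = 50.0                # kcal/mol/rad², harmonic angle force constant


class UnparameterizedResidueError(KeyError):
    """A residue name has no entry in the template library."""


class MissingAtomError(KeyError):
    """A template atom is absent from (or unknown in) a residue."""


@dataclass(frozen=True)
class AtomParams:
    epsilon: float   # kcal/mol
    rmin: float      # Å (pair minimum for two like atoms)
    charge: float    # e
    asp: float       # kcal/mol/Å², atomic solvation parameter
    radius: float    # Å, for SASA


@dataclass(frozen=True)
class ResidueTemplate:
    name: str
    atoms: tuple[str, ...]
    # (atom1, atom2, equilibrium length Å)
    bonds: tuple[tuple[str, str, float], ...]


def _t(name: str, side_atoms: Sequence[str],
       side_bonds: Sequence[tuple[str, str, float]]) -> ResidueTemplate:
    atoms = ("N", "CA", "C", "O") + tuple(side_atoms)
    bonds = (("N", "CA", 1.458), ("CA", "C", 1.525), ("C", "O", 1.231))
    if "CB" in side_atoms:
        bonds += (("CA", "CB", 1.530),)
    return ResidueTemplate(name, atoms, bonds + tuple(side_bonds))


_AROM = 1.39

TEMPLATES: dict[str, ResidueTemplate] = {t.name: t for t in [
    _t("GLY", [], []),
    _t("ALA", ["CB"], []),
    _t("SER", ["CB", "OG"], [("CB", "OG", 1.417)]),
    _t("CYS", ["CB", "SG"], [("CB", "SG", 1.808)]),
    _t("THR", ["CB", "OG1", "CG2"],
       [("CB", "OG1", 1.433), ("CB", "CG2", 1.521)]),
    _t("VAL", ["CB", "CG1", "CG2"],
       [("CB", "CG1", 1.521), ("CB", "CG2", 1.521)]),
    _t("LEU", ["CB", "CG", "CD1", "CD2"],
       [("CB", "CG", 1.530), ("CG", "CD1", 1.521), ("CG", "CD2", 1.521)]),
    _t("ILE", ["CB", "CG1", "CG2", "CD1"],
       [("CB", "CG1", 1.530), ("CB", "CG2", 1.521), ("CG1", "CD1", 1.513)]),
    _t("MET", ["CB", "CG", "SD", "CE"],
       [("CB", "CG", 1.520), ("CG", "SD", 1.803), ("SD", "CE", 1.791)]),
    _t("PRO", ["CB", "CG", "CD"],
       [("CB", "CG", 1.492), ("CG", "CD", 1.503), ("CD", "N", 1.473)]),
    _t("PHE", ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
       [("CB", "CG", 1.502), ("CG", "CD1", _AROM), ("CG", "CD2", _AROM),
        ("CD1", "CE1", _AROM), ("CD2", "CE2", _AROM),
        ("CE1", "CZ", _AROM), ("CE2", "CZ", _AROM)]),
    _t("TYR", ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
       [("CB", "CG", 1.502), ("CG", "CD1", _AROM), ("CG", "CD2", _AROM),
        ("CD1", "CE1", _AROM), ("CD2", "CE2", _AROM),
        ("CE1", "CZ", _AROM), ("CE2", "CZ", _AROM), ("CZ", "OH", 1.376)]),
    _t("TRP", ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3",
               "CH2"],
       [("CB", "CG", 1.498), ("CG", "CD1", 1.365), ("CG", "CD2", 1.433),
        ("CD1", "NE1", 1.374), ("NE1", "CE2", 1.370), ("CD2", "CE2", 1.409),
        ("CD2", "CE3", 1.398), ("CE2", "CZ2", 1.394), ("CE3", "CZ3", 1.382),
        ("CZ2", "CH2", 1.368), ("CZ3", "CH2", 1.400)]),
    _t("ASP", ["CB", "CG", "OD1", "OD2"],
       [("CB", "CG", 1.516), ("CG", "OD1", 1.249), ("CG", "OD2", 1.249)]),
    _t("GLU", ["CB", "CG", "CD", "OE1", "OE2"],
       [("CB", "CG", 1.520), ("CG", "CD", 1.516), ("CD", "OE1", 1.249),
        ("CD", "OE2", 1.249)]),
    _t("ASN", ["CB", "CG", "OD1", "ND2"],
       [("CB", "CG", 1.516), ("CG", "OD1", 1.231), ("CG", "ND2", 1.328)]),
    _t("GLN", ["CB", "CG", "CD", "OE1", "NE2"],
       [("CB", "CG", 1.520), ("CG", "CD", 1.516), ("CD", "OE1", 1.231),
        ("CD", "NE2", 1.328)]),
    _t("LYS", ["CB", "CG", "CD", "CE", "NZ"],
       [("CB", "CG", 1.520), ("CG", "CD", 1.520), ("CD", "CE", 1.520),
        ("CE", "NZ", 1.489)]),
    _t("ARG", ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
       [("CB", "CG", 1.520), ("CG", "CD", 1.520), ("CD", "NE", 1.460),
        ("NE", "CZ", 1.329), ("CZ", "NH1", 1.326), ("CZ", "NH2", 1.326)]),
    _t("HIS", ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
       [("CB", "CG", 1.497), ("CG", "ND1", 1.371), ("CG", "CD2", 1.356),
        ("ND1", "CE1", 1.319), ("CD2", "NE2", 1.374), ("CE1", "NE2", 1.345)]),
]}

# C-terminal carboxylate oxygen: optional extra atom on any residue
_OXT_BOND = ("C", "OXT", 1.249)


@dataclass
class Topology:
    """Per-atom parameters plus covalent terms, aligned with a Model."""

    epsilon: np.ndarray            # (n,)
    rmin: np.ndarray               # (n,)
    charge: np.ndarray             # (n,)
    asp: np.ndarray                # (n,)
    radius: np.ndarray             # (n,)
    bonds: np.ndarray              # (nb, 2) int atom indices
    bond_r0: np.ndarray            # (nb,)
    bond_k: np.ndarray             # (nb,)
    angles: np.ndarray             # (na, 3) int atom indices (i-j-k, j apex)
    angle_theta0: np.ndarray       # (na,) rad
    angle_k: np.ndarray            # (na,)
    excluded: set[tuple[int, int]] = field(default_factory=set)

    @property
    def n_atoms(self) -> int:
        return len(self.epsilon)


_PARAM_CACHE: dict[str, dict[tuple[str, str], AtomParams]] = {}


def load_param_table(name: str = "forcefield.tsv"
                     ) -> dict[tuple[str, str], AtomParams]:
    """Load the packaged (residue, atom) -> AtomParams table."""
    if name in _PARAM_CACHE:
        return _PARAM_CACHE[name]
    table: dict[tuple[str, str], AtomParams] = {}
    text = resources.files("airdock.data").joinpath(name).read_text()
    rows = [ln for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
    for row in csv.reader(rows, delimiter="\t"):
        resname, atom, eps, rmin, charge, asp, radius = row
        table[(resname, atom)] = AtomParams(
            float(eps), float(rmin), float(charge), float(asp), float(radius))
    _PARAM_CACHE[name] = table
    return table


def peptide_links(model: Model) -> list[tuple[int, int]]:
    """Inter-residue peptide bonds as (residue index, residue index) pairs.

    A link exists between consecutive residues of the same chain whose
    C(i)-N(i+1) distance is below 2.0 Å; chain breaks yield no link.
    """
    links: list[tuple[int, int]] = []
    residues = model.residues
    for i in range(len(residues) - 1):
        a, b = residues[i], residues[i + 1]
        if a.chain != b.chain:
            continue
        if not (a.has_atom("C") and b.has_atom("N")):
            continue
        d = np.linalg.norm(a.atom("C").xyz - b.atom("N").xyz)
        if d < PEPTIDE_LINK_CUTOFF:
            links.append((i, i + 1))
    return links


def _chain_termini(model: Model) -> tuple[set[int], set[int]]:
    """Residue indices that are free N-termini / C-termini (no peptide link)."""
    linked = peptide_links(model)
    has_prev = {j for _, j in linked}
    has_next = {i for i, _ in linked}
    n_term = {i for i in range(len(model.residues)) if i not in has_prev}
    c_term = {i for i in range(len(model.residues)) if i not in has_next}
    return n_term, c_term


def build_topology(model: Model,
                   params: dict[tuple[str, str], AtomParams] | None = None,
                   extra_templates: dict[str, ResidueTemplate] | None = None,
                   charged_termini: bool = True) -> Topology:
    """Assign parameters and covalent terms to every atom of a model.

    Raises :class:`UnparameterizedResidueError` for residues absent from the
    template library and :class:`MissingAtomError` for atoms missing from a
    residue or unknown to its template.  Users may extend coverage via
    ``extra_templates`` plus matching rows in a custom parameter table.
    """
    if params is None:
        params = load_param_table()
    templates = dict(TEMPLATES)
    if extra_templates:
        templates.update(extra_templates)

    n = model.n_atoms
    eps = np.zeros(n)
    rmin = np.zeros(n)
    charge = np.zeros(n)
    asp = np.zeros(n)
    radius = np.zeros(n)

    # global atom index per residue
    index: list[dict[str, int]] = []
    gi = 0
    for res in model.residues:
        amap: dict[str, int] = {}
        for atom in res.atoms:
            amap[atom.name] = gi
            gi += 1
        index.append(amap)

    bonds: list[tuple[int, int, float]] = []
    unknown = sorted({r.resname for r in model.residues
                      if r.resname not in templates})
    if unknown:
        raise UnparameterizedResidueError(
            f"no template for residue(s): {', '.join(unknown)}")

    for ri, res in enumerate(model.residues):
        tpl = templates[res.resname]
        amap = index[ri]
        allowed = set(tpl.atoms) | {"OXT"}
        for atom in res.atoms:
            if atom.name not in allowed:
                raise MissingAtomError(
                    f"atom {atom.name!r} of {res.resname} {res.key} unknown "
                    f"to its template")
        missing = [a for a in tpl.atoms if a not in amap]
        if missing:
            raise MissingAtomError(
                f"residue {res.resname} {res.key} missing template atom(s) "
                f"{missing}")
        for atom in res.atoms:
            key = (res.resname, atom.name)
            if key not in params and atom.name == "OXT":
                key = (res.resname, "O")    # OXT parameterized like O
            if key not in params:
                raise MissingAtomError(
                    f"no parameters for {key[0]}:{key[1]}")
            p = params[key]
            i = amap[atom.name]
            eps[i], rmin[i] = p.epsilon, p.rmin
            charge[i], asp[i], radius[i] = p.charge, p.asp, p.radius
        for a1, a2, r0 in tpl.bonds:
            if a1 in amap and a2 in amap:
                bonds.append((amap[a1], amap[a2], r0))
        if "OXT" in amap:
            bonds.append((amap[_OXT_BOND[0]], amap[_OXT_BOND[1]],
                          _OXT_BOND[2]))

    links = peptide_links(model)
    for i, j in links:
        bonds.append((index[i]["C"], index[j]["N"], PEPTIDE_BOND_LENGTH))

    if charged_termini:
        n_term, c_term = _chain_termini(model)
        for ri in n_term:
            res = model.residues[ri]
            if res.has_atom("N"):
                charge[index[ri]["N"]] += 1.0
        for ri in c_term:
            amap = index[ri]
            if "OXT" in amap and "O" in amap:
                charge[amap["O"]] += -0.5
                charge[amap["OXT"]] += -0.5
            elif "O" in amap:
                charge[amap["O"]] += -1.0

    bond_idx = np.array([(i, j) for i, j, _ in bonds], dtype=int).reshape(-1, 2)
    bond_r0 = np.array([r0 for _, _, r0 in bonds])
    bond_k = np.full(len(bonds), BOND_K)

    # angles from the bond graph; equilibrium value = current geometry
    adj: dict[int, list[int]] = {}
    for i, j, _ in bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    coords = model.coords()
    angles: list[tuple[int, int, int]] = []
    for j, nbrs in sorted(adj.items()):
        nbrs = sorted(nbrs)
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                angles.append((nbrs[x], j, nbrs[y]))
    theta0 = np.zeros(len(angles))
    for k, (i, j, l) in enumerate(angles):
        v1 = coords[i] - coords[j]
        v2 = coords[l] - coords[j]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        theta0[k] = np.arccos(np.clip(cosang, -1.0, 1.0))
    angle_idx = np.array(angles, dtype=int).reshape(-1, 3)
    angle_k = np.full(len(angles), ANGLE_K)

    excluded: set[tuple[int, int]] = set()
    for i, j, _ in bonds:
        excluded.add((min(i, j), max(i, j)))
    for i, j, l in angles:
        excluded.add((min(i, l), max(i, l)))

    return Topology(eps, rmin, charge, asp, radius,
                    bond_idx, bond_r0, bond_k,
                    angle_idx, theta0, angle_k, excluded)
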