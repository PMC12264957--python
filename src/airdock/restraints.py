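"""Ambiguous and unambiguous distance restraints.

An ambiguous interaction restraint (AIR) ties one *active* residue to the
set of active+passive residues of the partner through an effective distance

    d_eff = ( sum_i sum_k d_ik^-6 )^(-1/6)

over all cross pairs of heavy atoms, so the restraint is satisfied as soon
as *any* source/target atom pair comes close.  Active residues are required
to be at the interface (they generate restraints); passive residues may be
at the interface (they only receive them).

Restraints are read and written in a strict subset of the CNS ``assign``
statement dialect::

    assign (segid A and resid 10)
           ((segid B and resid 5) or (segid B and resid 6)) 2.0 2.0 0.0

The three numbers are distance, dminus, dplus: the allowed band is
[distance - dminus, distance + dplus].  Selections combine ``segid``,
``resid`` and optionally ``name`` with ``and``; unions use ``or``.  A
selection carrying atom names denotes an unambiguous (atom pair) restraint.
Anything outside this subset is a parse error, not a warning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .pdbio import Model

__all__ = [
    "ResidueTag",
    "AmbiguousRestraint",
    "UnambiguousRestraint",
    "RestraintSet",
    "TblParseError",
    "NoRestraintsError",
    "make_airs",
    "effective_distance",
    "air_energy",
    "random_removal",
    "parse_tbl",
    "write_tbl",
    "assign_restraint_sets",
    "AIR_UPPER_BOUND",
    "AIR_FORCE_CONSTANT",
    "AIR_ENERGY_CEILING",
]

AIR_UPPER_BOUND = 2.0        # Å, default upper bound on d_eff
AIR_FORCE_CONSTANT = 50.0    # kcal/mol/Å²
AIR_ENERGY_CEILING = 1000.0  # kcal/mol, soft-square cap


class TblParseError(ValueError):
    """Malformed restraint file; message names the line."""


class NoRestraintsError(ValueError):
    """Raised when a construction would yield zero restraints."""


@dataclass(frozen=True)
class ResidueTag:
    chain: str
    resseq: int
    icode: str = ""
    role: str = field(default="active", compare=False)


@dataclass(frozen=True)
class AmbiguousRestraint:
    source: ResidueTag
    targets: frozenset[ResidueTag]
    upper_bound: float = AIR_UPPER_BOUND
    lower_bound: float = 0.0

    def __post_init__(self):
        if not self.targets:
            raise ValueError("ambiguous restraint with empty target set")
        if not (self.upper_bound >= self.lower_bound >= 0):
            raise ValueError(
                f"invalid bounds [{self.lower_bound}, {self.upper_bound}]")


@dataclass(frozen=True)
class AtomRef:
    chain: str
    resseq: int
    name: str
    icode: str = ""


@dataclass(frozen=True)
class UnambiguousRestraint:
    atom_a: AtomRef
    atom_b: AtomRef
    distance: float
    dminus: float = 0.0
    dplus: float = 0.0

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.dminus < 0 or self.dplus < 0:
            raise ValueError("tolerances must be non-negative")


@dataclass
class RestraintSet:
    set_id: str
    ambiguous: list[AmbiguousRestraint] = field(default_factory=list)
    unambiguous: list[UnambiguousRestraint] = field(default_factory=list)
    origin_path: str | None = None

    def __len__(self) -> int:
        return len(self.ambiguous) + len(self.unambiguous)


def make_airs(active_a: Sequence[ResidueTag] = (),
              passive_a: Sequence[ResidueTag] = (),
              active_b: Sequence[ResidueTag] = (),
              passive_b: Sequence[ResidueTag] = (),
              upper_bound: float = AIR_UPPER_BOUND,
              set_id: str = "airs") -> RestraintSet:
    """Build AIRs from active/passive residue lists of two partners.

    Every active residue of partner A restrains to all active+passive
    residues of partner B, and symmetrically.  At least one partner must
    have at least one active residue.
    """
    active_a = [replace(t, role="active") for t in active_a]
    active_b = [replace(t, role="active") for t in active_b]
    passive_a = [replace(t, role="passive") for t in passive_a]
    passive_b = [replace(t, role="passive") for t in passive_b]
    if not active_a and not active_b:
        raise NoRestraintsError(
            "no active residues on either partner: no restraints result")
    airs: list[AmbiguousRestraint] = []
    tgt_b = frozenset(active_b + passive_b)
    tgt_a = frozenset(active_a + passive_a)
    for src in active_a:
        if not tgt_b:
            raise NoRestraintsError(
                f"active residue {src} has no target residues on partner B")
        airs.append(AmbiguousRestraint(src, tgt_b, upper_bound, 0.0))
    for src in active_b:
        if not tgt_a:
            raise NoRestraintsError(
                f"active residue {src} has no target residues on partner A")
        airs.append(AmbiguousRestraint(src, tgt_a, upper_bound, 0.0))
    return RestraintSet(set_id, ambiguous=airs)


def effective_distance(source_atoms: np.ndarray,
                       target_atoms: np.ndarray) -> float:
    """AIR effective distance over all cross pairs: (Σ d^-6)^(-1/6).

    Always ≤ the minimum pairwise distance; coincident atoms give 0 by
    convention.
    """
    a = np.asarray(source_atoms, dtype=float).reshape(-1, 3)
    b = np.asarray(target_atoms, dtype=float).reshape(-1, 3)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty atom set in effective distance")
    diff = a[:, None, :] - b[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    if np.any(d2 == 0.0):
        return 0.0
    s = float(np.sum(d2 ** -3))
    return s ** (-1.0 / 6.0)


def flat_bottom_energy(d_eff: float, lower: float, upper: float,
                       k: float = AIR_FORCE_CONSTANT,
                       ceiling: float = AIR_ENERGY_CEILING) -> float:
    """Soft-square flat-bottom penalty on an (effective) distance."""
    if d_eff > upper:
        viol = d_eff - upper
    elif d_eff < lower:
        viol = lower - d_eff
    else:
        return 0.0
    return min(k * viol * viol, ceiling)


def resolve_residue_atoms(model: Model, tag: ResidueTag) -> np.ndarray:
    """Heavy-atom coordinates of the residue a tag points to."""
    res = model.residue(tag.chain, tag.resseq, tag.icode)
    coords = [a.xyz for a in res.atoms if a.element != "H"]
    return np.array(coords, dtype=float)


def air_energy(restraint: AmbiguousRestraint, model: Model,
               k: float = AIR_FORCE_CONSTANT,
               ceiling: float = AIR_ENERGY_CEILING) -> float:
    """Flat-bottom AIR penalty evaluated on a model (heavy atoms)."""
    src = resolve_residue_atoms(model, restraint.source)
    tgt = np.concatenate([resolve_residue_atoms(model, t)
                          for t in sorted(restraint.targets,
                                          key=lambda t: (t.chain, t.resseq,
                                                         t.icode))])
    d_eff = effective_distance(src, tgt)
    return flat_bottom_energy(d_eff, restraint.lower_bound,
                              restraint.upper_bound, k, ceiling)


def random_removal(rset: RestraintSet, fraction: float,
                   seed: int) -> RestraintSet:
    """Remove a random fraction of the *ambiguous* restraints (seeded).

    Unambiguous restraints are never removed.  The number removed is
    ``round(fraction * n)``; survivor order is preserved.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    n = len(rset.ambiguous)
    n_remove = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(n, size=n_remove, replace=False)) if n_remove else set()
    kept = [r for i, r in enumerate(rset.ambiguous) if i not in drop]
    return RestraintSet(rset.set_id, ambiguous=kept,
                        unambiguous=list(rset.unambiguous),
                        origin_path=rset.origin_path)


def assign_restraint_sets(n_models: int, sets: Sequence[RestraintSet],
                          policy: str = "round_robin") -> list[str]:
    """Per-model restraint-set ids; the default policy is round-robin.

    Model i receives set ``i mod n_sets``, so sets are split as evenly as
    possible over the models.  The mapping is recorded in model provenance
    by the sampling stage and preserved by every downstream module.
    """
    if not sets:
        raise ValueError("at least one restraint set required")
    if policy != "round_robin":
        raise ValueError(f"unknown assignment policy {policy!r}")
    ids = [s.set_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate set ids: {ids}")
    return [ids[i % len(ids)] for i in range(n_models)]


# ---------------------------------------------------------------------------
# .tbl dialect parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[A-Za-z_][A-Za-z0-9_']*|[-+]?[0-9]*\.?[0-9]+")


class _Tokens:
    def __init__(self, text: str):
        self.toks: list[tuple[str, int]] = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("!")[0]
            pos = 0
            while pos < len(line):
                m = _TOKEN_RE.match(line, pos)
                if m is None:
                    if line[pos].isspace():
                        pos += 1
                        continue
                    raise TblParseError(
                        f"line {lineno}: unexpected character {line[pos]!r}")
                self.toks.append((m.group(0), lineno))
                pos = m.end()
        self.i = 0

    def peek(self) -> str | None:
        return self.toks[self.i][0] if self.i < len(self.toks) else None

    @property
    def lineno(self) -> int:
        i = min(self.i, len(self.toks) - 1)
        return self.toks[i][1] if self.toks else 0

    def next(self) -> str:
        if self.i >= len(self.toks):
            raise TblParseError("unexpected end of file")
        tok, _ = self.toks[self.i]
        self.i += 1
        return tok

    def expect(self, want: str) -> str:
        tok = self.next()
        if tok.lower() != want:
            raise TblParseError(
                f"line {self.lineno}: expected {want!r}, got {tok!r}")
        return tok


def _parse_selection(tk: _Tokens) -> list[dict]:
    """Parse a parenthesized selection into a list of leaf conditions."""
    tk.expect("(")
    leaves = _parse_or(tk)
    tk.expect(")")
    return leaves


def _parse_or(tk: _Tokens) -> list[dict]:
    leaves = _parse_term(tk)
    while tk.peek() is not None and tk.peek().lower() == "or":
        tk.next()
        leaves.extend(_parse_term(tk))
    return leaves


def _parse_term(tk: _Tokens) -> list[dict]:
    if tk.peek() == "(":
        tk.next()
        leaves = _parse_or(tk)
        tk.expect(")")
        return leaves
    cond: dict = {}
    while True:
        key = tk.next().lower()
        if key not in ("segid", "resid", "name"):
            raise TblParseError(
                f"line {tk.lineno}: unknown selection keyword {key!r}")
        val = tk.next()
        if key == "resid":
            try:
                cond["resid"] = int(val)
            except ValueError:
                raise TblParseError(
                    f"line {tk.lineno}: resid must be an integer, "
                    f"got {val!r}") from None
        else:
            cond[key] = val
        nxt = tk.peek()
        if nxt is not None and nxt.lower() == "and":
            tk.next()
            continue
        break
    if "segid" not in cond or "resid" not in cond:
        raise TblParseError(
            f"line {tk.lineno}: selection needs both segid and resid")
    return [cond]


def _parse_number(tk: _Tokens) -> float:
    tok = tk.next()
    try:
        return float(tok)
    except ValueError:
        raise TblParseError(
            f"line {tk.lineno}: expected a number, got {tok!r}") from None


def parse_tbl(path: str | Path, set_id: str | None = None) -> RestraintSet:
    """Parse a ``.tbl`` restraint file into a :class:`RestraintSet`.

    Residue-level assign statements become ambiguous restraints (the first
    selection is the source residue); statements whose selections carry
    atom names become unambiguous atom-pair restraints.
    """
    path = Path(path)
    text = path.read_text()
    tk = _Tokens(text)
    rset = RestraintSet(set_id or path.stem, origin_path=str(path))
    while tk.peek() is not None:
        word = tk.next()
        if word.lower() != "assign":
            raise TblParseError(
                f"line {tk.lineno}: expected 'assign', got {word!r}")
        sel1 = _parse_selection(tk)
        sel2 = _parse_selection(tk)
        d = _parse_number(tk)
        dminus = _parse_number(tk)
        dplus = _parse_number(tk)
        has_names = any("name" in c for c in sel1 + sel2)
        if has_names:
            if len(sel1) != 1 or len(sel2) != 1 \
                    or "name" not in sel1[0] or "name" not in sel2[0]:
                raise TblParseError(
                    f"line {tk.lineno}: atom-pair restraints need exactly "
                    f"one named atom on each side")
            a = AtomRef(sel1[0]["segid"], sel1[0]["resid"],
                        sel1[0]["name"])
            b = AtomRef(sel2[0]["segid"], sel2[0]["resid"],
                        sel2[0]["name"])
            rset.unambiguous.append(
                UnambiguousRestraint(a, b, d, dminus, dplus))
        else:
            if len(sel1) != 1:
                raise TblParseError(
                    f"line {tk.lineno}: ambiguous restraint source must be "
                    f"a single residue")
            src = ResidueTag(sel1[0]["segid"], sel1[0]["resid"],
                             role="active")
            targets = frozenset(
                ResidueTag(c["segid"], c["resid"], role="passive")
                for c in sel2)
            upper = d + dplus
            lower = max(d - dminus, 0.0)
            rset.ambiguous.append(
                AmbiguousRestraint(src, targets, upper, lower))
    return rset


def _fmt_tag(tag: ResidueTag) -> str:
    return f"(segid {tag.chain} and resid {tag.resseq})"


def write_tbl(rset: RestraintSet, path: str | Path) -> Path:
    """Write a restraint set in the supported ``assign`` dialect."""
    path = Path(path)
    lines: list[str] = [f"! restraint set {rset.set_id}"]
    for r in rset.ambiguous:
        # encode bounds as d=upper, dminus=upper-lower, dplus=0
        d = r.upper_bound
        dminus = r.upper_bound - r.lower_bound
        tgt = sorted(r.targets, key=lambda t: (t.chain, t.resseq, t.icode))
        union = "\n     or ".join(f"  {_fmt_tag(t)}" for t in tgt)
        lines.append(f"assign {_fmt_tag(r.source)}\n"
                     f"       (\n     {union}\n       ) "
                     f"{d:.2f} {dminus:.2f} 0.00")
    for r in rset.unambiguous:
        a = (f"(segid {r.atom_a.chain} and resid {r.atom_a.resseq} "
             f"and name {r.atom_a.name})")
        b = (f"(segid {r.atom_b.chain} and resid {r.atom_b.resseq} "
             f"and name {r.atom_b.name})")
        lines.append(f"assign {a} {b} "
                     f"{r.distance:.2f} {r.dminus:.2f} {r.dplus:.2f}")
    path.write_text("\n".join(lines) + "\n")
    return path
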