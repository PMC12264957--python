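"""Structural data model and PDB input/output.

The package represents a molecule as a :class:`Model`: an ordered list of
chains, each an ordered list of residues, each an ordered list of
:class:`AtomRecord`.  Multi-model PDB files (MODEL/ENDMDL blocks) are read
into an :class:`Ensemble`.  The representation is heavy-atom only: hydrogens
present in the input are dropped on parse, as are waters and alternate
locations other than blank/'A' (single-conformer convention).

Chain identifiers (not segids) define docking partners throughout the
package.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Model",
    "Ensemble",
    "Provenance",
    "PDBParseError",
    "CompositionError",
    "PDBFormatError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "partner_split",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP3"}


class PDBParseError(ValueError):
    """Raised for malformed fixed-column PDB input; message names the line."""


class CompositionError(ValueError):
    """Raised when ensemble members differ in chain/residue/atom composition."""


class PDBFormatError(ValueError):
    """Raised when a structure cannot be encoded in fixed PDB columns."""


class SelectionError(KeyError):
    """Raised for selections that reference absent chains or match nothing."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    icode: str
    xyz: np.ndarray
    element: str
    occupancy: float = 1.0
    bfactor: float = 0.0

    def copy(self) -> "AtomRecord":
        rec = copy.copy(self)
        rec.xyz = self.xyz.copy()
        return rec


@dataclass
class Residue:
    resname: str
    chain: str
    resseq: int
    icode: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.resname} {self.key}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def copy(self) -> "Residue":
        return Residue(self.resname, self.chain, self.resseq, self.icode,
                       [a.copy() for a in self.atoms])


@dataclass
class Provenance:
    """Where a model came from: step, file, restraint set, score, lineage."""

    origin_step: str | None = None
    source_path: str | None = None
    restraint_set_id: str | None = None
    score: float | None = None
    cluster_id: int | None = None
    cluster_rank: int | None = None
    name: str | None = None
    parent: str | None = None

    def copy(self) -> "Provenance":
        return copy.copy(self)


class Model:
    """Ordered chains of ordered residues of atoms, plus provenance."""

    def __init__(self, residues: Iterable[Residue], model_id: int = 1,
                 provenance: Provenance | None = None):
        self._residues: list[Residue] = list(residues)
        self.model_id = model_id
        self.provenance = provenance or Provenance()
        self._validate()

    def _validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for res in self._residues:
            if not res.atoms:
                raise CompositionError(
                    f"empty residue {res.resname} {res.key}")
            if res.key in seen:
                raise CompositionError(f"duplicate residue key {res.key}")
            seen.add(res.key)
        # chains must be contiguous blocks so chain ids are unique
        order: list[str] = []
        for res in self._residues:
            if not order or order[-1] != res.chain:
                order.append(res.chain)
        if len(order) != len(set(order)):
            raise CompositionError(f"chain ids not unique/contiguous: {order}")
        self._chain_order = order

    @property
    def chains(self) -> list[str]:
        return list(self._chain_order)

    @property
    def residues(self) -> list[Residue]:
        return self._residues

    def chain_residues(self, chain: str) -> list[Residue]:
        res = [r for r in self._residues if r.chain == chain]
        if not res:
            raise SelectionError(f"chain {chain!r} not in model "
                                 f"(has {self._chain_order})")
        return res

    def atoms(self) -> Iterator[AtomRecord]:
        for res in self._residues:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self._residues)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms()], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"coordinate shape {coords.shape} != "
                             f"({self.n_atoms}, 3)")
        for atom, xyz in zip(self.atoms(), coords):
            atom.xyz = xyz.copy()

    def residue(self, chain: str, resseq: int, icode: str = "") -> Residue:
        for r in self._residues:
            if r.key == (chain, resseq, icode):
                return r
        raise SelectionError(f"residue ({chain},{resseq},{icode!r}) not found")

    def composition(self) -> tuple:
        return tuple((r.chain, r.resseq, r.icode, r.resname,
                      tuple(a.name for a in r.atoms)) for r in self._residues)

    def copy(self) -> "Model":
        return Model([r.copy() for r in self._residues], self.model_id,
                     self.provenance.copy())

    def __repr__(self) -> str:
        return (f"<Model id={self.model_id} chains={self.chains} "
                f"residues={len(self._residues)} atoms={self.n_atoms}>")


class Ensemble:
    """Ordered list of models with identical atom composition."""

    def __init__(self, models: Sequence[Model]):
        models = list(models)
        if not models:
            raise ValueError("empty ensemble")
        ref = models[0].composition()
        for m in models[1:]:
            if m.composition() != ref:
                raise CompositionError(
                    f"model {m.model_id} differs in atom composition from "
                    f"model {models[0].model_id}")
        self.models = models

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[Model]:
        return iter(self.models)

    def __getitem__(self, i: int) -> Model:
        return self.models[i]


def _check_fixed_columns(path: Path) -> None:
    """Pre-scan coordinate lines so malformed input fails with a line number.

    gemmi tolerates some damage silently; docking needs hard guarantees on
    the coordinate columns, so validate them up front.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}:{lineno}: coordinate record shorter than 54 "
                    f"columns")
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise PDBParseError(
                    f"{path}:{lineno}: malformed fixed-width field "
                    f"({exc})") from exc
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise PDBParseError(
                    f"{path}:{lineno}: non-finite coordinate")


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.strip()
    if not el or el == "X":
        # infer from the atom name: first alphabetic character
        for ch in atom.name:
            if ch.isalpha():
                return ch.upper()
        return "C"
    return el.upper()


def read_pdb(path: str | Path, keep_hydrogens: bool = False) -> Ensemble:
    """Read a PDB file into an :class:`Ensemble`.

    One model per MODEL/ENDMDL block; a file without MODEL records yields a
    single-member ensemble.  HETATM records are retained; waters, hydrogens
    and alternate locations other than blank/'A' are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_fixed_columns(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc

    models: list[Model] = []
    for mi, gmodel in enumerate(st, start=1):
        residues: list[Residue] = []
        for gchain in gmodel:
            chain_id = (gchain.name or "A")[:1]
            for gres in gchain:
                if gres.name.strip() in _WATER_NAMES:
                    continue
                res = Residue(
                    resname=gres.name.strip(),
                    chain=chain_id,
                    resseq=gres.seqid.num,
                    icode=(gres.seqid.icode or " ").strip(),
                )
                for gatom in gres:
                    if gatom.altloc not in ("\0", "", "A"):
                        continue
                    element = _element_of(gatom)
                    if element == "H" and not keep_hydrogens:
                        continue
                    res.atoms.append(AtomRecord(
                        serial=gatom.serial,
                        name=gatom.name.strip(),
                        resname=res.resname,
                        chain=chain_id,
                        resseq=res.resseq,
                        icode=res.icode,
                        xyz=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        element=element,
                        occupancy=gatom.occ,
                        bfactor=gatom.b_iso,
                    ))
                if res.atoms:
                    residues.append(res)
        if not residues:
            continue
        models.append(Model(residues, model_id=mi,
                            provenance=Provenance(source_path=str(path))))
    if not models:
        raise PDBParseError(f"{path}: no coordinate records found")
    return Ensemble(models)


def _format_atom_line(atom: AtomRecord, serial: int) -> str:
    if atom.resseq > 9999 or atom.resseq < -999:
        raise PDBFormatError(
            f"residue number {atom.resseq} does not fit PDB columns")
    if serial > 99999:
        raise PDBFormatError(f"atom serial {serial} does not fit PDB columns")
    name = atom.name
    # standard alignment: 1-3 char names start in column 14
    if len(name) < 4:
        name = f" {name:<3s}"
    record = "ATOM  " if atom.resname in _STD_RESNAMES else "HETATM"
    x, y, z = atom.xyz
    if not all(math.isfinite(v) and abs(v) < 10000 for v in (x, y, z)):
        raise PDBFormatError(f"coordinate out of range for atom {atom.name}")
    return (f"{record}{serial:5d} {name:<4s}{'':1s}{atom.resname:>3s} "
            f"{atom.chain:1s}{atom.resseq:4d}{atom.icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
            f"{atom.bfactor:6.2f}          {atom.element:>2s}")


_STD_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def write_pdb(ensemble: Ensemble | Model, path: str | Path) -> Path:
    """Write an ensemble (or single model) in fixed-column PDB format.

    Multi-model ensembles are wrapped in MODEL/ENDMDL; a single model is
    written bare.  Coordinates are written at 3 decimals.
    """
    if isinstance(ensemble, Model):
        ensemble = Ensemble([ensemble])
    path = Path(path)
    lines: list[str] = []
    multi = len(ensemble) > 1
    for i, model in enumerate(ensemble, start=1):
        if multi:
            lines.append(f"MODEL {i:>8d}")
        serial = 0
        prev_chain = None
        for res in model.residues:
            if prev_chain is not None and res.chain != prev_chain:
                lines.append("TER")
            prev_chain = res.chain
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom_line(atom, serial))
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


_NAME_ORDER = {n: i for i, n in enumerate(
    ["N", "CA", "C", "O", "CB", "CG", "CG1", "CG2", "OG", "OG1", "SG",
     "CD", "CD1", "CD2", "OD1", "OD2", "ND1", "ND2", "SD",
     "CE", "CE1", "CE2", "CE3", "NE", "NE1", "NE2", "OE1", "OE2",
     "CZ", "CZ2", "CZ3", "NZ", "CH2", "OH", "NH1", "NH2", "OXT"])}


def _atom_sort_key(atom: AtomRecord) -> tuple:
    return (_NAME_ORDER.get(atom.name, len(_NAME_ORDER)), atom.name)


def select_atoms(model: Model, chains: Sequence[str] | None = None,
                 residues: set[tuple[str, int, str]] | None = None,
                 kind: str = "all") -> tuple[np.ndarray, list[AtomRecord]]:
    """Select atoms and return (coords, index map back to AtomRecords).

    kind: 'all' | 'heavy' | 'backbone' (N, CA, C, O).  Output order is
    deterministic: (chain order, resseq, icode, canonical atom-name order),
    independent of atom order inside a residue.
    """
    if kind not in ("all", "heavy", "backbone"):
        raise ValueError(f"unknown atom class {kind!r}")
    if chains is not None:
        known = set(model.chains)
        missing = [c for c in chains if c not in known]
        if missing:
            raise SelectionError(
                f"chain(s) {missing} not in model (has {model.chains})")
    picked: list[AtomRecord] = []
    for res in model.residues:
        if chains is not None and res.chain not in chains:
            continue
        if residues is not None and res.key not in residues:
            continue
        atoms = sorted(res.atoms, key=_atom_sort_key)
        for atom in atoms:
            if kind == "backbone" and atom.name not in BACKBONE_ATOMS:
                continue
            if kind == "heavy" and atom.element == "H":
                continue
            picked.append(atom)
    if not picked:
        raise SelectionError("selection matched no atoms")
    coords = np.array([a.xyz for a in picked], dtype=float)
    return coords, picked


def partner_split(model: Model, partner_defs: Sequence[Sequence[str]]
                  ) -> list[Model]:
    """Split a complex into partner models by groups of chain ids.

    Groups must be disjoint and cover all chains of the model.
    """
    flat: list[str] = [c for group in partner_defs for c in group]
    if len(flat) != len(set(flat)):
        raise ValueError(f"overlapping partner groups: {partner_defs}")
    known = set(model.chains)
    unknown = [c for c in flat if c not in known]
    if unknown:
        raise SelectionError(f"partner group references unknown chain(s) "
                             f"{unknown}")
    if set(flat) != known:
        raise ValueError(f"partner groups {partner_defs} do not cover all "
                         f"chains {model.chains}")
    out: list[Model] = []
    for group in partner_defs:
        gset = set(group)
        res = [r.copy() for r in model.residues if r.chain in gset]
        out.append(Model(res, model_id=model.model_id,
                         provenance=model.provenance.copy()))
    return out
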