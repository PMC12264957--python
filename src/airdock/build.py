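"""Ideal-geometry peptide construction.

Backbones are grown atom-by-atom with the natural-extension reference
frame (place an atom at a given bond length, bond angle and dihedral from
three predecessors); side chains are attached from the residue templates
with a simple zig-zag extension from CB.  The geometry is idealized, not
folded — good enough to parameterize, dock and refine toy complexes with
known ground truth.
"""

from __future__ import annotations

import numpy as np

from .forcefield import TEMPLATES
from .pdbio import AtomRecord, Model, Residue

__all__ = ["place_atom", "build_peptide", "place_sidechain", "HELIX",
           "EXTENDED"]

# (phi, psi, omega) in degrees
HELIX = (-57.0, -47.0, 180.0)
EXTENDED = (-139.0, 135.0, 180.0)

# ideal backbone internal coordinates
_N_CA = 1.458
_CA_C = 1.525
_C_N = 1.329
_C_O = 1.231
_ANG_N_CA_C = 111.0
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_CA_CB = 1.530


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float
               ) -> np.ndarray:
    """Position of atom D given A-B-C, |CD|, angle(BCD) and dihedral(ABCD)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _sidechain_tree(resname: str) -> dict[str, list[str]]:
    """Children map of the side-chain bond graph rooted at CA (tree edges)."""
    tpl = TEMPLATES[resname]
    adj: dict[str, list[str]] = {}
    for a, b, _ in tpl.bonds:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    tree: dict[str, list[str]] = {}
    seen = {"N", "CA", "C", "O"}
    stack = ["CA"]
    while stack:
        node = stack.pop()
        for nbr in sorted(adj.get(node, [])):
            if nbr in seen:
                continue
            seen.add(nbr)
            tree.setdefault(node, []).append(nbr)
            stack.append(nbr)
    return tree


def _bond_length(resname: str, a: str, b: str) -> float:
    for x, y, r0 in TEMPLATES[resname].bonds:
        if {x, y} == {a, b}:
            return r0
    return 1.52


def place_sidechain(resname: str, n: np.ndarray, ca: np.ndarray,
                    c: np.ndarray) -> dict[str, np.ndarray]:
    """Heavy side-chain atom positions grown from the N/CA/C frame.

    CB sits along the negated N-CA/C-CA bisector, tilted out of the
    backbone plane; deeper atoms extend in an alternating zig-zag with
    template bond lengths.  Ring closures are left to the minimizer.
    """
    tpl = TEMPLATES[resname]
    side = [a for a in tpl.atoms if a not in ("N", "CA", "C", "O")]
    if not side:
        return {}
    u = (n - ca) / np.linalg.norm(n - ca)
    v = (c - ca) / np.linalg.norm(c - ca)
    bisector = -(u + v)
    bisector /= np.linalg.norm(bisector)
    normal = np.cross(u, v)
    normal /= np.linalg.norm(normal)
    # tetrahedral-ish CB: tilt the bisector out of the N-CA-C plane
    cb_dir = bisector * np.cos(np.deg2rad(54.0)) \
        + normal * np.sin(np.deg2rad(54.0))
    pos: dict[str, np.ndarray] = {
        "CB": ca + _CA_CB * cb_dir / np.linalg.norm(cb_dir)}
    tree = _sidechain_tree(resname)
    parent = {"CB": "CA"}
    ppos = {"CA": ca}
    ppos.update(pos)

    def grow(node: str, depth: int) -> None:
        children = tree.get(node, [])
        if not children:
            return
        par = parent.get(node, "CA")
        base = ppos[node] - ppos[par]
        base /= np.linalg.norm(base)
        # a perpendicular for the zig-zag / branching pattern
        perp = np.cross(base, normal)
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(base, np.array([1.0, 0.0, 0.0]))
        perp /= np.linalg.norm(perp)
        zig = 1.0 if depth % 2 == 0 else -1.0
        offsets = [zig * 0.9, -zig * 0.9, 0.0]
        for k, child in enumerate(children):
            d = base + offsets[min(k, 2)] * perp
            d /= np.linalg.norm(d)
            ppos[child] = ppos[node] + _bond_length(resname, node, child) * d
            pos[child] = ppos[child]
            parent[child] = node
            grow(child, depth + 1)

    grow("CB", 0)
    missing = [a for a in side if a not in pos]
    if missing:
        raise ValueError(f"could not place side-chain atom(s) {missing} "
                         f"of {resname}")
    return pos


def build_peptide(sequence: list[str], chain: str = "A",
                  start_resseq: int = 1,
                  conformation: tuple[float, float, float] = HELIX,
                  origin: np.ndarray | None = None) -> Model:
    """Build an ideal-geometry peptide from three-letter residue names."""
    phi, psi, omega = conformation
    unknown = [r for r in sequence if r not in TEMPLATES]
    if unknown:
        raise KeyError(f"unknown residue name(s): {unknown}")
    if origin is None:
        origin = np.zeros(3)

    # backbone chain of N, CA, C atoms via NeRF
    bb: list[dict[str, np.ndarray]] = []
    n0 = origin + np.array([0.0, 0.0, 0.0])
    ca0 = origin + np.array([_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_ANG_N_CA_C)
    c0 = ca0 + _CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, len(sequence)):
        prev = bb[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"],
                       _C_N, _ANG_CA_C_N, psi)
        ca = place_atom(prev["CA"], prev["C"], n,
                        _N_CA, _ANG_C_N_CA, omega)
        c = place_atom(prev["C"], n, ca, _CA_C, _ANG_N_CA_C, phi)
        bb.append({"N": n, "CA": ca, "C": c})

    residues: list[Residue] = []
    serial = 1
    for i, resname in enumerate(sequence):
        frame = bb[i]
        # carbonyl O: anti to the next N (or to CA for the last residue)
        if i + 1 < len(bb):
            o = place_atom(bb[i + 1]["N"], frame["CA"], frame["C"],
                           _C_O, 121.0, 180.0)
        else:
            o = place_atom(frame["N"], frame["CA"], frame["C"],
                           _C_O, 121.0, -45.0)
        coords = {"N": frame["N"], "CA": frame["CA"], "C": frame["C"],
                  "O": o}
        coords.update(place_sidechain(resname, frame["N"], frame["CA"],
                                      frame["C"]))
        res = Residue(resname, chain, start_resseq + i, "")
        for name in TEMPLATES[resname].atoms:
            res.atoms.append(AtomRecord(
                serial=serial, name=name, resname=resname, chain=chain,
                resseq=res.resseq, icode="", xyz=np.asarray(coords[name]),
                element=_element_of(name)))
            serial += 1
        residues.append(res)
    return Model(residues)
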