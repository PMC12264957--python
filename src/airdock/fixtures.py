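"""Synthetic toy complexes with known ground truth.

The toy dimer is a pair of ideal α-helices docked side by side: a
20-residue receptor (chain A) and a 10-residue ligand (chain B) whose
interface carries two designed, opposite-polarity salt bridges.  Because the receptor
is (roughly) cylindrical, rotating the ligand around the receptor axis
produces equally plausible *wrong-epitope* poses on other faces — the
ground truth for multi-restraint-set experiments: one restraint set per
face, only one of them true.

Everything is generated programmatically and deterministically per seed;
no external data is needed anywhere in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .build import HELIX, build_peptide
from .capri import lrmsd
from .clustering import contacts
from .pdbio import Ensemble, Model, Provenance, Residue
from .restraints import RestraintSet, ResidueTag, make_airs, write_tbl

__all__ = ["ToyComplex", "make_toy_dimer", "make_decoys",
           "make_epitope_restraints"]

_CONTACT_GAP = 3.1       # Å, target closest heavy-atom approach
# wrong-epitope faces: (rotation about receptor axis, z shift, ligand spin)
_DECOY_PLACEMENTS = ((150.0, -5.0, 120.0), (250.0, -5.0, 120.0))


@dataclass
class ToyComplex:
    receptor: Model                  # chain A at the reference position
    ligand: Model                    # chain B at the reference bound pose
    reference: Model                 # the bound complex
    true_epitope: list[int]          # receptor resseqs at the interface
    decoy_epitopes: list[list[int]]  # disjoint alternative-face epitopes
    paratope: list[int]              # ligand resseqs at the interface
    decoy_poses: list[Model] = field(default_factory=list)
    # core interface residues whose AIR effective distance at the bound
    # pose is (near-)satisfied — the confident actives a practitioner
    # would restrain on; used by make_epitope_restraints("true")
    core_epitope: list[int] = field(default_factory=list)

    @property
    def ligand_residues(self) -> list[int]:
        return [r.resseq for r in self.ligand.residues]


def _axis_align(model: Model) -> Model:
    """Rotate/translate so the CA principal axis is +z, centroid at origin."""
    ca = np.array([r.atom("CA").xyz for r in model.residues])
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])
    coords = model.coords()
    model = model.copy()
    model.set_coords((coords - centroid) @ rot.as_matrix().T)
    return model


def _face_angle(model: Model, resseq: int) -> float:
    """Azimuth (deg) of a residue's CB around the +z helix axis."""
    res = model.residue(model.chains[0], resseq)
    cb = res.atom("CB").xyz
    return float(np.degrees(np.arctan2(cb[1], cb[0])))


def _flip_x(model: Model) -> Model:
    """180° rotation about x: reverses the helix direction (antiparallel)."""
    R = Rotation.from_euler("x", 180.0, degrees=True).as_matrix()
    out = model.copy()
    out.set_coords(model.coords() @ R.T)
    return out


def _rot_z(model: Model, angle_deg: float) -> Model:
    R = Rotation.from_euler("z", angle_deg, degrees=True).as_matrix()
    out = model.copy()
    out.set_coords(model.coords() @ R.T)
    return out


def _translate(model: Model, vec: np.ndarray) -> Model:
    out = model.copy()
    out.set_coords(model.coords() + vec)
    return out


def _heavy_coords(model: Model) -> np.ndarray:
    return np.array([a.xyz for a in model.atoms() if a.element != "H"])


def _combine(receptor: Model, ligand: Model) -> Model:
    return Model([r.copy() for r in receptor.residues] +
                 [r.copy() for r in ligand.residues],
                 provenance=Provenance(name="reference"))


def _set_contact_gap(receptor: Model, ligand: Model,
                     direction: np.ndarray, gap: float = _CONTACT_GAP,
                     exclude_resseq: set[int] | None = None) -> Model:
    """Slide the ligand along ``direction`` until the closest heavy-atom
    cross distance equals ``gap`` (bisection; distance is monotone in the
    slide).  ``exclude_resseq`` leaves designated residues (e.g. the
    salt-bridge pair) out of the criterion."""
    excl = exclude_resseq or set()
    rec = np.array([a.xyz for a in receptor.atoms()
                    if a.element != "H" and a.resseq not in excl])
    lig0 = np.array([a.xyz for a in ligand.atoms()
                     if a.element != "H" and a.resseq not in excl])

    def min_dist(s: float) -> float:
        return float(cdist(rec, lig0 + s * direction).min())

    # march inward from far outside until first contact, then bisect
    hi = 80.0
    if min_dist(hi) < gap:
        raise RuntimeError("cannot reach requested contact gap")
    lo = None
    s = hi
    while s > -80.0:
        s -= 1.0
        if min_dist(s) < gap:
            lo = s
            break
    if lo is None:
        raise RuntimeError("cannot reach requested contact gap")
    hi = lo + 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < gap:
            lo = mid
        else:
            hi = mid
    return _translate(ligand, 0.5 * (lo + hi) * direction)


def make_toy_dimer(seed: int = 0, relax_steps: int = 500) -> ToyComplex:
    """Deterministic toy receptor-ligand complex with known epitopes.

    The receptor LYS 12 and ligand ASP 5 face each other across the
    interface; after rigid placement the complex is relaxed by energy
    minimization so side chains pack and the salt bridge forms.  The true
    epitope is the receptor-side interface of the relaxed reference under
    the 5 Å heavy-atom rule; two decoy epitopes sit on faces rotated 150°
    and 250° around the receptor axis, disjoint from the true one.
    ``receptor`` and ``ligand`` are the relaxed partner conformations, so
    rigid-body docking can reconstruct the reference exactly.
    """
    from .docking import energy_minimize
    from .forcefield import build_topology
    from .pdbio import partner_split

    # two opposite-polarity salt bridges (K12-D5 and E16-K1) pin the
    # ligand orientation: the flipped pose pays like-charge repulsion.
    # The pairing is antiparallel — facing surface stripes of two
    # right-handed helices only run in register that way.
    rec_seq = ["SER", "LEU", "ALA", "SER", "LEU", "ALA", "SER", "LEU",
               "ALA", "SER", "LEU", "LYS", "SER", "LEU", "ALA", "GLU",
               "LEU", "ALA", "SER", "LEU"]
    lig_seq = ["LYS", "SER", "LEU", "SER", "ASP", "LEU", "SER", "ALA",
               "LEU", "SER"]
    receptor = _axis_align(build_peptide(rec_seq, chain="A",
                                         conformation=HELIX))
    ligand = _axis_align(build_peptide(lig_seq, chain="B",
                                       conformation=HELIX))
    ligand = _flip_x(ligand)       # antiparallel

    # point LYS 12 at +x and ASP 5 at -x, align their z levels
    receptor = _rot_z(receptor, -_face_angle(receptor, 12))
    ligand = _rot_z(ligand, 180.0 - _face_angle(ligand, 5))
    z_k = receptor.residue("A", 12).atom("CA").xyz[2]
    z_d = ligand.residue("B", 5).atom("CA").xyz[2]
    ligand = _translate(ligand, np.array([25.0, 0.0, z_k - z_d]))
    ligand = _set_contact_gap(receptor, ligand, np.array([1.0, 0.0, 0.0]),
                              gap=3.8, exclude_resseq={1, 5, 12, 16})

    # seeded jitter decorrelates seeds without changing the design
    rng = np.random.default_rng(seed)
    placed = _combine(receptor, ligand)
    placed.set_coords(placed.coords()
                      + rng.normal(scale=0.02, size=(placed.n_atoms, 3)))

    # relax: packs the interface and closes the salt bridge
    topology = build_topology(placed)
    reference, _ = energy_minimize(placed, topology, n_steps=relax_steps,
                                   partners=[["A"], ["B"]])
    reference.provenance = Provenance(name="reference")
    receptor, ligand = partner_split(reference, [["A"], ["B"]])
    iface = contacts(reference)
    true_epitope = sorted({a[1] for a, _ in iface.pairs})
    paratope = sorted({b[1] for _, b in iface.pairs})
    if not true_epitope:
        raise RuntimeError("toy construction produced an empty interface")

    # core actives: residues whose AIR to the whole ligand is satisfied
    # (within 0.5 Å of the 2 Å effective-distance bound) at the reference
    from .restraints import AIR_UPPER_BOUND, effective_distance, \
        resolve_residue_atoms
    lig_heavy = _heavy_coords(ligand)
    core_epitope = []
    for resseq in true_epitope:
        src = resolve_residue_atoms(reference, ResidueTag("A", resseq))
        if effective_distance(src, lig_heavy) <= AIR_UPPER_BOUND + 0.5:
            core_epitope.append(resseq)
    if not core_epitope:
        raise RuntimeError("no core epitope residues satisfy their AIR")

    # decoy epitopes: whole receptor faces around the decoy azimuths,
    # independent of any pose, never overlapping the true epitope
    lig_z = ligand.coords()[:, 2].mean()
    decoy_epitopes: list[list[int]] = []
    for angle, z_shift, _ in _DECOY_PLACEMENTS:
        epi = []
        for res in receptor.residues:
            az = _face_angle(receptor, res.resseq)
            dz = res.atom("CA").xyz[2] - (lig_z + z_shift)
            sep = (az - angle + 180.0) % 360.0 - 180.0
            if abs(sep) < 50.0 and abs(dz) < 8.0 \
                    and res.resseq not in true_epitope:
                epi.append(res.resseq)
        decoy_epitopes.append(sorted(epi))

    # wrong-epitope poses: the ligand docked onto the decoy faces
    decoy_poses: list[Model] = []
    for angle, dz, selfspin in _DECOY_PLACEMENTS:
        direction = np.array([np.cos(np.radians(angle)),
                              np.sin(np.radians(angle)), 0.0])
        lig_rot = _rot_z(ligand, angle)
        if selfspin:
            c = lig_rot.coords().mean(axis=0)
            R = Rotation.from_euler("z", selfspin, degrees=True).as_matrix()
            lig_rot = lig_rot.copy()
            lig_rot.set_coords((lig_rot.coords() - c) @ R.T + c)
        lig_rot = _translate(lig_rot, np.array([0.0, 0.0, dz]))
        lig_rot = _set_contact_gap(receptor, lig_rot, direction)
        pose = _combine(receptor, lig_rot)
        pose.provenance.name = f"decoy_pose_{int(angle)}"
        decoy_poses.append(pose)

    return ToyComplex(receptor, ligand, reference, true_epitope,
                      decoy_epitopes, paratope, decoy_poses,
                      core_epitope=core_epitope)


def make_decoys(toy: ToyComplex, rmsd_targets: list[float],
                n_per_level: int = 1, seed: int = 0,
                include_wrong_epitope: bool = True) -> Ensemble:
    """Decoy ensemble at controlled ligand-RMSD levels from the reference.

    Each decoy applies a seeded random rigid motion to the ligand,
    rescaled (secant iteration) until the achieved L-RMSD is within 10%
    of the requested target; targets of 0 give exact copies.  Optionally
    appends the wrong-epitope poses (fnat 0 by construction).
    """
    decoys: list[Model] = []
    rng = np.random.default_rng(seed)
    for target in rmsd_targets:
        if target < 0:
            raise ValueError("rmsd targets must be non-negative")
        for k in range(n_per_level):
            if target == 0:
                model = toy.reference.copy()
                model.provenance = Provenance(name=f"decoy_t0_{k + 1}")
                decoys.append(model)
                continue
            rotvec = rng.normal(size=3)
            rotvec /= np.linalg.norm(rotvec)
            trans = rng.normal(size=3)
            trans /= np.linalg.norm(trans)

            def perturbed(scale: float) -> Model:
                lig = toy.ligand.copy()
                coords = lig.coords()
                c = coords.mean(axis=0)
                R = Rotation.from_rotvec(
                    rotvec * scale * 0.05).as_matrix()
                lig.set_coords((coords - c) @ R.T + c + trans * scale)
                return _combine(toy.receptor, lig)

            scale = target
            achieved = lrmsd(perturbed(scale), toy.reference)
            for _ in range(12):
                if abs(achieved - target) <= 0.1 * target:
                    break
                scale *= target / max(achieved, 1e-9)
                achieved = lrmsd(perturbed(scale), toy.reference)
            model = perturbed(scale)
            model.provenance = Provenance(
                name=f"decoy_t{target:g}_{k + 1}")
            decoys.append(model)
    if include_wrong_epitope:
        for pose in toy.decoy_poses:
            model = pose.copy()
            model.provenance = Provenance(name=pose.provenance.name)
            decoys.append(model)
    return Ensemble(decoys)


def make_epitope_restraints(toy: ToyComplex, which: str = "true",
                            path=None) -> RestraintSet:
    """AIR set targeting the true or a decoy epitope.

    Active residues: the chosen receptor epitope (the *core* epitope for
    the true set — the confident actives whose restraint the bound pose
    satisfies).  Passive: the entire ligand.  With ``path`` the set is also written as a ``.tbl`` file.
    """
    if which == "true":
        epitope = toy.core_epitope or toy.true_epitope
    elif which.startswith("decoy_"):
        k = int(which.split("_", 1)[1])
        if not 1 <= k <= len(toy.decoy_epitopes):
            raise KeyError(f"no decoy epitope {which!r}")
        epitope = toy.decoy_epitopes[k - 1]
    else:
        raise KeyError(f"unknown epitope label {which!r}; use 'true' or "
                       f"'decoy_<k>'")
    active = [ResidueTag("A", r, role="active") for r in epitope]
    passive = [ResidueTag("B", r, role="passive")
               for r in toy.ligand_residues]
    rset = make_airs(active_a=active, passive_b=passive, set_id=which)
    if path is not None:
        write_tbl(rset, path)
        rset.origin_path = str(path)
    return rset
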