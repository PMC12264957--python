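# Methods

`airdock` is a desk-scale, modular platform for information-driven
protein–protein docking: a workflow engine that chains independent
topology / sampling / refinement / scoring / analysis modules, drives
rigid-body docking with ambiguous interaction restraints (AIRs), and
evaluates, clusters and analyzes the resulting models with CAPRI metrics,
fraction-of-common-contacts (FCC) and RMSD clustering, alanine scanning
and contact maps.  This note documents the models, the numerical choices
and what the synthetic test system does and does not demonstrate.

## Structural model

Structures are heavy-atom only.  Hydrogens, waters and alternate
locations other than blank/'A' are dropped on parsing (single-conformer
convention); chain identifiers — not segids — define docking partners.
Multi-model PDB files (MODEL/ENDMDL) become ensembles whose members must
share atom composition exactly.  Residue identity everywhere is the
triple (chain, residue number, insertion code); model/reference
correspondence in the CAPRI metrics is by identifier, **never** by
sequence alignment — inconsistent numbering between a model and its
reference is the user's responsibility.

## Force field

A deliberately simple, self-consistent heavy-atom parameter set, shipped
as a plain-text table (`data/forcefield.tsv`, one row per residue×atom):

* **Lennard-Jones**: per-element well depths and pair minima
  (C: ε 0.105 kcal/mol, rmin 4.0 Å; N: 0.160/3.50; O: 0.210/3.20;
  S: 0.250/3.90), combined with geometric-mean ε and arithmetic-mean
  rmin.
* **Charges** are formal: zero everywhere except charged side-chain
  groups (Asp/Glu −0.5 per carboxylate oxygen, Lys NZ +1, Arg NH1/NH2
  +0.5 each; His neutral) and, by default, chain termini (+1 on the
  N-terminal nitrogen, −1 on the C-terminal carboxylate; disable with
  `charged_termini = false`).
* **Atomic solvation parameters** follow the usual sign structure —
  positive for apolar atoms (burial favorable), negative for polar,
  strongly negative for ionic — at magnitudes of ±0.0125 to ±0.12
  kcal/mol/Å².
* **Covalent terms**: bonds come from per-residue templates with
  standard equilibrium lengths (k = 300 kcal/mol/Å²); peptide links are
  detected by a C–N distance below 2.0 Å between consecutive residues.
  Angles are enumerated from the bond graph with k = 50 kcal/mol/rad²
  and their *equilibrium values taken from the input conformation*: the
  minimizer's job here is to relieve clashes while preserving local
  geometry, not to idealize it, and this choice avoids shipping a large
  ideal-angle table.  Unknown residue names fail hard; the template
  library is user-extensible.

## Energies and the composite score

* van der Waals: LJ 12-6, 8.5 Å cutoff, optional per-pair soft-core
  energy cap.
* Electrostatics: Coulomb with constant relative dielectric ε = 10,
  smooth `(1-(r/rc)²)²` shift to zero at the 8.5 Å cutoff, and a flat
  plateau below 2.8 Å.  The clamp matters: with formal ±1 charges and no
  explicit hydrogens, an unclamped Coulomb term makes interpenetrating
  ion pairs arbitrarily favorable and rigid docking collapses onto them;
  2.8 Å is a genuine salt-bridge N–O contact distance, so the clamp
  removes the pathology without touching real contacts.
* Desolvation: `Σ asp_i·(SASA_complex,i − SASA_free,i)` with the free
  state being each partner in isolation at its complex coordinates;
  buried surface area (BSA) is the corresponding SASA loss.  Surface
  areas use Shrake–Rupley with a deterministic golden-spiral point set,
  960 points per atom, probe 1.4 Å (an isolated atom is exact to <1%;
  the implementation is cross-checked against an independent library in
  the tests).
* Restraints: flat-bottom quadratic on the AIR effective distance
  (below), k = 50 kcal/mol/Å², capped at 1000 kcal/mol (soft-square).

The composite score is the weighted sum
`w_vdw·E_vdw + w_elec·E_elec + w_desolv·E_desolv + w_air·E_air + w_bsa·BSA`
(lower is better) with three named profiles: `rigidbody`
(0.01, 1.0, 1.0, 0.1, −0.01), `refined` (1.0, 0.2, 1.0, 0.1, 0) and
`scoring` (1.0, 0.2, 1.0, 0, 0).  All weights are exposed per step in
the workflow configuration.

## Ambiguous interaction restraints

An AIR ties one *active* residue to the set of active+passive residues
of the partner through the effective distance

    d_eff = ( Σ_i Σ_k d_ik⁻⁶ )^(−1/6)

over all cross pairs of heavy atoms — satisfied as soon as *any* pair is
close, which is what encodes the ambiguity.  Default upper bound 2.0 Å
on d_eff.  Restraint files use a strict subset of the CNS `assign`
dialect (`segid`/`resid`/`name` conditions, `and`/`or`, three distance
numbers d, d⁻, d⁺); anything outside the subset is a parse error.
Multiple restraint files given to a sampling step become independent
restraint *sets*, distributed round-robin over the generated models; a
model's set id is recorded in its provenance and is never changed or
mixed by any later step.  Per model, a seeded random half of the
ambiguous restraints is removed at the rigid stage (fraction
configurable), reflecting that individual restraints may be wrong.

## Rigid-body sampling

Each model starts from a uniformly random ligand orientation with its
centroid at a random point on a sphere of radius R_rec + R_lig + 9 Å
around the receptor, then locally minimizes

    E = 0.01·E_vdw(softcore) + 1.0·E_elec + 0.1·E_air

over the six rigid degrees of freedom with a Nelder–Mead simplex
(≤300 energy evaluations; initial simplex steps of ~0.8 rad and 12 Å —
the default microscopic simplex cannot cross the gap to the receptor).
Two numerical points:

* during optimization the AIR term carries **no** ceiling: its quadratic
  tail is the long-range funnel that pulls the ligand onto the epitope
  (with the ceiling the landscape is flat at long range and a
  derivative-free optimizer stalls); the ceiling is restored for all
  reported energies;
* the soft-core cap is 500 kcal/mol per pair, i.e. ~5 score units after
  the 0.01 vdW weight: surface clashes are tolerated, deep
  interpenetration is unprofitable.

Models are ranked by the `rigidbody` score profile.  Every stochastic
draw is keyed to `seed + model index`, so runs are reproducible and
per-model work is order-independent.

## Refinement

Both refinement modules are restrained Cartesian L-BFGS minimizations
with analytic gradients (bonds, angles, LJ, shifted Coulomb, restraints,
tethers) — a deliberate, simplified Cartesian analogue of semiflexible
refinement protocols that anneal in torsion-angle space; pipeline
position and role are preserved, the dynamics engine is not.

* `flexref`: atoms of residues within 5 Å of the partner move freely,
  all other atoms are tethered to their input positions
  (k = 10 kcal/mol/Å²).  A zero cutoff returns the input unchanged
  (infinite-tether limit); with everything interfacial it coincides with
  plain minimization.
* `emref`: unrestrained minimization of the whole complex.

Refined models are re-scored with the `refined` profile and re-ranked.

## Evaluation and clustering

* Contacts: residue pairs of different chains with any heavy-atom pair
  below 5 Å.
* fnat, L-RMSD (fit receptor backbone, measure ligand backbone), i-RMSD
  (reference interface at 10 Å, fit+measure its backbone), IL-RMSD (fit
  receptor interface backbone, measure ligand interface heavy atoms),
  DockQ = (fnat + 1/(1+(i-RMSD/1.5)²) + 1/(1+(L-RMSD/8.5)²))/3, and the
  community quality classes (high/medium/acceptable/incorrect).  Without
  a reference, models are compared to the best-scored model.
* FCC clustering: directed similarity |a∩b|/|a|, Taylor–Butina with a
  mutual-neighbor rule (both directions ≥ 0.6), minimum cluster size 4.
  The minimum size should scale with the number of models being
  clustered; the reduced-sampling recovery runs below use 2.
* RMSD clustering: average-linkage hierarchy on the pairwise
  backbone-RMSD (or IL-RMSD) matrix, cut by a distance threshold or a
  cluster count (exactly one).
* Cluster bookkeeping: the Clustering object orders clusters by size,
  then best member score; the per-cluster evaluation table reports
  mean ± std (population) over each cluster's four best-scored members
  and additionally ranks clusters by that mean score.  Downstream, "top
  cluster" means best-scored cluster, and a cluster counts as
  acceptable when its best selected member is (best-representative
  convention).

## Analysis

`alascan` mutates every interface residue (5 Å rule) to alanine —
truncation at CB; Gly→Ala grows a CB on the N-CA-C bisector at 1.53 Å —
starting each mutant from the same wild-type coordinates, then applies a
short whole-complex minimization and reports
Δ = score(wild type) − score(mutant) per component (positive Δ = the
mutation worsens the score; hot-spot candidate).  Non-alanine targets
graft an ideal template side chain aligned on the N/CA/C frame;
mutations to proline and to ring residues (Phe/Tyr/Trp/His) are rejected
in v1 — ideal-geometry grafting without ring closure is not meaningful.
`contactmap` tabulates all residue pairs with minimal heavy-atom
distances, contact flags/frequencies (over a cluster) and residue-class
typing (charged: D/E/K/R/H; polar: S/T/N/Q/Y/W/C; apolar: the rest).

## Workflow engine

Workflows are TOML files — global parameters first (run directory, input
molecules, seed), then one section per step in execution order.  The
single dialect extension over strict TOML: module sections may repeat
(e.g. a second `[caprieval]`); repeats are normalized internally to
`name__k`.  Validation checks module names and parameters against the
registry (with nearest-name suggestions), verifies input paths, injects
defaults, and requires the first step to build topology.  Execution
creates `data/` plus one `<i>_<module>` directory per step (0-based);
each step writes its models and a `manifest.tsv` carrying name, file,
score, restraint-set id and parent model.  Manifests contain no
timestamps, so identical config + seed reruns are byte-identical.
`traceback` reconstructs every model's lineage across steps;
`report`/`analyze` writes per-step score summaries and score-vs-metric
scatter data (plus a static plot).  Only local, single-process execution
is supported.

## The synthetic test system

`make_toy_dimer` builds an antiparallel pair of ideal α-helices
(receptor: 20 residues, chain A; ligand: 10 residues, chain B) from
NeRF-grown backbones and zig-zag side chains, places them face to face,
and relaxes the complex with the package's own minimizer so side chains
pack.  Two opposite-polarity salt bridges (receptor Lys12–ligand Asp5
and receptor Glu16–ligand Lys1) pin the ligand orientation: the flipped
pose pays like-charge repulsion, so the *physics*, not the restraints,
distinguishes the native orientation.  Antiparallel is forced by
geometry — the facing surface stripes of two right-handed helices only
run in register that way.

Ground truth is measured on the relaxed reference: the true epitope is
the receptor-side 5 Å interface; the *core* epitope (used as the active
residues of the true restraint set) is its subset whose AIR effective
distance at the bound pose is within 0.5 Å of the 2 Å bound — at this
system size a fringe interface residue contributes too few atom pairs
for its effective distance ever to reach the bound, and restraining on
it would make the ground-truth pose violate its own restraints.  Two
decoy epitopes are defined geometrically on receptor faces rotated 150°
and 250° from the true face, disjoint from the true epitope; matching
wrong-epitope poses share no contact with the reference (fnat = 0).
`make_decoys` produces controlled-quality decoys by rescaling seeded
rigid ligand perturbations until the ligand RMSD is within 10% of a
target.

What the toy does *not* emulate: real protein folds and packing
(idealized helices, zig-zag side chains), conformational change on
binding (the unbound partners are the bound conformers), hydrogens and
protonation states, solvent, and sequence/structure variety.  Passing
recovery tests therefore demonstrates that the machinery — restraint
funnels, scoring, clustering, bookkeeping — behaves as designed at small
scale, not that the force field would rank models correctly on real
complexes.  One toy-specific caveat: the receptor helix is nearly
cylindrical, so *global* backbone RMSD between poses on different faces
is compressed by its rotational pseudo-symmetry; constructions that need
well-separated families break the symmetry with an axial shift.

## Problem sizes and reproducibility

The default workflow on the toy uses the stock sizes — 1000 rigid-body
models, 200 kept after selection, FCC clustering, 4 models per cluster —
with refinement shortened to 20 L-BFGS iterations.  The repeated
recovery experiments (5 seeds) use 120 rigid models / 40 selected for
single-restraint-set runs and 360 / 60 for three-set runs (the same
per-set sampling density), 30 refinement iterations, and FCC minimum
cluster size 2, matching the smaller model counts.  With these sizes the
complete acceptance computation runs in roughly a quarter hour on one
CPU.  All randomness flows from one integer seed: toy construction,
restraint removal, rigid starts and the engine manifests are bitwise
reproducible for a fixed seed.

## Known limitations

* Two-body docking only; the rigid stage uses the first conformer of
  each input ensemble.
* No explicit-solvent or torsion-angle dynamics; refinement is Cartesian
  minimization.
* Heavy-atom force field with formal charges; no pKa/protonation logic,
  no disulfide patches, amino acids only (templates are extensible).
* Score discrimination on the toy is weak near the acceptable threshold
  — at a few hundred atoms the energy differences between adjacent
  clusters are of the order of their noise, hence recovery criteria are
  statistical (4 of 5 seeds) rather than per-run.
* `alascan` scans the best-scored model only; mutations to proline and
  ring residues are unsupported.
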