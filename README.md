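# airdock

Modular, information-driven protein–protein docking at desk scale.

`airdock` is for structural biologists and method developers who want a
small, fully inspectable docking platform: a workflow engine that chains
independent modules — topology generation, restraint-driven rigid-body
sampling, Cartesian refinement, composite physics-based scoring, model
clustering, CAPRI-style evaluation and interface analysis — driven by a
single TOML configuration file.  Experimental or predicted knowledge of
the interface enters as **ambiguous interaction restraints (AIRs)**:
distance restraints from an *active* residue of one partner to the whole
set of candidate residues of the other, evaluated through the effective
distance

    d_eff = ( Σᵢ Σₖ d_ik⁻⁶ )^(−1/6)

so that any one contact can satisfy the restraint.  Several independent
restraint sets (e.g. alternative epitopes) can be sampled in one run;
each model remembers which set produced it at every later stage.

Models are scored with a weighted sum of intermolecular van der Waals,
electrostatic and desolvation energies, the restraint-violation energy
and buried surface area,

    score = w_vdw·E_vdw + w_elec·E_elec + w_desolv·E_desolv
          + w_air·E_air + w_bsa·BSA        (lower is better),

clustered by fraction of common contacts (FCC) or pairwise RMSD, and
judged against a reference with fnat, L-RMSD, i-RMSD, IL-RMSD, DockQ and
the CAPRI quality classes.  A synthetic-fixture module generates toy
helix dimers with known epitopes, decoys and restraint files, so the
whole pipeline is testable without downloading anything.

See `docs/methods.md` for the models, parameters and numerical choices.

## Worked example

Generate the toy complex and its restraint files, then dock:

```bash
$ airdock fixtures demo --seed 0
fixtures written to demo (true epitope: [8, 9, 11, 12, 13, 15, 16, 19])
```

`demo/` now holds `receptor.pdb` (20-residue helix, chain A),
`ligand.pdb` (10 residues, chain B), the bound `reference.pdb`, and
`.tbl` restraint files for the true epitope and two decoy epitopes.
Score the reference complex:

```bash
$ airdock score demo/reference.pdb --em-steps 50
score         -15.606
  vdw         -26.774 kcal/mol
  elec         -4.184 kcal/mol
  desolv       12.005 kcal/mol
  air           0.000 kcal/mol
  bsa           549.5 Å²
```

Tight packing (vdW −26.8) and two salt bridges (elec −4.2) outweigh the
desolvation penalty of burying polar surface: the bound pose scores
−15.6, strongly favorable.  Now run a docking workflow.  A configuration
file lists global parameters and then the steps in order — this is the
classic pipeline (rigid-body sampling → selection → semiflexible and
energy-minimization refinement → evaluation → FCC clustering → cluster
selection → cluster-based evaluation):

```toml
run_dir = "run1"
molecules = ["receptor.pdb", "ligand.pdb"]
seed = 42

[topoaa]
[rigidbody]
ambig_fname = "airs_true.tbl"   # 1000 models by default
[seletop]                        # keep the 200 best
[flexref]
ambig_fname = "airs_true.tbl"
[emref]
[caprieval]
reference_fname = "reference.pdb"
[clustfcc]
[seletopclusts]                  # top 4 models of each cluster
[caprieval]                      # again: cluster-based statistics
```

```bash
$ airdock run demo/wf.toml
run completed: demo/run1
  0_topoaa
  1_rigidbody
  ...
  8_caprieval
```

Each step writes a numbered directory with its models and a
`manifest.tsv` (model, file, score, restraint-set id, parent model).
The final `capri_clt.tsv` ranks clusters by the mean score of their four
best members; from a reduced-sampling run of the same pipeline:

```
cluster_rank  cluster_id  n  score_mean  fnat_mean  irmsd_mean  dockq_mean
1             4           2  -15.41      0.06       3.57        0.23
2             5           2  -13.80      0.17       2.62        0.33
3             2           4  -12.30      0.14       4.34        0.23
```

The top-ranked clusters sit at interface RMSDs of 2.6–4.3 Å with DockQ
up to 0.33 — acceptable-quality poses on the restrained epitope.  Other
tools:

```bash
airdock cfg rigidbody          # parameter names, defaults, descriptions
airdock restraints --active-a A:12,A:16 --passive-b B:1,B:5 --out my.tbl
airdock traceback demo/run1    # lineage of every model across steps
airdock analyze demo/run1      # summary tables + score-vs-RMSD plot
```

Giving `ambig_fname` a *list* of `.tbl` files samples several restraint
sets in one run (round-robin over models); the per-model set id is
propagated to every table, so the final clusters reveal which epitope
hypothesis the scoring supports.

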