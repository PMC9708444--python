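# protqa

Single-model protein structure quality assessment: given one predicted
model structure (a "decoy") and nothing else — no other decoys, no known
homologous structure — estimate how close it is to the (unknown) native
structure on the GDT-TS scale, and rank whole decoy sets by that estimate.

This is the estimation-of-model-accuracy (EMA) problem from the CASP
community. `protqa` implements a pure single-model scorer: 19
sequence/structure features are extracted from the model alone and fed to
a small multi-layer perceptron that regresses the model's GDT-TS against
its native.

## The method

**Accuracy scale.** GDT-TS(model, reference) is the mean over distance
cutoffs c ∈ {1, 2, 4, 8} Å of the maximal fraction of model CA atoms that
some rigid-body superposition places within c Å of their paired reference
CA atoms (here on a [0, 1] scale). The maximisation uses an LGA-style
deterministic heuristic: superpositions seeded from contiguous sequence
windows of lengths {3, 5, 7, ⌈N/2⌉, N} and refined by alternating inlier
selection with Kabsch re-superposition. A reference scored against itself
gives exactly 1.0.

**Features** (19, fixed order). Eleven statistical-preference features:
mean log-odds ln P(b | ctx)/P(b) of each residue's (φ, ψ) bin (20°×20°)
and of its relative-solvent-accessibility class (buried / intermediate /
exposed, Shrake–Rupley SASA over Gly-X-Gly maxima), each conditioned on
amino-acid type, secondary-structure class (Kabsch–Sander style H/E/C) and
their combination; modal-class fractions; a sequence-to-secondary-structure
fitness score; and the average of the ten. Five stereochemistry features:
rotamer outlier and favored fractions (χ bins at 120°), % Cα virtual-geometry
outliers, steric clash score per 100 residues, and a MolProbity-style
composite. Three G-factors: dihedral normality, covalent-geometry normality
(mean −z²/2 against ideal bond lengths/angles), and their mean.

**Regressor.** An MLP with 5 fully connected hidden layers of 100 neurons,
logistic-sigmoid activation and Adam optimisation (≤ 500 iterations),
trained on min-max-scaled features with targets in [0, 1]; experimental
reference structures enter training with target 1.0. Training is
deterministic given the seed; cross-validation is grouped by protein target
so decoys of one target never straddle a fold.

**Evaluation.** Per-target Pearson r and Spearman ρ between predicted and
observed GDT-TS, absolute loss d = |GDT_pred − GDT_obs| of the top-ranked
model, and GDT-TS loss g = observed quality forfeited by not picking the
truly best decoy; aggregated as unweighted mean ± sd over targets, with a
two-sample Kolmogorov–Smirnov test for method comparison.

**Synthetic benchmark.** Because real decoy archives are large, a generator
builds ideal native backbones from torsion angles (mixed helix/strand/coil
topologies), perturbs them — by default in dihedral space, which preserves
the near-ideal covalent geometry of real predicted models — at noise levels
spanning GDT-TS from ~1.0 down to < 0.3, and labels every decoy by actually
computing its GDT-TS against the native.

## Worked example

Run the whole pipeline (generate decoys → learn preference tables →
extract features → train → evaluate held-out targets) at the small
built-in scale:

```bash
protqa run --quick --seed 2 --out quickrun
```

prints the held-out aggregates (8 targets, 20 decoys each; 5 training /
3 evaluation targets):

```json
{
  "pearson_r":     {"mean": 0.9726, "sd": 0.0138},
  "spearman_rho":  {"mean": 0.9460, "sd": 0.0247},
  "absolute_loss": {"mean": 0.1509, "sd": 0.0974},
  "gdt_loss":      {"mean": 0.0318, "sd": 0.0324}
}
```

Reading: on the held-out targets the predicted scores rank the decoys
almost perfectly (ρ ≈ 0.95), and the decoy the method ranks first is on
average within 0.03 GDT-TS of the best decoy available (g). The artifacts
(manifest, preference tables, feature TSV, trained model, per-target
report) land in `quickrun/`.

Individual stages are available as subcommands (`gen-decoys`,
`build-tables`, `extract-features`, `gdt`, `train`, `score`, `evaluate`,
`compare`); `protqa gdt --model m.pdb --reference native.pdb` scores one
model against a reference. `build-tables --pdb-dir` accepts any directory
of PDB files (e.g. a PISCES cull) to learn preference tables from real
structures.

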