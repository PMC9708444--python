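# Methods

This note records the models, numerical choices and limitations behind
`protqa`, at the level of detail a maintainer or reviewer needs.

## Structure model and geometry

Structures are chain → residue → atom hierarchies of the 20 standard
amino acids, heavy atoms only (hydrogens are dropped on input; clash radii
are implicit-hydrogen values). Parsing uses gemmi; policies on top of it:
ATOM records only, alternate locations resolved to the highest-occupancy
conformer (ties by altloc letter), first MODEL unless another is
requested, residues missing N/CA/C flagged incomplete but kept. Internal
residue indexing is 0-based and contiguous per chain; author numbering is
carried as metadata only, which decouples the math from PDB numbering
gaps. A peptide bond with C–N distance > 2.5 Å is treated as a chain
break: torsions across it are undefined and its covalent terms are not
scored.

Torsions use the IUPAC sign convention (cis = 0°, trans = 180°); the
implementation is the standard atan2 form, cross-checked in tests against
an independent rotate-to-canonical-frame oracle at 1e-9°.
Superposition is closed-form Kabsch via SVD with the reflection branch
excluded; tests verify minimality against 10,000 random rotations.

## GDT-TS

GDT-TS is CA-only, cutoffs {1, 2, 4, 8} Å, score = mean over cutoffs of
the maximal in-cutoff fraction. The exact maximisation is intractable, so
the search is a deterministic LGA-style heuristic: seeds from all
contiguous windows of lengths {3, 5, 7, ⌈N/2⌉, N} (full length first, so
self-comparisons terminate immediately at 1.0), each refined by iterating
(superpose on inliers → recompute inliers) to a fixed point, ≤ 20
iterations, best fraction kept. Fractions are made monotone in the cutoff
by a running maximum over ascending cutoffs (a transform feasible at a
small cutoff is feasible at a larger one). Determinism makes every score
bit-reproducible. Model/reference residues pair positionally for
identical sequences, otherwise by longest exact-match sequence blocks;
no alignment dependency is pulled in because decoys share the target
sequence.

The heuristic can only improve on a single global superposition and on
single-fit window seeds; both bounds are asserted in tests. Scores are
therefore comparable to, but not guaranteed bit-identical with, other GDT
implementations.

## Features

The descriptor has 19 components in a fixed order (see
`features.FEATURE_NAMES`). Undefined components (e.g. rotamer fractions
of a poly-glycine chain) are encoded 0 with a validity flag, keeping the
vector width fixed for the regressor.

**Preference tables.** Counts of 20°×20° (φ, ψ) bins and of three
relative-accessibility classes (buried < 0.1, intermediate 0.1–0.4,
exposed > 0.4 of the Gly-X-Gly theoretical maximum) are accumulated per
amino acid, per secondary-structure class and per (aa, ss) pair over a
reference set, then scored as log-odds against the context-free
background. Conditional distributions use a Dirichlet prior centred on
the background with total mass `pseudocount × n_cells` (default
pseudocount 1.0). The centring matters: with a uniform prior and a small
reference set, the conditionals shrink towards uniform while the
background does not, which inverts the sign of the log-odds for
on-distribution structures; centring on the background makes sparse
contexts shrink towards log-odds 0 instead. By default tables are learned
from the package's own synthetic natives so the whole pipeline runs
without downloads; any PDB directory (e.g. a PISCES cull) can be
substituted.

**Secondary structure** is a reduced Kabsch–Sander assignment: amide H
rebuilt 1.0 Å from N anti-parallel to the preceding carbonyl, H-bond
energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol,
accepted below −0.5; consecutive i→i+4 turns give H, bridge patterns
(including inter-chain) give E, else C. Pi/3-10 helices, bends and turns
are not distinguished — they land in C — so helix/strand contents are
slightly conservative relative to full DSSP.

**SASA** is Shrake–Rupley with a deterministic golden-spiral lattice
(960 points, probe 1.4 Å; radii C 1.70, N 1.55, O 1.52, S 1.80 Å).
Because the point lattice is fixed in space, raw output depends weakly on
molecular orientation; coordinates are first expressed in a deterministic
principal-axes frame (axis signs fixed by the third moment of the
projections), which makes every feature rigid-motion invariant to
numerical precision. Exactly symmetric structures could defeat the sign
rule; real chains never are.

**Stereochemistry.** A clash is a non-bonded atom pair (> 3 covalent
bonds apart; bonds inferred geometrically but only within a residue or
between sequence-adjacent residues) overlapping by more than 0.4 Å;
the score is clashes per 100 residues, with a per-1000-atoms switch for
MolProbity-style comparability. Rotamer χ angles are binned at 120°
(g+/t/g−); a residue is favored at reference frequency ≥ 2 %, an outlier
below 0.5 %, with prefix-marginalisation so truncated side chains score
consistently. Cα geometry flags interior residues with CA–CA distance
outside [3.6, 4.0] Å (cis-proline window [2.8, 3.2]) or virtual angle
outside [75°, 150°]. The composite combines clash, rotamer-outlier and
Ramachandran-favored terms through the published MolProbity-style log
formula. G-factors score dihedral-bin log-odds (plus χ-bin log-odds
against a uniform background) and covalent z-values against ideal
geometry (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; angles 111.2°,
116.2°, 121.7°; σ 0.02 Å / 2.0°) as the pooled mean of −z²/2.

The field's tools name these features but their exact functional forms
differ between implementations; the forms above are this package's
concrete, documented choices, each preserving what the feature measures.
The averaged preference feature (f11) is the plain arithmetic mean of
f01–f10, an exact identity asserted in tests.

## Regressor

`sklearn.neural_network.MLPRegressor` with hidden layers (100,)×5,
logistic activation, Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), batch size 200,
≤ 500 iterations, tol 1e-6, no early stopping, min-max feature scaling
fitted on training data only, predictions clipped to [0, 1]. The seed
fixes weight initialisation and batch shuffling, so training is
bit-reproducible. Cross-validation uses grouped k-fold (k = 10) by
protein target; leakage is structurally impossible and asserted.
Model archives (joblib: config, scaler, weights, feature-order hash)
refuse to load across format versions or feature reorderings.

## Synthetic data

`build_chain` places N, CA, C, O sequentially from ideal covalent
geometry (NeRF), ω fixed trans; CB is placed at the L-chirality improper
torsion C-N-CA-CB = −120°, plus a single χ1 partner atom per residue
type at a coarse modal rotamer. Natives are random helix/strand/coil
segment topologies (lengths 50–120). Decoys degrade a native at graded
noise: dihedral mode (default; Gaussian noise on φ/ψ, rebuilt with ideal
geometry — the way real predicted models are wrong), cartesian mode
(i.i.d. Gaussian atom displacement) and fragment swaps. The default
dihedral grid {1, 2, 5, 10, 20, 40}° spans observed GDT-TS from ~1.0 to
below 0.3, covering the excellent/good/poor quality bands; the cartesian
grid {0.2, 0.5, 1, 2, 4, 8} Å does the same but breaks covalent geometry,
and beyond σ ≈ 1 Å it dilates the structure enough that clash counts fall
again — one reason dihedral noise is the benchmark default. Every decoy
label is computed by the GDT module, never assumed.

What the generator does not emulate: real packing (no full side chains,
so natives carry some self-clashes in coil regions), β-sheet hydrogen-bond
registry in natives (strand torsions without pairing), sequence-structure
co-variation, and method-correlated decoy error. Passing tests therefore
demonstrate that the pipeline recovers quality signal under controlled
degradation, not benchmark parity on CASP archives; the manifest format
accepts real decoy sets unchanged for that purpose.

## Problem sizes and defaults

The end-to-end experiment defaults to 20 targets × 30 decoys with a
0.65 target-level train split — small enough to run on a laptop core in a
few minutes while leaving several hundred training rows and 7 held-out
targets; the `--quick` profile (8 × 20, lengths 50–60) is the smallest
size that still satisfies the ≥ 100-row training contract. Known-mapping
recovery tests use n = 2000 synthetic feature rows with noise sd 0.02.

## Known limitations

- Global score only; no per-residue (local) accuracy estimates.
- No mmCIF, nucleic acids, ligands or hydrogen-aware clash analysis.
- Membrane proteins are not detected or treated specially.
- Disulfide bridges are not modelled as bonds, so a genuine S–S contact
  between sequence-distant cysteines would count as a clash.
- GDT search quality (not correctness) depends on the seed-window
  scheme; pathological adversarial inputs could need more seeds.
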