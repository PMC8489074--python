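# Methods

## Problem setting

Given lncRNA nucleotide sequences, protein amino-acid sequences and a
binary interaction matrix Y (y_ij = 1 when lncRNA i is known to bind
protein j), the task is to score unobserved (i, j) cells. The package
treats this as binary classification of pair vectors
x = [PCA(lncRNA descriptor) || PCA(protein descriptor)], with balanced
negative sampling from the zero cells of Y (unobserved pairs are treated
as negatives; this is the standard, imperfect assumption of the field —
some "negatives" are simply untested).

## Sequence descriptors

**lncRNA (3,051 dims).** Sequences are uppercased, U→T, and symbols
outside {A,C,G,T} removed with a logged count so composition denominators
stay exact. Blocks, in order: raw-count z-curve (3), GC content (1),
(A+T)/(G+C) ratio (1, defined 0 for GC-free input), GC/AT skews (2, zero
denominators give 0), pseudo k-nucleotide composition for k = 1..3 (84;
each k-block is a frequency vector summing to 1), and eight gapped-pattern
families (16, 256, 64, 64, 1024, 256, 64→truncated..., see below; total
2,960). A gapped family counts patterns L·gap(g)·R with left/right k-mer
orders read from the family name; gaps run over 1..5 restricted to a
per-family gap set chosen so the emitted width equals the block's declared
constant. Two families (monoTri 64, diTri 256) have declared widths that
no (gap-set × pattern-count) product reaches; they enumerate the natural
single-gap pattern set and truncate lexicographically, logging once. The
block widths are treated as fixed external constants of the descriptor
layout; only the layout, not any biological claim, depends on them.

**Protein (9,890 dims).** Blocks in order: amino-acid/di-/tripeptide
compositions (20/400/8000); normalized Moreau–Broto, Moran and Geary
autocorrelation (240 each: 8 physicochemical scales z-scored over the 20
residues × lags 1..30; Moran/Geary are defined 0 where the sequence's
property variance vanishes); CTD over the 7 canonical groupings ×3 classes
(composition 21, transition 21, distribution 105 — per class the
normalised positions of the first/25%/50%/75%/last occurrence, absent
classes contribute zeros); conjoint triads over the 7 dipole/volume
classes (343); sequence-order coupling numbers
τ_d = Σ d(r_i, r_{i+d})² for lags 1..30 under two residue-distance
matrices (60); quasi-sequence order (per matrix: 20 composition terms and
30 weighted coupling terms, weight 0.1; 100); classic pseudo amino-acid
composition (λ = 30, weight 0.05, correlation factors from z-scored
hydrophobicity/hydrophilicity/side-chain mass; 50) and amphiphilic PseAAC
(λ = 15, alternating hydrophobicity/hydrophilicity products; 50). The λ
values are fixed by the declared block widths (20 + λ = 50 and
20 + 2λ = 50); the weights are the field's common defaults and are
exposed as arguments.

The two distance matrices are (a) a physicochemical composite — euclidean
distance over z-scored hydrophobicity, hydrophilicity and side-chain
mass, scaled by 1/√3 — and (b) the Grantham chemical distance, computed
from Grantham's composition/polarity/volume table with the published
weights and scaling (spot checks: Leu–Ile ≈ 5, Arg–Lys ≈ 26). Only the
block dimensions are externally constrained; the matrix choice is a
package decision and both matrices ship as code, not data files.

## Reduction and pair assembly

Each entity type is reduced separately by mean-centred PCA
(`PaddedPCA`). The effective rank is min(d, n−1, p); score columns beyond
it are zero-padded so the pair width is always exactly 2d regardless of
entity counts (35 proteins against d = 100 is a real case). Component
signs are canonicalised (largest-|loading| positive) for determinism.
PCA is fitted on all entities of a type — it is unsupervised and touches
no interaction labels — but `scale` and per-fold fitting are switchable
for leakage-averse runs. By default features enter PCA unscaled; the
synthetic benchmark enables `scale=True` because descriptor blocks mix
raw counts (z-curve, O(sequence length)) with frequencies (O(10⁻²)), and
unscaled PCA would measure little but the z-curve.

## Base learner

`GradientBoostedTrees` is a stage-wise additive model: f₀ = column means
of the (possibly multi-output) target, then K rounds each fitting one
CART regression tree to the current residuals (the analytic negative
gradient under squared loss) and adding it with constant shrinkage — the
squared-loss line search for the stage weight is exact, so it is folded
into the shrinkage. Trees are multi-output (vector leaves, split score =
variance reduction summed over outputs, midpoint thresholds, ≥1 sample
per leaf) and grown by scikit-learn's `DecisionTreeRegressor`; the
boosting loop, initialisation and staging are implemented here. Fits are
deterministic for a fixed `random_state` (each tree receives a derived
seed that fixes split-score tie-breaking; on continuous features ties
are measure-zero anyway). Training squared error is non-increasing per
round for shrinkage in (0, 2) — each leaf update moves the residual mean
toward zero.

## The layered model

`DeepGBDTClassifier` stacks forward mappings F_1..F_L (widths
`hidden_dims`, default (16, 16)), inverse mappings G_2..G_L, and an
L2-regularised logistic head (lbfgs, tol 1e-8, refit every epoch). The
linear head *is* the top layer of the architecture: it supplies the loss
gradient that starts target propagation, and it needs no inverse mapping.

**Initialisation.** Tree structure cannot be sampled from a prior the way
weights can, so each F_i starts as a single depth-2 tree round fitted
from o_{i−1} to Gaussian noise targets N(0, ε²I) of the layer width, and
each G_i likewise from F_i(o_{i−1}) back to o_{i−1}. With ε = 0 this
degenerates to all-zero initial representations.

**Per epoch.** (1) Top pseudo-label p = o − α·(σ(z) − y)·W — the gradient
of the *per-sample* binary cross-entropy through the head
(z = o·Wᵀ + b). The per-sample (sum) convention is deliberate: a
mean-loss convention would scale the step by 1/n and stall propagation
at realistic n. A `literal` mode instead applies a squared loss directly
between each output coordinate and the 0/1 label, so α = 1 collapses the
pseudo-label onto the label — useful as an analytic check and as the
plainest reading of the update rule. (2) Top-down, each G_i is boosted
(n_rounds × num_boost_round trees) toward reconstructing
noise-perturbed inputs (ε ~ N(0, ε²I)), then p_{i−1} = G_i(p_i). The
inverse pass necessarily precedes the forward pass within an epoch
because the forward targets p_{i−1} only exist after inverse
propagation. (3) Bottom-up, each F_i is boosted toward p_i and outputs
refresh. (4) Head refit; the epoch's global loss (mean BCE) and
per-mapping reconstruction-loss traces are logged in `history_`.

All randomness flows from one seeded generator; identical seeds give
bit-identical histories. A `diagnostic_identity` flag bypasses the tree
stack entirely, reducing the model exactly to its logistic head.

## Evaluation protocol

Negatives are resampled per repeat (not fixed once), and test folds are
scored on the balanced sample rather than on all unknown cells — the
design that matches near-balanced reported accuracies. CV1 partitions
lncRNA ids into k folds (a test pair is any sampled pair touching a
held-out lncRNA), CV2 symmetrically on proteins, CV3 partitions the
sampled pairs; fold sizes differ by ≤1 and folds exactly partition their
universe. Thresholded metrics use 0.5 on the sigmoid scores; AUC uses
the rank statistic with tie averaging, AUPR the precision–recall step
integral (scikit-learn implementations). Degenerate single-class folds
are skipped with a warning. Repeats default to 20 and are reduced for
desk-scale runs.

## Synthetic benchmark

The generator plants signal in the *sequences*: each entity draws a
latent class with probability 0.7 (else no class), class-k lncRNAs get a
12-nt class motif and class-k proteins an 8-residue motif implanted at a
random position over i.i.d. uniform background, and y_ij = 1 iff classes
match, with optional independent label flips. `class_prob` = 0.7 keeps
the positive density near 25% — the densest of the published benchmark
shapes — and, unlike all-classed entities with two classes (≥50%
density), leaves enough zero cells for balanced negative sampling.
Motif lengths are chosen long enough to be effectively unique, so a
motif-presence indicator is a perfect oracle on noise-free data; the
pipeline is required to approach it (mean CV3 AUC ≥ 0.90) from raw
sequences. What the generator does **not** emulate: realistic base/residue
composition, motif degeneracy, shared structure between classes,
entity-degree heterogeneity. Passing it shows the machinery propagates
composition signal end to end, not that real-data AUCs transfer.

The desk-scale benchmark (`evaluate_synthetic`) uses 200 lncRNAs × 20
proteins, d = 16 with standardised features, 5-fold CV, and the published
model hyperparameters. d = 16 matches the hidden width and the protein
rank bound (19 with 20 proteins); the full d = 100 would be
mostly zero padding at these entity counts.

## Numerical choices and degenerate inputs

Zero denominators in composition ratios/skews return 0 with a warning;
constant-property sequences zero the Moran/Geary statistics; sequences
too short for a gap block contribute a zero block; the full descriptors
reject sequences shorter than their binding constraint (16 nt / 32 aa)
with the constraint named. Logistic fits use tol 1e-8. Score ties in
ranking exports are broken stably by cell order.

## Known limitations

* The gapped-family definitions behind the two truncated widths are
  underdetermined; the truncation is explicit and logged but remains a
  convention.
* Autocorrelation scales, CTD groupings, distance matrices and PseAAC
  weights follow common usage; alternatives would change descriptor
  values (not dimensions) and are not swappable per call except where
  parameters are exposed.
* Training cost is dominated by first-layer tree fits and grows with
  2d × n_pairs; the full-scale configuration (d = 100, 20 repeats, five
  datasets) is supported but sized for real workstation runs, not the
  test suite.
* The inverse mappings are approximate inverses only near the data
  manifold; pseudo-labels propagated through them can drift for layers
  far from the head (with two hidden layers only one propagation step
  occurs).
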