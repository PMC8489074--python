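# lpiboost

Sequence-based prediction of lncRNA–protein interactions (LPIs) with a
multi-layer deep architecture of gradient-boosted decision trees.

Long noncoding RNAs act largely through the proteins they bind, but known
interactions cover a tiny fraction of the possible pairs and wet-lab
screening is slow. `lpiboost` ranks candidate pairs from sequence alone:
it turns every lncRNA into a 3,051-dimensional composition descriptor
(z-curve, GC content, AT/GC ratio, skews, pseudo k-nucleotide composition,
eight gapped k-mer families) and every protein into a 9,890-dimensional
descriptor (k-mer compositions up to tripeptides, three autocorrelation
statistics over eight physicochemical scales, CTD, conjoint triads,
sequence-order coupling numbers, quasi-sequence order, classic and
amphiphilic pseudo amino-acid composition), reduces each side to *d*
principal components, and classifies the concatenated 2*d*-dimensional
pair vector.

## The model

The classifier is a feed-forward stack of gradient-boosted tree layers
trained **without backpropagation**. Layer *i* holds a forward mapping
F<sub>i</sub> (a multi-output GBDT taking o<sub>i−1</sub> to
o<sub>i</sub>) and, for *i* ≥ 2, an inverse mapping G<sub>i</sub> trained
so that G<sub>i</sub>(F<sub>i</sub>(o)) ≈ o. A linear sigmoid head scores
the top representation. Training iterates target propagation:

1. the top layer's pseudo-label is its output nudged against the loss
   gradient, p = o − α ∂L/∂o (α = `target_lr`);
2. pseudo-labels are propagated downward through the inverse mappings,
   p<sub>i−1</sub> = G<sub>i</sub>(p<sub>i</sub>), each G<sub>i</sub>
   being boosted on noise-perturbed inputs (ε ~ N(0, σ²I),
   σ = `epsilon`) beforehand;
3. bottom-up, each F<sub>i</sub> runs additive boosting rounds toward its
   pseudo-label (each round fits trees to the residuals
   p<sub>i</sub> − F<sub>i</sub>(o<sub>i−1</sub>));
4. the head is refitted on the refreshed top output.

The base learner is a stage-wise GBDT with vector-leaf CART trees (split
score = variance reduction summed over outputs, midpoint thresholds,
squared loss, line search absorbed into a constant shrinkage). Defaults
follow the published architecture (input–16–16–output) and settings
(target_lr 1.0, epsilon 0.3, n_rounds 3, d 100, max_depth 5,
num_boost_round 5, n_epochs 15).

Evaluation uses balanced negative sampling (as many sampled non-edges as
known edges) under three 5-fold protocols: **CV1** holds out whole lncRNAs,
**CV2** whole proteins (both cold-start), **CV3** random pairs; metrics are
precision, recall, accuracy, F1, AUC and AUPR, averaged over repeats.

## Worked example

Because the published interaction datasets require downloads, the package
ships a generator that plants class-specific sequence motifs: class-k
lncRNAs and class-k proteins interact, everything else does not, and the
signal must survive the whole descriptor → PCA → classifier pipeline.

```python
from lpiboost import DeepGBDTClassifier, PaddedPCA, run_experiment
from lpiboost.features import nucleotide, protein
from lpiboost.synthetic import SyntheticSpec, generate_dataset

spec = SyntheticSpec(n_lncrna=60, n_protein=14,
                     lncrna_length=(80, 120), protein_length=(50, 80))
data = generate_dataset(spec, seed=0)
lnc = PaddedPCA(16, scale=True).fit_transform(
    nucleotide.feature_matrix(data.lncrnas))
prot = PaddedPCA(16, scale=True).fit_transform(
    protein.feature_matrix(data.proteins))
report = run_experiment(data.dataset, lnc, prot,
                        DeepGBDTClassifier(), mode="cv3", k=5,
                        repeats=1, seed=0)
for name, stats in report.summary().items():
    print(f"{name:>9}: {stats['mean']:.4f} +/- {stats['std']:.4f}")
```

prints

```
precision: 0.9165 +/- 0.0335
   recall: 0.9947 +/- 0.0105
 accuracy: 0.9488 +/- 0.0273
       f1: 0.9537 +/- 0.0183
      auc: 0.9868 +/- 0.0186
     aupr: 0.9894 +/- 0.0127
```

i.e. on noise-free planted-motif data the pipeline recovers the
interaction rule almost perfectly under pair-level CV; the cold-start
protocols (CV1, CV2) are measurably harder, matching the expected
difficulty ordering CV3 ≥ CV1 ≥ CV2.

A command-line interface mirrors the library
(`lpiboost simulate | featurize-lncrna | featurize-protein | reduce |
train | predict | evaluate | rank`); `lpiboost evaluate --dataset dir/
--mode cv1 --out run/` runs the whole pipeline on a directory containing
`lncrnas.fa`, `proteins.fa` and `interactions.tsv` (a two-column edge
list). Real benchmark data in those formats drops in directly.

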