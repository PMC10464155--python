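# Methods

## Model overview and assumptions

`hybridseq` classifies nucleotide sequences from their k-mer
composition.  The core assumption is compositional: class membership is
reflected in the frequencies of short substrings, not in their
positions.  The hybrid classifier adds a second assumption — that a
class may be a union of latent subgroups whose compositional signals
differ in strength or even in sign, and that those subgroups surface as
distinct *confidence levels* of a smooth probability model.  When the
second assumption fails (homogeneous classes), the method degrades
gracefully: with one cluster it is exactly a plain soft-voting ensemble,
and the silhouette selection is free to choose a small cluster count.

## Pipeline and parameters

| parameter | default | units / domain | why |
|---|---|---|---|
| `k` | 3 | substring length | trigram spectrum; 4³ = 64 features balances resolution against per-column sampling noise at gene-like lengths; 1, 2, 5, 6 supported |
| feature mode | frequency | counts or frequency | sequences have unequal lengths; rows sum to one |
| canonical collapsing | off | — | strand-specific input assumed; collapsing to 32 classes available |
| min-max target | [0, 1] | — | training-set min/max per feature; test values are *not* clipped, so covariate shift remains visible; constant features map to 0 |
| discriminant projection | on (pipeline), off (recovery studies) | ≤ classes − 1 components | see "LDA and subgroup structure" |
| `probability_regularization` (C) | 0.01 | inverse L2 strength | see "The probability model must not saturate" |
| `cluster_range` | (2, 8) | K-means k | silhouette argmax, ties to smaller k; [1, 1] disables clustering |
| `min_cluster_size` | 5 | samples | smaller clusters are folded into the nearest centroid so per-cluster learners remain fittable |
| `combination` | RF, LR, KNN, MLP | subsets of {SVM, RF, LR, KNN, MLP} | the best-performing four-learner combination in benchmark runs |
| voting | soft | soft / hard | mean of member class-probability vectors; argmax, lowest class index on ties |
| hold-out | 60/40, unstratified | — | single shuffled partition; floor(0.6 n) to train |
| CV | 5-fold | — | shuffled folds, sizes differing by ≤ 1 |

Base-learner defaults: RBF-kernel SVM with probability outputs (C = 1),
100-tree random forest, L2 logistic regression (C = 1), k = 5 nearest
neighbours (k clamped to the cluster size), one-hidden-layer MLP
(64 units, ≤ 800 iterations).  All are overridable per learner, and the
tuning module can search them.

## The probability model must not saturate

Phase 3 clusters the per-sample class-probability vectors.  On
well-separated classes a maximum-likelihood logistic fit pushes its
weights up until nearly every sample sits at probability ≈ 0 or ≈ 1;
the confidence structure that distinguishes subgroups then collapses
into two saturated bands and clustering can only rediscover the class
split.  The phase-2 model is therefore *strongly* regularized by
default (C = 0.01): it is used as a smooth confidence map, not as a
classifier, and its job is to spread heterogeneous subgroups across
distinct probability levels.  The final class decision never comes from
this model, so the strong penalty costs nothing downstream.

## LDA and subgroup structure

The Fisher projection maximizes between-class mean separation while
*minimizing within-class scatter* — and latent subgroups are, by
definition, within-class scatter.  The projection therefore actively
suppresses the very structure phases 3–5 exploit; empirically, with the
projection enabled the silhouette selection always returns the class
count.  Consequently:

* the default end-to-end pipeline keeps the projection (it is a
  standard variance-reduction step and helps when classes are
  homogeneous), but
* all subgroup-recovery experiments (tests and the acceptance script)
  run with min-max scaling only (`lda=False` / `PreprocessConfig(lda=False)`).

A related caveat: with ~180 samples and 64 collinear features the
scatter estimate is noisy, so the projection can overfit; the
within-class scatter matrix is ridge-regularized with
`1e-6 · trace(S_w)/d` when singular, and directions are made
deterministic by forcing the first nonzero coefficient positive.
Min-max before projection is the default order; the Fisher criterion is
affine-invariant, so the order is benign and configurable.

## Synthetic study conditions

The generator emulates a curated two-class gene collection with latent
subgroups.  Defaults: 2 classes × 2 subgroups × 45 sequences of length
1000 (180 records — the scale of a curated disease-gene set), i.i.d.
bases per position from a subgroup-specific composition (an order-1
Markov chain is available).  Structure is planted along a zero-sum
class direction *u* in composition space; each subgroup's coefficient
on *u* sets how much, and with which sign, it expresses the class
signal:

* **aligned** (default): coefficients ±0.5δ and ±1.5δ — subgroups
  differ in signal *strength*, so they occupy four distinct confidence
  levels; used for cluster-recovery studies.  δ = 0.35 is the "high
  divergence" condition (accuracy saturates, subgroup count 4 is
  recovered), δ = 0 the chance condition.
* **opposing**: coefficients +1.0δ and −0.5δ — the second subgroup of
  each class carries a *sign-flipped* class signal (a partial XOR), so
  a single global fit misclassifies it while cluster routing plus local
  models resolve it; δ = 0.25 is the study condition for the
  hybrid-vs-plain comparison.

What the generator does **not** emulate: codon/ORF structure, repeats,
GC heterogeneity along a sequence, phylogenetic correlation between
records, length variation, and ambiguity codes.  Passing tests
therefore demonstrate the machinery is correct and that the hybrid
exploits planted compositional heterogeneity; they do not certify
accuracy figures on real gene collections, whose heterogeneity is
weaker and confounded.

Study sizes (10 seeds per condition, 50 for the equivalence check,
length-300 sequences there) were chosen so the full suite and the
acceptance script each run in well under a minute on a single core
while keeping binomial noise on reported rates small.

## Numerical and design choices

* Composite labels are the dense encoding of (class, cluster) pairs;
  the bridge SVM learns them jointly, so one prediction both routes a
  test sample and carries class information.  Phase 5 re-predicts the
  class within the routed cluster; a cluster containing one class
  yields a constant predictor (probability 1).
* A bridge prediction routing to a cluster absent from training falls
  back to the phase-2 probability model (cannot occur when the codec
  is built from training pairs, kept as a guard).
* Ambiguous (non-ACGT) symbols: k-mer windows containing them are
  skipped rather than expanded — unbiased over the clean portion of a
  record; a record with zero valid windows becomes an all-zero row with
  a warning, never NaN.
* Metric denominators that are 0/0 report 0 with a warning, keeping
  benchmark tables finite.
* Z and χ² degenerate inputs: equal accuracies give Z = 0; a 2×2 table
  with an empty correct/incorrect margin gives χ² = 0.
* Determinism: every fit derives its randomness from a single config
  seed (per-learner seeds are a fixed function of it); refitting with
  the same seed reproduces assignments, predictions and fitted arrays.
* The Bayesian optimizer uses a Matérn-5/2 Gaussian-process surrogate
  with a small white-noise term, expected-improvement acquisition over
  a 256-point seeded random candidate pool, and 5 space-filling initial
  draws (budget default 25).  Log-scaled domains are searched in log
  space; integers round; categoricals index.  The objective is mean
  5-fold CV accuracy.

## Known limitations

* Phase 3 sees only class-probability vectors: subgroup structure that
  is orthogonal to the probability map (invisible to the phase-2 model)
  cannot be discovered.  For binary problems the probability space is
  effectively one-dimensional, which also biases silhouette selection
  toward coarse splits when the levels are unevenly spaced.
* Silhouette-based count selection inherits silhouette's preference for
  the dominant gap; hierarchical subgroup structure may be reported at
  the class level unless confidence levels are comparably spaced.
* In-sample phase-2 probabilities (the default, matching the sequential
  construction) are optimistically biased; `out_of_fold` is available
  when leakage is a concern.
* The quoted accuracies in the worked example are specific to the
  synthetic study conditions above and should not be read as expected
  performance on real sequence collections.
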