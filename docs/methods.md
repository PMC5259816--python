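# Methods

## Problem and data model

The classifier consumes gene-level somatic point-mutation presence/absence
only: a binary matrix `A ∈ {0,1}^(m×n)` over m genes (rows) and n tumor
samples (columns), with integer class labels 1..K. MAF-like call files are
binarized by collapsing any number of records for a (gene, sample) pair to
a single 1. All variant classifications are retained by default (silent
mutations included — cohort summary totals conventionally count them); an
opt-in `class_filter` restricts to a chosen set. Blank or placeholder gene
symbols are dropped with a logged count rather than raising. Gene rows are
sorted lexicographically at load and that order defines the canonical
1-based gene index used by every downstream component; index 0 is reserved
as the padding symbol of the sparse encoding, which is why the scheme is
1-based.

## Clustered gene filtering

CGF is a greedy, frequency-first feature selector for binary data:

1. rank genes by row sum, descending; ties by ascending gene index
   (the procedure is deterministic end to end — every tie in ranking and
   selection is broken the same way);
2. walk the ranking; each still-ungrouped gene seeds a group and absorbs
   every later still-ungrouped gene with Jaccard similarity strictly
   greater than `d_CGF` (strict, as the workflow prints it);
3. groups with fewer than `n_CGF` members are discarded; each surviving
   group contributes its `n_CGF` most frequent members.

Two conventions the source workflow leaves open are fixed here:

* **All-zero genes.** Jaccard of two empty supports is defined as 0, so
  never-mutated genes neither merge with each other nor pass selection
  (they are skipped in step 3 even when `n_CGF = 1`). Treating 0/0 as
  similarity 1 would pool all junk genes into one large "qualifying"
  group.
* **Fit scope.** Inside cross-validation the subset `g_out` is fitted on
  the training partition only and applied frozen to held-out samples.
  Fitting on all columns is label-free but fold-dependent information; a
  `fit_on_all` switch exists for faithfulness experiments, and a
  poison-gene test asserts the leakage-free default.

The implementation is vectorized; a literal loop transcription of the
published workflow lives in the test suite and the two are checked for
exact agreement on hundreds of random small matrices.

## Indexed sparsity reduction

Each sample's binary vector becomes the ascending list of its 1-based
non-zero gene indices, fixed to length `n_ISR`: when the support exceeds
`n_ISR`, the genes ranking highest in the cohort-wide frequency ranking
are kept (ties by ascending index); otherwise the tail is zero-padded.
The map is exactly invertible whenever `n_NZ ≤ n_ISR` (tested on random
samples), and the output has zero padding fraction for saturated samples —
the sparsity-suppression mechanism the encoding exists for. The ranking is
fitted on training columns and frozen, like the CGF subset. ISR operates
on the full gene space, not on the CGF output: the two views are computed
separately and concatenated (binary evidence plus index evidence), never
chained, since chaining would discard the binary block.

Whether index magnitudes should be rescaled before entering the network is
not specified by the source description; raw indices of order 1e4
destabilize first-layer training, so indices are divided by m (into
[0, 1]) by default, with raw indices behind a flag.

## Network

A plain MLP: hidden layers compute `ReLU(W_l x_l + b_l)`, the output layer
emits raw logits (applying the rectifier to logits would zero negative
evidence before the softmax). The printed softmax in the source omits the
exponential in the numerator and its layer-indexing pair of equations is
circular as printed; both are implemented in the standard form. Softmax is
stabilized by max subtraction; the log loss clamps true-class
probabilities at 1e-12. Backpropagation is derived analytically
(`∂J/∂logits = P − y`, chain rule through the ReLU masks); weight decay
adds `λ·W_l` to the weight gradients only, never the biases. Gradients are
verified against central differences (relative error < 1e-5) in the
suite.

Training: mini-batch SGD, samples reshuffled each epoch under a seeded
generator, one learning rate per epoch from a log-spaced schedule
(defaults: 50 epochs, 1e-1 → 1e-4 — the point count and the epoch count
match by design), the last incomplete batch is trained, a NaN/inf loss
aborts with a diagnostic. Initialization is zero-mean Gaussian with
variance 2/fan-in (rectifier-appropriate; wide layers do not train from
unit-variance draws) and zero biases. The full trajectory is bitwise
deterministic given the seed. Full-size defaults are 4 hidden layers of
8192 units and a 12-way output.

## Evaluation protocol

Stratified k-fold assignment deals each class's shuffled samples
round-robin into k folds (per-class fold sizes differ by at most one; a
class smaller than k raises an error naming it). The reported
cross-validation accuracy is the *mean of per-fold accuracies* — not the
pooled-prediction accuracy — because the per-fold standard deviation is
what the accompanying t-test consumes. Hold-out evaluation draws a
stratified test fraction (default 10%).

The two-classifier comparison is computed in two forms. The as-printed
form divides the mean difference by `s · sqrt(2/n)` with
`s = (s₁² + s₂²)/2`, i.e. the *mean of the variances without a square
root*; on the published worked example (0.601 vs 0.527, s.d. 0.0151 and
0.0212, n = 10) it gives s = 3.387e-4 and t = 488.5. That scale is not a
standard deviation, so the statistic is not a textbook t — the library
therefore also returns the standard Student form (pooled s.d.
`sqrt((s₁²+s₂²)/2)`, here t ≈ 8.99) clearly labeled; no attempt is made
to guess which the original authors intended. Relative improvement
between two accuracies is `100·(a−b)/b`.

## Synthetic cohorts

The generator emulates the statistical shape of real somatic-mutation
cohorts: per-gene background rates drawn from a discretized power law
(heavy-tailed frequency profile; exponent 2 by default, clipped at 0.3),
disjoint per-class driver gene sets mutated at an elevated rate in their
class only, and co-mutation blocks driven by latent per-sample indicators
(giving the Jaccard grouping true clusters to find). Everything is
deterministic under one seed. It does **not** model mutational signatures,
per-sample mutation-load heterogeneity beyond the block mixture, or
epistasis, so passing tests demonstrate the machinery, not biological
validity.

Shipped presets (these **are** the study conditions of the test suite):

| preset | m | classes × samples | signal | purpose |
|---|---|---|---|---|
| `toy` | 40 | 3 × 10 | 3 drivers @ 0.9 | fast unit tests |
| `strong` | 500 | 12 × 40 | 5 drivers @ 0.8, bg mean 0.005, 4 blocks | recovery/accuracy study |
| `confounded` | 1000 | 12 × 30 | strong signal + 150 rare 3-gene blocks (rate 0.05) | preprocessing-ordering study |
| `null` | 200 | 12 × 20 | no drivers, shared background + blocks | leakage guard |
| `tcga-like` | 22,834 | 12 × 260 | ~155 expected mutations/sample | sparsity-profile emulation |

`desk_scale_params()` fixes the filtering/encoding/network settings used
with these presets: `d_CGF = 0.4`, derived a priori — with 12 balanced
classes and driver rate 0.8, two same-class drivers have expected
cohort-wide Jaccard ≈ 0.6 (0.64/0.96 within the class, diluted by
background elsewhere) while unrelated genes sit near 0, and 0.4 splits
the regimes with margin; `n_CGF = 5` (the full-size default); `n_ISR = 50`
and a 2 × 64-unit network scaling the 800/8192 full-size configuration to
the preset gene counts; the training schedule unchanged except batch 64.

## What the reduced-scale studies show — and what they do not

* On the `strong` preset the pipeline's 10-fold CV accuracy is 0.95–0.98
  over seeds and CGF recovers all planted drivers; on the `null` preset
  pooled accuracy stays inside the 99% binomial band around 1/12. These
  bound correctness, not real-data performance.
* The ordering *combined ≥ best single preprocessing ≥ raw* is a claim
  about when preprocessing helps. Experiments during development showed
  that with purely independent background noise a raw-input MLP is close
  to optimal at every gene count tried (500–20,000): independent sparse
  noise averages out, and there is nothing for filtering to remove. The
  advantage of the group-size threshold appears when the cohort contains
  *correlated, class-independent* rare patterns — which real cohorts have
  in abundance — because the raw-input network memorizes them while CGF
  discards any group smaller than `n_CGF` wholesale. The `confounded`
  preset plants exactly that structure, and there the gap is large
  (filtering beats raw by ≈ 0.25 accuracy; the acceptance test allows a
  0.02 stochastic tolerance on each inequality of the chain, medians over
  3 seeds).
* The index encoding alone is information-lossless but
  optimization-hostile at small capacity: detecting membership of a value
  in a sorted, position-jittered index list needs far more units than a
  2 × 64 network, so the ISR-only arm sits near chance at desk scale.
  Only the better single-preprocessing arm enters the ordering
  comparison, so this does not decide the property; it is reported here
  because it is a real limitation of the encoding at small network sizes.

## Numerical and degenerate-input choices

Jaccard 0/0 := 0; Pearson correlation with a zero-variance vector := 0
(logged); KNN vote ties go to the smallest class index, distance ties to
the earliest training sample; prediction ties to the smallest class; the
naïve-Bayes "prior" (per-class mean non-zero fraction) does not sum to 1
across classes and is renormalized before use (argmax-invariant), with
add-one smoothing on the Bernoulli rates to avoid log 0; an empty CGF
subset raises an error advising to lower `n_CGF` or `d_CGF` rather than
silently producing a zero-width feature block.

## Known limitations

* No convolutional layers, dropout, batch normalization, or GPU path; the
  network is intentionally the plain architecture described above.
* The SVM baseline is a thin adapter over scikit-learn's linear-kernel
  SVC; its hyperparameter grid search is out of scope.
* MAF export of a simulated cohort cannot represent samples or genes with
  zero mutations (a call file has no rows for them); round-trips are
  exact on the mutated support.
* Real-cohort accuracies depend on data this package deliberately does
  not ship; all quantitative claims here are about synthetic cohorts and
  published summary statistics.
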