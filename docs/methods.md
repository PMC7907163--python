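# Methods

This note documents the generative model behind the synthetic cohorts,
the classifier and its training protocol, the attribution/decimation
procedure, the numerical choices made where the design was open, and the
limits of what the synthetic experiments can show.

## Synthetic cohort model

Each run is a stationary zero-mean multivariate normal time series over
N ROIs (default 115, 180 volumes at TR = 2 s, i.e. one 6-minute run, so a
half-run is 90 samples), plus structured nuisance:

* a **background correlation matrix** shared by all participants: sparse
  random off-diagonal structure (density 0.10, magnitudes ~N(0, 0.25)),
  within-cluster pairs elevated by +0.35 (these pairs are trivially
  correlated by construction and are masked out of the analysis), then
  repaired to the nearest positive-semidefinite correlation matrix;
* **planted group coupling**: 40 ROI pairs whose correlation is raised by
  Δr = +0.3 for the highly-skilled group only;
* **planted condition coupling**: 40 disjoint pairs raised by Δr = +0.15
  in the word condition only. The two sets default to disjoint so the
  two heads' attribution rankings are substantially decorrelated, which
  mirrors the empirical finding that group- and lexicality-predictive
  connections barely overlap;
* **nuisance**: a random linear drift per ROI and two shared smooth
  (slow sinusoid-mixture) signals with random per-ROI loadings, all
  scaled by `nuisance_amplitude` (default 0.5). The nuisance signals are
  emitted alongside each run and regressed out, with intercept and
  trend, before connectivity is computed.

PSD repair is eigenvalue clipping at 10⁻⁶ followed by rescaling to unit
diagonal and clipping off-diagonals to ±0.99, iterated to convergence;
planted cells are preserved to within ±0.02. Every emitted covariance is
checked to satisfy smallest eigenvalue ≥ −10⁻⁸ and unit diagonal. All
sampling is driven by per-participant `SeedSequence` streams derived from
the cohort seed, so cohorts are bit-reproducible and stages never share
RNG state.

The default design: 14 + 14 participants, 4 runs per lexicality
condition; the transfer cohort has 5 + 5 new participants, 4 runs each,
the *same* group edges and deltas, and a fresh independently drawn task
edge set applied to every transfer run (its single task has no lexicality
labels; patterns carry a `transfer` marker and the metrics layer refuses
to compute lexical accuracy for them). One longitudinal timepoint is
simulated; a second would only duplicate the generative process.

**What the generator does not emulate:** event-related trial structure,
hemodynamic convolution, motion, scanner drift beyond a linear term,
participant-level idiosyncrasy (all participants of a group share one
covariance), and any nonlinear dependence beyond what a Gaussian copula
induces. Two consequences matter when interpreting test results. First,
because the data are Gaussian, XMI carries strictly less planted signal
than Pearson correlation (for a bivariate normal, MI is a deterministic
function of r, and the binned plug-in estimate at 90 samples is noisy),
so XMI-derived patterns decode worse than Pearson-derived ones here —
on real data XMI can capture nonlinear coupling the generator simply
does not produce. Second, real runs from one participant share
individual connectivity signatures that pattern-level cross-validation
can exploit; synthetic cohorts have no such signatures, making the
synthetic decoding problem *harder* at matched effect size. Passing
calibration tests therefore demonstrates correctness of the machinery,
not expected effect sizes on real data.

## Pattern generation

Residualization is exact OLS against [intercept, linear trend, nuisance
columns], with a rank check that names dependent columns. Odd-length
runs split with the first half getting ⌊T/2⌋ samples. Pearson and XMI
matrices are computed per half; XMI uses B = 8 equal-frequency (quantile)
bins at zero lag, in bits, with the binned entropy on the diagonal; a
lagged variant exists but is off by default. Degenerate (constant)
columns are hard errors, never silent fills.

Vectorization takes the strict upper triangle in row-major order
(6,555 features at N = 115). Normalization is per-pattern min–max to
[0, 1] followed by an element-wise square root, applied separately to
each method's vector (Pearson and XMI live on different scales); a
preceding z-score would be absorbed affinely by min–max and is omitted.
Per-pattern scope avoids any train/validation leakage through shared
normalization statistics. The within-cluster mask (253 pairs under the
default parcellation with cluster sizes 10,10,10,10,9,6,5,4,3,3 among
115 ROIs) is applied after vectorization, leaving 6,302 features with
their original ROI-pair identities.

## Classifier and training

Architecture and hyperparameters are fixed, not tuned: noise SD 0.05,
dropout 0.2, three ReLU hidden layers of sizes (max(16, 2⌈log₂ i⌉), ·/2,
·/2) with batch normalization between the affine map and the ReLU, ℓ1 =
5·10⁻⁴ on the first dense matrix only, two sigmoid heads with equally
weighted binary cross-entropies, SGD with ε = 0.01, momentum 0.9, batch
16, and a per-epoch inverse-time schedule ε/(1 + 0.05·epoch). 216 epochs
is a cap, not a fixed budget; early stopping monitors the validation
lexical-head loss and restores the best weights. Dense weights use
Glorot-uniform initialization. Folds are stratified jointly on
(group, lexicality) at the pattern level — every pattern is validated
exactly once — which permits one participant's other patterns in
training; a `group_by_participant` option provides leakage-free folds
for comparison. Classification threshold is 0.5, with ties mapping to
class 1. Input noise is added to the already-[0, 1] features without
re-clipping.

Three numerical decisions depart from textbook defaults and deserve
explanation:

* **Batch-normalization inference statistics** are recomputed exactly —
  per-layer activation moments over the full clean training set under
  the current weights — at the end of each epoch, rather than tracked by
  a momentum-0.99 moving average. While SGD with momentum is still
  moving the weights quickly, an EMA trails the parameters badly enough
  to distort validation losses and restored models (observed: ~7 points
  of validation accuracy on identical weights); the exact statistics are
  what batch normalization's inference mode is meant to approximate, and
  recomputing them costs one extra full-set forward pass per epoch.
* **Early-stopping patience is 48 epochs.** With the synthetic cohort's
  weak lexical effect the validation lexical loss is noisy and
  non-monotone early in training; short patience (e.g. 16) freezes
  training at transient minima around epoch ~4–20 and measurably harms
  the monitored metric itself (pooled lexical accuracy 0.63 vs 0.74, and
  group accuracy 0.78 vs 0.86, at patience 16 vs 48 under otherwise
  identical settings). Patience 48 under the 216-epoch cap keeps early
  stopping meaningful while letting optimization escape those minima.
* **`decay` is interpreted per epoch.** The per-iteration (legacy
  TensorFlow) reading collapses the learning rate within the first epoch
  (ε ≈ 0.003 after 45 minibatches) and underfits at every budget tried;
  the per-epoch inverse-time schedule is the conventional reading of a
  `decay` argument for plain SGD and trains stably.

The lexical head skips patterns labeled `transfer` (no lexical ground
truth) in its loss; the group head always trains.

## Attribution and decimation

Summed path weights are the matrix product W1·W2·W3·w_head, one signed
score per (feature, head); biases and batch-normalization parameters are
excluded — path products use the dense inter-layer weights only. An
exhaustive path-enumeration oracle verifies the product on small
networks to 10⁻⁹. Per generation: train k folds, sum the *absolute*
per-fold path weights per head, mark each head's ⌈0.1·F⌉ lowest-scoring
features (ties broken by ascending index), remove the union, re-derive
the architecture from the surviving feature count, and re-randomize fold
assignments from the generation seed. The stopping threshold is anchored
to the full pre-mask feature count — ⌊0.05 × 6,555⌋ = 327 — because the
composite arithmetic (327/6,555 = 0.049) is defined against the full
set. Families are fully independent: each gets its own seed stream and
no state crosses families.

With disjoint planted effects the two heads' bottom deciles overlap
little, so ~19% of features disappear per generation and a family needs
15–16 generations to fall from 6,302 to ≤ 327 (the mathematically
possible range under the 10–20% removal band is 14–29). The realized
trainable-weight ratio between final- and first-generation models is
reported, not assumed (first-generation dense weights ≈ 164k, final
≈ 6k; ratio ≈ 0.04).

## Composite model and predictive networks

Final-generation feature sets are tallied across families; features
retained by ≥ `min_family_count` families (default 4-of-20) form the
composite set, evaluated with 10-fold cross-validation at the
architecture Eq. rule implies for its size. On scaled-down replications
the threshold is auto-tuned to yield ≈ 5% of the full feature set, since
that is the property the default threshold was chosen to achieve. Per
head, each composite feature's signed path weight is averaged across the
10 fold models and z-scored across features (average-then-normalize, the
simpler of the two orders, since the per-fold z-scores are not
independent); |z| > 1 flags highly-relevant edges. The sign assigns the
predicted class; per-class adjacency matrices hold the mean normalized
connectivity of each flagged edge over patterns of that class, with node
strength (row sums) exported for visualization. No anatomical labels
are fabricated for synthetic ROIs.

## Transfer evaluation

The "3-fold" transfer protocol is implemented as independent stratified
66% subsamples of the training patterns (they are random partitions, not
a disjoint fold cover); the held-out 34% drives early stopping. Every
model scores every transfer pattern; group metrics use the transfer
cohort's group labels, and the lexicality head is profiled as per-model
and pooled word/pseudoword proportions with a unanimity flag. Transfer
models never see transfer patterns during training (disjoint
participants, disjoint provenance).

## Problem sizes used in the test suite

The acceptance suite runs the full reference scale (115 ROIs, 14+14
participants, 6,302 features, one complete family at a 64-epoch cap) for
the structural arithmetic and decimation dynamics, and a replication
scale — 24 ROIs, 8+8 participants, 12+12 planted edges at the same
deltas, 5 families, 3 folds, 32-epoch cap — for the multi-family
composite-recovery, calibration, and transfer checks, where the logic
under test is scale-invariant and twenty full-size families would add
only runtime. Effect sizes, architecture rules and training protocol are
identical at both scales.

## Known limitations

* The synthetic generator's Gaussianity makes XMI strictly redundant
  with Pearson in distribution; cross-method non-redundancy here comes
  from estimator noise, not from nonlinear coupling.
* Pattern-level cross-validation leaks run- and participant-level
  information on real data; on synthetic cohorts (no participant
  signatures) this leakage is absent, so synthetic accuracies understate
  what the same pipeline reports on real data at matched effect size.
* d′ at ceiling depends on the 1/(2n) extreme-rate correction; values
  above ~4 are effectively "ceiling" and should not be compared finely.
* The decimation loop's generation count is sensitive to the correlation
  between the two heads' attribution rankings; designs whose group and
  condition effects share edges will decimate more slowly.
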