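# connfp — task-based functional-connectivity fingerprinting

`connfp` is a reusable implementation of a dual-task "connectivity
fingerprint" analysis for task fMRI: from ROI-level BOLD time series it
builds functional-connectivity patterns, trains multilayer feedforward
classifiers that *simultaneously* decode two attributes of each pattern —
reading-skill group (poor vs. highly-skilled reader) and lexicality (word
vs. pseudoword) — and then iteratively prunes the connectivity feature
space to isolate the small set of inter-regional connections that drive
both decisions. A synthetic-cohort generator with planted, ground-truth
connectivity effects makes every stage testable without any imaging data.

It is aimed at researchers in neuroimaging machine learning who want a
transparent, fully scripted version of this family of analyses (MVPA on
connectivity with recursive feature elimination), or a sandbox in which to
study its statistical behavior under known ground truth.

## The analysis

**Patterns.** Each 6-minute run's ROI time series (115 ROIs by default) is
residualized against intercept, linear trend and nuisance regressors,
split in half, and each half is summarized by two connectivity estimators:
the Pearson correlation r(i, j) and the cross-mutual information
XMI(i, j) (plug-in mutual information on 8 quantile bins, in bits).
The strict upper triangle — N(N−1)/2 = 6,555 values for N = 115 — is
vectorized, min–max rescaled to [0, 1] and square-root transformed; the
253 within-cluster ROI pairs are masked out, leaving 6,302 features. Each
run therefore yields 2 halves × 2 estimators = 4 labeled patterns.

**Classifier.** A dual-output multilayer perceptron: input → Gaussian
noise (SD 0.05) → dropout (0.2) → three dense ReLU layers with batch
normalization → two parallel single-unit sigmoid heads (group,
lexicality). The first hidden layer has

    h1 = max(16, 2 · ⌈log2 i⌉)

units for i input features; the deeper layers have h1/2. Training is
plain SGD (ε = 0.01, inverse-time decay 0.05/epoch, momentum 0.9, batch
16, ℓ1 = 5·10⁻⁴ on the first weight matrix), with the two heads' binary
cross-entropies equally weighted, stratified 5-fold cross-validation, and
early stopping on the validation lexical-head loss.

**Attribution and decimation.** A feature's influence on a head is its
summed path weight — the sum over all hidden-unit paths of the product of
dense weights, computed for all features at once as `W1 @ W2 @ W3 @ w_head`.
Per generation, the per-fold absolute path weights are summed and the
union of the two heads' bottom-decile features is eliminated; generations
repeat until ≤ 5% of the full feature set remains (≤ 327 of 6,555).
Twenty independent families repeat this from scratch; features retained
by ≥ 4 family finals form a *composite* model, evaluated with 10-fold
cross-validation. Composite features with |z| > 1 normalized attribution
are flagged *highly-relevant* and signed into per-class adjacency
matrices (negative → pseudoword/poor, positive → word/skilled).

**Transfer.** First-generation models trained on random 66% subsamples of
the training-task patterns are scored on a different task's patterns,
testing whether the group fingerprint persists across cognitive domains;
the lexicality head, which has no ground truth there, is profiled as
class proportions.

Performance everywhere is reported as accuracy, d′ = z(hit rate) −
z(false-alarm rate), the phi coefficient, and a 1-df chi-square against
the 50/50 chance split.

## Worked example

```python
import connfp

spec = connfp.CohortSpec(n_per_group=8, n_roi=24, runs_per_condition=4,
                         n_group_edges=12, n_condition_edges=12, seed=2)
runs, truth = connfp.generate_cohort(spec)
fmap = connfp.FeatureIndexMap.for_parcellation(spec.n_roi, spec.cluster_assignment)
patterns = connfp.build_pattern_set(runs, map_=fmap)
print(f"{patterns.n_patterns} patterns x {patterns.n_features} connectivity features")

config = connfp.TrainingConfig(k_folds=3, max_epochs=32, patience=24)
models, folds = connfp.evaluate_kfold(patterns, config, seed=5)
g = connfp.pooled_metrics(folds, connfp.GROUP_HEAD)
l = connfp.pooled_metrics(folds, connfp.LEX_HEAD)
print(f"group:      accuracy={g.accuracy:.3f}  d'={g.d_prime:.2f}  phi={g.phi:.2f}  chi2={g.chi_square:.1f}")
print(f"lexicality: accuracy={l.accuracy:.3f}  d'={l.d_prime:.2f}  phi={l.phi:.2f}  chi2={l.chi_square:.1f}")
```

Output:

```
512 patterns x 264 connectivity features
group:      accuracy=0.863  d'=2.49  phi=0.74  chi2=270.3
lexicality: accuracy=0.625  d'=0.64  phi=0.25  chi2=32.0
```

The cohort plants a Δr = 0.3 group effect on 12 ROI pairs and a weaker
Δr = 0.15 lexicality effect on 12 disjoint pairs, so the group head
decodes far better than the lexical head — the qualitative signature this
analysis exhibits on real reading data. `truth` carries the planted edge
indices, so recovery by decimation can be scored exactly
(`connfp.planted_edge_enrichment`).

## Command line

Every stage is a subcommand of the `connfp` console script:

```bash
connfp simulate  --config cohort.yaml --out cohort/ --seed 1
connfp featurize --cohort cohort/ --out patterns.h5
connfp decimate  --patterns patterns.h5 --families 20 --out families/
connfp composite --patterns patterns.h5 --families families/ --out composite/
connfp transfer  --train patterns.h5 --test transfer.h5 --out transfer/
connfp run-all   --config pipeline.yaml --out run/ --seed 1
```

Cohorts are plain TSVs with a JSON sidecar; pattern sets and models are
HDF5 containers; all metrics are JSON.

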