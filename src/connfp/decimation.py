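"""Summed-path-weight attribution and iterative feature decimation.

The influence of an input feature on a classification head is the sum over
all hidden-unit paths of the product of dense weights along the path,
computed for every feature at once as the matrix product
``W1 @ W2 @ W3 @ w_head``. Each *generation* trains a k-fold ensemble on
the currently retained features, sums the absolute path weights per head
across folds, and eliminates the union of the two heads' bottom-decile
features. A *family* iterates generations from the full (post-mask)
feature set down to at most 5% of the full pre-mask set; independent
families repeat the procedure from different seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureIndexMap, PatternSet


def _column_subset(patterns: PatternSet, retained: np.ndarray) -> PatternSet:
    """Pattern set restricted to ``retained`` feature columns; surviving
    features keep their original ROI-pair identities in the reduced map."""
    if retained.size == patterns.n_features and np.array_equal(retained, np.arange(patterns.n_features)):
        return patterns
    sub_map = FeatureIndexMap(
        pairs=patterns.index_map.pairs[retained],
        within_cluster_mask=patterns.index_map.within_cluster_mask[retained],
        roi_names=patterns.index_map.roi_names,
    )
    return PatternSet(
        features=patterns.features[:, retained],
        group=patterns.group,
        lexicality=patterns.lexicality,
        participant=patterns.participant,
        run_index=patterns.run_index,
        half=patterns.half,
        method=patterns.method,
        index_map=sub_map,
        provenance=dict(patterns.provenance),
    )
from .mlp import (
    DualHeadMLP,
    FoldResult,
    TrainingConfig,
    evaluate_kfold,
    pooled_metrics,
    GROUP_HEAD,
    LEX_HEAD,
)
from .metrics import ClassificationMetrics


def summed_path_weights(model: DualHeadMLP) -> np.ndarray:
    """(n_features, 2) signed scores: column 0 = group head, 1 = lexical.

    Biases and batch-normalization parameters are excluded: only the dense
    weight matrices between layers enter the path products. A negative
    score drives the head toward class 0 (pseudoword / poor), a positive
    one toward class 1 (word / highly-skilled).
    """
    w1, w2, w3, wg, wl = model.weight_matrices
    if w1.shape[1] != w2.shape[0] or w2.shape[1] != w3.shape[0] or w3.shape[1] != wg.shape[0]:
        raise ValueError("inconsistent layer shapes")
    m = w1 @ w2 @ w3
    return np.column_stack([(m @ wg).ravel(), (m @ wl).ravel()])


def aggregate_fold_scores(models: list[DualHeadMLP]) -> np.ndarray:
    """Sum of absolute per-fold path weights, per head: (n_features, 2)."""
    return np.sum([np.abs(summed_path_weights(m)) for m in models], axis=0)


def decimate_features(scores: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Indices (original order) surviving one decimation step.

    Per head, the ``ceil(fraction * F)`` lowest |score| features are marked
    (ties broken by ascending feature index); the union of the two marked
    sets is removed.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be (F, 2)")
    f = scores.shape[0]
    k = math.ceil(fraction * f)
    if 2 * k >= f:
        raise ValueError(
            f"cannot decimate {f} features at fraction {fraction}: the union of the "
            "two bottom sets could eliminate every feature"
        )
    doomed = np.zeros(f, dtype=bool)
    for head in (GROUP_HEAD, LEX_HEAD):
        # stable sort => ties resolved by ascending feature index
        order = np.argsort(scores[:, head], kind="stable")
        doomed[order[:k]] = True
    return np.where(~doomed)[0]


@dataclass
class GenerationResult:
    """One generation of one family."""

    generation: int
    features_in: np.ndarray  # feature indices (into the masked map) trained on
    features_out: np.ndarray  # survivors after decimation
    fold_results: list[FoldResult]
    scores: np.ndarray  # (len(features_in), 2) fold-aggregated |path weight|
    group_metrics: ClassificationMetrics
    lexical_metrics: ClassificationMetrics
    hidden_sizes: tuple[int, int, int]


@dataclass
class FamilyResult:
    """All generations of one independent decimation run."""

    family_seed: int
    generations: list[GenerationResult] = field(default_factory=list)

    @property
    def final_features(self) -> np.ndarray:
        return self.generations[-1].features_out

    @property
    def n_generations(self) -> int:
        return len(self.generations)

    def first_generation(self) -> GenerationResult:
        return self.generations[0]

    def final_generation(self) -> GenerationResult:
        return self.generations[-1]


def run_generation(
    patterns: PatternSet,
    retained: np.ndarray,
    config: TrainingConfig,
    seed: int,
    generation: int = 0,
    fraction: float = 0.1,
) -> GenerationResult:
    """Train one generation on ``retained`` features and decimate.

    The architecture is re-derived from the current feature count, so
    hidden layers shrink as the feature set shrinks.
    """
    retained = np.asarray(retained, dtype=int)
    if retained.size == 0:
        raise ValueError("no retained features")
    sub = _column_subset(patterns, retained)
    models, fold_results = evaluate_kfold(sub, config, seed)
    scores = aggregate_fold_scores(models)
    survivors_local = decimate_features(scores, fraction)
    return GenerationResult(
        generation=generation,
        features_in=retained,
        features_out=retained[survivors_local],
        fold_results=fold_results,
        scores=scores,
        group_metrics=pooled_metrics(fold_results, GROUP_HEAD),
        lexical_metrics=pooled_metrics(fold_results, LEX_HEAD),
        hidden_sizes=models[0].hidden_sizes_,
    )


def run_family(
    patterns: PatternSet,
    config: TrainingConfig,
    family_seed: int,
    stop_fraction: float = 0.05,
    full_feature_count: int | None = None,
    fraction: float = 0.1,
    max_generations: int = 40,
) -> FamilyResult:
    """Iterate generations until at most ``stop_fraction`` of the *full*
    (pre-mask) feature set remains.

    The stopping threshold is anchored to the full N(N-1)/2 pair count,
    not the post-mask count, so the retained fraction is computed against
    all functional connections (327 of 6,555 for the 115-ROI default).
    """
    if full_feature_count is None:
        n = patterns.index_map.n_roi
        full_feature_count = n * (n - 1) // 2
    threshold = math.floor(stop_fraction * full_feature_count)
    retained = np.arange(patterns.n_features)
    family = FamilyResult(family_seed=family_seed)
    gen_seeds = np.random.SeedSequence(family_seed).generate_state(max_generations) % (2**31)
    for g in range(max_generations):
        result = run_generation(patterns, retained, config, int(gen_seeds[g]), generation=g, fraction=fraction)
        family.generations.append(result)
        retained = result.features_out
        if retained.size <= threshold:
            return family
        if retained.size >= result.features_in.size:
            raise RuntimeError("decimation failed to shrink the feature set")
    raise RuntimeError(
        f"family did not reach {threshold} features within {max_generations} generations "
        f"(at {retained.size})"
    )


def run_families(
    patterns: PatternSet,
    config: TrainingConfig,
    n_families: int = 20,
    base_seed: int = 0,
    stop_fraction: float = 0.05,
    full_feature_count: int | None = None,
    fraction: float = 0.1,
) -> list[FamilyResult]:
    """Independent decimation families; family seeds derive from
    ``base_seed`` and no state is shared between families."""
    seeds = np.random.SeedSequence([base_seed, 0xFA41]).generate_state(n_families) % (2**31)
    return [
        run_family(
            patterns,
            config,
            int(seeds[k]),
            stop_fraction=stop_fraction,
            full_feature_count=full_feature_count,
            fraction=fraction,
        )
        for k in range(n_families)
    ]
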