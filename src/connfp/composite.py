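"""Composite model over reliably retained features and the class-predictive
networks it implies.

Features surviving to the final generation of each independent decimation
family are tallied; those retained by at least ``min_family_count``
families (default 4 of 20) form the composite feature set, which is
re-evaluated with 10-fold cross-validation. Per head, the mean signed path
weight of each composite feature across the 10 fold models is z-scored
across features; |z| > 1 flags *highly-relevant* connections, whose weight
sign assigns them a predicted class (negative -> pseudoword / poor,
positive -> word / highly-skilled). Per-class adjacency matrices hold, at
each flagged edge, the mean connectivity over all patterns of the
predicted class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import PatternSet
from .decimation import FamilyResult, summed_path_weights, _column_subset
from .mlp import TrainingConfig, evaluate_kfold, pooled_metrics, FoldResult, GROUP_HEAD, LEX_HEAD
from .metrics import ClassificationMetrics

CLASS_NAMES = {
    (GROUP_HEAD, 0): "poor",
    (GROUP_HEAD, 1): "skilled",
    (LEX_HEAD, 0): "pseudoword",
    (LEX_HEAD, 1): "word",
}


@dataclass(frozen=True)
class CompositeConfig:
    min_family_count: int = 4
    composite_k_folds: int = 10
    z_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.min_family_count < 1:
            raise ValueError("min_family_count must be >= 1")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


@dataclass
class RelevantEdge:
    feature_index: int  # index into the masked feature map
    roi_pair: tuple[int, int]
    head: int
    mean_weight: float
    z: float
    predicted_class: int
    class_name: str
    mean_connectivity: float = float("nan")


@dataclass
class CompositeResult:
    counts: np.ndarray  # per masked-map feature: number of families retaining it
    composite_features: np.ndarray
    fold_results: list[FoldResult]
    group_metrics: ClassificationMetrics
    lexical_metrics: ClassificationMetrics
    relevant_edges: list[RelevantEdge] = field(default_factory=list)
    class_adjacency: dict = field(default_factory=dict)
    hidden_sizes: tuple[int, int, int] | None = None


def feature_frequencies(families: list[FamilyResult], n_features: int) -> np.ndarray:
    """Count, per feature of the shared (masked) map, how many families
    retained it in their final generation."""
    if not families:
        raise ValueError("need at least one family")
    counts = np.zeros(n_features, dtype=int)
    for fam in families:
        final = fam.final_features
        if final.size and final.max() >= n_features:
            raise ValueError("family feature indices exceed the shared map")
        counts[final] += 1
    return counts


def select_composite(counts: np.ndarray, config: CompositeConfig) -> np.ndarray:
    """Features retained by >= min_family_count families, ascending order."""
    chosen = np.where(np.asarray(counts) >= config.min_family_count)[0]
    if chosen.size == 0:
        raise ValueError(
            f"no feature was retained by {config.min_family_count}+ families; lower min_family_count"
        )
    return chosen


def tune_min_family_count(
    counts: np.ndarray,
    full_feature_count: int,
    target_fraction: float = 0.05,
    n_families: int | None = None,
) -> int:
    """Smallest threshold whose selection size is closest to
    ``target_fraction`` of the full feature set (the reference analysis
    chose its threshold because it yielded ~5%)."""
    counts = np.asarray(counts)
    n_families = int(counts.max()) if n_families is None else n_families
    target = target_fraction * full_feature_count
    best_t, best_gap = 1, np.inf
    for t in range(1, n_families + 1):
        size = int((counts >= t).sum())
        if size == 0:
            break
        gap = abs(size - target)
        if gap < best_gap:
            best_t, best_gap = t, gap
    return best_t


def train_composite(
    patterns: PatternSet,
    composite_features: np.ndarray,
    training: TrainingConfig,
    config: CompositeConfig,
    seed: int = 0,
) -> tuple[list, list[FoldResult]]:
    """k-fold evaluation of the composite feature set (default 10 folds);
    hidden sizes re-derived from the composite feature count."""
    composite_features = np.asarray(composite_features, dtype=int)
    if composite_features.size == 0:
        raise ValueError("composite feature set is empty")
    sub = _column_subset(patterns, composite_features)
    cfg = TrainingConfig(**{**training.__dict__, "k_folds": config.composite_k_folds})
    return evaluate_kfold(sub, cfg, seed)


def flag_highly_relevant(
    models: list,
    composite_features: np.ndarray,
    index_map_pairs: np.ndarray,
    config: CompositeConfig,
) -> list[RelevantEdge]:
    """z-score mean signed path weights across composite features per head
    and flag |z| > threshold."""
    if not models:
        raise ValueError("need at least one composite fold model")
    signed = np.mean([summed_path_weights(m) for m in models], axis=0)  # (F_comp, 2)
    edges: list[RelevantEdge] = []
    for head in (GROUP_HEAD, LEX_HEAD):
        col = signed[:, head]
        sd = col.std(ddof=0)
        if sd == 0:
            raise ValueError("zero variance of path-weight scores; cannot normalize")
        z = (col - col.mean()) / sd
        for local, (zval, w) in enumerate(zip(z, col)):
            if abs(zval) > config.z_threshold:
                cls = 1 if w > 0 else 0
                fidx = int(composite_features[local])
                edges.append(
                    RelevantEdge(
                        feature_index=fidx,
                        roi_pair=tuple(int(v) for v in index_map_pairs[fidx]),
                        head=head,
                        mean_weight=float(w),
                        z=float(zval),
                        predicted_class=cls,
                        class_name=CLASS_NAMES[(head, cls)],
                    )
                )
    return edges


def build_class_adjacency(
    edges: list[RelevantEdge],
    patterns: PatternSet,
) -> dict[str, np.ndarray]:
    """Per-class symmetric adjacency matrices over the parcellation.

    For each flagged edge, the cell (and its mirror) holds the mean
    connectivity of that edge over all patterns belonging to the edge's
    predicted class; every other cell is zero. Also fills each edge's
    ``mean_connectivity`` in place.
    """
    n = patterns.index_map.n_roi
    adjacency = {name: np.zeros((n, n)) for name in CLASS_NAMES.values()}
    class_rows = {
        "poor": patterns.group == 0,
        "skilled": patterns.group == 1,
        "pseudoword": patterns.lexicality == 0,
        "word": patterns.lexicality == 1,
    }
    # locate each feature's column in the masked map by its ROI pair
    pair_to_col = {tuple(p): c for c, p in enumerate(map(tuple, patterns.index_map.pairs))}
    for edge in edges:
        rows = class_rows[edge.class_name]
        if not rows.any():
            raise ValueError(f"no patterns for class {edge.class_name!r}")
        col = pair_to_col[edge.roi_pair]
        mean_conn = float(patterns.features[rows, col].mean())
        edge.mean_connectivity = mean_conn
        i, j = edge.roi_pair
        adjacency[edge.class_name][i, j] = mean_conn
        adjacency[edge.class_name][j, i] = mean_conn
    return adjacency


def node_strength(adjacency: np.ndarray) -> np.ndarray:
    """Row sums, for visualization export (node diameter proxy)."""
    return adjacency.sum(axis=1)


def planted_edge_enrichment(
    composite_features: np.ndarray,
    planted_features: np.ndarray,
    n_features_total: int,
) -> tuple[float, float]:
    """(recovered fraction, hypergeometric p) of planted features in the
    composite set, against draws-without-replacement chance."""
    composite = set(int(v) for v in composite_features)
    planted = set(int(v) for v in planted_features)
    overlap = len(composite & planted)
    recovered = overlap / max(len(planted), 1)
    p = float(
        stats.hypergeom.sf(overlap - 1, n_features_total, len(planted), len(composite))
    )
    return recovered, p


def build_composite_result(
    patterns: PatternSet,
    families: list[FamilyResult],
    training: TrainingConfig,
    config: CompositeConfig | None = None,
    seed: int = 0,
) -> CompositeResult:
    """Full composite stage: tally -> select -> 10-fold evaluate -> flag
    highly-relevant edges -> class adjacency."""
    config = config or CompositeConfig()
    counts = feature_frequencies(families, patterns.n_features)
    composite = select_composite(counts, config)
    models, fold_results = train_composite(patterns, composite, training, config, seed)
    edges = flag_highly_relevant(models, composite, patterns.index_map.pairs, config)
    adjacency = build_class_adjacency(edges, patterns)
    return CompositeResult(
        counts=counts,
        composite_features=composite,
        fold_results=fold_results,
        group_metrics=pooled_metrics(fold_results, GROUP_HEAD),
        lexical_metrics=pooled_metrics(fold_results, LEX_HEAD),
        relevant_edges=edges,
        class_adjacency=adjacency,
        hidden_sizes=models[0].hidden_sizes_,
    )
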