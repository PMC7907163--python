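"""From residualized ROI run series to labeled connectivity patterns.

Each 6-minute run is residualized against nuisance regressors, split in
half, and each half is summarized by two complementary connectivity
estimators: the Pearson correlation (linear dependency) and cross-mutual
information (XMI; general, possibly nonlinear dependency). The strict
upper triangle of each ROI x ROI matrix is vectorized, min-max rescaled to
[0, 1], square-root transformed (to de-skew), and within-cluster ROI pairs
are masked out. Split-half augmentation and the two estimators multiply
each run into four training patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cohort import ROIRunSeries, within_cluster_pairs


@dataclass(frozen=True)
class FeatureIndexMap:
    """Bijection between feature indices and strictly-upper-triangle ROI
    pairs, in row-major order, plus the within-cluster mask."""

    pairs: np.ndarray  # (F, 2) int, i < j
    within_cluster_mask: np.ndarray  # (F,) bool
    roi_names: tuple[str, ...]

    @classmethod
    def for_parcellation(
        cls,
        n_roi: int,
        cluster_assignment: np.ndarray | None = None,
        roi_names: Sequence[str] | None = None,
    ) -> "FeatureIndexMap":
        iu = np.triu_indices(n_roi, k=1)
        pairs = np.column_stack(iu).astype(int)
        mask = np.zeros(len(pairs), dtype=bool)
        if cluster_assignment is not None:
            wc = set(within_cluster_pairs(np.asarray(cluster_assignment)))
            mask = np.array([(int(i), int(j)) in wc for i, j in pairs], dtype=bool)
        if roi_names is None:
            roi_names = tuple(f"ROI{k:03d}" for k in range(n_roi))
        return cls(pairs=pairs, within_cluster_mask=mask, roi_names=tuple(roi_names))

    @property
    def n_features(self) -> int:
        return len(self.pairs)

    @property
    def n_roi(self) -> int:
        return len(self.roi_names)

    def feature_index(self, i: int, j: int) -> int:
        n = self.n_roi
        if not 0 <= i < j < n:
            raise ValueError(f"({i}, {j}) is not a strict upper-triangle pair")
        return i * n - i * (i + 1) // 2 + (j - i - 1)


@dataclass(frozen=True)
class ConnectivityConfig:
    """Estimator settings for pattern generation."""

    methods: tuple[str, ...] = ("pearson", "xmi")
    xmi_bins: int = 8
    xmi_binning: str = "quantile"
    xmi_lag: int = 0

    def __post_init__(self) -> None:
        if self.xmi_bins < 2:
            raise ValueError("xmi_bins must be >= 2")
        if not self.methods:
            raise ValueError("at least one connectivity method required")
        for m in self.methods:
            if m not in ("pearson", "xmi"):
                raise ValueError(f"unknown method {m!r}")
        if self.xmi_binning not in ("quantile", "equal-width"):
            raise ValueError("xmi_binning must be 'quantile' or 'equal-width'")


@dataclass
class PatternSet:
    """Stack of connectivity patterns sharing one feature index map.

    ``lexicality`` uses 0 = pseudoword, 1 = word, -1 = transfer (no ground
    truth). ``features`` rows live in [0, 1].
    """

    features: np.ndarray  # (n_patterns, F)
    group: np.ndarray  # (n_patterns,) int
    lexicality: np.ndarray  # (n_patterns,) int
    participant: np.ndarray  # (n_patterns,) str
    run_index: np.ndarray  # (n_patterns,) int
    half: np.ndarray  # (n_patterns,) str: "first" | "second"
    method: np.ndarray  # (n_patterns,) str
    index_map: FeatureIndexMap
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.features.shape[1] != self.index_map.n_features:
            raise ValueError("feature width does not match the index map")
        if not np.isfinite(self.features).all():
            raise ValueError("patterns contain non-finite values")

    @property
    def n_patterns(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, rows: np.ndarray) -> "PatternSet":
        return PatternSet(
            features=self.features[rows],
            group=self.group[rows],
            lexicality=self.lexicality[rows],
            participant=self.participant[rows],
            run_index=self.run_index[rows],
            half=self.half[rows],
            method=self.method[rows],
            index_map=self.index_map,
            provenance=dict(self.provenance),
        )


def residualize(run: ROIRunSeries) -> ROIRunSeries:
    """OLS-residualize every ROI column against intercept, linear trend and
    the run's nuisance regressors."""
    t = run.n_timepoints
    if t < 4:
        raise ValueError("need at least 4 time points to residualize")
    trend = np.linspace(-1.0, 1.0, t)
    cols = [np.ones(t), trend]
    if run.nuisance.size:
        cols.extend(run.nuisance.T)
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name offending columns via QR diagnostics
        _, r = np.linalg.qr(design)
        bad = [k for k in range(design.shape[1]) if abs(r[k, k]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        names = ["intercept", "linear_trend"] + [f"nuisance_{q}" for q in range(design.shape[1] - 2)]
        raise ValueError(f"rank-deficient nuisance design; dependent columns: {[names[k] for k in bad]}")
    beta, *_ = np.linalg.lstsq(design, run.values, rcond=None)
    resid = run.values - design @ beta
    return ROIRunSeries(
        values=resid,
        participant_id=run.participant_id,
        group_label=run.group_label,
        condition_label=run.condition_label,
        run_index=run.run_index,
        nuisance=run.nuisance,
        timepoint=run.timepoint,
        residualized=True,
    )


def split_halves(run: ROIRunSeries) -> tuple[ROIRunSeries, ROIRunSeries]:
    """First half = rows [0, floor(T/2)); second half = the remainder."""
    t = run.n_timepoints
    if t < 8:
        raise ValueError("need at least 8 time points to split")
    cut = t // 2
    halves = []
    for rows, nuis in ((slice(0, cut), slice(0, cut)), (slice(cut, t), slice(cut, t))):
        halves.append(
            ROIRunSeries(
                values=run.values[rows],
                participant_id=run.participant_id,
                group_label=run.group_label,
                condition_label=run.condition_label,
                run_index=run.run_index,
                nuisance=run.nuisance[nuis] if run.nuisance.size else run.nuisance,
                timepoint=run.timepoint,
                residualized=run.residualized,
            )
        )
    return halves[0], halves[1]


def pearson_matrix(series: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the columns; errors on any
    zero-variance ROI."""
    x = np.asarray(series, dtype=float)
    sd = x.std(axis=0)
    dead = np.where(sd <= 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance ROI column(s): {dead.tolist()}")
    c = np.corrcoef(x, rowvar=False)
    c = np.clip((c + c.T) / 2, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def _bin_codes(x: np.ndarray, bins: int, scheme: str) -> np.ndarray:
    """Per-column integer bin codes in [0, bins)."""
    t, n = x.shape
    dead = np.where(x.max(axis=0) - x.min(axis=0) <= 0)[0]
    if dead.size:
        raise ValueError(f"degenerate column(s) {dead.tolist()}: all values tie under binning")
    if scheme == "quantile":
        # equal-frequency bins from the rank order; ties in the underlying
        # continuous data are measure-zero, but constant columns are not
        order = np.argsort(x, axis=0, kind="stable")
        ranks = np.empty_like(order)
        rows = np.arange(t)[:, None]
        np.put_along_axis(ranks, order, np.broadcast_to(rows, (t, n)), axis=0)
        codes = (ranks * bins) // t
    else:
        lo, hi = x.min(axis=0), x.max(axis=0)
        span = hi - lo
        if np.any(span <= 0):
            raise ValueError("degenerate (constant) column under equal-width binning")
        codes = np.minimum((bins * (x - lo) / span).astype(int), bins - 1)
    for col in range(n):
        if len(np.unique(codes[:, col])) < 2:
            raise ValueError(f"degenerate column {col}: all values tie under binning")
    return codes.astype(np.int64)


def xmi_matrix(series: np.ndarray, config: ConnectivityConfig | None = None) -> np.ndarray:
    """Cross-mutual information (bits) between all ROI pairs.

    Plug-in MI on binned marginals (default: 8 quantile bins, zero lag).
    The diagonal holds each column's binned entropy, which is the MI of a
    variable with itself. Joint histograms for all pairs are computed in
    one Gram-matrix product over one-hot bin indicators.
    """
    config = config or ConnectivityConfig()
    x = np.asarray(series, dtype=float)
    t, n = x.shape
    b = config.xmi_bins
    if t < b:
        raise ValueError("need at least as many time points as bins")
    lag = config.xmi_lag
    if lag:
        a_codes = _bin_codes(x[:-lag], b, config.xmi_binning)
        b_codes = _bin_codes(x[lag:], b, config.xmi_binning)
        t_eff = t - lag
    else:
        a_codes = b_codes = _bin_codes(x, b, config.xmi_binning)
        t_eff = t
    onehot_a = np.zeros((t_eff, n * b), dtype=np.float64)
    onehot_a[np.arange(t_eff)[:, None], np.arange(n)[None, :] * b + a_codes] = 1.0
    if lag:
        onehot_b = np.zeros((t_eff, n * b), dtype=np.float64)
        onehot_b[np.arange(t_eff)[:, None], np.arange(n)[None, :] * b + b_codes] = 1.0
    else:
        onehot_b = onehot_a
    joint = onehot_a.T @ onehot_b  # (n*b, n*b): co-occurrence counts
    joint = joint.reshape(n, b, n, b).transpose(0, 2, 1, 3) / t_eff  # (n, n, b, b)
    pa = joint.sum(axis=3)  # (n, n, b) marginal of the row variable
    pb = joint.sum(axis=2)  # (n, n, b) marginal of the column variable
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (pa[:, :, :, None] * pb[:, :, None, :])
        terms = np.where(joint > 0, joint * np.log2(ratio), 0.0)
    mi = terms.sum(axis=(2, 3))
    mi = np.maximum((mi + mi.T) / 2, 0.0)
    return mi


def vectorize_upper(matrix: np.ndarray, map_: FeatureIndexMap | None = None) -> tuple[np.ndarray, FeatureIndexMap]:
    """Row-major strict-upper-triangle vector of a symmetric matrix."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    if map_ is None:
        map_ = FeatureIndexMap.for_parcellation(n)
    return m[iu], map_


def matrix_from_features(features: np.ndarray, map_: FeatureIndexMap) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (diagonal set to zero)."""
    n = map_.n_roi
    m = np.zeros((n, n))
    i, j = map_.pairs[:, 0], map_.pairs[:, 1]
    m[i, j] = features
    m[j, i] = features
    return m


def rescale_and_sqrt(features: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1], then element-wise square root.

    The square root de-skews the positively-skewed connectivity values;
    both steps preserve rank order.
    """
    f = np.asarray(features, dtype=float)
    lo, hi = f.min(), f.max()
    if hi - lo <= 0:
        raise ValueError("constant feature vector: zero range")
    return np.sqrt((f - lo) / (hi - lo))


def apply_feature_mask(patterns: PatternSet, mask: np.ndarray | None = None) -> PatternSet:
    """Drop masked (within-cluster) features from the set and its map."""
    if mask is None:
        mask = patterns.index_map.within_cluster_mask
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != patterns.n_features:
        raise ValueError("mask length does not match feature count")
    keep = ~mask
    new_map = FeatureIndexMap(
        pairs=patterns.index_map.pairs[keep],
        within_cluster_mask=np.zeros(int(keep.sum()), dtype=bool),
        roi_names=patterns.index_map.roi_names,
    )
    return PatternSet(
        features=patterns.features[:, keep],
        group=patterns.group,
        lexicality=patterns.lexicality,
        participant=patterns.participant,
        run_index=patterns.run_index,
        half=patterns.half,
        method=patterns.method,
        index_map=new_map,
        provenance=dict(patterns.provenance),
    )


def build_pattern_set(
    runs: Iterable[ROIRunSeries],
    config: ConnectivityConfig | None = None,
    map_: FeatureIndexMap | None = None,
    mask_within_cluster: bool = True,
    residualize_runs: bool = True,
) -> PatternSet:
    """Full pattern-generation pipeline over a cohort's runs.

    Per run: residualize -> split halves -> {pearson, xmi} -> vectorize ->
    rescale+sqrt, then the within-cluster mask is applied across the set.
    """
    config = config or ConnectivityConfig()
    rows, groups, lexs, pids, ridx, halves, methods = [], [], [], [], [], [], []
    for run in runs:
        r = residualize(run) if (residualize_runs and not run.residualized) else run
        if map_ is None:
            map_ = FeatureIndexMap.for_parcellation(r.n_roi)
        for half_name, half_run in zip(("first", "second"), split_halves(r)):
            for method in config.methods:
                if method == "pearson":
                    mat = pearson_matrix(half_run.values)
                else:
                    mat = xmi_matrix(half_run.values, config)
                vec, _ = vectorize_upper(mat, map_)
                rows.append(rescale_and_sqrt(vec))
                groups.append(run.group_label)
                lexs.append(run.condition_label)
                pids.append(run.participant_id)
                ridx.append(run.run_index)
                halves.append(half_name)
                methods.append(method)
    if not rows:
        raise ValueError("no runs supplied")
    patterns = PatternSet(
        features=np.vstack(rows),
        group=np.array(groups, dtype=int),
        lexicality=np.array(lexs, dtype=int),
        participant=np.array(pids, dtype=object),
        run_index=np.array(ridx, dtype=int),
        half=np.array(halves, dtype=object),
        method=np.array(methods, dtype=object),
        index_map=map_,
        provenance={"methods": list(config.methods), "xmi_bins": config.xmi_bins},
    )
    if mask_within_cluster and patterns.index_map.within_cluster_mask.any():
        patterns = apply_feature_mask(patterns)
    return patterns
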