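"""Signal-detection and association metrics for binary classifier output.

All pipeline stages report performance through the same small vocabulary:
accuracy, d' (sensitivity), the phi coefficient (association between
predicted and true labels), and a one-degree-of-freedom chi-square test of
the split of correct/incorrect decisions against a 50/50 chance split.
Conventions: the positive class (word / highly-skilled) is the signal, so a
*hit* is a positive pattern called positive and a *false alarm* is a
negative pattern called positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 decision table for one classification head.

    Laid out as signal-detection counts: ``hits`` and ``misses`` partition
    the true-positive patterns, ``false_alarms`` and ``correct_rejections``
    partition the true-negative patterns.
    """

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        counts = (self.hits, self.misses, self.false_alarms, self.correct_rejections)
        if any(int(c) != c or c < 0 for c in counts):
            raise ValueError("contingency counts must be nonnegative integers")
        if sum(counts) == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.hits + self.misses + self.false_alarms + self.correct_rejections

    @property
    def n_correct(self) -> int:
        return self.hits + self.correct_rejections

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ContingencyTable":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValueError("label vectors differ in length")
        if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
            raise ValueError("labels must be binary 0/1")
        return cls(
            hits=int(np.sum((y_true == 1) & (y_pred == 1))),
            misses=int(np.sum((y_true == 1) & (y_pred == 0))),
            false_alarms=int(np.sum((y_true == 0) & (y_pred == 1))),
            correct_rejections=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


def dprime(table: ContingencyTable) -> float:
    """d' = z(hit rate) - z(false-alarm rate).

    Extreme rates (0 or 1) are replaced by 1/(2n) and 1 - 1/(2n) where n is
    the relevant margin (signal-present count for the hit rate,
    signal-absent count for the false-alarm rate), keeping d' finite at
    ceiling performance.
    """
    n_signal = table.hits + table.misses
    n_noise = table.false_alarms + table.correct_rejections
    if n_signal == 0 or n_noise == 0:
        raise ValueError("d' undefined: a signal margin is empty")

    def _rate(k: int, n: int) -> float:
        r = k / n
        if r <= 0.0:
            r = 1.0 / (2 * n)
        elif r >= 1.0:
            r = 1.0 - 1.0 / (2 * n)
        return r

    hr = _rate(table.hits, n_signal)
    far = _rate(table.false_alarms, n_noise)
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))


def phi_coefficient(table: ContingencyTable) -> float:
    """Phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).

    Equals the Pearson correlation of the two underlying binary vectors.
    Requires all four margins to be nonzero.
    """
    a, b = table.hits, table.misses
    c, d = table.false_alarms, table.correct_rejections
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("phi undefined: a table margin is zero")
    return float((a * d - b * c) / np.sqrt(np.prod([float(m) for m in margins])))


def chi_square_vs_chance(n_correct: int, n_total: int) -> tuple[float, float]:
    """1-df goodness-of-fit of the correct/incorrect split against 50/50.

    Both far-above- and far-below-chance splits yield large statistics; no
    continuity correction is applied.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    expected = n_total / 2.0
    statistic = (n_correct - expected) ** 2 / expected + ((n_total - n_correct) - expected) ** 2 / expected
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


@dataclass(frozen=True)
class ClassificationMetrics:
    """Bundle of the standard per-head metrics for one evaluation."""

    accuracy: float
    d_prime: float
    phi: float
    chi_square: float
    p_value: float
    n: int

    @classmethod
    def from_table(cls, table: ContingencyTable) -> "ClassificationMetrics":
        statistic, p = chi_square_vs_chance(table.n_correct, table.n)
        try:
            phi = phi_coefficient(table)
        except ValueError:
            phi = float("nan")
        return cls(
            accuracy=table.accuracy,
            d_prime=dprime(table),
            phi=phi,
            chi_square=statistic,
            p_value=p,
            n=table.n,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FamilySummary:
    """Mean / SD / t-based 95% CI per metric over model families, plus the
    Pearson correlation between paired group and lexical d' values."""

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    dprime_correlation: float = float("nan")
    n_families: int = 0


def summarize_families(
    group_metrics: list[ClassificationMetrics],
    lexical_metrics: list[ClassificationMetrics],
) -> FamilySummary:
    """Family-level distributional summary of per-family metrics.

    CIs are two-sided 95% intervals from the t distribution with
    ``n_families - 1`` degrees of freedom. The cross-metric correlation
    pairs each family's group d' with its lexical d'.
    """
    if len(group_metrics) != len(lexical_metrics):
        raise ValueError("group and lexical metric lists differ in length")
    n = len(group_metrics)
    if n < 2:
        raise ValueError("need at least 2 families to summarize")

    means: dict = {}
    sds: dict = {}
    ci95: dict = {}
    tcrit = stats.t.ppf(0.975, df=n - 1)
    for head, metrics in (("group", group_metrics), ("lexical", lexical_metrics)):
        for name in ("accuracy", "d_prime", "phi"):
            vals = np.array([getattr(m, name) for m in metrics], dtype=float)
            key = f"{head}_{name}"
            means[key] = float(vals.mean())
            sds[key] = float(vals.std(ddof=1))
            half = tcrit * sds[key] / np.sqrt(n)
            ci95[key] = (means[key] - half, means[key] + half)

    g = np.array([m.d_prime for m in group_metrics])
    l = np.array([m.d_prime for m in lexical_metrics])
    if np.std(g) == 0 or np.std(l) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(g, l)[0, 1])
    return FamilySummary(means=means, sds=sds, ci95=ci95, dprime_correlation=r, n_families=n)
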