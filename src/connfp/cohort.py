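"""Synthetic ROI time-series cohorts with planted connectivity effects.

Emulates the study design the downstream pipeline expects: a reading-task
cohort of poor and highly-skilled readers, each contributing several runs
per lexicality condition of multivariate BOLD-like time series over a
115-ROI parcellation, plus a smaller transfer cohort performing a different
task. Group membership and task condition perturb the inter-ROI correlation
structure on known ("planted") edge sets, so recovery of those edges by the
classifier/decimation machinery can be scored against ground truth.

The generative model per run is a stationary zero-mean multivariate normal
with a group/condition-dependent correlation matrix, plus a linear drift
and two shared low-frequency nuisance signals. Event-related structure,
hemodynamics and motion are deliberately not simulated: the analysis
operates on whole-run residualized series, for which a stationary
correlated process is the minimal sufficient emulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: condition labels
PSEUDOWORD, WORD = 0, 1
TRANSFER = -1
#: group labels
POOR, SKILLED = 0, 1

#: Cluster sizes for the default 115-ROI parcellation. The ten functional
#: clusters below contain sum(k*(k-1)/2) = 253 within-cluster ROI pairs;
#: the remaining 45 ROIs are singleton parcels contributing none.
DEFAULT_CLUSTER_SIZES = (10, 10, 10, 10, 9, 6, 5, 4, 3, 3)


def default_cluster_assignment(n_roi: int = 115) -> np.ndarray:
    """ROI -> cluster labels; cluster -1 marks singleton ROIs."""
    if n_roi < sum(DEFAULT_CLUSTER_SIZES):
        # small parcellations get proportionally shrunken clusters
        labels = np.full(n_roi, -1, dtype=int)
        k = max(2, n_roi // 8)
        n_clusters = max(1, n_roi // (2 * k))
        pos = 0
        for c in range(n_clusters):
            labels[pos : pos + k] = c
            pos += k
        return labels
    labels = np.full(n_roi, -1, dtype=int)
    pos = 0
    for c, size in enumerate(DEFAULT_CLUSTER_SIZES):
        labels[pos : pos + size] = c
        pos += size
    return labels


def within_cluster_pairs(cluster_assignment: np.ndarray) -> list[tuple[int, int]]:
    """Upper-triangle ROI pairs that share a (non-singleton) cluster."""
    labels = np.asarray(cluster_assignment)
    pairs = []
    n = len(labels)
    for i in range(n):
        if labels[i] < 0:
            continue
        for j in range(i + 1, n):
            if labels[j] == labels[i]:
                pairs.append((i, j))
    return pairs


@dataclass
class CohortSpec:
    """Design parameters for one synthetic cohort.

    Defaults mirror the reference study conditions: 14 participants per
    reading-skill group, 115 ROIs, 4 runs per lexicality condition, 180
    volumes per run at TR = 2 s (6 minutes), 40 planted group edges at
    delta r = +0.3 and 40 disjoint planted condition edges at +0.15.
    """

    n_per_group: int = 14
    n_roi: int = 115
    runs_per_condition: int = 4
    volumes_per_run: int = 180
    tr_seconds: float = 2.0
    cluster_assignment: np.ndarray | None = None
    n_group_edges: int = 40
    n_condition_edges: int = 40
    delta_group: float = 0.3
    delta_condition: float = 0.15
    group_edges: Sequence[tuple[int, int]] | None = None
    condition_edges: Sequence[tuple[int, int]] | None = None
    base_density: float = 0.10
    base_strength: float = 0.25
    nuisance_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roi < 3:
            raise ValueError("n_roi must be >= 3")
        if self.volumes_per_run < 4:
            raise ValueError("volumes_per_run must be >= 4")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.cluster_assignment is None:
            self.cluster_assignment = default_cluster_assignment(self.n_roi)
        self.cluster_assignment = np.asarray(self.cluster_assignment, dtype=int)
        if len(self.cluster_assignment) != self.n_roi:
            raise ValueError("cluster_assignment length must equal n_roi")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort, for scoring recovery."""

    group_edges: list[tuple[int, int]]
    condition_edges: list[tuple[int, int]]
    delta_group: float
    delta_condition: float
    base: np.ndarray

    def _feature_index(self, i: int, j: int, n: int) -> int:
        # row-major strictly-upper-triangle linear index
        if not (0 <= i < j < n):
            raise ValueError(f"({i}, {j}) is not an upper-triangle pair")
        return i * n - i * (i + 1) // 2 + (j - i - 1)

    def group_feature_indices(self) -> np.ndarray:
        n = self.base.shape[0]
        return np.array([self._feature_index(i, j, n) for i, j in self.group_edges], dtype=int)

    def condition_feature_indices(self) -> np.ndarray:
        n = self.base.shape[0]
        return np.array([self._feature_index(i, j, n) for i, j in self.condition_edges], dtype=int)


@dataclass
class ROIRunSeries:
    """One run's time x ROI matrix plus labels and nuisance regressors."""

    values: np.ndarray
    participant_id: str
    group_label: int
    condition_label: int
    run_index: int
    nuisance: np.ndarray
    timepoint: int = 1
    residualized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nuisance = np.asarray(self.nuisance, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a time x ROI matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries")
        if self.group_label not in (POOR, SKILLED):
            raise ValueError("group_label must be 0 or 1")
        if self.condition_label not in (PSEUDOWORD, WORD, TRANSFER):
            raise ValueError("condition_label must be 0, 1 or transfer (-1)")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_roi(self) -> int:
        return self.values.shape[1]


class GenerationError(RuntimeError):
    pass


def _nearest_psd_correlation(matrix: np.ndarray, floor: float = 1e-6, max_iter: int = 20) -> np.ndarray:
    """Repair a symmetric matrix to a positive semidefinite correlation
    matrix by eigenvalue clipping followed by unit-diagonal rescaling."""
    c = np.array(matrix, dtype=float)
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(c)
        if vals.min() >= floor / 2:
            break
        vals = np.clip(vals, floor, None)
        c = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        np.fill_diagonal(c, 1.0)
        off = ~np.eye(c.shape[0], dtype=bool)
        c[off] = np.clip(c[off], -0.99, 0.99)
        c = (c + c.T) / 2
    return c


def build_base_correlation(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Shared background correlation: sparse random off-diagonal structure
    of density ``base_density`` and magnitude ~ ``base_strength``, with
    mildly elevated within-cluster coupling, PSD-repaired."""
    n = spec.n_roi
    base = np.eye(n)
    iu = np.triu_indices(n, k=1)
    n_off = len(iu[0])
    active = rng.random(n_off) < spec.base_density
    vals = np.zeros(n_off)
    vals[active] = rng.normal(0.0, spec.base_strength, size=active.sum())
    # within-cluster pairs are trivially correlated by construction
    labels = spec.cluster_assignment
    same = (labels[iu[0]] == labels[iu[1]]) & (labels[iu[0]] >= 0)
    vals[same] += 0.35
    vals = np.clip(vals, -0.9, 0.9)
    base[iu] = vals
    base = base + base.T
    np.fill_diagonal(base, 1.0)
    return _nearest_psd_correlation(base)


def build_run_covariance(
    base: np.ndarray,
    truth: GroundTruth,
    group: int,
    condition: int,
) -> np.ndarray:
    """Correlation matrix for runs of one (group, condition) cell.

    Planted group edges gain ``delta_group`` for the skilled group; planted
    condition edges gain ``delta_condition`` for the word condition. Cells
    are clipped to [-0.99, 0.99] pre-repair and the result is repaired to
    the nearest PSD correlation matrix.
    """
    base = np.asarray(base, dtype=float)
    if base.ndim != 2 or base.shape[0] != base.shape[1]:
        raise ValueError("base must be square")
    if not np.allclose(base, base.T, atol=1e-10):
        raise ValueError("base must be symmetric")
    c = base.copy()
    changed = False
    if group == SKILLED:
        for i, j in truth.group_edges:
            c[i, j] = c[j, i] = np.clip(c[i, j] + truth.delta_group, -0.99, 0.99)
            changed = True
    if condition == WORD:
        for i, j in truth.condition_edges:
            c[i, j] = c[j, i] = np.clip(c[i, j] + truth.delta_condition, -0.99, 0.99)
            changed = True
    if not changed:
        return c
    c = _nearest_psd_correlation(c)
    if np.linalg.eigvalsh(c).min() < -1e-8:
        raise GenerationError(
            f"PSD repair failed for group={group}, condition={condition}; "
            f"edges {truth.group_edges[:3]}..."
        )
    return c


def _draw_edges(
    rng: np.random.Generator,
    n_roi: int,
    n_edges: int,
    cluster_assignment: np.ndarray,
    exclude: set[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Planted edges avoid within-cluster pairs (those are masked away
    downstream) and any excluded pairs."""
    labels = cluster_assignment
    candidates = [
        (i, j)
        for i in range(n_roi)
        for j in range(i + 1, n_roi)
        if not (labels[i] >= 0 and labels[i] == labels[j]) and (i, j) not in exclude
    ]
    if n_edges > len(candidates):
        raise ValueError("not enough eligible ROI pairs for requested edges")
    idx = rng.choice(len(candidates), size=n_edges, replace=False)
    return [candidates[k] for k in sorted(idx)]


def _nuisance_signals(rng: np.random.Generator, t: int) -> np.ndarray:
    """Two shared smooth nuisance signals (slow sinusoid mixtures with
    random phases), unit-variance columns; stand-ins for global/physio
    signals a real pipeline regresses out."""
    time = np.arange(t) / t
    sigs = []
    for _ in range(2):
        s = np.zeros(t)
        for f in (1.0, 2.0, 3.5):
            s += rng.normal(0, 1) * np.sin(2 * np.pi * (f * time + rng.random()))
        s = (s - s.mean()) / (s.std() + 1e-12)
        sigs.append(s)
    return np.column_stack(sigs)


def _sample_run(
    rng: np.random.Generator,
    chol: np.ndarray,
    t: int,
    nuisance_amplitude: float,
) -> tuple[np.ndarray, np.ndarray]:
    n = chol.shape[0]
    core = rng.standard_normal((t, n)) @ chol.T
    nuis = _nuisance_signals(rng, t)
    loadings = rng.normal(0.0, 1.0, size=(2, n))
    drift_slope = rng.normal(0.0, 1.0, size=n)
    drift = np.linspace(-1.0, 1.0, t)[:, None] * drift_slope[None, :]
    values = core + nuisance_amplitude * (nuis @ loadings + drift)
    return values, nuis


def _cell_cholesky(base: np.ndarray, truth: GroundTruth, groups: Sequence[int], conditions: Sequence[int]) -> dict:
    chols = {}
    for g in groups:
        for c in conditions:
            cov = build_run_covariance(base, truth, g, c)
            # jitter keeps Cholesky stable at the PSD boundary
            chols[(g, c)] = np.linalg.cholesky(cov + 1e-9 * np.eye(cov.shape[0]))
    return chols


def generate_cohort(spec: CohortSpec) -> tuple[list[ROIRunSeries], GroundTruth]:
    """Generate the training-task cohort and its ground truth.

    2 x n_per_group participants, runs_per_condition runs per lexicality
    condition each; deterministic given ``spec.seed``.
    """
    root = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x5EED]))
    base = build_base_correlation(spec, root)
    exclude: set[tuple[int, int]] = set()
    if spec.group_edges is not None:
        group_edges = [tuple(e) for e in spec.group_edges]
    else:
        group_edges = _draw_edges(root, spec.n_roi, spec.n_group_edges, spec.cluster_assignment, exclude)
    exclude |= set(group_edges)
    if spec.condition_edges is not None:
        condition_edges = [tuple(e) for e in spec.condition_edges]
    else:
        condition_edges = _draw_edges(root, spec.n_roi, spec.n_condition_edges, spec.cluster_assignment, exclude)
    truth = GroundTruth(
        group_edges=group_edges,
        condition_edges=condition_edges,
        delta_group=spec.delta_group,
        delta_condition=spec.delta_condition,
        base=base,
    )
    chols = _cell_cholesky(base, truth, (POOR, SKILLED), (PSEUDOWORD, WORD))

    runs: list[ROIRunSeries] = []
    for g, group in enumerate((POOR, SKILLED)):
        for p in range(spec.n_per_group):
            pid = f"sub-{'P' if group == POOR else 'S'}{p:03d}"
            prng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1, g, p]))
            run_index = 0
            for condition in (PSEUDOWORD, WORD):
                for _ in range(spec.runs_per_condition):
                    values, nuis = _sample_run(
                        prng, chols[(group, condition)], spec.volumes_per_run, spec.nuisance_amplitude
                    )
                    runs.append(
                        ROIRunSeries(
                            values=values,
                            participant_id=pid,
                            group_label=group,
                            condition_label=condition,
                            run_index=run_index,
                            nuisance=nuis,
                        )
                    )
                    run_index += 1
    return runs, truth


def generate_transfer_cohort(
    spec: CohortSpec,
    truth: GroundTruth,
    n_per_group: int = 5,
    runs_per_participant: int = 4,
    seed_offset: int = 7_777,
) -> list[ROIRunSeries]:
    """Transfer cohort: new participants sharing the training cohort's
    group edges and deltas, but whose task engages a fresh, independent
    edge set (applied identically to every run, since the transfer task has
    a single condition). Condition labels are ``TRANSFER``.
    """
    root = np.random.default_rng(np.random.SeedSequence([int(spec.seed), seed_offset]))
    exclude = set(truth.group_edges) | set(truth.condition_edges)
    task_edges = _draw_edges(root, spec.n_roi, len(truth.condition_edges), spec.cluster_assignment, exclude)
    # transfer-task coupling rides on the shared base; group edges persist
    transfer_truth = GroundTruth(
        group_edges=truth.group_edges,
        condition_edges=task_edges,
        delta_group=truth.delta_group,
        delta_condition=truth.delta_condition,
        base=truth.base,
    )
    # every transfer run carries the task edges -> use the WORD slot for them
    chols = _cell_cholesky(truth.base, transfer_truth, (POOR, SKILLED), (WORD,))

    runs: list[ROIRunSeries] = []
    for g, group in enumerate((POOR, SKILLED)):
        for p in range(n_per_group):
            pid = f"sub-T{'P' if group == POOR else 'S'}{p:03d}"
            prng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), seed_offset, 1, g, p]))
            for run_index in range(runs_per_participant):
                values, nuis = _sample_run(
                    prng, chols[(group, WORD)], spec.volumes_per_run, spec.nuisance_amplitude
                )
                runs.append(
                    ROIRunSeries(
                        values=values,
                        participant_id=pid,
                        group_label=group,
                        condition_label=TRANSFER,
                        run_index=run_index,
                        nuisance=nuis,
                    )
                )
    return runs
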