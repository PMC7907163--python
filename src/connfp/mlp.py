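"""Dual-output multilayer feedforward classifier.

One network simultaneously classifies each connectivity pattern on two
binary dimensions: reading-skill group (poor vs. highly-skilled) and
lexicality (pseudoword vs. word). Architecture: input -> Gaussian noise
(SD 0.05, training only) -> dropout (rate 0.2, training only) -> three
dense ReLU hidden layers with batch normalization -> two parallel
single-unit sigmoid heads. The first hidden layer's width is
``max(16, 2 * ceil(log2 i))`` for ``i`` input features; the second and
third are half that. An l1 penalty (0.0005) on the first dense weight
matrix promotes sparsity over input features.

Training: plain SGD with momentum 0.9, batch size 16, learning rate 0.01
under an inverse-time schedule ``lr / (1 + 0.05 * epoch)``, at most 216
epochs, early stopping on validation lexical-head loss (patience 16,
restore best). Both heads' binary cross-entropies are equally weighted.

Implemented directly on numpy; the estimator follows scikit-learn
conventions (``fit`` / ``predict`` / ``predict_proba``, ``get_params``,
fitted attributes with trailing underscores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold

from .features import PatternSet
from .metrics import ContingencyTable, ClassificationMetrics

GROUP_HEAD, LEX_HEAD = 0, 1
_BN_EPS = 1e-3
_CLIP = 1e-7


def hidden_layer_sizes(i: int) -> tuple[int, int, int]:
    """(h1, h2, h3) with h1 = max(16, 2*ceil(log2 i)) and h2 = h3 = h1/2."""
    if i < 2:
        raise ValueError("need at least 2 input features")
    h1 = max(16, 2 * math.ceil(math.log2(i)))
    return h1, h1 // 2, h1 // 2


@dataclass
class TrainingConfig:
    """Hyperparameters for one training run (defaults are the reference
    protocol; none were tuned)."""

    learning_rate: float = 0.01
    decay: float = 0.05
    momentum: float = 0.9
    batch_size: int = 16
    max_epochs: int = 216
    patience: int = 48
    k_folds: int = 5
    noise_sd: float = 0.05
    dropout_rate: float = 0.2
    l1: float = 0.0005
    group_by_participant: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "momentum"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.patience < self.max_epochs:
            raise ValueError("patience must be in (0, max_epochs)")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p.astype(np.float64), _CLIP, 1 - _CLIP)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class DualHeadMLP(BaseEstimator):
    """Dual-head MLP classifier over connectivity features.

    Parameters mirror :class:`TrainingConfig`; ``fit`` expects ``Y`` of
    shape (n, 2) with columns (group, lexicality). A lexicality label of
    -1 marks patterns without lexical ground truth; those are excluded
    from the lexical head's loss but still drive the group head.
    """

    def __init__(
        self,
        noise_sd: float = 0.05,
        dropout_rate: float = 0.2,
        l1: float = 0.0005,
        learning_rate: float = 0.01,
        decay: float = 0.05,
        momentum: float = 0.9,
        batch_size: int = 16,
        max_epochs: int = 216,
        patience: int = 48,
        random_state: int | None = None,
    ):
        self.noise_sd = noise_sd
        self.dropout_rate = dropout_rate
        self.l1 = l1
        self.learning_rate = learning_rate
        self.decay = decay
        self.momentum = momentum
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state

    # -- initialization ------------------------------------------------

    def _init_params(self, n_features: int, rng: np.random.Generator) -> dict:
        h1, h2, h3 = hidden_layer_sizes(n_features)
        self.hidden_sizes_ = (h1, h2, h3)
        sizes = [n_features, h1, h2, h3]
        params: dict[str, np.ndarray] = {}
        for layer in range(3):
            fan_in, fan_out = sizes[layer], sizes[layer + 1]
            lim = math.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            params[f"W{layer + 1}"] = rng.uniform(
                -lim, lim, size=(fan_in, fan_out)
            ).astype(np.float32)
            params[f"b{layer + 1}"] = np.zeros(fan_out, dtype=np.float32)
            params[f"gamma{layer + 1}"] = np.ones(fan_out, dtype=np.float32)
            params[f"beta{layer + 1}"] = np.zeros(fan_out, dtype=np.float32)
        limit = math.sqrt(6.0 / (h3 + 1))
        for head in ("g", "l"):
            params[f"w_{head}"] = rng.uniform(-limit, limit, size=(h3, 1)).astype(np.float32)
            params[f"b_{head}"] = np.zeros(1, dtype=np.float32)
        return params

    # -- forward passes ------------------------------------------------

    def _forward_train(self, x: np.ndarray, p: dict, rng: np.random.Generator) -> dict:
        cache: dict = {}
        if self.noise_sd > 0:
            x = x + rng.normal(0.0, self.noise_sd, size=x.shape).astype(np.float32)
        if self.dropout_rate > 0:
            keep = (rng.random(x.shape) >= self.dropout_rate).astype(np.float32)
            x = x * keep / np.float32(1.0 - self.dropout_rate)
        cache["x0"] = x
        h = x
        for layer in (1, 2, 3):
            z = h @ p[f"W{layer}"] + p[f"b{layer}"]
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv_std
            a = p[f"gamma{layer}"] * zhat + p[f"beta{layer}"]
            h = np.maximum(a, 0.0)
            cache[f"zhat{layer}"] = zhat
            cache[f"inv_std{layer}"] = inv_std
            cache[f"a{layer}"] = a
            cache[f"h{layer}"] = h
        cache["p_g"] = _sigmoid(h @ p["w_g"] + p["b_g"])
        cache["p_l"] = _sigmoid(h @ p["w_l"] + p["b_l"])
        return cache

    def _population_stats(self, X: np.ndarray, p: dict) -> dict:
        """Exact inference-time BN statistics: per-layer activation moments
        over the full (clean) training set under the current weights.
        Recomputed at each epoch end instead of tracking a moving average,
        which lags badly while the weights are still moving."""
        stats: dict = {}
        h = X
        for layer in (1, 2, 3):
            z = h @ p[f"W{layer}"] + p[f"b{layer}"]
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            stats[f"mean{layer}"] = mu
            stats[f"var{layer}"] = var
            zhat = (z - mu) / np.sqrt(var + _BN_EPS)
            h = np.maximum(p[f"gamma{layer}"] * zhat + p[f"beta{layer}"], 0.0)
        return stats

    def _forward_eval(self, x: np.ndarray, p: dict, running: dict) -> np.ndarray:
        h = x.astype(np.float32)
        for layer in (1, 2, 3):
            z = h @ p[f"W{layer}"] + p[f"b{layer}"]
            zhat = (z - running[f"mean{layer}"]) / np.sqrt(running[f"var{layer}"] + _BN_EPS)
            h = np.maximum(p[f"gamma{layer}"] * zhat + p[f"beta{layer}"], 0.0)
        pg = _sigmoid(h @ p["w_g"] + p["b_g"])
        pl = _sigmoid(h @ p["w_l"] + p["b_l"])
        return np.column_stack([pg.ravel(), pl.ravel()])

    def _batch_step(
        self,
        xb: np.ndarray,
        ygb: np.ndarray,
        ylb: np.ndarray,
        mb: np.ndarray,
        p: dict,
        rng: np.random.Generator,
    ) -> tuple[float, dict]:
        """One minibatch: forward in training mode, total loss (both
        heads' BCE + l1 on W1), and exact gradients for every parameter."""
        b = np.float32(len(xb))
        cache = self._forward_train(xb, p, rng)
        pg, pl = cache["p_g"], cache["p_l"]
        n_lex = max(float(mb.sum()), 1.0)
        loss = _bce(pg, ygb)
        if mb.any():
            pl64 = np.clip(pl.astype(np.float64), _CLIP, 1 - _CLIP)
            loss += float(-np.sum(mb * (ylb * np.log(pl64) + (1 - ylb) * np.log(1 - pl64))) / n_lex)
        loss += self.l1 * float(np.abs(p["W1"]).sum())

        grads: dict[str, np.ndarray] = {}
        dlog_g = (pg - ygb) / b
        dlog_l = mb * (pl - ylb) / np.float32(n_lex)
        h3 = cache["h3"]
        grads["w_g"] = h3.T @ dlog_g
        grads["b_g"] = dlog_g.sum(axis=0)
        grads["w_l"] = h3.T @ dlog_l
        grads["b_l"] = dlog_l.sum(axis=0)
        dh = dlog_g @ p["w_g"].T + dlog_l @ p["w_l"].T
        for layer in (3, 2, 1):
            da = dh * (cache[f"a{layer}"] > 0)
            zhat = cache[f"zhat{layer}"]
            grads[f"gamma{layer}"] = (da * zhat).sum(axis=0)
            grads[f"beta{layer}"] = da.sum(axis=0)
            dzhat = da * p[f"gamma{layer}"]
            dz = (
                cache[f"inv_std{layer}"]
                / b
                * (b * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0))
            )
            xin = cache["x0"] if layer == 1 else cache[f"h{layer - 1}"]
            grads[f"W{layer}"] = xin.T @ dz
            grads[f"b{layer}"] = dz.sum(axis=0)
            if layer > 1:
                dh = dz @ p[f"W{layer}"].T
        grads["W1"] = grads["W1"] + np.float32(self.l1) * np.sign(p["W1"])
        return loss, grads

    # -- training ------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        validation_data: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> "DualHeadMLP":
        X = np.asarray(X, dtype=np.float32)
        Y = np.asarray(Y)
        if X.ndim != 2 or Y.ndim != 2 or Y.shape[1] != 2 or len(X) != len(Y):
            raise ValueError("X must be (n, F) and Y must be (n, 2)")
        n, f = X.shape
        self.n_features_in_ = f
        rng = np.random.default_rng(self.random_state)
        p = self._init_params(f, rng)
        running = self._population_stats(X, p)
        vel = {k: np.zeros_like(v) for k, v in p.items()}

        yg = Y[:, 0].astype(np.float32)[:, None]
        yl = Y[:, 1].astype(np.float32)[:, None]
        lex_known = (Y[:, 1] >= 0).astype(np.float32)[:, None]

        best_val = np.inf
        best_epoch = -1
        best_state: tuple[dict, dict] | None = None
        wait = 0
        self.history_: dict[str, list[float]] = {"train_loss": [], "val_group_loss": [], "val_lex_loss": []}

        mom = np.float32(self.momentum)
        for epoch in range(self.max_epochs):
            lr = np.float32(self.learning_rate / (1.0 + self.decay * epoch))
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                loss, grads = self._batch_step(
                    X[idx], yg[idx], yl[idx], lex_known[idx], p, rng
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: diverged (lr={lr}, batch {n_batches})"
                    )
                epoch_loss += loss
                n_batches += 1
                for k in p:
                    vel[k] = mom * vel[k] - lr * grads[k]
                    p[k] += vel[k]

            self.history_["train_loss"].append(epoch_loss / max(n_batches, 1))
            running = self._population_stats(X, p)

            if validation_data is not None:
                xv, yv = validation_data
                proba = self._forward_eval(np.asarray(xv, dtype=np.float32), p, running)
                vg = _bce(proba[:, 0:1], np.asarray(yv)[:, 0:1].astype(float))
                lex_v = np.asarray(yv)[:, 1]
                known = lex_v >= 0
                vl = _bce(proba[known, 1:2], lex_v[known, None].astype(float)) if known.any() else vg
                self.history_["val_group_loss"].append(vg)
                self.history_["val_lex_loss"].append(vl)
                if vl < best_val - 1e-12:
                    best_val = vl
                    best_epoch = epoch
                    best_state = ({k: v.copy() for k, v in p.items()}, {k: v.copy() for k, v in running.items()})
                    wait = 0
                else:
                    wait += 1
                    if wait >= self.patience:
                        break

        if best_state is not None:
            p, running = best_state
            self.best_epoch_ = best_epoch
            self.best_val_lex_loss_ = best_val
        else:
            self.best_epoch_ = len(self.history_["train_loss"]) - 1
        self.params_ = p
        self.running_stats_ = running
        self.n_epochs_ = len(self.history_["train_loss"])
        return self

    # -- inference -----------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) head probabilities (group, lexicality); deterministic
        inference mode (no noise/dropout, running BN statistics)."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
            )
        return self._forward_eval(X, self.params_, self.running_stats_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard labels; probability >= 0.5 maps to class 1."""
        return (self.predict_proba(X) >= 0.5).astype(int)

    @property
    def weight_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(W1, W2, W3, w_group, w_lex) as float64 arrays."""
        p = self.params_
        return (
            p["W1"].astype(np.float64),
            p["W2"].astype(np.float64),
            p["W3"].astype(np.float64),
            p["w_g"].astype(np.float64),
            p["w_l"].astype(np.float64),
        )


@dataclass
class FoldResult:
    """Validation-set output of one cross-validation fold."""

    fold_index: int
    val_indices: np.ndarray
    proba: np.ndarray  # (n_val, 2)
    group_true: np.ndarray
    lex_true: np.ndarray
    epochs_trained: int
    final_losses: dict = field(default_factory=dict)

    def table(self, head: int) -> ContingencyTable:
        true = self.group_true if head == GROUP_HEAD else self.lex_true
        if head == LEX_HEAD and (true < 0).any():
            raise ValueError("lexicality ground truth unavailable for transfer patterns")
        pred = (self.proba[:, head] >= 0.5).astype(int)
        return ContingencyTable.from_predictions(true, pred)


def stratified_kfold(
    patterns: PatternSet,
    k: int,
    seed: int,
    group_by_participant: bool = False,
) -> list[np.ndarray]:
    """Validation-index arrays of a k-fold partition stratified jointly on
    (group, lexicality). Every pattern is validated exactly once. With
    ``group_by_participant`` a participant's patterns never straddle the
    train/validation boundary (leakage-free variant)."""
    strata = patterns.group * 2 + np.maximum(patterns.lexicality, 0)
    counts = np.bincount(strata)
    if (counts[counts > 0] < k).any():
        raise ValueError(f"a (group, lexicality) stratum has fewer than k={k} patterns")
    x_dummy = np.zeros((patterns.n_patterns, 1))
    if group_by_participant:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
        splits = splitter.split(x_dummy, strata, groups=patterns.participant)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
        splits = splitter.split(x_dummy, strata)
    return [val for _, val in splits]


def train_fold(
    patterns: PatternSet,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: TrainingConfig,
    fold_index: int = 0,
    seed: int | None = None,
) -> tuple[DualHeadMLP, FoldResult]:
    """Train one fold's model and score its withheld validation patterns."""
    Y = np.column_stack([patterns.group, patterns.lexicality])
    ytr = Y[train_idx]
    if len(np.unique(ytr[:, 0])) < 2:
        raise ValueError("training labels degenerate for the group head")
    model = DualHeadMLP(
        noise_sd=config.noise_sd,
        dropout_rate=config.dropout_rate,
        l1=config.l1,
        learning_rate=config.learning_rate,
        decay=config.decay,
        momentum=config.momentum,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        random_state=config.seed if seed is None else seed,
    )
    model.fit(
        patterns.features[train_idx],
        ytr,
        validation_data=(patterns.features[val_idx], Y[val_idx]),
    )
    proba = model.predict_proba(patterns.features[val_idx])
    result = FoldResult(
        fold_index=fold_index,
        val_indices=np.asarray(val_idx),
        proba=proba,
        group_true=patterns.group[val_idx],
        lex_true=patterns.lexicality[val_idx],
        epochs_trained=model.n_epochs_,
        final_losses={
            "train": model.history_["train_loss"][-1],
            "val_lex": model.history_["val_lex_loss"][-1] if model.history_["val_lex_loss"] else None,
        },
    )
    return model, result


def evaluate_kfold(
    patterns: PatternSet,
    config: TrainingConfig,
    seed: int,
) -> tuple[list[DualHeadMLP], list[FoldResult]]:
    """Train all k folds; fold assignments and per-fold init seeds derive
    deterministically from ``seed``."""
    folds = stratified_kfold(patterns, config.k_folds, seed, config.group_by_participant)
    all_idx = np.arange(patterns.n_patterns)
    models, results = [], []
    child_seeds = np.random.SeedSequence(seed).generate_state(config.k_folds) % (2**31)
    for fold_index, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, val_idx)
        model, res = train_fold(
            patterns, train_idx, val_idx, config, fold_index, seed=int(child_seeds[fold_index])
        )
        models.append(model)
        results.append(res)
    return models, results


def pooled_metrics(results: Sequence[FoldResult], head: int) -> ClassificationMetrics:
    """Collapse validation decisions across folds into one metric set."""
    true = np.concatenate([r.group_true if head == GROUP_HEAD else r.lex_true for r in results])
    proba = np.concatenate([r.proba[:, head] for r in results])
    if head == LEX_HEAD and (true < 0).any():
        raise ValueError("lexicality metrics undefined for transfer patterns")
    table = ContingencyTable.from_predictions(true, (proba >= 0.5).astype(int))
    return ClassificationMetrics.from_table(table)
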