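"""Cross-task transfer evaluation.

First-generation models (no decimation) are trained on random stratified
66% subsamples of the training-task pattern set and evaluated on *all*
patterns from a different task. The group head is scored against the
transfer cohort's group labels; the lexicality head has no ground truth on
the transfer task, so its output is profiled as class proportions (the
reference analysis observed a unanimous all-pseudoword profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .features import PatternSet
from .mlp import DualHeadMLP, TrainingConfig, GROUP_HEAD, LEX_HEAD
from .metrics import ContingencyTable, ClassificationMetrics


@dataclass(frozen=True)
class TransferConfig:
    n_sets: int = 5
    partitions_per_set: int = 3
    train_fraction: float = 0.66

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


@dataclass
class TransferModelOutcome:
    set_index: int
    partition_index: int
    group_metrics: ClassificationMetrics
    lexicality_proportions: dict  # {"word": float, "pseudoword": float}
    proba: np.ndarray  # (n_transfer, 2)


@dataclass
class TransferResult:
    outcomes: list[TransferModelOutcome] = field(default_factory=list)
    n_transfer_patterns: int = 0

    @property
    def mean_group_accuracy(self) -> float:
        return float(np.mean([o.group_metrics.accuracy for o in self.outcomes]))

    @property
    def mean_group_dprime(self) -> float:
        return float(np.mean([o.group_metrics.d_prime for o in self.outcomes]))


def run_transfer(
    train_set: PatternSet,
    transfer_set: PatternSet,
    training: TrainingConfig,
    config: TransferConfig | None = None,
    seed: int = 0,
) -> TransferResult:
    """Train n_sets x partitions_per_set models on random 0.66 stratified
    subsamples of the training set and score every transfer pattern with
    each. The 0.66 partitions are independent subsamples (not a disjoint
    fold partition); the held-out 34% serves as the early-stopping
    validation set."""
    config = config or TransferConfig()
    if train_set.index_map.n_roi != transfer_set.index_map.n_roi or (
        train_set.n_features != transfer_set.n_features
    ):
        raise ValueError("training and transfer sets do not share a feature map")
    strata = train_set.group * 2 + np.maximum(train_set.lexicality, 0)
    y_train = np.column_stack([train_set.group, train_set.lexicality])
    y_transfer_group = transfer_set.group
    model_seeds = np.random.SeedSequence([seed, 0x7AEB]).generate_state(
        config.n_sets * config.partitions_per_set
    ) % (2**31)

    result = TransferResult(n_transfer_patterns=transfer_set.n_patterns)
    k = 0
    for s in range(config.n_sets):
        for part in range(config.partitions_per_set):
            mseed = int(model_seeds[k])
            k += 1
            idx_train, idx_val = train_test_split(
                np.arange(train_set.n_patterns),
                train_size=config.train_fraction,
                stratify=strata,
                random_state=mseed % (2**32),
            )
            model = DualHeadMLP(
                noise_sd=training.noise_sd,
                dropout_rate=training.dropout_rate,
                l1=training.l1,
                learning_rate=training.learning_rate,
                decay=training.decay,
                momentum=training.momentum,
                batch_size=training.batch_size,
                max_epochs=training.max_epochs,
                patience=training.patience,
                random_state=mseed,
            )
            model.fit(
                train_set.features[idx_train],
                y_train[idx_train],
                validation_data=(train_set.features[idx_val], y_train[idx_val]),
            )
            proba = model.predict_proba(transfer_set.features)
            pred_group = (proba[:, GROUP_HEAD] >= 0.5).astype(int)
            table = ContingencyTable.from_predictions(y_transfer_group, pred_group)
            word_frac = float(np.mean(proba[:, LEX_HEAD] >= 0.5))
            result.outcomes.append(
                TransferModelOutcome(
                    set_index=s,
                    partition_index=part,
                    group_metrics=ClassificationMetrics.from_table(table),
                    lexicality_proportions={"word": word_frac, "pseudoword": 1.0 - word_frac},
                    proba=proba,
                )
            )
    return result


@dataclass
class LexicalityProfile:
    per_model: list[dict]
    pooled: dict
    unanimous_class: str | None


def lexicality_profile(result: TransferResult) -> LexicalityProfile:
    """Per-model and pooled word/pseudoword assignment fractions on the
    transfer patterns; flags unanimity when one class receives every
    pattern from every model."""
    per_model = [dict(o.lexicality_proportions) for o in result.outcomes]
    word = float(np.mean([m["word"] for m in per_model]))
    pooled = {"word": word, "pseudoword": 1.0 - word}
    unanimous = None
    if all(m["word"] == 1.0 for m in per_model):
        unanimous = "word"
    elif all(m["pseudoword"] == 1.0 for m in per_model):
        unanimous = "pseudoword"
    return LexicalityProfile(per_model=per_model, pooled=pooled, unanimous_class=unanimous)
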