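"""Shared fixtures: small synthetic cohorts and pattern sets.

All fixtures are generated programmatically at session scope; sizes are
chosen so the whole unit suite stays fast while every pipeline stage is
exercised on data with known planted structure.
"""

from __future__ import annotations

import pytest

import connfp


@pytest.fixture(scope="session")
def small_spec() -> connfp.CohortSpec:
    return connfp.CohortSpec(
        n_per_group=4,
        n_roi=20,
        runs_per_condition=2,
        volumes_per_run=120,
        n_group_edges=8,
        n_condition_edges=8,
        delta_group=0.3,
        delta_condition=0.15,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    runs, truth = connfp.generate_cohort(small_spec)
    return runs, truth


@pytest.fixture(scope="session")
def small_patterns(small_spec, small_cohort):
    runs, _ = small_cohort
    fmap = connfp.FeatureIndexMap.for_parcellation(
        small_spec.n_roi, small_spec.cluster_assignment
    )
    return connfp.build_pattern_set(runs, map_=fmap)


@pytest.fixture(scope="session")
def quick_training_config() -> connfp.TrainingConfig:
    return connfp.TrainingConfig(max_epochs=24, patience=16, k_folds=2)
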