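"""Synthetic cohort generator: shape contracts, PSD guarantees, planted
effect sizes against Monte-Carlo estimates, and determinism."""

import numpy as np
import pytest
from scipy import stats

import connfp
from connfp.cohort import (
    CohortSpec,
    GroundTruth,
    build_base_correlation,
    build_run_covariance,
    default_cluster_assignment,
    generate_cohort,
    generate_transfer_cohort,
    within_cluster_pairs,
)
from connfp.features import residualize


def test_default_parcellation_has_253_within_cluster_pairs():
    labels = default_cluster_assignment(115)
    assert len(labels) == 115
    assert len(within_cluster_pairs(labels)) == 253


def test_cluster_sizes_sum_matches():
    sizes = np.array(connfp.cohort.DEFAULT_CLUSTER_SIZES)
    assert (sizes * (sizes - 1) // 2).sum() == 253


class TestBuildRunCovariance:
    def _truth(self, n, edges, delta):
        base = np.eye(n)
        return GroundTruth(
            group_edges=edges, condition_edges=[], delta_group=delta,
            delta_condition=0.0, base=base,
        )

    def test_zero_deltas_identity(self):
        rng = np.random.default_rng(0)
        spec = CohortSpec(n_roi=20, n_group_edges=3, n_condition_edges=3, seed=0)
        base = build_base_correlation(spec, rng)
        truth = GroundTruth([], [], 0.0, 0.0, base)
        out = build_run_covariance(base, truth, group=1, condition=1)
        np.testing.assert_array_equal(out, base)

    def test_planted_cell_near_target_after_repair(self):
        # base r(i,j) = 0.1, delta +0.4 -> repaired cell within 0.02 of 0.5
        n = 115
        base = np.eye(n)
        base[3, 77] = base[77, 3] = 0.1
        truth = self._truth(n, [(3, 77)], 0.4)
        out = build_run_covariance(base, truth, group=1, condition=0)
        assert out[3, 77] == pytest.approx(0.5, abs=0.02)
        assert np.linalg.eigvalsh(out).min() >= -1e-8
        assert np.allclose(np.diag(out), 1.0)

    def test_overflow_clipped_before_repair(self):
        n = 10
        base = np.eye(n)
        base[0, 1] = base[1, 0] = 0.85
        truth = self._truth(n, [(0, 1)], 0.4)
        out = build_run_covariance(base, truth, group=1, condition=0)
        assert out[0, 1] <= 0.99 + 1e-9

    def test_non_symmetric_base_rejected(self):
        base = np.eye(4)
        base[0, 1] = 0.2  # mirror missing
        truth = self._truth(4, [(0, 1)], 0.1)
        with pytest.raises(ValueError):
            build_run_covariance(base, truth, 1, 0)


class TestGenerateCohort:
    def test_shape_contract(self):
        spec = CohortSpec(
            n_per_group=4, n_roi=20, runs_per_condition=2, volumes_per_run=180,
            n_group_edges=5, n_condition_edges=5, seed=3,
        )
        runs, truth = generate_cohort(spec)
        assert len(runs) == 8 * 4  # 8 participants x 4 runs
        assert all(r.values.shape == (180, 20) for r in runs)
        assert len({r.participant_id for r in runs}) == 8
        groups = np.array([r.group_label for r in runs])
        assert (groups == 0).sum() == (groups == 1).sum()

    def test_determinism(self):
        spec = CohortSpec(
            n_per_group=2, n_roi=12, runs_per_condition=1, volumes_per_run=40,
            n_group_edges=3, n_condition_edges=3, seed=11,
        )
        a, _ = generate_cohort(spec)
        b, _ = generate_cohort(spec)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.values, rb.values)

    def test_ground_truth_maps_to_valid_feature_indices(self, small_cohort, small_spec):
        _, truth = small_cohort
        n_pairs = small_spec.n_roi * (small_spec.n_roi - 1) // 2
        for idx in truth.group_feature_indices():
            assert 0 <= idx < n_pairs

    def test_planted_group_delta_recovered(self):
        """Residualized sample correlation difference (skilled - poor) at
        planted edges matches delta 0.4 within +-0.05, pooled over seeds."""
        diffs = []
        for seed in range(10):
            spec = CohortSpec(
                n_per_group=4, n_roi=20, runs_per_condition=2, volumes_per_run=180,
                n_group_edges=5, n_condition_edges=5, delta_group=0.4, seed=100 + seed,
            )
            runs, truth = generate_cohort(spec)
            per_group = {0: [], 1: []}
            for run in runs:
                r = np.corrcoef(residualize(run).values, rowvar=False)
                per_group[run.group_label].append(
                    np.mean([r[i, j] for i, j in truth.group_edges])
                )
            diffs.append(np.mean(per_group[1]) - np.mean(per_group[0]))
        assert np.mean(diffs) == pytest.approx(0.4, abs=0.05)

    def test_null_cohort_groups_indistinguishable(self):
        """With all deltas zero the pooled edge-correlation distributions
        of the two groups agree (two-sample KS)."""
        pooled = {0: [], 1: []}
        for seed in range(10):
            spec = CohortSpec(
                n_per_group=2, n_roi=15, runs_per_condition=1, volumes_per_run=90,
                n_group_edges=4, n_condition_edges=4,
                delta_group=0.0, delta_condition=0.0, seed=200 + seed,
            )
            runs, _ = generate_cohort(spec)
            iu = np.triu_indices(15, k=1)
            for run in runs:
                r = np.corrcoef(residualize(run).values, rowvar=False)
                pooled[run.group_label].extend(r[iu][:20])
        p = stats.ks_2samp(pooled[0], pooled[1]).pvalue
        assert p > 0.01

    def test_sample_correlation_converges_at_root_t(self):
        """Doubling run length halves the RMS deviation of sample edge
        correlations from the generative target, within 20%."""
        rms = {}
        for volumes in (90, 360):  # factor 4 -> RMS ratio should be ~2
            devs = []
            for seed in range(6):
                spec = CohortSpec(
                    n_per_group=2, n_roi=12, runs_per_condition=2, volumes_per_run=volumes,
                    n_group_edges=3, n_condition_edges=3, delta_group=0.0,
                    delta_condition=0.0, nuisance_amplitude=0.0, seed=300 + seed,
                )
                runs, truth = generate_cohort(spec)
                iu = np.triu_indices(12, k=1)
                target = truth.base[iu]
                for run in runs:
                    r = np.corrcoef(run.values, rowvar=False)[iu]
                    devs.extend(r - target)
            rms[volumes] = np.sqrt(np.mean(np.square(devs)))
        ratio = rms[90] / rms[360]
        assert 2.0 * 0.8 <= ratio <= 2.0 * 1.2

    def test_emitted_covariances_are_psd_with_unit_diagonal(self, small_spec, small_cohort):
        _, truth = small_cohort
        for group in (0, 1):
            for condition in (0, 1):
                c = build_run_covariance(truth.base, truth, group, condition)
                assert np.linalg.eigvalsh(c).min() >= -1e-8
                np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)


class TestTransferCohort:
    def test_shape_and_balance(self, small_spec, small_cohort):
        _, truth = small_cohort
        runs = generate_transfer_cohort(small_spec, truth, n_per_group=5, runs_per_participant=4)
        assert len(runs) == 10 * 4
        groups = np.array([r.group_label for r in runs])
        assert (groups == 0).sum() == (groups == 1).sum()
        assert all(r.condition_label == connfp.cohort.TRANSFER for r in runs)

    def test_group_effect_persists_and_condition_effect_absent(self):
        """Transfer cohorts keep the group edges (diff ~ delta_group) but
        carry none of the training task's condition effect."""
        gdiffs, cdiffs = [], []
        for seed in range(10):
            spec = CohortSpec(
                n_per_group=4, n_roi=20, runs_per_condition=2, volumes_per_run=180,
                n_group_edges=5, n_condition_edges=5, delta_group=0.3, seed=400 + seed,
            )
            _, truth = generate_cohort(spec)
            runs = generate_transfer_cohort(spec, truth, n_per_group=4, runs_per_participant=2)
            per_group = {0: [], 1: []}
            cond_vals = []
            for run in runs:
                r = np.corrcoef(residualize(run).values, rowvar=False)
                per_group[run.group_label].append(
                    np.mean([r[i, j] for i, j in truth.group_edges])
                )
                cond_vals.append(np.mean([r[i, j] - truth.base[i, j] for i, j in truth.condition_edges]))
            gdiffs.append(np.mean(per_group[1]) - np.mean(per_group[0]))
            cdiffs.append(np.mean(cond_vals))
        assert np.mean(gdiffs) == pytest.approx(0.3, abs=0.07)
        assert abs(np.mean(cdiffs)) < 0.03


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        CohortSpec(n_roi=2)
    with pytest.raises(ValueError):
        CohortSpec(volumes_per_run=3)
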