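"""Pattern generation: residualization, split halves, Pearson and XMI
estimators against analytic oracles, vectorization and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import skew

import connfp
from connfp.cohort import ROIRunSeries
from connfp.features import (
    ConnectivityConfig,
    FeatureIndexMap,
    apply_feature_mask,
    matrix_from_features,
    pearson_matrix,
    rescale_and_sqrt,
    residualize,
    split_halves,
    vectorize_upper,
    xmi_matrix,
)


def make_run(values, nuisance=None, **kw):
    defaults = dict(participant_id="sub-X", group_label=0, condition_label=0, run_index=0)
    defaults.update(kw)
    if nuisance is None:
        nuisance = np.zeros((len(values), 0))
    return ROIRunSeries(values=np.asarray(values, float), nuisance=nuisance, **defaults)


class TestResidualize:
    def test_removes_linear_trend(self):
        t = np.arange(50, dtype=float)
        run = make_run(np.column_stack([3 + 0.5 * t, np.random.default_rng(0).normal(size=50)]))
        out = residualize(run)
        assert np.abs(out.values[:, 0]).max() < 1e-10

    def test_residuals_orthogonal_to_nuisance(self):
        rng = np.random.default_rng(1)
        nuis = rng.normal(size=(80, 2))
        signal = rng.normal(size=(80, 3))
        run = make_run(signal + 2.0 * nuis[:, [0]], nuisance=nuis)
        out = residualize(run)
        for col in range(3):
            for q in range(2):
                r = np.corrcoef(out.values[:, col], nuis[:, q])[0, 1]
                assert abs(r) < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        run = make_run(rng.normal(size=(60, 4)), nuisance=rng.normal(size=(60, 2)))
        once = residualize(run)
        twice = residualize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_collinear_nuisance_named_in_error(self):
        t = 40
        nuis = np.column_stack([np.linspace(-1, 1, t)])  # duplicates the trend column
        run = make_run(np.random.default_rng(3).normal(size=(t, 2)), nuisance=nuis)
        with pytest.raises(ValueError, match="nuisance|linear_trend"):
            residualize(run)


class TestSplitHalves:
    @pytest.mark.parametrize("t, first, second", [(180, 90, 90), (181, 90, 91), (8, 4, 4)])
    def test_split_sizes(self, t, first, second):
        run = make_run(np.random.default_rng(0).normal(size=(t, 3)))
        a, b = split_halves(run)
        assert a.n_timepoints == first and b.n_timepoints == second
        assert a.group_label == run.group_label and b.condition_label == run.condition_label

    def test_partition_property(self):
        run = make_run(np.random.default_rng(1).normal(size=(55, 4)))
        a, b = split_halves(run)
        np.testing.assert_array_equal(np.vstack([a.values, b.values]), run.values)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            split_halves(make_run(np.zeros((6, 3)) + np.random.default_rng(0).normal(size=(6, 3))))


class TestPearson:
    def test_duplicated_and_negated_columns(self):
        x = np.random.default_rng(0).normal(size=(50, 1))
        m = pearson_matrix(np.column_stack([x, x, -x]))
        assert m[0, 1] == pytest.approx(1.0)
        assert m[0, 2] == pytest.approx(-1.0)
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 1.0)

    def test_zero_variance_column_named(self):
        x = np.random.default_rng(0).normal(size=(30, 3))
        x[:, 1] = 2.5
        with pytest.raises(ValueError, match="1"):
            pearson_matrix(x)

    def test_null_correlation_magnitude_matches_closed_form(self):
        """For independent normal columns, E|r| ~ sqrt(2/(pi(T-1)))."""
        t = 90
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(200):
            m = pearson_matrix(rng.normal(size=(t, 8)))
            iu = np.triu_indices(8, k=1)
            vals.extend(np.abs(m[iu]))
        assert np.mean(vals) == pytest.approx(np.sqrt(2 / (np.pi * (t - 1))), abs=0.01)

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(40, 5))
        a = pearson_matrix(x)
        b = pearson_matrix(3.7 * x + 11.0)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestXMI:
    def test_monotone_pair_saturates_at_log2_bins(self):
        t, bins = 96, 8
        x = np.random.default_rng(0).normal(size=t)
        y = np.exp(x)  # strictly monotone, nonlinear
        m = xmi_matrix(np.column_stack([x, y]), ConnectivityConfig(xmi_bins=bins))
        assert m[0, 1] == pytest.approx(np.log2(bins), abs=1e-12)

    def test_diagonal_is_binned_entropy(self):
        t, bins = 96, 8
        x = np.random.default_rng(1).normal(size=(t, 2))
        m = xmi_matrix(x, ConnectivityConfig(xmi_bins=bins))
        # quantile bins on 96 samples: equal counts of 12 -> entropy log2(8)
        assert m[0, 0] == pytest.approx(np.log2(bins), abs=1e-12)

    def test_independent_columns_match_plugin_bias(self):
        """Mean plug-in MI of independent columns is within a factor of 2
        of the Miller-Madow bias (B-1)^2 / (2 T ln 2)."""
        t, bins = 90, 8
        expected_bias = (bins - 1) ** 2 / (2 * t * np.log(2))
        rng = np.random.default_rng(2)
        vals = [
            xmi_matrix(rng.normal(size=(t, 2)), ConnectivityConfig(xmi_bins=bins))[0, 1]
            for _ in range(200)
        ]
        assert expected_bias / 2 <= np.mean(vals) <= expected_bias * 2

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(3)
        m = xmi_matrix(rng.normal(size=(64, 6)), ConnectivityConfig())
        assert np.allclose(m, m.T, atol=1e-12)
        assert (m >= 0).all()

    def test_degenerate_column_rejected(self):
        x = np.random.default_rng(0).normal(size=(40, 2))
        x[:, 0] = 1.0
        with pytest.raises(ValueError, match="degenerate|tie"):
            xmi_matrix(x, ConnectivityConfig())


class TestVectorize:
    def test_115_roi_yields_6555_features(self):
        m = np.zeros((115, 115))
        vec, fmap = vectorize_upper(m)
        assert len(vec) == 6555
        assert fmap.n_features == 6555

    def test_row_major_order(self):
        m = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
        vec, _ = vectorize_upper(m)
        np.testing.assert_array_equal(vec, [1.0, 2.0, 3.0])

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(9, 9))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        vec, fmap = vectorize_upper(m)
        np.testing.assert_allclose(matrix_from_features(vec, fmap), m, atol=1e-15)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=3, max_value=130))
    def test_feature_count_invariant(self, n):
        vec, fmap = vectorize_upper(np.zeros((n, n)))
        assert len(vec) == n * (n - 1) // 2
        # bijection: every pair strictly upper-triangle, strictly ordered
        assert (fmap.pairs[:, 0] < fmap.pairs[:, 1]).all()
        assert len({tuple(p) for p in fmap.pairs}) == len(vec)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            vectorize_upper(np.zeros((3, 4)))


class TestRescaleAndSqrt:
    def test_worked_endpoints(self):
        out = rescale_and_sqrt(np.array([-1.0, 0.0, 1.0]))
        np.testing.assert_allclose(out, [0.0, np.sqrt(0.5), 1.0], atol=1e-12)

    def test_unit_interval_endpoints_fixed(self):
        v = np.array([0.0, 0.3, 0.6, 1.0])
        out = rescale_and_sqrt(v)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_skewness_strictly_decreases_for_right_skewed_input(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=5000) ** 2
        assert skew(rescale_and_sqrt(v)) < skew((v - v.min()) / np.ptp(v))

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=100)
        out = rescale_and_sqrt(v)
        np.testing.assert_array_equal(np.argsort(out), np.argsort(v))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rescale_and_sqrt(np.full(10, 3.3))


class TestFeatureMask:
    def test_default_115_mask_leaves_6302(self):
        fmap = FeatureIndexMap.for_parcellation(115, connfp.default_cluster_assignment(115))
        assert fmap.within_cluster_mask.sum() == 253
        assert fmap.n_features - fmap.within_cluster_mask.sum() == 6302

    def test_mask_preserves_pair_identity(self, small_patterns):
        # small_patterns is already masked; surviving features keep pairs
        pairs = small_patterns.index_map.pairs
        assert (pairs[:, 0] < pairs[:, 1]).all()
        assert not small_patterns.index_map.within_cluster_mask.any()

    def test_empty_mask_is_identity(self, small_patterns):
        out = apply_feature_mask(small_patterns, np.zeros(small_patterns.n_features, bool))
        np.testing.assert_array_equal(out.features, small_patterns.features)

    def test_length_mismatch_rejected(self, small_patterns):
        with pytest.raises(ValueError):
            apply_feature_mask(small_patterns, np.zeros(3, bool))


class TestBuildPatternSet:
    def test_pattern_count_and_labels(self, small_spec, small_cohort, small_patterns):
        runs, _ = small_cohort
        n_participants = 2 * small_spec.n_per_group
        n_runs = 2 * small_spec.runs_per_condition
        assert small_patterns.n_patterns == n_participants * n_runs * 2 * 2
        word = small_patterns.lexicality == 1
        assert word.sum() == small_patterns.n_patterns // 2
        assert np.isin(small_patterns.group, (0, 1)).all()
        assert (small_patterns.features >= 0).all() and (small_patterns.features <= 1).all()
        assert np.isfinite(small_patterns.features).all()

    def test_methods_give_distinct_but_related_views(self, small_patterns):
        """Pearson- and XMI-derived vectors from the same half correlate
        positively but are far from redundant."""
        ps = small_patterns
        key = list(zip(ps.participant, ps.run_index, ps.half))
        pearson_rows = {k: i for i, k in enumerate(key) if ps.method[i] == "pearson"}
        cors = []
        for i, k in enumerate(key):
            if ps.method[i] == "xmi" and k in pearson_rows:
                r = np.corrcoef(ps.features[i], ps.features[pearson_rows[k]])[0, 1]
                cors.append(r)
        mean_r = np.mean(cors)
        assert 0.0 < mean_r < 0.9
        assert max(cors) < 0.999
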