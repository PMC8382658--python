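import numpy as np
import pytest
from scipy import stats

from clustvalid.preprocess import normalize
from clustvalid.synthetic_data import (
    CohortSpec,
    estimate_covariance,
    inject_missingness,
    simulate_cohort,
    simulate_null,
    t2d_registry_preset,
)


class TestRegistryPreset:
    def test_published_subgroup_moments(self):
        spec = t2d_registry_preset()
        j = spec.variable_names.index("hba1c")
        assert spec.component_means[0, j] == 89.5
        assert spec.component_sds[0, j] == 21.12
        sizes = np.array([12133, 27888, 41555, 32825], dtype=float)
        np.testing.assert_allclose(spec.mixture_weights, sizes / sizes.sum())

    def test_weighted_age_mean_matches_population_mean(self):
        spec = t2d_registry_preset()
        age = spec.mixture_weights @ spec.component_means[:, 0]
        assert abs(age - 62.8) < 0.5

    def test_follow_up_calibration(self):
        cohort = simulate_cohort(t2d_registry_preset(n_individuals=30_000), seed=4)
        assert 0.10 < cohort.event.mean() < 0.20          # ~85% censored
        assert 4.7 < np.median(cohort.time) < 5.7          # median follow-up ~5.2 y


class TestSimulateCohort:
    def test_determinism_bit_identical(self):
        spec = t2d_registry_preset(n_individuals=500)
        a = simulate_cohort(spec, seed=9)
        b = simulate_cohort(spec, seed=9)
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.event, b.event)
        np.testing.assert_array_equal(a.missing_mask, b.missing_mask)

    def test_unit_covariance_recovered_at_large_n(self):
        spec = CohortSpec(n_individuals=50_000, variable_names=list("abcde"))
        cohort = simulate_cohort(spec, seed=1)
        cov = np.cov(cohort.features, rowvar=False)
        np.testing.assert_allclose(cov, np.eye(5), atol=0.05)

    def test_component_means_recovered(self):
        spec = t2d_registry_preset(n_individuals=50_000)
        cohort = simulate_cohort(spec, seed=2)
        for c in range(4):
            rows = cohort.true_labels == c + 1
            n_c = rows.sum()
            tol = 4 * spec.component_sds[c] / np.sqrt(n_c)
            np.testing.assert_array_less(
                np.abs(cohort.features[rows].mean(axis=0) - spec.component_means[c]),
                tol,
            )

    def test_null_effect_times_independent_of_features(self):
        spec = CohortSpec(n_individuals=5_000, variable_names=list("abc"))
        cohort = simulate_cohort(spec, seed=3)
        for j in range(3):
            rho = stats.spearmanr(cohort.features[:, j], cohort.time).statistic
            assert abs(rho) < 4 / np.sqrt(len(cohort.time))

    def test_non_psd_covariance_rejected_with_component_name(self):
        bad = np.array([[[1.0, 2.0], [2.0, 1.0]]])  # eigenvalues (3, -1)
        with pytest.raises(ValueError, match="component 1"):
            CohortSpec(
                n_individuals=10,
                variable_names=["a", "b"],
                component_covariances=bad,
            )


class TestEstimateCovariance:
    def test_duplicated_column_gives_exact_unit_correlation(self, rng):
        x = rng.normal(size=2_000)
        nm = normalize(np.column_stack([x, x, rng.normal(size=2_000)]))
        cov = estimate_covariance(nm).covariance
        assert cov[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_columns_near_zero_offdiagonal(self):
        X = np.random.default_rng(0).normal(size=(100_000, 3))
        cov = estimate_covariance(normalize(X)).covariance
        off = cov[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_known_mixture_correlation_recovered(self):
        rng = np.random.default_rng(8)
        n, w = 20_000, 0.6
        a = rng.normal(size=n)
        b = w * a + np.sqrt(1 - w**2) * rng.normal(size=n)
        cov = estimate_covariance(normalize(np.column_stack([a, b]))).covariance
        se = (1 - w**2) / np.sqrt(n)
        assert abs(cov[0, 1] - w) < 3 * se

    def test_missing_values_rejected(self):
        from clustvalid.preprocess import NormalizedMatrix

        vals = np.random.default_rng(0).normal(size=(50, 2))
        vals[0, 0] = np.nan
        nm = NormalizedMatrix(vals, np.zeros(2), np.ones(2), ["a", "b"])
        with pytest.raises(ValueError, match="impute"):
            estimate_covariance(nm)


class TestSimulateNull:
    def _cov(self, mat):
        from clustvalid.synthetic_data import CovarianceEstimate

        p = mat.shape[0]
        return CovarianceEstimate(mat, np.zeros(p), np.ones(p), 1000)

    def test_identity_covariance_recovered(self):
        null = simulate_null(self._cov(np.eye(4)), 50_000, seed=0)
        np.testing.assert_allclose(np.cov(null.values, rowvar=False), np.eye(4), atol=0.05)

    def test_zero_mean_construction(self):
        cov = 0.5 * np.eye(3) + 0.5
        null = simulate_null(self._cov(cov), 10_000, seed=1)
        assert np.abs(null.values.mean(axis=0)).max() < 4 / np.sqrt(10_000)

    def test_marginals_look_gaussian(self):
        null = simulate_null(self._cov(0.3 * np.eye(4) + 0.7), 20_000, seed=2)
        skew = stats.skew(null.values, axis=0)
        kurt = stats.kurtosis(null.values, axis=0)
        assert np.abs(skew).max() < 0.08
        assert np.abs(kurt).max() < 0.15

    def test_correlation_raises_hopkins(self):
        from clustvalid.validity import hopkins

        strong = simulate_null(self._cov(0.1 * np.eye(5) + 0.9), 3_000, seed=3)
        weak = simulate_null(self._cov(np.eye(5)), 3_000, seed=3)
        h_strong = hopkins(strong, 300, seed=4).hopkins_h
        h_weak = hopkins(weak, 300, seed=4).hopkins_h
        assert h_strong > h_weak

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            simulate_null(self._cov(np.eye(2)), 1, seed=0)


class TestInjectMissingness:
    def test_zero_rates_give_empty_mask(self, rng):
        X = rng.normal(size=(100, 3))
        assert not inject_missingness(X, np.zeros(3), seed=0).any()

    def test_realized_rate_matches_target(self):
        X = np.random.default_rng(1).normal(size=(10_000, 3))
        mask = inject_missingness(X, np.array([0.0, 0.2, 0.0]), seed=2)
        assert 0.18 <= mask[:, 1].mean() <= 0.22
        assert not mask[:, 0].any() and not mask[:, 2].any()

    def test_mar_masked_rows_differ_on_anchor(self):
        X = np.random.default_rng(3).normal(size=(20_000, 2))
        mask = inject_missingness(X, np.array([0.0, 0.3]), seed=4, mar_slope=2.0)
        assert X[mask[:, 1], 0].mean() - X[~mask[:, 1], 0].mean() > 0.5

    def test_all_maskable_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        with pytest.raises(ValueError, match="fully observed"):
            inject_missingness(X, np.array([0.1, 0.1]), seed=0)
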