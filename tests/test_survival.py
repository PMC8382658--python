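import numpy as np
import pandas as pd
import pytest

from clustvalid.survival import (
    ModelSpec,
    SurvivalDataset,
    benchmark_models,
    build_design,
    cluster_design,
    cox_loglik_grad_hess,
    fit_cox,
    harrell_c,
    harrell_c_bruteforce,
    spline_basis,
)
from clustvalid.synthetic_data import simulate_endpoint


def random_survival(n, seed, censoring=0.3, tie_rounding=None):
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0, n) + 0.01
    if tie_rounding:
        t = np.round(t, tie_rounding) + 0.01
    e = (rng.uniform(size=n) > censoring).astype(int)
    r = rng.normal(size=n)
    if tie_rounding:
        r = np.round(r, 1)
    return t, e, r


class TestSplineBasis:
    def test_df_columns_and_linear_containment(self, rng):
        x = rng.normal(size=500)
        for df in (2, 3, 4):
            B = spline_basis(x, df=df)
            assert B.shape == (500, df)
            # linear functions lie in the natural-spline space
            design = np.column_stack([np.ones(500), B])
            coef, *_ = np.linalg.lstsq(design, 3.0 * x - 1.0, rcond=None)
            np.testing.assert_allclose(design @ coef, 3.0 * x - 1.0, atol=1e-8)

    def test_reproduces_a_natural_spline_through_the_knots(self, rng):
        x = np.sort(rng.uniform(0, 10, size=400))
        B = spline_basis(x, df=3)
        y = B @ np.array([0.7, -1.3, 2.1])  # a natural cubic spline by construction
        refit, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(400), spline_basis(x, df=3)]), y, rcond=None
        )
        np.testing.assert_allclose(
            np.column_stack([np.ones(400), B]) @ refit, y, atol=1e-8
        )

    def test_linear_beyond_boundary_knots(self, rng):
        x = rng.normal(size=1_000)
        B = spline_basis(x, df=3)
        hi = np.quantile(x, 0.95)
        # second differences vanish on an equally spaced grid beyond the boundary
        grid = hi + 1.0 + np.arange(20) * 0.5
        Bg = spline_basis(
            np.concatenate([x, grid]), df=3,
            knots=np.quantile(x, np.linspace(0.05, 0.95, 4)),
        )[-20:]
        second = np.diff(Bg, n=2, axis=0)
        np.testing.assert_allclose(second, 0.0, atol=1e-8)
        assert B.shape[1] == 3

    def test_df_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            spline_basis(rng.normal(size=50), df=1)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            spline_basis(np.array([1.0, 1.0, 2.0, 2.0] * 5), df=3)


class TestClusterDesign:
    def test_two_levels_single_indicator(self):
        design, names = cluster_design(np.array([1, 2, 2, 1]), 2)
        assert design.shape == (4, 1)
        assert set(np.unique(design)) == {0.0, 1.0}

    def test_reference_rows_all_zero_and_counts(self):
        labels = np.array([1, 2, 3, 3, 3, 2])
        design, names = cluster_design(labels, 3)  # largest cluster (3) = reference
        assert names == ["cluster_1", "cluster_2"]
        np.testing.assert_array_equal(design[labels == 3], 0.0)
        np.testing.assert_allclose(design.sum(axis=0), [1, 2])

    def test_empty_level_rejected(self):
        with pytest.raises(ValueError, match="level 3"):
            cluster_design(np.array([1, 2, 2]), 3)


class TestFitCox:
    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(0)
        n = 5_000
        X = rng.normal(size=(n, 1))
        t, e, _ = simulate_endpoint(rng.normal(size=(n, 1)), np.array([0.5]), seed=1)
        fit = fit_cox(design=X, time=t, event=e)
        assert abs(fit.coefficients[0]) < 3 * fit.standard_errors()[0]

    def test_single_covariate_recovery(self):
        ests, ses = [], []
        for seed in range(20):
            X = np.random.default_rng(seed).normal(size=(5_000, 1))
            t, e, _ = simulate_endpoint(X, np.array([0.693]), seed=seed)
            fit = fit_cox(design=X, time=t, event=e)
            ests.append(fit.coefficients[0])
            ses.append(fit.standard_errors()[0])
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.693) < 3 * mc_se

    def test_matches_lifelines_with_and_without_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 1_000
        X = rng.normal(size=(n, 3))
        t, e, _ = simulate_endpoint(X, np.array([0.5, -0.3, 0.2]), seed=2)
        for tt in (t, np.ceil(t * 4) / 4):  # continuous and heavily tied
            ours = fit_cox(design=X, time=tt, event=e)
            df = pd.DataFrame(X, columns=["a", "b", "c"]).assign(T=tt, E=e)
            ref = CoxPHFitter().fit(df, "T", "E")
            np.testing.assert_allclose(ours.coefficients, ref.params_.values, atol=2e-6)
            np.testing.assert_allclose(
                ours.standard_errors(), ref.standard_errors_.values, rtol=1e-4
            )
            assert ours.log_likelihood == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_score_vanishes_at_optimum(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(800, 2))
        t, e, _ = simulate_endpoint(X, np.array([0.4, -0.2]), seed=3)
        fit = fit_cox(design=X, time=t, event=e)
        assert fit.converged
        _, grad, _ = cox_loglik_grad_hess(fit.coefficients, t, e, X - X.mean(axis=0))
        assert np.abs(grad).max() < 1e-6

    def test_duplicated_column_rank_deficiency_error(self, rng):
        X = rng.normal(size=(100, 1))
        t = rng.exponential(1, 100) + 0.1
        e = np.ones(100, dtype=int)
        with pytest.raises(ValueError, match="collinear"):
            fit_cox(design=np.column_stack([X, X]), time=t, event=e,
                    column_names=["a", "a_copy"])

    def test_monotone_likelihood_guard(self, rng):
        t = np.sort(rng.exponential(1, 60)) + 0.1
        e = np.ones(60, dtype=int)
        x = -t[:, None]  # risk ranking identical to event order -> separation
        with pytest.raises(ValueError, match="monotone|separation"):
            fit_cox(design=x, time=t, event=e)

    def test_time_scaling_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(400, 2))
        t, e, _ = simulate_endpoint(X, np.array([0.6, -0.4]), seed=6)
        a = fit_cox(design=X, time=t, event=e)
        b = fit_cox(design=X, time=3.7 * t, event=e)
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-8)


class TestHarrellC:
    def test_perfect_ranking_gives_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        res = harrell_c(-t, time=t, event=np.ones(4, int))
        assert res.c_index == 1.0
        assert res.comparable == 6

    def test_constant_scores_give_exact_half(self, rng):
        t = rng.exponential(1, 50) + 0.1
        e = rng.integers(0, 2, 50)
        res = harrell_c(np.zeros(50), time=t, event=e)
        assert res.c_index == 0.5
        assert res.risk_tied == res.comparable

    @pytest.mark.parametrize("seed,censoring,ties", [(0, 0.0, None), (1, 0.3, 1),
                                                     (2, 0.5, 1), (3, 0.2, None)])
    def test_fast_path_equals_bruteforce(self, seed, censoring, ties):
        t, e, r = random_survival(200, seed, censoring, ties)
        fast = harrell_c(r, time=t, event=e)
        brute = harrell_c_bruteforce(r, t, e)
        assert (fast.concordant, fast.discordant, fast.risk_tied, fast.comparable) == (
            brute.concordant, brute.discordant, brute.risk_tied, brute.comparable
        )
        assert fast.c_index == pytest.approx(brute.c_index, abs=1e-15)

    def test_matches_lifelines_value(self):
        from lifelines.utils import concordance_index

        t, e, r = random_survival(500, 7, 0.3, 1)
        assert harrell_c(r, time=t, event=e).c_index == pytest.approx(
            concordance_index(t, -r, e), abs=1e-12
        )

    def test_standard_error_matches_r_survival_fixture(self):
        # frozen reference computed with R survival::concordance (reverse=TRUE)
        rng = np.random.default_rng(42)
        n = 400
        t = np.round(rng.exponential(1, n), 2) + 0.01
        e = rng.integers(0, 2, n)
        r = rng.normal(size=n) + 0.5 * (-np.log(t))
        res = harrell_c(r, time=t, event=e)
        assert res.c_index == pytest.approx(0.673582, abs=5e-6)
        assert res.se == pytest.approx(0.021095, abs=5e-6)

    def test_shift_invariance_and_ci_brackets(self):
        t, e, r = random_survival(300, 11, 0.3)
        a = harrell_c(r, time=t, event=e)
        b = harrell_c(r + 100.0, time=t, event=e)
        assert a == b
        assert a.ci95[0] <= a.c_index <= a.ci95[1]

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c(np.array([1.0, 2.0]), time=np.array([1.0, 2.0]),
                      event=np.array([0, 0]))


class TestBenchmarkModels:
    def _dataset(self, n=1_500, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        t, e, _ = simulate_endpoint(X, np.array([0.8, -0.5, 0.3]), seed=seed + 1)
        feats = pd.DataFrame(X, columns=["a", "b", "c"])
        return SurvivalDataset(t, e, feats), rng

    def test_table_layout_and_linear_beats_clusters(self):
        ds, rng = self._dataset()
        labels = {k: rng.integers(1, k + 1, size=ds.n) for k in (2, 3)}
        for k in labels:  # ensure all levels present
            labels[k][:k] = np.arange(1, k + 1)
        table = benchmark_models({"death": ds}, labels)
        assert list(table["model"]) == ["2 cluster", "3 cluster", "PH Cox", "Spline Cox"]
        lin = table.loc[table.model == "PH Cox", "concordance"].item()
        # random labels carry no signal
        for k in (2, 3):
            assert lin > table.loc[table.model == f"{k} cluster", "concordance"].item()
        assert ((table.ci_lo <= table.concordance) & (table.concordance <= table.ci_hi)).all()

    def test_spline_generated_hazard_favors_spline_model(self):
        rng = np.random.default_rng(3)
        n = 4_000
        x = rng.normal(size=(n, 1))
        lp = 1.2 * (x[:, 0] ** 2 - 1.0)  # strongly nonlinear effect
        u = rng.uniform(size=n)
        t = 30.0 * (-np.log(u) * np.exp(-lp)) ** (1 / 1.4)
        cens = rng.exponential(9.0, n)
        time, event = np.minimum(t, cens), (t <= cens).astype(int)
        ds = SurvivalDataset(time, event, pd.DataFrame(x, columns=["x"]))
        d_lin, _ = build_design(ds, ModelSpec.all_linear(["x"]))
        d_spl, _ = build_design(ds, ModelSpec.all_spline(["x"], 3))
        c_lin = harrell_c(
            fit_cox(design=d_lin, time=time, event=event).predict_risk(d_lin),
            time=time, event=event).c_index
        c_spl = harrell_c(
            fit_cox(design=d_spl, time=time, event=event).predict_risk(d_spl),
            time=time, event=event).c_index
        assert c_spl > c_lin + 0.05

    def test_mismatched_label_length_rejected(self):
        ds, _ = self._dataset(n=200)
        with pytest.raises(ValueError, match="length"):
            benchmark_models({"death": ds}, {2: np.array([1, 2])})
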