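"""Correlation, permutation inference, OLS/AIC, nested F tests, and the
residual-separability procedure."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import physep as pp
from physep.inference import LinearFit


class TestPearson:
    def test_hand_oracle(self):
        """r for (1..5) vs (2,1,4,3,5) is 0.8 by the covariance/SD formula."""
        assert pp.pearson_r([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_identity_and_sign_flip(self):
        x = np.array([0.1, 0.5, 0.2, 0.9])
        assert pp.pearson_r(x, x) == pytest.approx(1.0)
        assert pp.pearson_r(x, -x) == pytest.approx(-1.0)

    @pytest.mark.parametrize("x,y", [([1, 1, 1], [1, 2, 3]), ([1, 2], [3, 4])])
    def test_degenerate_inputs_error(self, x, y):
        with pytest.raises(pp.UndefinedCorrelationError):
            pp.pearson_r(x, y)

    @given(
        hnp.arrays(
            np.float64,
            st.integers(min_value=3, max_value=30),
            elements=st.floats(-100, 100),
        ),
        st.integers(min_value=0, max_value=2**16),
    )
    def test_bounded(self, x, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=len(x))
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert -1.0 <= pp.pearson_r(x, y) <= 1.0 + 1e-12


class TestPermutationTest:
    def test_matches_exhaustive_enumeration_at_n5(self):
        """Monte-Carlo p within 3 MC standard errors of the exact p over all
        120 pairings."""
        x = np.array([0.2, 0.9, 0.4, 0.7, 0.1])
        y = np.array([0.3, 0.8, 0.5, 0.9, 0.2])
        obs = pp.pearson_r(x, y)
        null = [pp.pearson_r(x, y[list(p)]) for p in permutations(range(5))]
        p_exact = np.mean(np.abs(null) > abs(obs))
        n_iter = 20_000
        res = pp.permutation_test(x, y, n_iter=n_iter, seed=6)
        se = math.sqrt(p_exact * (1 - p_exact) / n_iter)
        assert res.p_two_tailed == pytest.approx(p_exact, abs=3 * se)

    def test_generic_statistic_path_agrees_with_fast_path(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=40), rng.normal(size=40)
        fast = pp.permutation_test(x, y, n_iter=500, seed=8)
        slow = pp.permutation_test(x, y, statistic=lambda a, b: pp.pearson_r(a, b),
                                   n_iter=500, seed=8)
        assert fast.observed_stat == pytest.approx(slow.observed_stat)
        # same permutations are consumed differently; compare distributions
        assert abs(fast.p_two_tailed - slow.p_two_tailed) < 0.08

    def test_strict_inequality_and_smoothing(self):
        """Ties in |null| do not count against the observed statistic; the
        smoothed option applies add-one correction."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pp.permutation_test(x, x.copy(), n_iter=100, seed=0)
        assert res.p_two_tailed == 0.0  # |null r| can never exceed |r| = 1
        smoothed = pp.permutation_test(x, x.copy(), n_iter=100, seed=0, smoothed=True)
        assert smoothed.p_two_tailed == pytest.approx(1 / 101)

    def test_default_iterations(self):
        x = np.arange(10.0)
        rng = np.random.default_rng(2)
        res = pp.permutation_test(x, rng.normal(size=10), seed=3)
        assert res.n_iter == 10_000 and len(res.null_stats) == 10_000


class TestOLS:
    def test_toy_hand_oracle(self):
        """Normal equations on x=(0,1,2,3), y=(1,2,2,3): slope 0.6,
        intercept 1.1, RSS 0.2."""
        fit = pp.ols_fit([1, 2, 2, 3], [0, 1, 2, 3])
        assert fit.coefficients == pytest.approx([1.1, 0.6], abs=1e-10)
        assert fit.rss == pytest.approx(0.2, abs=1e-10)
        assert fit.k == 2 and fit.n == 4

    def test_intercept_only_projects_onto_mean(self):
        y = np.array([2.0, 4.0, 9.0, 1.0])
        fit = pp.ols_fit(y, np.empty((4, 0)))
        assert fit.coefficients == pytest.approx([y.mean()])
        assert fit.rss == pytest.approx(np.sum((y - y.mean()) ** 2))

    def test_perfect_fit_has_zero_residuals_and_no_aic(self):
        x = np.arange(6.0)
        fit = pp.ols_fit(2 * x + 1, x)
        assert np.abs(fit.residuals).max() < 1e-10
        with pytest.raises(pp.AICUndefinedError):
            _ = fit.aic

    def test_rank_deficient_design_errors(self):
        x = np.arange(8.0)
        with pytest.raises(pp.PhysepError, match="rank"):
            pp.ols_fit(np.sin(x), np.column_stack([x, 2 * x]))

    @given(seed=st.integers(min_value=0, max_value=2**16))
    def test_residual_orthogonality(self, seed):
        """Residuals are orthogonal to every design column, intercept
        included (|r.c| <= 1e-8 ||y|| ||c||)."""
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 40)
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        fit = pp.ols_fit(y, X)
        cols = np.column_stack([np.ones(n), X])
        for j in range(cols.shape[1]):
            c = cols[:, j]
            bound = 1e-8 * np.linalg.norm(y) * np.linalg.norm(c)
            assert abs(fit.residuals @ c) <= bound
        assert abs(fit.residuals.sum()) <= 1e-8 * np.linalg.norm(y) * math.sqrt(n)

    def test_matches_normal_equations_on_random_problems(self):
        """Independent oracle: solve the normal equations directly."""
        rng = np.random.default_rng(44)
        X = rng.normal(size=(30, 3))
        y = X @ np.array([0.5, -1.0, 2.0]) + rng.normal(size=30)
        fit = pp.ols_fit(y, X)
        D = np.column_stack([np.ones(30), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
        np.testing.assert_allclose(fit.rss, np.sum((y - D @ beta) ** 2), atol=1e-10)


class TestModelComparison:
    def test_evidence_ratio_examples(self):
        assert pp.evidence_ratio(-481.07, -480.03).ratio == pytest.approx(1.7, abs=0.05)
        er = pp.evidence_ratio(-473.03, -470.87)
        assert round(er.ratio, 1) == 2.9 and er.favored == "a"
        tie = pp.evidence_ratio(-10.0, -10.0)
        assert tie.ratio == 1.0 and tie.favored == "tie"
        with pytest.raises(pp.PhysepError):
            pp.evidence_ratio(float("nan"), 0.0)

    def test_no_improvement_gives_f_zero_p_one(self):
        resid = np.array([1.0, -1.0, 0.5, -0.5, 0.0])
        red = LinearFit(np.zeros(1), resid, rss=2.5, n=5, k=1, names=("intercept",))
        full = LinearFit(np.zeros(2), resid, rss=2.5, n=5, k=2, names=("intercept", "x0"))
        cmp_ = pp.nested_f_test(red, full)
        assert cmp_.f_stat == 0.0 and cmp_.p_value == pytest.approx(1.0)

    def test_planted_effect_matches_arithmetic(self):
        """F from the two fitted RSS values equals the printed formula."""
        rng = np.random.default_rng(7)
        x1, x2 = rng.normal(size=10), rng.normal(size=10)
        y = 1.0 + 0.8 * x1 + 0.6 * x2 + 0.3 * rng.normal(size=10)
        red = pp.ols_fit(y, x1, names=("x1",))
        full = pp.ols_fit(y, np.column_stack([x1, x2]), names=("x1", "x2"))
        cmp_ = pp.nested_f_test(red, full)
        f_hand = ((red.rss - full.rss) / 1) / (full.rss / (10 - 3))
        assert cmp_.f_stat == pytest.approx(f_hand, abs=1e-12)
        assert (cmp_.df_num, cmp_.df_den) == (1, 7)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(9)
        x1, x2 = rng.normal(size=12), rng.normal(size=12)
        y = rng.normal(size=12)
        a = pp.ols_fit(y, x1, names=("x1",))
        b = pp.ols_fit(y, np.column_stack([x2, x2**2]), names=("x2", "x2sq"))
        with pytest.raises(pp.NonNestedModelsError):
            pp.nested_f_test(a, b)

    def test_aic_sign_flips_exactly_where_f_crosses_threshold(self):
        """For nested Gaussian fits, dAIC changes sign exactly where
        n*ln(1 + dk*F/(n-k_f)) = 2*dk."""
        n, k_r, k_f = 50, 2, 3
        dk, df_den = k_f - k_r, n - k_f
        for f in np.linspace(0.05, 10.0, 60):
            rss_f = 1.0
            rss_r = rss_f * (1 + dk * f / df_den)
            red = LinearFit(np.zeros(k_r), np.zeros(n), rss=rss_r, n=n, k=k_r,
                            names=("intercept", "x1"))
            full = LinearFit(np.zeros(k_f), np.zeros(n), rss=rss_f, n=n, k=k_f,
                             names=("intercept", "x1", "x2"))
            d_aic = full.aic - red.aic
            threshold = n * math.log(1 + dk * f / df_den) - 2 * dk
            assert (d_aic < 0) == (threshold > 0) or math.isclose(threshold, 0, abs_tol=1e-9)


class TestResidualSeparability:
    def test_structure_and_orthogonality(self, default_trials, default_scores):
        res = pp.residual_separability(default_trials, default_scores, seed=3,
                                       n_iter_perm=500)
        assert -1.0 <= res.r_resid <= 1.0
        assert res.n_participants == len(default_scores)
        X = default_scores.sort_values("participant_id")[
            ["combined_spatial", "combined_wm"]
        ].to_numpy()
        cols = np.column_stack([np.ones(len(X)), X])
        for fit in (res.fit_a, res.fit_b):
            for j in range(3):
                assert abs(fit.residuals @ cols[:, j]) < 1e-8 * np.linalg.norm(cols[:, j]) * 10

    def test_recovery_monotone_in_unique_loading(self):
        """Expected residual correlation increases with the physics-unique
        loading (0, moderate, large), all else fixed."""
        mean_r = {}
        for u in (0.0, 0.5, 1.2):
            rs = []
            for rep in range(6):
                cfg = pp.default_config(n_participants=150, u_loading=u, seed=700 + rep)
                _, trials = pp.simulate_cohort(cfg)
                scores = pp.score_primary(trials)
                rs.append(
                    pp.residual_separability(trials, scores, seed=rep, n_iter_perm=1).r_resid
                )
            mean_r[u] = np.mean(rs)
        assert mean_r[0.0] < mean_r[0.5] < mean_r[1.2]

    def test_requires_combined_predictors(self, default_trials, default_scores):
        with pytest.raises(pp.PhysepError, match="combined_spatial"):
            pp.residual_separability(
                default_trials, default_scores.drop(columns=["combined_spatial"]), seed=0
            )
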