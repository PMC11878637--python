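import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from ewaskit.models import (
    adjust_pvalues,
    fit_cox_site,
    fit_glm_site,
    fit_lmm_site,
    scale_exposure,
)


class TestScaleExposure:
    def test_unit_is_identity(self, rng):
        x = rng.normal(size=20)
        assert np.array_equal(scale_exposure(x, "unit"), x)

    def test_iqr_linear_interpolation_rule(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.allclose(scale_exposure(x, "iqr"), x / 2.0)

    def test_sd_uses_sample_denominator(self):
        out = scale_exposure(np.array([0.0, 2.0]), "sd")
        assert np.allclose(out, [0.0, 2.0 / np.sqrt(2.0)])

    def test_degenerate_spread_errors(self):
        with pytest.raises(ValueError, match="zero"):
            scale_exposure(np.ones(5), "sd")


class TestGLM:
    def test_known_slope(self):
        y = np.array([1.0, 2.0, 2.0, 4.0])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(4), x])
        fit = fit_glm_site(y, X, 1)
        assert fit.estimate == pytest.approx(0.9, abs=1e-12)

    def test_constant_outcome_convention(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        fit = fit_glm_site(np.full(10, 0.5), X, 1)
        assert fit.estimate == 0.0 and fit.p == 1.0 and fit.converged

    def test_planted_recovery_within_3_se(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = 0.05 * x + rng.normal(0, 0.1, n)
        fit = fit_glm_site(y, np.column_stack([np.ones(n), x]), 1)
        assert abs(fit.estimate - 0.05) < 3 * fit.se

    def test_matches_normal_equations_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 50))
            p = int(rng.integers(2, 6))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            fit = fit_glm_site(y, X, 1)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert abs(fit.estimate - beta[1]) < 1e-8

    def test_rank_deficient_flagged(self, rng):
        x = rng.normal(size=12)
        X = np.column_stack([np.ones(12), x, 2 * x])
        fit = fit_glm_site(rng.normal(size=12), X, 1)
        assert not fit.converged and "rank" in fit.reason

    def test_missing_values_complete_case(self, rng):
        n = 30
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(0, 0.05, n)
        y[:5] = np.nan
        fit = fit_glm_site(y, np.column_stack([np.ones(n), x]), 1)
        assert fit.n_used == 25


class TestAdjustPvalues:
    def test_bonferroni_analytic(self):
        out = adjust_pvalues([0.01, 0.02, 0.03], "bonferroni")
        assert np.allclose(out, [0.03, 0.06, 0.09])

    def test_bh_step_up_example(self):
        out = adjust_pvalues([0.005, 0.01, 0.03, 0.04], "bh")
        assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        for method in ("bonferroni", "bh"):
            assert adjust_pvalues([0.2], method)[0] == pytest.approx(0.2)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bh")

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            mine = adjust_pvalues(p, "bh")
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(mine, ref, atol=1e-12)
            mine_b = adjust_pvalues(p, "bonferroni")
            assert np.allclose(mine_b, np.minimum(1, p * p.size), atol=0)

    def test_nans_excluded_from_m(self):
        out = adjust_pvalues([0.01, np.nan, 0.02], "bonferroni")
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(0.02)  # m = 2, not 3

    def test_bh_rank_monotone(self, rng):
        p = rng.random(200)
        adj = adjust_pvalues(p, "bh")
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestLMM:
    def test_boundary_equals_glm_with_singleton_groups(self, rng):
        n = 40
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = 0.1 * x + rng.normal(0, 0.2, n)
        groups = np.arange(n)  # one observation per subject
        lmm = fit_lmm_site(y, X, groups, 1)
        glm = fit_glm_site(y, X, 1)
        assert abs(lmm.estimate - glm.estimate) < 1e-6
        assert abs(lmm.se - glm.se) < 1e-6

    def test_paired_design_recovery(self, rng):
        n_subj, effect = 50, 0.03
        subj = np.repeat(np.arange(n_subj), 2)
        x = rng.normal(size=2 * n_subj)
        u = rng.normal(0, 0.1, n_subj)
        y = effect * x + u[subj] + rng.normal(0, 0.02, 2 * n_subj)
        X = np.column_stack([np.ones(2 * n_subj), x])
        fit = fit_lmm_site(y, X, subj, 1)
        assert abs(fit.estimate - effect) < 3 * fit.se
        assert fit.extra["var_group"] > fit.extra["var_resid"]

    def test_matches_statsmodels_mixedlm(self, rng):
        """Independent cross-check of the profiled-REML fitter."""
        import statsmodels.api as sm

        n_subj = 30
        subj = np.repeat(np.arange(n_subj), 3)
        x = rng.normal(size=3 * n_subj)
        y = 0.2 * x + rng.normal(0, 0.3, n_subj)[subj] + rng.normal(0, 0.1, 3 * n_subj)
        X = np.column_stack([np.ones(3 * n_subj), x])
        mine = fit_lmm_site(y, X, subj, 1)
        ref = sm.MixedLM(y, X, groups=subj).fit(reml=True)
        assert mine.estimate == pytest.approx(ref.params[1], abs=1e-5)
        assert mine.se == pytest.approx(ref.bse[1], abs=1e-5)

    def test_null_p_uniform(self, rng):
        """Paired null data: Wald p-values should be ~Uniform(0,1)."""
        n_subj = 40
        subj = np.repeat(np.arange(n_subj), 2)
        x = rng.normal(size=2 * n_subj)
        X = np.column_stack([np.ones(2 * n_subj), x])
        pvals = []
        for _ in range(300):
            y = rng.normal(0, 0.1, n_subj)[subj] + rng.normal(0, 0.1, 2 * n_subj)
            fit = fit_lmm_site(y, X, subj, 1)
            pvals.append(fit.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_fewer_than_two_groups_flagged(self, rng):
        n = 10
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        fit = fit_lmm_site(rng.normal(size=n), X, np.zeros(n), 1)
        assert not fit.converged


def _cox_partial_loglik(beta, time, event, x):
    """Brute-force partial log-likelihood (no ties)."""
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_matches_brute_force_oracle(self, rng):
        n = 20
        x = (rng.random(n) > 0.5).astype(float)
        if x.sum() in (0, n):
            x[0] = 1 - x[0]
        time = rng.exponential(1.0, n) + rng.random(n) * 1e-6  # distinct times
        event = np.ones(n)
        fit = fit_cox_site(time, event, x)
        res = optimize.minimize_scalar(
            lambda b: -_cox_partial_loglik(b, time, event, x), bounds=(-8, 8),
            method="bounded", options={"xatol": 1e-10},
        )
        assert fit.estimate == pytest.approx(res.x, abs=1e-4)

    def test_constant_methylation_flagged(self, rng):
        n = 12
        fit = fit_cox_site(rng.exponential(1, n), np.ones(n), np.full(n, 0.4))
        assert not fit.converged and "variation" in fit.reason

    def test_all_censored_errors(self, rng):
        n = 10
        with pytest.raises(ValueError, match="event"):
            fit_cox_site(rng.exponential(1, n), np.zeros(n), rng.random(n))

    def test_hr_is_exp_estimate_with_wald_ci(self, rng):
        n = 80
        x = rng.random(n)
        time = rng.exponential(np.exp(-1.0 * x))
        fit = fit_cox_site(time, np.ones(n), x)
        assert fit.extra["hr"] == pytest.approx(np.exp(fit.estimate), rel=1e-12)
        assert fit.extra["hr_low"] < fit.extra["hr"] < fit.extra["hr_high"]
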