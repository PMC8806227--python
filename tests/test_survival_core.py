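"""Survival estimators against hand computations and independent oracles."""

import numpy as np
import pytest
from scipy import stats

from pairhazard.errors import DomainError
from pairhazard.survival_core import (cox_fit, cox_log_partial_likelihood,
                                      km_estimate, logrank_test, optimal_cutoff,
                                      td_roc)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # events at 1 and 2 among 3 subjects: S = 2/3 then (2/3)(1/2) = 1/3
        km = km_estimate([1, 2, 3], [1, 1, 0])
        assert km.event_times.tolist() == [1, 2]
        assert km.survival == pytest.approx([2 / 3, 1 / 3])
        assert km.survival_at(3.0) == pytest.approx(1 / 3)

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert len(km.event_times) == 0
        assert km.survival_at(99.0) == 1.0

    def test_doubling_records_leaves_curve_unchanged(self):
        t, e = [2, 4, 5, 7], [1, 0, 1, 1]
        a = km_estimate(t, e)
        b = km_estimate(t * 2, e * 2)
        assert np.allclose(a.survival, b.survival)
        assert np.array_equal(a.event_times, b.event_times)

    def test_record_order_invariance(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 30) + 0.01
        e = rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        a, b = km_estimate(t, e), km_estimate(t[perm], e[perm])
        assert np.allclose(a.survival, b.survival)

    def test_left_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 0])
        assert km.survival_at(1.0, left=True) == 1.0
        assert km.survival_at(1.0) == pytest.approx(2 / 3)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t, e = [1, 2, 3, 4], [1, 0, 1, 1]
        res = logrank_test(t + t, e + e, [0] * 4 + [1] * 4)
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_hand_worked_six_subject_fixture(self):
        # groups A=(1+,3c,5+), B=(2+,4+,6c); '+'=event, 'c'=censored.
        # Per event time (O1-E1, V): t=1: (-1/2, 1/4); t=2: (2/5, 6/25);
        # t=4: (1/3, 2/9); t=5: (-1/2, 1/4).  Sum O-E = -4/15,
        # sum V = 433/450, chi2 = (4/15)^2 / (433/450) = 32/433.
        times = [1, 3, 5, 2, 4, 6]
        events = [1, 0, 1, 1, 1, 0]
        group = [0, 0, 0, 1, 1, 1]
        res = logrank_test(times, events, group)
        assert res.chi_square == pytest.approx(32 / 433, rel=1e-12)
        assert res.p_value == pytest.approx(stats.chi2.sf(32 / 433, 1), rel=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(3, 40) + 0.01
        e = rng.integers(0, 2, 40)
        g = rng.integers(0, 2, 40)
        assert logrank_test(t, e, g).chi_square == pytest.approx(
            logrank_test(t, e, 1 - g).chi_square)

    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            logrank_test([1, 2], [1, 1], [0, 0])


def _sim_cox(n, beta, seed, binary=True, censor=0.3):
    rng = np.random.default_rng(seed)
    x = (rng.binomial(1, 0.5, n) if binary else rng.normal(size=n)).astype(float)
    t = rng.exponential(1 / (0.1 * np.exp(beta * x)))
    c = rng.exponential(1 / (censor * 0.1), n)
    return np.minimum(t, c), (t <= c).astype(int), x


class TestCoxFit:
    def test_score_test_equals_logrank_on_binary_covariate(self):
        t, e, x = _sim_cox(80, 0.7, seed=4)
        assert len(np.unique(t)) == len(t)  # tie-free
        fit = cox_fit(t, e, x)
        lr = logrank_test(t, e, x.astype(int))
        assert fit.score_chi2 == pytest.approx(lr.chi_square, abs=1e-6)

    def test_parameter_recovery_within_3_se(self, study):
        # covariate = a planted latent state; its true log-hazard is known
        (expr1, clin1), _ = study.cohorts
        z = study.truth.z[0].iloc[0].to_numpy(dtype=float)
        fit = cox_fit(clin1.os_time, clin1.os_event, z)
        beta_true = study.truth.betas[0]
        assert abs(fit.coefficients[0] - beta_true) < 3 * fit.standard_errors[0]

    def test_matches_lifelines_on_two_covariates(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        t, e, x = _sim_cox(150, 0.5, seed=9)
        x2 = np.random.default_rng(10).normal(size=150)
        fit = cox_fit(t, e, np.column_stack([x, x2]))
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x, "x2": x2}), "t", "e")
        assert fit.coefficients == pytest.approx(cph.params_.to_numpy(), abs=1e-5)
        assert fit.standard_errors == pytest.approx(
            cph.standard_errors_.to_numpy(), abs=1e-5)
        assert fit.log_partial_likelihood == pytest.approx(
            cph.log_likelihood_, abs=1e-6)

    def test_all_censored_flagged_degenerate(self):
        fit = cox_fit([1, 2, 3], [0, 0, 0], [0.0, 1.0, 2.0])
        assert not fit.converged and "no events" in fit.note

    def test_constant_covariate_flagged(self):
        fit = cox_fit([1, 2, 3, 4], [1, 1, 0, 1], [2.0, 2.0, 2.0, 2.0])
        assert not fit.converged

    def test_breslow_equals_efron_without_ties(self):
        t, e, x = _sim_cox(60, 0.8, seed=5)
        fe = cox_fit(t, e, x, ties="efron")
        fb = cox_fit(t, e, x, ties="breslow")
        assert fe.coefficients == pytest.approx(fb.coefficients, abs=1e-9)
        assert fe.log_partial_likelihood == pytest.approx(
            fb.log_partial_likelihood, abs=1e-9)

    def test_wald_ci_is_exp_of_coef_pm_1p96_se(self):
        t, e, x = _sim_cox(100, 0.6, seed=6)
        fit = cox_fit(t, e, x)
        lo = np.exp(fit.coefficients - 1.959963984540054 * fit.standard_errors)
        assert fit.ci_lower == pytest.approx(lo)
        assert fit.hazard_ratios == pytest.approx(np.exp(fit.coefficients))

    def test_fixed_beta_loglik_matches_fit_optimum(self):
        t, e, x = _sim_cox(70, 0.5, seed=8)
        fit = cox_fit(t, e, x, ties="breslow")
        ll = cox_log_partial_likelihood(fit.coefficients, t, e, x, ties="breslow")
        assert ll == pytest.approx(fit.log_partial_likelihood, abs=1e-9)
        # any other beta has lower partial likelihood (optimum check)
        assert cox_log_partial_likelihood(fit.coefficients + 0.3, t, e, x,
                                          ties="breslow") < ll


class TestTdROC:
    def test_auc_equals_mann_whitney_without_censoring(self):
        rng = np.random.default_rng(11)
        n = 20
        t = rng.exponential(5, n) + 0.01
        e = np.ones(n, dtype=int)
        m = rng.normal(size=n)
        h = float(np.median(t))
        roc = td_roc(t, e, m, h)
        cases, ctrls = m[t <= h], m[t > h]
        conc = np.mean([(a > b) + 0.5 * (a == b) for a in cases for b in ctrls])
        assert roc.auc == pytest.approx(conc, abs=1e-12)

    def test_matches_sksurv_under_censoring(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        from sksurv.util import Surv
        rng = np.random.default_rng(12)
        n = 150
        t, e, x = _sim_cox(n, 1.0, seed=12, binary=False)
        m = x + rng.normal(0, 0.5, n)
        y = Surv.from_arrays(e.astype(bool), t)
        h = float(np.quantile(t, 0.4))
        auc_sk, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, m, [h])
        assert td_roc(t, e, m, h).auc == pytest.approx(auc_sk[0], abs=1e-10)

    def test_perfect_marker_gives_auc_one(self):
        t = np.array([1, 2, 3, 11, 12, 13], dtype=float)
        e = np.ones(6, dtype=int)
        m = np.array([9, 8, 7, 1, 2, 3], dtype=float)  # separates cases/controls
        roc = td_roc(t, e, m, horizon=5.0)
        assert roc.auc == 1.0

    def test_null_marker_auc_near_half(self):
        rng = np.random.default_rng(13)
        n = 400
        t = rng.exponential(5, n) + 0.01
        e = rng.binomial(1, 0.7, n)
        m = rng.normal(size=n)  # independent of outcome
        roc = td_roc(t, e, m, float(np.median(t)))
        assert abs(roc.auc - 0.5) < 0.08

    def test_no_cases_raises_naming_horizon(self):
        with pytest.raises(DomainError, match="0.5"):
            td_roc([1, 2, 3], [1, 1, 1], [1.0, 2.0, 3.0], horizon=0.5)

    def test_positive_affine_marker_transform_invariance(self):
        t, e, x = _sim_cox(100, 0.8, seed=14)
        h = float(np.quantile(t, 0.5))
        a = td_roc(t, e, x, h)
        b = td_roc(t, e, 3.5 * x + 7.0, h)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert np.allclose(a.tpr, b.tpr)

    def test_monotone_curves_and_range(self):
        t, e, x = _sim_cox(120, 0.6, seed=15)
        roc = td_roc(t, e, x, float(np.quantile(t, 0.5)))
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)
        assert 0.0 <= roc.auc <= 1.0


class TestOptimalCutoff:
    def test_separating_marker_cutoff_in_gap(self):
        t = np.array([1, 2, 3, 11, 12, 13], dtype=float)
        e = np.ones(6, dtype=int)
        m = np.array([7, 8, 9, 1, 2, 3], dtype=float)
        cut = optimal_cutoff(td_roc(t, e, m, horizon=5.0))
        assert 3.0 < cut < 7.0

    def test_known_youden_maximizer(self):
        # markers .1-.6; cases at .2,.4,.5,.6; controls at .1,.3; horizon 10.
        # Exhaustive J over midpoints: J(.35) = 3/4 is the unique maximum.
        t = np.array([15, 5, 15, 5, 5, 5], dtype=float)
        e = np.ones(6, dtype=int)
        m = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        roc = td_roc(t, e, m, horizon=10.0)
        # independent brute-force oracle over all candidate thresholds
        cases, ctrls = m[t <= 10], m[t > 10]
        grid = (np.sort(np.unique(m))[:-1] + np.sort(np.unique(m))[1:]) / 2
        j = [np.mean(cases > c) - np.mean(ctrls > c) for c in grid]
        assert grid[int(np.argmax(j))] == pytest.approx(0.35)
        assert optimal_cutoff(roc) == pytest.approx(0.35)

    def test_null_roc_cutoff_near_marker_median(self):
        rng = np.random.default_rng(16)
        n = 300
        t = rng.exponential(5, n) + 0.01
        e = np.ones(n, dtype=int)
        m = rng.normal(size=n)
        roc = td_roc(t, e, m, float(np.median(t)))
        med = float(np.median(m))
        assert abs(optimal_cutoff(roc) - med) < np.std(m)
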