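"""Kaplan-Meier, log-rank and the Cox engine against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import optimize

from screenbias.survival import (RankDeficiencyError, build_design, fit_cox,
                                 km_estimate, logrank_test,
                                 schoenfeld_residuals, SIM_MODEL_SPEC)


# ---------------------------------------------------------------------------
# Independent oracles (naive loops, no shared code with the engine)

def naive_partial_loglik(beta, time, event, X, ties):
    """Explicit Efron/Breslow partial likelihood via risk-set loops."""
    beta = np.atleast_1d(beta)
    ll = 0.0
    for t in sorted(set(time[event])):
        dead = np.flatnonzero(event & (time == t))
        risk = np.flatnonzero(time >= t)
        eta_dead = X[dead] @ beta
        w_risk = np.exp(X[risk] @ beta)
        w_dead = np.exp(eta_dead)
        d = len(dead)
        ll += eta_dead.sum()
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            ll -= np.log(w_risk.sum() - frac * w_dead.sum())
    return ll


def brute_force_cox(time, event, X, ties):
    res = optimize.minimize(
        lambda b: -naive_partial_loglik(b, time, event, X, ties),
        x0=np.zeros(X.shape[1]), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return res.x


def naive_logrank(time, event, groups):
    """Two-group observed-minus-expected tabulation over risk sets."""
    labels = sorted(set(groups))
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(time[event])):
        at_risk = time >= t
        dead = event & (time == t)
        n = at_risk.sum()
        d = dead.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d1 = (dead & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        curve = km_estimate([1.0, 2.0, 3.0], [True, True, False])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 1 / 3])
        assert curve.survival_at(0.5) == 1.0
        assert curve.survival_at(2.5) == pytest.approx(1 / 3)

    def test_no_events_flat_curve_median_undefined(self):
        curve = km_estimate([5.0, 6.0, 7.0], [False, False, False])
        assert np.all(curve.survival == 1.0)
        assert np.isnan(curve.median)

    def test_censoring_free_equals_empirical_survival(self, rng):
        times = rng.exponential(100, size=40)
        curve = km_estimate(times, np.ones(40, dtype=bool))
        grid = np.sort(times)
        empirical = 1.0 - np.arange(1, 41) / 40
        assert np.allclose(curve.survival_at(grid), empirical)

    def test_monotone_and_bounded(self, rng):
        times = rng.exponential(50, 100)
        events = rng.random(100) < 0.6
        curve = km_estimate(times, events)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))
        assert np.all(np.diff(curve.at_risk) <= 0)
        assert np.all(curve.greenwood_var >= 0)

    def test_median_is_smallest_time_below_half(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.median == 2.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1], dtype=bool)
        g = np.r_[np.zeros(4), np.ones(4)]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_tabulation(self):
        t = np.array([1.0, 3, 5, 2, 4, 6])
        e = np.ones(6, dtype=bool)
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(naive_logrank(t, e, g), rel=1e-10)
        assert res.df == 1

    def test_permutation_reference(self, rng):
        """Chi-square p agrees with the exhaustive permutation p at small n."""
        t = np.array([1.0, 2, 3, 9, 10, 11, 12, 13])
        e = np.ones(8, dtype=bool)
        g_obs = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        stat_obs = logrank_test(t, e, g_obs).statistic
        stats = []
        for idx in itertools.combinations(range(8), 4):
            g = np.zeros(8, dtype=int)
            g[list(idx)] = 1
            stats.append(naive_logrank(t, e, g))
        perm_p = np.mean(np.asarray(stats) >= stat_obs - 1e-9)
        chi2_p = logrank_test(t, e, g_obs).p_value
        assert abs(perm_p - chi2_p) < 0.12

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [True, True], ["a", "a"])


TINY_FIXTURES = [
    # (time, event, X) with n <= 10; mixtures of ties and censoring
    (np.array([3.0, 1, 2, 5, 4, 8, 7, 6]),
     np.array([1, 1, 1, 0, 1, 1, 0, 1], bool),
     np.array([[0.0], [1], [1], [0], [1], [0], [1], [0]])),
    (np.array([2.0, 2, 2, 4, 4, 6, 7, 9]),       # heavy ties
     np.array([1, 1, 0, 1, 1, 1, 0, 1], bool),
     np.array([[1.0], [0], [1], [0], [1], [0], [1], [0]])),
    (np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10]),
     np.array([1, 0, 1, 1, 0, 1, 1, 0, 1, 1], bool),
     np.column_stack([[1, 0, 1, 0, 1, 0, 1, 0, 1, 0],
                      [0.2, -1.0, 0.5, 0.0, 1.2, -0.3, 0.8, 0.1, -0.7, 0.4]])),
]


class TestCoxEngine:
    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    @pytest.mark.parametrize("fixture", range(len(TINY_FIXTURES)))
    def test_matches_brute_force_oracle(self, fixture, ties):
        """Engine beta equals naive partial-likelihood maximisation to 1e-6."""
        t, e, X = TINY_FIXTURES[fixture]
        fit = fit_cox(t, e, X, ties=ties)
        oracle = brute_force_cox(t, e, X, ties)
        assert np.max(np.abs(fit.beta - oracle)) < 1e-6
        ll_fit = naive_partial_loglik(fit.beta, t, e, X, ties)
        assert fit.loglik == pytest.approx(ll_fit, abs=1e-8)

    def test_exchangeable_halves_give_null_beta(self):
        t = np.tile([1.0, 2, 3, 4, 5], 2)
        e = np.tile([1, 1, 0, 1, 1], 2).astype(bool)
        x = np.r_[np.zeros(5), np.ones(5)][:, None]
        fit = fit_cox(t, e, x)
        assert abs(fit.beta[0]) < 1e-8

    def test_breslow_equals_efron_without_ties(self, rng):
        t = rng.exponential(10, 50)
        e = rng.random(50) < 0.7
        X = (rng.random((50, 3)) < 0.5).astype(float)
        fa = fit_cox(t, e, X, ties="efron")
        fb = fit_cox(t, e, X, ties="breslow")
        assert np.allclose(fa.beta, fb.beta, atol=1e-9)
        assert fa.loglik == pytest.approx(fb.loglik, abs=1e-9)

    def test_hr_and_ci_consistency(self, rng):
        t = rng.exponential(10, 200)
        e = rng.random(200) < 0.7
        X = (rng.random((200, 2)) < 0.5).astype(float)
        fit = fit_cox(t, e, X, names=["a", "b"])
        assert np.allclose(fit.hr, np.exp(fit.beta))
        assert np.all(fit.ci_low < fit.hr) and np.all(fit.hr < fit.ci_high)
        assert fit.converged
        row = fit["a"]
        assert row["hr"] == pytest.approx(float(fit.hr[0]))

    def test_agrees_with_lifelines_cross_check(self, rng):
        """Independent implementation comparison on tied day-scale data."""
        from lifelines import CoxPHFitter
        import pandas as pd
        n = 400
        X = (rng.random((n, 3)) < 0.5).astype(float)
        t = np.ceil(rng.exponential(1 / (0.01 * np.exp(X @ [0.5, -0.4, 0.2]))))
        c = np.ceil(rng.exponential(300, n))
        e = t <= c
        tt = np.minimum(t, c)
        fit = fit_cox(tt, e, X, ties="efron")
        df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        df["T"], df["E"] = tt, e.astype(int)
        cph = CoxPHFitter()
        cph.fit(df, "T", "E")
        assert np.allclose(fit.beta, cph.params_.values, atol=1e-5)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-6)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            fit_cox([1.0, 2.0], [False, False], np.ones((2, 1)))

    def test_rank_deficiency_reported(self, rng):
        t = rng.exponential(10, 30)
        e = np.ones(30, bool)
        x = (rng.random(30) < 0.5).astype(float)
        X = np.column_stack([x, x])  # duplicated column
        with pytest.raises(RankDeficiencyError):
            fit_cox(t, e, X, names=["a", "a_copy"])

    def test_perfect_separation_flagged_not_silent(self):
        # covariate = indicator of the earliest half of event times
        t = np.arange(1.0, 21)
        e = np.ones(20, bool)
        x = (t <= 10).astype(float)[:, None]
        fit = fit_cox(t, e, x)
        assert not fit.converged
        assert any("monotone likelihood" in f or "iteration budget" in f
                   for f in fit.flags)

    def test_design_builder_reference_levels(self, tiny_cohort):
        X, names = build_design(tiny_cohort, SIM_MODEL_SPEC)
        assert "stage_I" not in names          # reference level dropped
        assert {"stage_II", "stage_III", "stage_IV", "screened",
                "region_XF", "sex_male"} <= set(names)
        assert X.shape == (len(tiny_cohort), len(names))


class TestSchoenfeld:
    @staticmethod
    def _fit_and_residuals(t, e, X):
        fit = fit_cox(t, e, X)
        return fit, schoenfeld_residuals(fit, t, e, X)

    def test_residuals_sum_to_zero_at_mle(self, rng):
        t = rng.exponential(5, 150)
        e = rng.random(150) < 0.7
        X = (rng.random((150, 2)) < 0.5).astype(float)
        _, res = self._fit_and_residuals(t, e, X)
        assert np.allclose(res.residuals.sum(axis=0), 0.0, atol=1e-6)
        assert res.residuals.shape[0] == int(e.sum())

    def test_type_one_error_rate_under_proportional_hazards(self):
        """~5% of covariates flagged when the model is well specified."""
        flagged = total = 0
        for s in range(100):
            r = np.random.default_rng(300 + s)
            n = 150
            X = (r.random((n, 2)) < 0.5).astype(float)
            t = r.exponential(1 / (0.1 * np.exp(X @ [0.4, -0.3])))
            c = r.exponential(20, n)
            e = t <= c
            fit = fit_cox(np.minimum(t, c), e, X)
            res = schoenfeld_residuals(fit, np.minimum(t, c), e, X)
            flagged += int(np.sum(res.p < 0.05))
            total += 2
        assert 0.01 <= flagged / total <= 0.10

    def test_sign_reversing_effect_detected(self):
        """A hazard effect that flips sign mid-follow-up violates PH."""
        detected = 0
        for s in range(20):
            r = np.random.default_rng(900 + s)
            n = 600
            x = (r.random(n) < 0.5).astype(float)
            t0 = 2.0
            t1 = r.exponential(1 / (0.5 * np.exp(1.2 * x)))
            t2 = t0 + r.exponential(1 / (0.5 * np.exp(-1.2 * x)))
            t = np.where(t1 < t0, t1, t2)
            e = np.ones(n, bool)
            fit = fit_cox(t, e, x[:, None])
            res = schoenfeld_residuals(fit, t, e, x[:, None])
            detected += int(res.p[0] < 0.05)
        assert detected >= 16

    def test_too_few_events_flagged_undefined(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.array([1, 1, 0, 0], bool)
        x = np.array([[0.5], [0.2], [1.0], [0.0]])
        fit = fit_cox(t, e, x, check_rank=False)
        res = schoenfeld_residuals(fit, t, e, x)
        assert not res.defined
        assert np.isnan(res.p).all()
        assert res.violated()[fit.names[0]] is None
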