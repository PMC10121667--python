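"""Kaplan–Meier, log-rank, Cox PH fitting and diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from tmakit.exceptions import EstimationError, ParameterError
from tmakit.survival import (
    cox_score_test,
    fit_cox,
    km_estimate,
    logrank,
    loo_influence,
    ph_supremum_test,
    posthoc_power,
    tertile_categorize,
)
from tmakit.synthetic import CohortSimConfig, simulate_cohort

COVARIATES = ["age", "stage", "grade", "debulking", "family_history",
              "cd8_density", "caix_density"]


def censored_fixture(seed=0, n=60):
    rng = np.random.default_rng(seed)
    t = rng.exponential(10.0, size=n)
    c = rng.exponential(14.0, size=n)
    return np.minimum(t, c), (t <= c).astype(int)


# ---------------------------------------------------------------------------
# Kaplan–Meier


class TestKaplanMeier:
    def test_no_events_means_flat_survival(self):
        out = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])["0"]
        assert out.empty  # no event times -> S(t) stays at 1 throughout

    def test_three_events_closed_form(self):
        out = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])["0"]
        np.testing.assert_allclose(out["survival"], [2 / 3, 1 / 3, 0.0])

    def test_matches_risk_set_enumeration_oracle(self):
        times, events = censored_fixture(seed=3)
        got = km_estimate(times, events)["0"]
        # independent oracle: explicit risk-set product over event times
        surv = 1.0
        expected = []
        for tk in sorted(set(times[events == 1])):
            n_risk = int((times >= tk).sum())
            d = int(((times == tk) & (events == 1)).sum())
            surv *= 1 - d / n_risk
            expected.append((tk, surv))
        np.testing.assert_allclose(got["time"], [t for t, _ in expected])
        np.testing.assert_allclose(got["survival"], [s for _, s in expected])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        times, events = censored_fixture(seed=4)
        got = km_estimate(times, events)["0"]
        kmf = KaplanMeierFitter().fit(times, events)
        sf = kmf.survival_function_at_times(got["time"]).to_numpy()
        np.testing.assert_allclose(got["survival"], sf, atol=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5.0, size=40)
        out = km_estimate(t, np.ones(40, dtype=int))["0"]
        for tk, s in zip(out["time"], out["survival"]):
            assert s == pytest.approx((t > tk).mean())

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            km_estimate([1.0], [1, 0])


# ---------------------------------------------------------------------------
# log-rank


class TestLogrank:
    def test_identical_groups_give_zero(self):
        times, events = censored_fixture(seed=6, n=30)
        t2 = np.concatenate([times, times])
        e2 = np.concatenate([events, events])
        g = np.repeat([0, 1], 30)
        res = logrank(t2, e2, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.df == 1

    def test_single_group_rejected(self):
        with pytest.raises(ParameterError):
            logrank([1.0, 2.0], [1, 1], [0, 0])

    def test_hand_computed_hypergeometric_tally(self):
        # two groups, no ties: tally O-E and V per event time by hand
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 0])
        groups = np.array([0, 1, 0, 1, 0, 1])
        O = E = V = 0.0
        for tk in [1.0, 2.0, 4.0, 5.0]:
            at_risk = times >= tk
            n = at_risk.sum()
            n1 = ((groups == 0) & at_risk).sum()
            d1 = float(((times == tk) & (events == 1) & (groups == 0)).sum())
            O += d1
            E += n1 / n
            V += (n1 / n) * (1 - n1 / n)  # d=1, (n-d)/(n-1) = 1
        expected_chi2 = (O - E) ** 2 / V
        res = logrank(times, events, groups)
        assert res.chi2 == pytest.approx(expected_chi2)

    def test_type_i_error_near_nominal(self):
        """Two groups simulated at HR = 1 reject at ~5% (alpha = 0.05)."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            t = rng.exponential(10.0, size=80)
            c = rng.exponential(15.0, size=80)
            g = np.repeat([0, 1], 40)
            res = logrank(np.minimum(t, c), (t <= c).astype(int), g)
            rejections += res.p_value < 0.05
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07

    def test_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        times, events = censored_fixture(seed=8, n=90)
        g = np.repeat([0, 1, 2], 30)
        res = logrank(times, events, g)
        ll = multivariate_logrank_test(times, g, events)
        assert res.chi2 == pytest.approx(ll.test_statistic)
        assert res.df == 2


# ---------------------------------------------------------------------------
# tertiles


class TestTertiles:
    def test_1_to_100_gives_34_32_34(self):
        labels = tertile_categorize(np.arange(1.0, 101.0))
        counts = pd.Series(labels).value_counts()
        assert counts["low"] == 34
        assert counts["moderate"] == 32
        assert counts["high"] == 34

    def test_all_zeros_single_category_with_warning(self):
        with pytest.warns(UserWarning, match="single category"):
            labels = tertile_categorize(np.zeros(10))
        assert set(labels) == {"low"}

    def test_monotone_transform_keeps_labels(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        a = tertile_categorize(x)
        b = tertile_categorize(np.exp(x))
        assert list(a) == list(b)


# ---------------------------------------------------------------------------
# Cox PH


class TestCoxFit:
    def test_two_subject_partial_likelihood_closed_form(self):
        """With 2 subjects and a binary covariate the partial likelihood
        is l(b) = b - log(exp(b) + 1): the implementation must reproduce
        it (and its derivatives) and flag the monotone likelihood."""
        from tmakit.survival import _cox_loglik

        X = np.array([[1.0], [0.0]])
        times = np.array([1.0, 2.0])
        events = np.array([1, 1])
        for b in (-1.0, 0.0, 0.7, 2.5):
            ll, grad, info = _cox_loglik(np.array([b]), X, times, events, "efron")
            eb = math.exp(b)
            # analytic: first event contributes b - log(eb + 1), second 0
            assert ll == pytest.approx(b - math.log(eb + 1))
            assert grad[0] == pytest.approx(1 - eb / (eb + 1))
            assert info[0, 0] == pytest.approx(eb / (eb + 1) ** 2)
        df = pd.DataFrame({"time": times, "event": events, "x": X[:, 0]})
        fit = fit_cox(df, ["x"])
        assert fit.flagged is not None  # separation: no finite MLE

    def test_zero_variance_covariate_rejected(self):
        df = pd.DataFrame(
            {"time": [1.0, 2, 3, 4], "event": [1, 0, 1, 1], "x": [2.0] * 4}
        )
        with pytest.raises(ParameterError, match="x"):
            fit_cox(df, ["x"])

    def test_zero_events_rejected(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]}
        )
        with pytest.raises(EstimationError, match="event"):
            fit_cox(df, ["x"])

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_lifelines_without_ties(self, ties):
        # with continuous times there are no ties, so Efron == Breslow
        # and both must agree with lifelines' Efron implementation
        df = simulate_cohort(CohortSimConfig(n_subjects=250, seed=10))
        fit = fit_cox(df, COVARIATES, ties=ties)
        from lifelines import CoxPHFitter

        from tmakit.survival import build_design

        X = build_design(df, COVARIATES)
        X["time"], X["event"] = df["time"], df["event"]
        cph = CoxPHFitter().fit(X, "time", "event")
        np.testing.assert_allclose(
            fit.params.to_numpy(),
            cph.params_[fit.params.index].to_numpy(),
            atol=2e-4,
        )
        np.testing.assert_allclose(
            fit.bse.to_numpy(),
            cph.standard_errors_[fit.params.index].to_numpy(),
            atol=1e-4,
        )

    def test_efron_handles_ties_like_lifelines(self):
        rng = np.random.default_rng(11)
        n = 120
        df = pd.DataFrame(
            {
                "time": rng.integers(1, 15, size=n).astype(float),  # many ties
                "event": rng.integers(0, 2, size=n),
                "x": rng.normal(size=n),
                "z": rng.normal(size=n),
            }
        )
        fit = fit_cox(df, ["x", "z"], ties="efron")
        from lifelines import CoxPHFitter

        cph = CoxPHFitter().fit(df[["time", "event", "x", "z"]], "time", "event")
        np.testing.assert_allclose(
            fit.params.to_numpy(), cph.params_[["x", "z"]].to_numpy(), atol=2e-4
        )

    def test_martingale_residuals_sum_to_zero(self):
        df = simulate_cohort(CohortSimConfig(n_subjects=300, seed=12))
        fit = fit_cox(df, COVARIATES)
        assert abs(fit.residuals["martingale"].sum()) < 1e-6

    def test_score_test_equals_logrank_chi2(self):
        # two-group comparison, no ties, Breslow: score test == log-rank
        times, events = censored_fixture(seed=13, n=80)
        g = np.repeat([0.0, 1.0], 40)
        df = pd.DataFrame({"time": times, "event": events, "g": g})
        chi2_score, _ = cox_score_test(df, ["g"], ties="breslow")
        chi2_lr = logrank(times, events, g).chi2
        assert chi2_score == pytest.approx(chi2_lr, rel=1e-10)

    def test_parameter_recovery_bias_small(self):
        """Coefficients are recovered without material bias over 200
        synthetic cohorts at n = 500.

        The Cox partial-likelihood MLE carries a small O(1/n)
        away-from-zero bias that 200 replicates can resolve, so each
        coefficient must satisfy either |bias| < 2 Monte Carlo SEs or a
        standardized bias (bias / sampling SD) below 25% — the usual
        simulation-study negligibility criterion.
        """
        truth = CohortSimConfig().log_hazard_coefs
        rows = []
        for seed in range(200):
            df = simulate_cohort(CohortSimConfig(n_subjects=500, seed=seed))
            fit = fit_cox(df, COVARIATES)
            rows.append(fit.params)
        est = pd.DataFrame(rows)
        for col in est.columns:
            bias = est[col].mean() - truth[col]
            sd = est[col].std(ddof=1)
            mc_se = sd / math.sqrt(len(est))
            assert abs(bias) < 2 * mc_se or abs(bias) / sd < 0.25, col

    def test_hr_ci_ordering(self):
        df = simulate_cohort(CohortSimConfig(n_subjects=200, seed=14))
        fit = fit_cox(df, COVARIATES)
        ci = fit.confint()
        assert (ci["hr_lo"] <= fit.hazard_ratios).all()
        assert (fit.hazard_ratios <= ci["hr_hi"]).all()


# ---------------------------------------------------------------------------
# leave-one-out influence


class TestLooInfluence:
    def test_removing_one_of_two_copies_is_unremarkable(self):
        # a subject whose exact covariate/outcome copy stays in the data
        # cannot stand out of the influence ranking, and is never flagged
        df = simulate_cohort(CohortSimConfig(n_subjects=40, seed=15))
        df2 = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        fit = fit_cox(df2, ["age", "cd8_density", "caix_density"])
        infl = loo_influence(fit)
        assert not infl.loc[0, "flagged"]
        assert infl.loc[0, "max_std_delta"] <= infl["max_std_delta"].max()
        assert infl.loc[0, "max_std_delta"] < 3.0

    def test_duplicated_dataset_flags_nobody(self):
        df = simulate_cohort(CohortSimConfig(n_subjects=35, seed=16))
        df2 = pd.concat([df, df], ignore_index=True)
        fit = fit_cox(df2, ["age", "cd8_density", "caix_density"])
        infl = loo_influence(fit)
        assert not infl["flagged"].any()

    def test_implanted_outlier_has_largest_influence(self):
        """A subject with an extreme implanted density and discordant
        outcome dominates the leave-one-out deltas in >= 95% of seeds."""
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            df = simulate_cohort(CohortSimConfig(n_subjects=40, seed=100 + seed))
            df = df.reset_index(drop=True)
            # extreme CD8 density with an early event: high influence
            df.loc[0, "cd8_density"] = df["cd8_density"].max() * 8
            df.loc[0, "time"] = df["time"].quantile(0.02) + 1e-3
            df.loc[0, "event"] = 1
            fit = fit_cox(df, ["age", "cd8_density", "caix_density"])
            infl = loo_influence(fit)
            hits += infl["max_std_delta"].idxmax() == 0
        assert hits >= 0.95 * n_rep


# ---------------------------------------------------------------------------
# PH supremum test


def simulate_tv_effect(rng, n=200, b1=1.0, b2=-1.0, tau=10.0, lam=0.04):
    """Piecewise-constant covariate effect: beta(t) switches at tau."""
    x = rng.integers(0, 2, size=n).astype(float)
    e = rng.exponential(size=n)
    h1 = lam * np.exp(b1 * x)
    t = e / h1
    late = t > tau
    t[late] = tau + (e[late] - h1[late] * tau) / (lam * np.exp(b2 * x[late]))
    c = rng.uniform(5.0, 40.0, size=n)
    return pd.DataFrame(
        {"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x}
    )


class TestPhSupremumTest:
    def test_p_values_in_unit_interval(self):
        df = simulate_cohort(CohortSimConfig(n_subjects=150, seed=17))
        fit = fit_cox(df, ["age", "cd8_density"])
        out = ph_supremum_test(fit, n_sim=300, seed=1)
        assert ((out["p_value"] >= 0) & (out["p_value"] <= 1)).all()

    def test_size_under_proportional_hazards(self):
        """Under a PH-respecting model the test rejects at ~5%."""
        rng = np.random.default_rng(18)
        rejections = 0
        n_rep = 200
        for k in range(n_rep):
            x = rng.normal(size=120)
            t = np.random.default_rng(k).exponential(
                10.0 / np.exp(0.3 * x)
            )
            c = np.full(120, np.quantile(t, 0.8))
            df = pd.DataFrame(
                {"time": np.minimum(t, c), "event": (t <= c).astype(int),
                 "x": x}
            )
            fit = fit_cox(df, ["x"])
            p = ph_supremum_test(fit, n_sim=500, rng=rng)["p_value"]["x"]
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.015 <= rate <= 0.10

    def test_power_against_time_varying_effect(self):
        rng = np.random.default_rng(19)
        pvals = []
        for _ in range(50):
            df = simulate_tv_effect(rng)
            fit = fit_cox(df, ["x"])
            pvals.append(ph_supremum_test(fit, n_sim=300, rng=rng)["p_value"]["x"])
        assert np.median(pvals) < 0.05


# ---------------------------------------------------------------------------
# post-hoc power


class TestPosthocPower:
    def test_null_effect_gives_alpha_level_power(self):
        power = posthoc_power(
            n=120, log_hr=0.0, covariate_sd=1.0, event_rate=0.6,
            alpha=0.05, n_sim=500, seed=20,
        )
        assert 0.02 <= power <= 0.09

    def test_huge_effect_gives_full_power(self):
        power = posthoc_power(
            n=100, log_hr=3.0, covariate_sd=1.0, event_rate=0.7,
            n_sim=200, seed=21,
        )
        assert power > 0.99

    def test_monotone_in_n_at_default_truth(self):
        """At the default truth (log-HR -0.026, CD8 sd ~ 15, ~50% events)
        power is a nontrivial, increasing function of n."""
        powers = [
            posthoc_power(n=n, log_hr=-0.026, covariate_sd=15.0,
                          event_rate=0.5, n_sim=400, seed=22)
            for n in (60, 154, 400)
        ]
        assert 0.05 < powers[0] < 1.0
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] > powers[0]

    def test_zero_event_rate_rejected(self):
        with pytest.raises(ParameterError):
            posthoc_power(n=50, log_hr=0.1, covariate_sd=1.0, event_rate=0.0)
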