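import numpy as np
import pandas as pd
import pytest

import herbsurv as h
from herbsurv.errors import DataError
from herbsurv.survival_stats import (
    cause_specific_subset,
    cox_fit,
    km_estimate,
    logrank_test,
    run_mortality_analysis,
)

COVS = ["chm", "age_30_40", "age_ge40", "female", "cci_1_2", "cci_ge3"]


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert list(km.at_risk) == [3, 2, 1]
        # Greenwood by hand: S^2 * sum d/(n(n-d))
        assert km.greenwood_var[0] == pytest.approx((2 / 3) ** 2 * (1 / 6))
        assert km.greenwood_var[1] == pytest.approx(
            (1 / 3) ** 2 * (1 / 6 + 1 / 2))

    def test_all_censored_is_unit_survival(self):
        km = km_estimate([5, 8, 13], [0, 0, 0])
        assert len(km.event_times) == 0
        assert km.survival_at(100.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 50, size=200).astype(float)
        km = km_estimate(t, np.ones(200))
        for u in np.unique(t):
            assert km.survival_at(u) == pytest.approx(np.mean(t > u))

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        df = h.simulate_survival_frame(200, seed=2)
        km = km_estimate(df["time"], df["event"])
        kmf = lifelines.KaplanMeierFitter().fit(df["time"], df["event"])
        sf = kmf.survival_function_.iloc[:, 0]
        for t in km.event_times:
            assert km.survival_at(t) == pytest.approx(sf.loc[t], abs=1e-12)

    def test_rejects_nonpositive_times(self):
        with pytest.raises(DataError):
            km_estimate([0, 1], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        chi2, p = logrank_test(t + t, e + e, [0] * 5 + [1] * 5)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        df = h.simulate_survival_frame(300, seed=4)
        a = logrank_test(df["time"], df["event"], df["chm"])
        b = logrank_test(df["time"], df["event"], 1 - df["chm"])
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_matches_lifelines(self):
        stats_mod = pytest.importorskip("lifelines.statistics")
        df = h.simulate_survival_frame(250, seed=5)
        chi2, p = logrank_test(df["time"], df["event"], df["chm"])
        g0 = df[df["chm"] == 0]
        g1 = df[df["chm"] == 1]
        ref = stats_mod.logrank_test(g0["time"], g1["time"],
                                     g0["event"], g1["event"])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-10)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_power_under_strong_planted_effect(self):
        """At the matched-cohort scale (266 users vs 532 controls) a
        hazard ratio of 0.3 is detected at p < 0.01 in >= 95% of runs."""
        rng = np.random.default_rng(6)
        hits = 0
        reps = 200
        for _ in range(reps):
            n1, n0 = 266, 532
            lam = 2.0e-4
            t0 = rng.exponential(1 / lam, size=n0)
            t1 = rng.exponential(1 / (lam * 0.3), size=n1)
            t = np.concatenate([t0, t1])
            c = rng.uniform(500, 3000, size=n0 + n1)
            time = np.maximum(1.0, np.minimum(t, c))
            event = t <= c
            g = np.r_[np.zeros(n0), np.ones(n1)]
            _, p = logrank_test(time, event, g)
            hits += p < 0.01
        assert hits / reps >= 0.95

    def test_one_group_empty_rejected(self):
        with pytest.raises(DataError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCox:
    def test_two_group_rate_ratio_recovered(self):
        rng = np.random.default_rng(7)
        n = 5000
        g = rng.integers(0, 2, size=n)
        t = rng.exponential(1 / (0.001 * 2.0**g))
        c = rng.uniform(200, 4000, size=n)
        df = pd.DataFrame({
            "time": np.minimum(t, c), "event": t <= c, "g": g})
        fit = cox_fit(df, ["g"])
        se = np.sqrt(fit.covariance[0, 0])
        assert abs(fit.coefficients["g"] - np.log(2.0)) < 3 * se

    def test_permuted_covariate_is_null(self):
        rng = np.random.default_rng(8)
        df = h.simulate_survival_frame(2000, seed=8)
        df["noise"] = rng.permutation(df["chm"].to_numpy())
        fit = cox_fit(df, ["noise"])
        se = np.sqrt(fit.covariance[0, 0])
        assert abs(fit.coefficients["noise"]) < 3.5 * se

    @pytest.mark.parametrize("tie_scale", [None, 30.0])
    def test_matches_lifelines(self, tie_scale):
        lifelines = pytest.importorskip("lifelines")
        df = h.simulate_survival_frame(300, seed=3)
        if tie_scale:  # coarsen times to force heavy ties
            df["time"] = np.ceil(df["time"] / tie_scale)
        fit = cox_fit(df, COVS)
        cph = lifelines.CoxPHFitter()
        cph.fit(df[["time", "event"] + COVS], "time", "event",
                fit_options=dict(precision=1e-12))
        for cov in COVS:
            assert fit.coefficients[cov] == pytest.approx(
                cph.params_[cov], abs=1e-6)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(9)
        n = 400
        df = pd.DataFrame({
            "time": rng.exponential(1000, size=n),  # continuous: no ties
            "event": rng.random(n) < 0.7,
            "x": rng.normal(size=n),
            "z": rng.integers(0, 2, size=n).astype(float),
        })
        fe = cox_fit(df, ["x", "z"], ties="efron")
        fb = cox_fit(df, ["x", "z"], ties="breslow")
        for cov in ("x", "z"):
            assert fe.coefficients[cov] == pytest.approx(
                fb.coefficients[cov], abs=1e-7)

    def test_ci_and_hr_consistency(self):
        df = h.simulate_survival_frame(800, seed=10)
        fit = cox_fit(df, COVS)
        for cov in COVS:
            assert fit.hr[cov] == pytest.approx(np.exp(fit.coefficients[cov]))
            assert fit.ci_low[cov] < fit.hr[cov] < fit.ci_high[cov]
            assert 0 <= fit.p[cov] <= 1

    def test_constant_covariate_rejected(self):
        df = h.simulate_survival_frame(100, seed=11)
        df["k"] = 1.0
        with pytest.raises(DataError):
            cox_fit(df, ["k"])


class TestCauseSpecific:
    def _frame(self):
        return pd.DataFrame({
            "event": [1, 1, 0, 1],
            "cause_category": ["circulatory", "neoplasms", "none",
                               "infections_parasites"],
        })

    def test_listed_causes_kept_as_events(self):
        out = cause_specific_subset(self._frame())
        assert set(out["cause_category"]) == {"circulatory", "none",
                                              "infections_parasites"}
        assert out["event"].sum() == 2

    def test_other_cause_deaths_removed_not_censored(self):
        out = cause_specific_subset(self._frame())
        assert len(out) == 3  # the neoplasm death is gone entirely

    def test_censored_subjects_retained(self):
        out = cause_specific_subset(self._frame())
        assert (out["event"] == 0).sum() == 1


class TestRunMortalityAnalysis:
    def test_cause_specific_bookkeeping(self, small_cohort):
        cohort, _ = small_cohort
        res = run_mortality_analysis(cohort, outcome="infect_circ")
        other = ((cohort["event"] == 1)
                 & ~cohort["cause_category"].isin(
                     {"infections_parasites", "circulatory"})).sum()
        assert res.n == len(cohort) - other

    def test_subgroup_filter(self, small_cohort):
        cohort, _ = small_cohort
        res = run_mortality_analysis(cohort, subgroup="cns_infection")
        n_sub = cohort["neuro_subtypes"].str.contains("cns_infection").sum()
        assert res.n == n_sub

    def test_interval_sensitivity_covariate(self, small_cohort):
        cohort, _ = small_cohort
        res = run_mortality_analysis(
            cohort, extra_covariates=("interval_days",))
        assert "interval_days" in res.adjusted.coefficients
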