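"""Validation-stage statistics: KM, log-rank, Cox, ROC, contingency tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specount.errors import DegenerateModelError, ValidationError
from specount.simulate import CohortSimConfig, simulate_cohort
from specount.survival import (
    contingency_test,
    cox_fit,
    km_estimate,
    liver_rfs_analysis,
    log_rank,
    rank_test,
    roc_cutoff,
    survival_at,
)


# ---------------------------------------------------------------------------
# independent oracles


def km_oracle(times, events):
    """Hand product-limit arithmetic: S(t) over distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = {}
    for t in sorted(set(times[events == 1])):
        r = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / r
        out[t] = s
    return out


def logrank_oracle(times, events, labels):
    """O-E / V log-rank chi-square for two groups, hand bookkeeping."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    labels = np.asarray(labels)
    g1 = np.unique(labels)[0]
    o_minus_e, v = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (labels == g1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (labels == g1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v


def cox_score_at_zero(times, events, x):
    """Cox partial-likelihood score test statistic U(0)^2 / I(0) for one
    covariate (exact identity with log-rank when event times are untied)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    u, info = 0.0, 0.0
    for t in times[events == 1]:
        risk = times >= t
        xbar = x[risk].mean()
        u += x[(times == t) & (events == 1)][0] - xbar
        info += np.mean((x[risk] - xbar) ** 2)
    return u * u / info


def cox_grid_oracle(times, events, x, lo=-5.0, hi=5.0, step=1e-4):
    """Brute-force maximization of the explicit partial likelihood."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    betas = np.arange(lo, hi + step, step)
    ll = np.zeros_like(betas)
    for t in times[events == 1]:
        xi = x[(times == t) & (events == 1)][0]
        risk = x[times >= t]
        ll += betas * xi - np.log(np.exp(np.outer(betas, risk)).sum(axis=1))
    return betas[np.argmax(ll)]


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKM:
    def test_hand_product_limit(self):
        km = km_estimate([5, 10, 15, 20], [1, 1, 0, 1])
        assert km.survival_at(5) == pytest.approx(0.75)
        assert km.survival_at(10) == pytest.approx(0.5)
        assert km.survival_at(17) == pytest.approx(0.5)  # censoring is not a step
        assert km.survival_at(20) == pytest.approx(0.0)
        assert km.survival_at(1) == 1.0

    def test_all_censored_flat_at_one(self):
        km = km_estimate([3, 8, 12], [0, 0, 0])
        assert km.survival_at(100) == 1.0

    def test_distinct_event_times_step_by_one_over_n(self):
        n = 6
        km = km_estimate(np.arange(1, n + 1), np.ones(n, int))
        assert km.times.size == n
        np.testing.assert_allclose(km.survival, 1 - np.arange(1, n + 1) / n, atol=1e-12)
        assert km.survival_at(km.times[-1]) == pytest.approx(0.0)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(1, 30), st.booleans()), min_size=1, max_size=25
        )
    )
    def test_matches_hand_oracle_with_ties(self, subjects):
        times = [t for t, _ in subjects]
        events = [int(e) for _, e in subjects]
        km = km_estimate(times, events)
        for t, s in km_oracle(times, events).items():
            assert km.survival_at(t) == pytest.approx(s, abs=1e-10)

    def test_at_risk_counts_non_increasing(self):
        km = km_estimate([2, 2, 5, 7, 7, 9], [1, 0, 1, 1, 1, 0])
        assert (np.diff(km.at_risk) <= 0).all()
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])
        with pytest.raises(ValidationError):
            km_estimate([0.0, 5.0], [1, 0])


# ---------------------------------------------------------------------------
# log-rank


class TestLogRank:
    def test_identical_groups_give_zero(self):
        times = [5, 8, 12, 20, 5, 8, 12, 20]
        events = [1, 0, 1, 1, 1, 0, 1, 1]
        labels = ["a"] * 4 + ["b"] * 4
        res = log_rank(times, events, labels)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)
        assert res.df == 1

    def test_matches_hand_o_minus_e(self):
        times = [3, 5, 7, 9, 11, 14, 2, 4, 6, 8, 10, 30]
        events = [1, 1, 1, 0, 1, 1, 1, 0, 1, 1, 0, 0]
        labels = ["pos"] * 6 + ["neg"] * 6
        res = log_rank(times, events, labels)
        assert res.statistic == pytest.approx(
            logrank_oracle(times, events, labels), abs=1e-8
        )

    def test_equals_cox_score_test_at_beta_zero(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = 12
            times = rng.permutation(np.arange(1, n + 1)).astype(float)  # no ties
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            x = rng.integers(0, 2, n)
            if x.min() == x.max():
                x[0] = 1 - x[0]
            score_stat = cox_score_at_zero(times, events, x)
            res = log_rank(times, events, np.where(x == 1, "a", "b"))
            assert res.statistic == pytest.approx(score_stat, abs=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            log_rank([1, 2], [1, 1], ["a", "a"])

    def test_no_events_p_one(self):
        res = log_rank([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert res.statistic == 0.0 and res.p == 1.0


# ---------------------------------------------------------------------------
# Cox proportional hazards


class TestCox:
    def test_grid_search_oracle_four_subjects(self):
        times = np.array([2.0, 4.0, 6.0, 8.0])
        events = np.array([1, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        fit = cox_fit(pd.DataFrame({"x": x}), times, events)
        beta_star = cox_grid_oracle(times, events, x)
        assert fit.summary.loc["x", "coef"] == pytest.approx(beta_star, abs=1e-4)

    def test_grid_search_oracle_seven_subjects(self):
        times = np.array([1.0, 3.0, 4.0, 5.5, 7.0, 9.0, 12.0])
        events = np.array([1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        fit = cox_fit(pd.DataFrame({"x": x}), times, events)
        beta_star = cox_grid_oracle(times, events, x)
        assert fit.summary.loc["x", "coef"] == pytest.approx(beta_star, abs=1e-4)

    def test_matches_lifelines_on_simulated_cohort(self):
        from lifelines import CoxPHFitter

        cohort, _ = simulate_cohort(
            CohortSimConfig(n_patients=400, sync_probability=0.0,
                            baseline_hazard=("exponential", 0.003), seed=21)
        )
        ar = cohort.at_risk()
        X = pd.DataFrame(
            {
                "marker": ar["marker_CNPY2"].astype(float),
                "size_high": (ar["tumor_size_mm"] >= 42).astype(float),
            }
        )
        fit = cox_fit(X, ar["liver_rfs_months"], ar["liver_recurrence"])
        df = X.assign(T=ar["liver_rfs_months"].values, E=ar["liver_recurrence"].values)
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(
            fit.summary["coef"], cph.params_[X.columns], atol=1e-4
        )

    def test_ci_brackets_hr(self):
        cohort, _ = simulate_cohort(
            CohortSimConfig(n_patients=300, sync_probability=0.0, seed=5)
        )
        ar = cohort.at_risk()
        fit = cox_fit(
            pd.DataFrame({"m": ar["marker_CNPY2"].astype(float)}),
            ar["liver_rfs_months"], ar["liver_recurrence"],
        )
        row = fit.summary.loc["m"]
        assert row["ci_low"] <= row["hr"] <= row["ci_high"]
        assert row["hr"] > 0

    def test_constant_covariate_flagged(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 0, 1]
        X = pd.DataFrame({"const": [1, 1, 1, 1], "x": [0, 1, 0, 1]})
        fit = cox_fit(X, times, events)
        assert "const" in fit.flags
        assert np.isnan(fit.summary.loc["const", "hr"])
        assert np.isfinite(fit.summary.loc["x", "hr"])

    def test_zero_events_degenerate(self):
        with pytest.raises(DegenerateModelError, match="no events"):
            cox_fit(pd.DataFrame({"x": [0, 1]}), [1.0, 2.0], [0, 0])

    def test_separation_flagged_not_silent(self):
        # covariate perfectly orders events before censorings
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        try:
            fit = cox_fit(pd.DataFrame({"x": x}), times, events)
            assert ("x" in fit.flags) or (not fit.converged)
        except DegenerateModelError:
            pass  # also an acceptable outcome, as long as it is explicit

    def test_breslow_ties_available(self):
        cohort, _ = simulate_cohort(
            CohortSimConfig(n_patients=200, sync_probability=0.0, seed=3)
        )
        ar = cohort.at_risk()
        X = pd.DataFrame({"m": ar["marker_CNPY2"].astype(float)})
        efron = cox_fit(X, ar["liver_rfs_months"], ar["liver_recurrence"], ties="efron")
        breslow = cox_fit(X, ar["liver_rfs_months"], ar["liver_recurrence"], ties="breslow")
        assert efron.ties == "efron" and breslow.ties == "breslow"
        # both finite, close but not necessarily identical under ties
        assert np.isfinite(efron.summary.loc["m", "coef"])
        assert np.isfinite(breslow.summary.loc["m", "coef"])


# ---------------------------------------------------------------------------
# ROC cutoff


class TestRoc:
    def test_perfect_separation(self):
        r = roc_cutoff([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 3 < r.cutoff < 10

    def test_worked_example(self):
        r = roc_cutoff([3, 5, 1, 2, 4], [1, 1, 0, 0, 0])
        assert r.auc == pytest.approx(5 / 6)
        assert 2 < r.cutoff < 3
        assert r.sensitivity == 1.0
        assert r.specificity == pytest.approx(2 / 3)

    @settings(max_examples=100, derandomize=True)
    @given(
        pos=st.lists(st.integers(0, 8), min_size=1, max_size=15),
        neg=st.lists(st.integers(0, 8), min_size=1, max_size=15),
    )
    def test_auc_is_mann_whitney_u(self, pos, neg):
        r = roc_cutoff(pos + neg, [1] * len(pos) + [0] * len(neg))
        u = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert r.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        r1 = roc_cutoff(x, y)
        r2 = roc_cutoff(np.exp(3 * x) + 7, y)
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        assert r1.sensitivity == pytest.approx(r2.sensitivity, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_cutoff([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------------
# contingency and rank tests


class TestCategorical:
    def test_fisher_enumeration_oracle(self):
        p = contingency_test([[10, 0], [0, 10]], "fisher_2x2")
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_fisher_requires_2x2(self):
        with pytest.raises(ValidationError):
            contingency_test([[1, 2, 3], [4, 5, 6]], "fisher_2x2")

    def test_marker_by_group_table(self):
        """Three-group positivity pattern (7/8, 10/12, 19/50): chi-square
        near 0.002 and the exact test near 0.001."""
        tab = [[7, 10, 19], [1, 2, 31]]
        p_chi2 = contingency_test(tab, "chi2")
        assert p_chi2 == pytest.approx(0.002, abs=0.0005)
        p_exact = contingency_test(tab, "exact_mc", n_mc=40000, seed=3)
        assert p_exact == pytest.approx(0.001, abs=0.0005)

    def test_auto_falls_back_to_exact_for_sparse_tables(self):
        sparse = [[8, 1], [1, 8]]
        assert contingency_test(sparse, "auto") == pytest.approx(
            contingency_test(sparse, "fisher_2x2"), rel=1e-9
        )

    def test_kruskal_nominal_rate_under_null(self):
        rng = np.random.default_rng(8)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            vals = rng.normal(size=90)
            labels = np.repeat(["a", "b", "c"], 30)
            if rank_test(vals, labels, "kruskal_wallis") < 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) < 0.03

    def test_mann_whitney_two_groups_only(self):
        with pytest.raises(ValidationError):
            rank_test([1, 2, 3], ["a", "b", "c"], "mann_whitney")


# ---------------------------------------------------------------------------
# end-to-end liver RFS


class TestLiverRFS:
    def test_synchronous_excluded_and_marker_strata(self, table3_cohort):
        res = liver_rfs_analysis(table3_cohort, "CNPY2")
        assert res.n_excluded_synchronous == 8
        assert res.n_analyzed == 62
        assert set(res.km_by_stratum) == {0, 1}
        assert res.logrank is not None

    def test_landmark_survival_read_from_step_function(self, table3_cohort):
        res = liver_rfs_analysis(table3_cohort, "CNPY2", landmark_months=120.0)
        for stratum, km in res.km_by_stratum.items():
            assert res.landmark_survival[stratum] == pytest.approx(
                survival_at(km, 120.0)
            )

    def test_univariate_gate_excludes_p_above_alpha(self, table3_cohort):
        res = liver_rfs_analysis(table3_cohort, "CNPY2")
        for cov in res.multivariate_covariates:
            assert res.univariate.loc[cov, "p"] < 0.05
        excluded = [
            c
            for c in res.univariate.index
            if np.isfinite(res.univariate.loc[c, "p"])
            and res.univariate.loc[c, "p"] >= 0.05
        ]
        assert not set(excluded) & set(res.multivariate_covariates)

    def test_force_covariates_override_gate(self, table3_cohort):
        res = liver_rfs_analysis(
            table3_cohort, "CNPY2", force_covariates=["vascular_invasion"]
        )
        assert "vascular_invasion" in res.multivariate_covariates

    def test_no_recurrence_cohort_flat_curves(self, table3_cohort):
        t = table3_cohort.table.copy()
        t["liver_recurrence"] = np.where(t["group"] == "synchronous", np.nan, 0)
        t["group"] = t["group"].replace({"metachronous": "none"})
        from specount.io import CohortTable

        res = liver_rfs_analysis(CohortTable(t), "CNPY2")
        for km in res.km_by_stratum.values():
            assert km.survival_at(240.0) == 1.0
        assert res.logrank.p == 1.0

    def test_positive_stratum_dominated_under_planted_effect(self):
        cohort, _ = simulate_cohort(
            CohortSimConfig(n_patients=3000, sync_probability=0.05,
                            baseline_hazard=("exponential", 0.002), seed=13)
        )
        res = liver_rfs_analysis(cohort, "CNPY2")
        neg, pos = res.km_by_stratum[0], res.km_by_stratum[1]
        for t in [12, 36, 60, 120, 180]:
            assert pos.survival_at(t) <= neg.survival_at(t) + 1e-12

    def test_missing_marker_column_is_actionable(self, table3_cohort):
        with pytest.raises(ValidationError, match="NOPE"):
            liver_rfs_analysis(table3_cohort, "NOPE")
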