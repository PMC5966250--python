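"""Validation-stage statistics: group comparisons, ROC cutoffs,
Kaplan-Meier liver recurrence-free survival, log-rank and Cox models.

Liver RFS (recurrence-free survival) is the time from resection of the
primary pancreatic tumor to the first liver metastasis; patients with
synchronous liver metastasis have no such time and are excluded before any
survival computation.  Kaplan-Meier estimation and the log-rank test are
delegated to lifelines; Cox proportional-hazards fits go through
statsmodels' partial-likelihood implementation (Efron tie handling by
default, Breslow available), wrapped with diagnostics for the degeneracies
small clinical cohorts actually produce: zero events, constant covariates,
and monotone likelihood (perfect separation), which is flagged instead of
silently reporting an enormous hazard ratio.

ROC cutoffs for continuous markers (Ki-67 labeling index, tumor size) are
chosen by maximizing Youden's J = sensitivity + specificity - 1 over
observed-value midpoints, classifying ``value >= cutoff`` as positive;
the AUC uses the Mann-Whitney construction (ties count 1/2) and its
p-value is the two-sided Mann-Whitney test against AUC = 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.special import gammaln
from statsmodels.duration.hazard_regression import PHReg

from .errors import DegenerateModelError, ValidationError
from .io import CohortTable

SEPARATION_COEF_LIMIT = 15.0  # |log HR| beyond this on clinical data = separation


# ---------------------------------------------------------------------------
# result containers


@dataclass
class KMCurve:
    """Product-limit survival curve with at-risk bookkeeping."""

    times: np.ndarray           # distinct observed times, ascending
    survival: np.ndarray        # S(t) at each time (right-continuous steps)
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    se: np.ndarray              # Greenwood standard errors
    n: int

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function (events at t included)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


@dataclass
class CoxFit:
    """Cox proportional-hazards fit: per-covariate HR, Wald CI and p."""

    summary: pd.DataFrame  # index covariate; coef, hr, ci_low, ci_high, se, p
    log_likelihood: float
    converged: bool
    n: int
    n_events: int
    ties: str
    flags: dict[str, str] = field(default_factory=dict)


@dataclass
class ROCCutoff:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    p: float  # AUC vs 0.5 (two-sided Mann-Whitney)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored at an event time remain at risk for the event at that
    time (the standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty survival input")
    if times.size != events.size:
        raise ValidationError("times and events have different lengths")
    if (times <= 0).any():
        raise ValidationError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    et = kmf.event_table[kmf.event_table.index > 0]  # drop the t=0 anchor row
    grid = et.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[grid, "KM_estimate"].to_numpy()
    # Greenwood: Var(S) = S^2 * cumsum(d / (r (r - d)))
    d = et["observed"].to_numpy(dtype=float)
    r = et["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(r > d, d / (r * (r - d)), np.inf)
    se = surv * np.sqrt(np.cumsum(np.where(np.isfinite(inc), inc, 0.0)))
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=r.astype(int),
        n_events=d.astype(int),
        n_censored=et["censored"].to_numpy(dtype=int),
        se=se,
        n=int(times.size),
    )


def survival_at(curve: KMCurve, t: float) -> float:
    return curve.survival_at(t)


def log_rank(times, events, group_labels) -> LogRankResult:
    """Log-rank test across two or more groups (chi-square, df = groups - 1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("log-rank needs at least two non-empty groups")
    df = int(uniq.size - 1)
    if events.sum() == 0:
        return LogRankResult(statistic=0.0, df=df, p=1.0)
    res = multivariate_logrank_test(times, labels, events)
    return LogRankResult(
        statistic=float(res.test_statistic), df=df, p=float(res.p_value)
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


def cox_fit(covariates: pd.DataFrame, times, events, ties: str = "efron") -> CoxFit:
    """Maximize the Cox partial likelihood and report Wald inference.

    ``covariates`` is a numeric DataFrame (one column per covariate).
    Constant covariates are flagged non-identifiable (HR = NaN) and removed
    from the optimization; suspected monotone likelihood / perfect
    separation is flagged on the affected covariate.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown tie method {ties!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = covariates.astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()][0]
        raise ValidationError(f"missing values in covariate {bad!r}")
    n, n_events = len(X), int(events.sum())
    if n_events == 0:
        raise DegenerateModelError("no events: Cox model is not identifiable")

    flags: dict[str, str] = {}
    keep = []
    for col in X.columns:
        if np.ptp(X[col].to_numpy()) == 0:
            flags[col] = "constant covariate: HR not identifiable"
        else:
            keep.append(col)
    if not keep:
        raise DegenerateModelError("all covariates constant")

    model = PHReg(times, X[keep].to_numpy(), status=events, ties=ties)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=False)
        except Exception as exc:  # noqa: BLE001 — surfaced as a diagnostic
            raise DegenerateModelError(f"Cox fit failed: {exc}") from exc
    coefs = np.asarray(res.params, dtype=float)
    ses = np.asarray(res.bse, dtype=float)
    if not (np.isfinite(coefs).all() and np.isfinite(ses).all()):
        converged = False

    rows = []
    z = stats.norm.ppf(0.975)
    for col in X.columns:
        if col in flags:
            rows.append((col, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        i = keep.index(col)
        b, se = coefs[i], ses[i]
        if abs(b) > SEPARATION_COEF_LIMIT or not np.isfinite(se):
            flags[col] = "monotone likelihood / separation suspected"
            converged = False
        p = 2.0 * stats.norm.sf(abs(b) / se) if se > 0 else np.nan
        with np.errstate(over="ignore"):  # separated fits overflow to inf
            rows.append(
                (col, b, np.exp(b), np.exp(b - z * se), np.exp(b + z * se), se, p)
            )
    summary = pd.DataFrame(
        rows, columns=["covariate", "coef", "hr", "ci_low", "ci_high", "se", "p"]
    ).set_index("covariate")
    return CoxFit(
        summary=summary,
        log_likelihood=float(model.loglike(coefs)),
        converged=converged,
        n=n,
        n_events=n_events,
        ties=ties,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# ROC cutoff discovery


def roc_cutoff(marker_values, outcome_binary) -> ROCCutoff:
    """AUC (Mann-Whitney construction) and the Youden-optimal cutoff.

    Classification is ``value >= cutoff`` -> predicted positive.  Candidate
    cutoffs are midpoints between adjacent distinct observed values plus
    both boundaries; ties in Youden's J break toward the lower cutoff.
    """
    x = np.asarray(marker_values, dtype=float)
    y = np.asarray(outcome_binary, dtype=int)
    pos, neg = x[y == 1], x[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both outcome classes must be present")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    auc = float(u.statistic) / (pos.size * neg.size)

    distinct = np.unique(x)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    best = None
    for c in candidates:  # ascending; strict > keeps the lowest J-maximizer
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    _, cutoff, sens, spec = best
    return ROCCutoff(
        auc=auc, cutoff=float(cutoff), sensitivity=sens, specificity=spec,
        p=float(u.pvalue),
    )


# ---------------------------------------------------------------------------
# categorical / rank tests


def contingency_test(table, method: str = "chi2", yates: bool = False,
                     n_mc: int = 20000, seed: int = 0) -> float:
    """Two-sided p-value for an r x c count table.

    ``method``: ``"fisher_2x2"`` (exact, 2x2 only), ``"chi2"`` (Pearson,
    no Yates correction unless asked), ``"exact_mc"`` (Monte-Carlo exact
    test for r x c, fixed margins) or ``"auto"`` (chi-square, falling back
    to an exact test when any expected cell is below 5).
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("contingency table must hold non-negative integers")
    if method == "fisher_2x2":
        if t.shape != (2, 2):
            raise ValidationError(f"fisher_2x2 requires a 2x2 table, got {t.shape}")
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    if method == "chi2":
        return float(stats.chi2_contingency(t, correction=yates)[1])
    if method == "exact_mc":
        return _exact_mc_p(t.astype(int), n_mc, seed)
    if method == "auto":
        expected = stats.contingency.expected_freq(t)
        if (expected < 5).any():
            if t.shape == (2, 2):
                return float(stats.fisher_exact(t, alternative="two-sided")[1])
            return _exact_mc_p(t.astype(int), n_mc, seed)
        return float(stats.chi2_contingency(t, correction=yates)[1])
    raise ValidationError(f"unknown contingency method {method!r}")


def _table_log_prob(t: np.ndarray) -> float:
    """Log probability of a table under fixed margins (multivariate
    hypergeometric / Fisher null)."""
    row, col, n = t.sum(1), t.sum(0), t.sum()
    return float(
        gammaln(row + 1).sum() + gammaln(col + 1).sum()
        - gammaln(n + 1) - gammaln(t + 1).sum()
    )


def _exact_mc_p(t: np.ndarray, n_mc: int, seed: int) -> float:
    """Monte-Carlo Fisher-type exact test for r x c tables: the p-value is
    the null probability of a table no more probable than the observed one."""
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(t.sum(1), t.sum(0))
    draws = sampler.rvs(size=n_mc, random_state=rng)
    lp_obs = _table_log_prob(t)
    lp = np.array([_table_log_prob(d) for d in draws])
    # +1 correction keeps the estimate a valid p-value
    return float((np.sum(lp <= lp_obs + 1e-9) + 1) / (n_mc + 1))


def rank_test(values, groups, method: str = "mann_whitney") -> float:
    """Two-sided rank test p-value for a continuous variate across groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    samples = [values[labels == g] for g in np.unique(labels)]
    if any(s.size == 0 for s in samples):
        raise ValidationError("every group must be non-empty")
    if method == "mann_whitney":
        if len(samples) != 2:
            raise ValidationError("mann_whitney requires exactly two groups")
        return float(stats.mannwhitneyu(*samples, alternative="two-sided").pvalue)
    if method == "kruskal_wallis":
        return float(stats.kruskal(*samples).pvalue)
    raise ValidationError(f"unknown rank test {method!r}")


# ---------------------------------------------------------------------------
# end-to-end liver-RFS analysis


@dataclass
class LiverRFSResult:
    marker: str
    n_excluded_synchronous: int
    n_analyzed: int
    km_by_stratum: dict[int, KMCurve]
    landmark_months: float
    landmark_survival: dict[int, float]
    logrank: LogRankResult | None
    roc: dict[str, ROCCutoff]
    univariate: pd.DataFrame
    multivariate: CoxFit | None
    multivariate_covariates: list[str]
    stratum_warnings: list[str] = field(default_factory=list)


def _covariate_frame(at_risk: pd.DataFrame, cohort: CohortTable,
                     roc: dict[str, ROCCutoff]) -> pd.DataFrame:
    """Binary covariates screened univariately for liver RFS."""
    cov = pd.DataFrame(index=at_risk.index)
    cov["functioning"] = (at_risk["function_type"] != "NF").astype(int)
    cov["grade_G2G3"] = at_risk["who_grade"].isin(["G2", "G3"]).astype(int)
    cov["grade_G3"] = (at_risk["who_grade"] == "G3").astype(int)
    cov["ki67_high"] = (at_risk["ki67"] >= roc["ki67"].cutoff).astype(int)
    cov["size_high"] = (at_risk["tumor_size_mm"] >= roc["tumor_size"].cutoff).astype(int)
    cov["lymph_node_metastasis"] = at_risk["lymph_node_metastasis"].astype(int)
    cov["vascular_invasion"] = at_risk["vascular_invasion"].astype(int)
    cov["lymphatic_invasion"] = at_risk["lymphatic_invasion"].astype(int)
    cov["stage_III_IV"] = at_risk["enets_stage"].isin(["III", "IV"]).astype(int)
    for m in cohort.marker_columns:
        cov[m] = at_risk[m].astype(int)
    return cov


def liver_rfs_analysis(
    cohort: CohortTable,
    marker: str,
    landmark_months: float = 120.0,
    ties: str = "efron",
    univariate_alpha: float = 0.05,
    force_covariates: list[str] | None = None,
) -> LiverRFSResult:
    """Liver recurrence-free survival analysis for one candidate marker.

    Synchronous-metastasis patients are excluded first; the remaining
    cohort is stratified by marker positivity for Kaplan-Meier curves, the
    log-rank test and landmark survival.  Continuous covariates (Ki-67,
    tumor size) are dichotomized at ROC/Youden cutoffs against the
    liver-recurrence outcome; every covariate is screened with a univariate
    Cox model and those with univariate p below ``univariate_alpha`` (plus
    any ``force_covariates``) enter the multivariate model.
    """
    col = marker if marker in cohort.table.columns else f"marker_{marker}"
    if col not in cohort.table.columns:
        raise ValidationError(
            f"marker column {marker!r} not found; available: {cohort.marker_columns}"
        )
    at_risk = cohort.at_risk()
    n_excluded = len(cohort.table) - len(at_risk)
    times = at_risk["liver_rfs_months"].to_numpy(dtype=float)
    events = at_risk["liver_recurrence"].to_numpy(dtype=float).astype(int)

    km: dict[int, KMCurve] = {}
    landmark: dict[int, float] = {}
    notes: list[str] = []
    for stratum in (0, 1):
        mask = at_risk[col].to_numpy() == stratum
        if mask.sum() == 0:
            notes.append(f"stratum {stratum} of {col} has zero patients")
            continue
        km[stratum] = km_estimate(times[mask], events[mask])
        landmark[stratum] = km[stratum].survival_at(landmark_months)
    lr = None
    if len(km) == 2:
        lr = log_rank(times, events, at_risk[col].to_numpy())
    else:
        notes.append("log-rank skipped: marker stratum empty")

    if events.sum() == 0:
        # no recurrences: ROC and Cox are undefined, curves stay at 1
        notes.append("no liver recurrences: ROC and Cox screening skipped")
        return LiverRFSResult(
            marker=col,
            n_excluded_synchronous=n_excluded,
            n_analyzed=len(at_risk),
            km_by_stratum=km,
            landmark_months=landmark_months,
            landmark_survival=landmark,
            logrank=lr,
            roc={},
            univariate=pd.DataFrame(
                columns=["hr", "ci_low", "ci_high", "p", "flag"]
            ),
            multivariate=None,
            multivariate_covariates=[],
            stratum_warnings=notes,
        )

    roc = {
        "ki67": roc_cutoff(at_risk["ki67"], events),
        "tumor_size": roc_cutoff(at_risk["tumor_size_mm"], events),
    }
    cov = _covariate_frame(at_risk, cohort, roc)

    uni_rows = []
    for c in cov.columns:
        if np.ptp(cov[c].to_numpy()) == 0:
            uni_rows.append((c, np.nan, np.nan, np.nan, np.nan,
                             "constant covariate"))
            continue
        try:
            fit = cox_fit(cov[[c]], times, events, ties=ties)
            r = fit.summary.loc[c]
            uni_rows.append((c, r["hr"], r["ci_low"], r["ci_high"], r["p"],
                             fit.flags.get(c, "")))
        except DegenerateModelError as exc:
            uni_rows.append((c, np.nan, np.nan, np.nan, np.nan, str(exc)))
    univariate = pd.DataFrame(
        uni_rows, columns=["covariate", "hr", "ci_low", "ci_high", "p", "flag"]
    ).set_index("covariate")

    selected = [
        c for c in cov.columns
        if np.isfinite(univariate.loc[c, "p"]) and univariate.loc[c, "p"] < univariate_alpha
    ]
    for c in force_covariates or []:
        if c not in selected and c in cov.columns:
            selected.append(c)
    multivariate = None
    if selected:
        try:
            multivariate = cox_fit(cov[selected], times, events, ties=ties)
        except DegenerateModelError as exc:
            notes.append(f"multivariate model degenerate: {exc}")
    return LiverRFSResult(
        marker=col,
        n_excluded_synchronous=n_excluded,
        n_analyzed=len(at_risk),
        km_by_stratum=km,
        landmark_months=landmark_months,
        landmark_survival=landmark,
        logrank=lr,
        roc=roc,
        univariate=univariate,
        multivariate=multivariate,
        multivariate_covariates=selected,
        stratum_warnings=notes,
    )
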