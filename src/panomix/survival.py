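"""Survival analysis: Kaplan-Meier, log-rank, Cox PH, and stratifications.

Estimation is delegated to lifelines (product-limit estimator, k-group
log-rank chi-square, Cox proportional hazards with Efron tie handling); this
module provides the pipeline's contracts around it — input validation,
median-split dichotomization (low = values at or below the median), and the
mutation x expression four-subgroup stratification with the within-stratum
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .exceptions import AnalysisError

HIGH, LOW = "high", "low"


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with at-risk/event counts.

    Returns a DataFrame indexed by time with columns ``at_risk``,
    ``observed`` (events at that time), ``censored`` and ``survival``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise AnalysisError("no subjects")
    if (times < 0).any():
        raise AnalysisError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "at_risk": table["at_risk"],
            "observed": table["observed"],
            "censored": table["censored"],
            "survival": surv.reindex(table.index),
        }
    )
    out.index.name = "time"
    return out


@dataclass
class LogrankResult:
    statistic: float
    df: int
    pvalue: float


def logrank(times, events, groups) -> LogrankResult:
    """k-group log-rank test (chi-square with k-1 degrees of freedom)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise AnalysisError("log-rank needs at least two non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    return LogrankResult(float(res.test_statistic), len(labels) - 1, float(res.p_value))


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (Efron ties).

    ``summary`` holds one row per covariate: coef (log HR), hr, se, z, p,
    hr_lower/hr_upper (95% CI = exp(coef +/- 1.96 se)).
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    ties: str = "efron"

    def coef(self, covariate: str) -> float:
        return float(self.summary.at[covariate, "coef"])

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.at[covariate, "hr"])


def cox_fit(data: pd.DataFrame, duration_col: str, event_col: str, covariates: list[str]) -> CoxFit:
    """Fit a Cox PH model by partial-likelihood maximization (Efron ties).

    Raises :class:`AnalysisError` on constant covariates, absent events, or
    non-convergence (monotone likelihood / separation) instead of returning a
    silently unstable fit.
    """
    cols = [duration_col, event_col, *covariates]
    df = data[cols].dropna()
    if df[event_col].sum() < 1:
        raise AnalysisError("no events observed")
    for c in covariates:
        if df[c].nunique() <= 1:
            raise AnalysisError(f"constant covariate {c!r}")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise AnalysisError(f"Cox fit failed to converge: {exc}") from exc
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": np.exp(s["coef"]),
            "se": s["se(coef)"],
            "z": s["z"],
            "p": s["p"],
            "hr_lower": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
            "hr_upper": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
        }
    )
    out.index.name = "covariate"
    return CoxFit(
        summary=out,
        log_likelihood=float(cph.log_likelihood_),
        n=int(df.shape[0]),
        n_events=int(df[event_col].sum()),
    )


def median_dichotomize(values: pd.Series) -> pd.Series:
    """Split into expression subgroups: low = at or below the median."""
    values = values.dropna()
    if values.size < 2:
        raise AnalysisError("need at least two values to dichotomize")
    if values.nunique() == 1:
        raise AnalysisError("all values identical; median split undefined")
    med = values.median()
    return pd.Series(np.where(values > med, HIGH, LOW), index=values.index, name="expression_group")


def mutation_expression_strata(
    mut_status: pd.Series,
    expression: pd.Series,
    times: pd.Series,
    events: pd.Series,
) -> dict:
    """Four-subgroup survival stratification by mutation and expression.

    Samples are split into {mut/high, mut/low, wt/high, wt/low} by mutation
    status and the median expression split.  Returns the labels, the overall
    4-group log-rank test, the two within-stratum 2-group tests, and a
    Student t comparison of expression between mutant and wild-type carriers.
    Tests touching an empty subgroup are skipped with a warning.
    """
    idx = mut_status.index.intersection(expression.index).intersection(times.index)
    mut = mut_status.reindex(idx).astype(bool)
    split = median_dichotomize(expression.reindex(idx))
    labels = pd.Series(
        np.where(mut, "mut/", "wt/") + split.reindex(idx).to_numpy(), index=idx, name="stratum"
    )
    t = times.reindex(idx).astype(float)
    e = events.reindex(idx).astype(int)

    out: dict = {"labels": labels, "group_sizes": labels.value_counts().to_dict()}

    def _maybe_logrank(mask, key):
        sub = labels[mask]
        if sub.nunique() < 2 or sub.value_counts().min() < 1 or len(sub) < 2:
            warnings.warn(f"{key}: empty subgroup, test skipped")
            out[key] = None
            return
        out[key] = logrank(t[mask], e[mask], sub)

    if labels.nunique() == 4:
        out["overall"] = logrank(t, e, labels)
    else:
        warnings.warn("overall 4-group test skipped: empty subgroup")
        out["overall"] = None
    _maybe_logrank(mut.to_numpy(), "within_mutant")
    _maybe_logrank((~mut).to_numpy(), "within_wildtype")

    x, y = expression.reindex(idx)[mut.to_numpy()], expression.reindex(idx)[(~mut).to_numpy()]
    if len(x) >= 2 and len(y) >= 2:
        tt = stats.ttest_ind(x, y, equal_var=True)
        out["expression_ttest"] = {"statistic": float(tt.statistic), "pvalue": float(tt.pvalue)}
    else:
        warnings.warn("expression t-test skipped: fewer than two samples in a group")
        out["expression_ttest"] = None
    return out
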