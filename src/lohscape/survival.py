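"""Clinical sub-cohort analysis: Kaplan-Meier, log-rank and Cox regression.

Estimators are backed by :mod:`lifelines` behind small adapters that add the
package's error semantics (no-events, single-group, convergence failures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import (ConvergenceError, InvalidArgumentError, NoEventsError,
                     SingleGroupError)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with Greenwood variance, right-continuous."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n: int
    n_events: int


@dataclass
class SurvivalFit:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: dict[str, dict] = field(default_factory=dict)  # per covariate
    logrank_p: float | None = None
    km_curves: dict[str, KMCurve] | None = None
    median_cutoff: float | None = None


def dichotomize_by_median(records: pd.DataFrame, column: str = "gloh") -> tuple[pd.DataFrame, float]:
    """Label records 'high' when strictly above the group median, else 'low'."""
    if len(records) < 2:
        raise InvalidArgumentError("need >= 2 records to dichotomize")
    values = records[column].to_numpy(dtype=float)
    if np.ptp(values) == 0:
        raise SingleGroupError(f"all {column} values identical; cannot form two groups")
    median = float(np.median(values))
    out = records.copy()
    out["group"] = np.where(values > median, "high", "low")
    return out, median


def km_estimate(records: pd.DataFrame, group_col: str | None = None) -> dict[str, KMCurve]:
    """Kaplan-Meier curve per group ('all' when ungrouped)."""
    if not records["event"].astype(bool).any():
        raise NoEventsError("no events in the data; product-limit estimator undefined")
    groups = {"all": records} if group_col is None else {
        str(g): sub for g, sub in records.groupby(group_col)
    }
    curves = {}
    for label, sub in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"].astype(bool))
        surv = kmf.survival_function_["KM_estimate"]
        # Greenwood variance of S(t): lifelines exposes it via the fitted object
        var = kmf._cumulative_sq_.reindex(surv.index).to_numpy() * surv.to_numpy() ** 2
        curves[label] = KMCurve(
            times=surv.index.to_numpy(dtype=float),
            survival=surv.to_numpy(dtype=float),
            variance=np.asarray(var, dtype=float),
            n=len(sub),
            n_events=int(sub["event"].astype(bool).sum()),
        )
    return curves


def logrank_test(records: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Two-group log-rank chi-squared statistic and p-value."""
    labels = records[group_col].unique()
    if len(labels) != 2:
        raise InvalidArgumentError(f"log-rank needs exactly 2 groups; got {list(labels)}")
    a = records[records[group_col] == labels[0]]
    b = records[records[group_col] == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise InvalidArgumentError("a group has zero at-risk subjects")
    if not records["event"].astype(bool).any():
        raise NoEventsError("no events in either group")
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"].astype(bool),
                      event_observed_B=b["event"].astype(bool))
    return float(res.test_statistic), float(res.p_value)


def cox_fit(records: pd.DataFrame, covariates: list[str], tie_method: str = "efron") -> SurvivalFit:
    """Cox proportional-hazards fit; HR with Wald 95% CI for the first covariate."""
    if not records["event"].astype(bool).any():
        raise NoEventsError("no events; partial likelihood undefined")
    for cov in covariates:
        if records[cov].nunique() < 2:
            raise InvalidArgumentError(f"covariate {cov!r} is constant")
    df = records[["time", "event"] + list(covariates)].copy()
    df["event"] = df["event"].astype(int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event",
                    fit_options={"step_size": 0.5})
    except (_LLConvergenceError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"Cox fit failed to converge: {exc}") from exc

    summary = cph.summary
    coef = {}
    for name, row in summary.iterrows():
        coef[str(name)] = {
            "hr": float(row["exp(coef)"]),
            "ci_low": float(row["exp(coef) lower 95%"]),
            "ci_high": float(row["exp(coef) upper 95%"]),
            "p": float(row["p"]),
            "log_hr": float(row["coef"]),
        }
    first = coef[str(summary.index[0])]
    return SurvivalFit(
        hr=first["hr"], ci_low=first["ci_low"], ci_high=first["ci_high"],
        p_value=first["p"], coef=coef,
    )


def run_survival_analysis(records: pd.DataFrame, covariates: list[str] | None = None) -> SurvivalFit:
    """Median-gLOH dichotomization -> KM curves -> log-rank -> Cox on the
    high-vs-low indicator (plus optional extra covariates)."""
    labeled, median = dichotomize_by_median(records)
    labeled["gloh_high"] = (labeled["group"] == "high").astype(int)
    curves = km_estimate(labeled, group_col="group")
    stat, logrank_p = logrank_test(labeled, group_col="group")
    fit = cox_fit(labeled, ["gloh_high"] + list(covariates or []))
    fit.logrank_p = logrank_p
    fit.km_curves = curves
    fit.median_cutoff = median
    return fit
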