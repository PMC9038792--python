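"""Cohort-level description of the gLOH distribution.

The inflection-point cutoff follows the published recipe — differentiate the
ranked (sorted) gLOH sequence and take the point where the first derivative
is greatest while the second derivative is zero — made computable by
smoothing the ranked curve first: raw finite differences of sorted data form
a step function whose second derivative is almost never exactly zero.  The
smoothing bandwidth is configurable and reported in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError, NoInflectionError


@dataclass(frozen=True)
class InflectionResult:
    cutoff_percent: float
    rank_index: int
    smoothing_bandwidth: int
    boundary: bool  # first-derivative maximum sat at the end of the curve


@dataclass(frozen=True)
class GLOHClassification:
    cutoff: float
    n_high: int
    n_total: int

    @property
    def fraction_high(self) -> float:
        return self.n_high / self.n_total


@dataclass(frozen=True)
class DistributionSummary:
    mean: float
    sd: float
    lognormal_mu: float
    lognormal_sigma: float
    gof_p: float  # Kolmogorov-Smirnov p against the fitted log-normal
    n: int


def _smooth(x: np.ndarray, bandwidth: int) -> np.ndarray:
    return pd.Series(x).rolling(bandwidth, center=True, min_periods=1).mean().to_numpy()


def find_inflection_point(gloh_values, bandwidth: int | None = None) -> InflectionResult:
    """Inflection of the smoothed rank -> gLOH curve.

    Returns the value at the zero crossing of the (smoothed) second
    derivative nearest the maximum of the (smoothed) first derivative.  If
    the first-derivative maximum lies at the end of the curve (pure
    convexity), the nearest crossing below it is returned with
    ``boundary=True``.
    """
    y = np.sort(np.asarray(gloh_values, dtype=float))
    n = len(y)
    if n < 50:
        raise InsufficientDataError(f"need >= 50 values for derivative stability; got {n}")
    if np.ptp(y) == 0:
        raise NoInflectionError("all values identical")
    if bandwidth is None:
        # n/200 keeps a clean interior inflection exact while leaving enough
        # curvature noise for the tail zero-crossing of heavy-tailed cohorts
        # to sit in the far upper tail rather than being smoothed away
        bandwidth = max(5, n // 200)

    y_s = _smooth(y, bandwidth)
    d1 = _smooth(np.gradient(y_s), bandwidth)
    d2 = _smooth(np.gradient(d1), bandwidth)

    # rolling means flatten near the ends; judge the curve on its interior
    lo, hi = bandwidth, max(bandwidth + 1, n - bandwidth)
    interior = slice(lo, hi)
    d1_in, d2_in = d1[interior], d2[interior]
    scale = np.max(np.abs(d1_in))
    if scale <= 0 or np.ptp(d1_in) < 1e-6 * scale:
        raise NoInflectionError("first derivative is constant; ranked curve has no inflection")

    i_max = lo + int(np.argmax(d1_in))
    boundary = i_max >= hi - bandwidth - 1
    crossings = lo + np.flatnonzero(np.diff(np.sign(d2_in)) != 0)
    if len(crossings) == 0:
        raise NoInflectionError("second derivative never crosses zero")
    i_cross = int(crossings[np.argmin(np.abs(crossings - i_max))])
    return InflectionResult(
        cutoff_percent=float(y_s[i_cross]),
        rank_index=i_cross,
        smoothing_bandwidth=int(bandwidth),
        boundary=bool(boundary),
    )


def classify_gloh_high(gloh_values, cutoff: float) -> GLOHClassification:
    """Count samples at or above the cutoff (ties at the cutoff count high)."""
    values = np.asarray(gloh_values, dtype=float)
    if len(values) == 0:
        raise InvalidArgumentError("empty gLOH vector")
    if np.isnan(cutoff):
        raise InvalidArgumentError("cutoff must be finite or +/-inf")
    return GLOHClassification(
        cutoff=float(cutoff),
        n_high=int(np.sum(values >= cutoff)),
        n_total=len(values),
    )


def summarize_distribution(gloh_values, zero_offset: float = 0.1) -> DistributionSummary:
    """Arithmetic moments plus a maximum-likelihood log-normal fit.

    Zeros are shifted by ``zero_offset`` before taking logs.  The
    goodness-of-fit p-value is a KS test against the fitted log-normal
    (parameters estimated from the same data, so the p-value is
    conservative; it still separates grossly non-log-normal shapes).
    """
    values = np.asarray(gloh_values, dtype=float)
    if len(values) < 3:
        raise InsufficientDataError(f"need >= 3 values; got {len(values)}")
    if np.any(values < 0):
        raise InvalidArgumentError("gLOH values must be >= 0")
    shifted = np.where(values <= 0, zero_offset, values)
    logs = np.log(shifted)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs))
    if sigma == 0:
        gof_p = 1.0
    else:
        gof_p = float(stats.kstest(shifted, stats.lognorm(s=sigma, scale=np.exp(mu)).cdf).pvalue)
    return DistributionSummary(
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        lognormal_mu=mu,
        lognormal_sigma=sigma,
        gof_p=gof_p,
        n=len(values),
    )


def summarize_cohort(cohort: pd.DataFrame) -> dict:
    """Demographics-table-shaped summary: counts with one-decimal percentages."""
    n = len(cohort)
    if n == 0:
        raise InvalidArgumentError("empty cohort")

    def entry(count) -> dict:
        count = int(count)
        return {"n": count, "pct": round(100.0 * count / n, 1)}

    out: dict = {"n_total": n}
    if "sex" in cohort:
        out["sex"] = {level: entry((cohort["sex"] == level).sum())
                      for level in ("female", "male")}
    if "uterine" in cohort:
        out["uterine"] = entry(int(cohort["uterine"].astype(bool).sum()))
    if "msi" in cohort:
        out["msi"] = {level: entry((cohort["msi"] == level).sum())
                      for level in sorted(cohort["msi"].unique())}
    if "age" in cohort:
        out["age"] = {"mean": round(float(cohort["age"].mean()), 1),
                      "sd": round(float(cohort["age"].std()), 1)}
    if "tmb" in cohort:
        out["tmb"] = {"mean": round(float(cohort["tmb"].mean()), 1),
                      "sd": round(float(cohort["tmb"].std()), 1),
                      "ge_10": entry(int((cohort["tmb"] >= 10).sum()))}
    if "gloh" in cohort:
        out["gloh"] = {"mean": round(float(cohort["gloh"].mean()), 1),
                       "sd": round(float(cohort["gloh"].std()), 1)}
    return out
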