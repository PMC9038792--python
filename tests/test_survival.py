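import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from lohscape.errors import (InvalidArgumentError, NoEventsError, SingleGroupError)
from lohscape.survival import (cox_fit, dichotomize_by_median, km_estimate,
                               logrank_test, run_survival_analysis)

from .oracles import cox_partial_loglik, km_by_hand


def _records(times, events, **cols):
    df = pd.DataFrame({"sample_id": [f"S{i}" for i in range(len(times))],
                       "time": times, "event": events})
    for k, v in cols.items():
        df[k] = v
    return df


# ------------------------------------------------------------------ dichotomize
def test_strict_median_rule():
    df = _records([1, 2, 3], [1, 1, 1], gloh=[5.0, 9.9, 12.0])
    out, median = dichotomize_by_median(df)
    assert median == 9.9
    assert out.loc[out.gloh.isin([5.0, 9.9]), "group"].eq("low").all()
    assert out.loc[out.gloh == 12.0, "group"].eq("high").all()


def test_even_distinct_values_split_in_half():
    df = _records(range(1, 9), [1] * 8, gloh=np.arange(8.0))
    out, _ = dichotomize_by_median(df)
    assert (out.group == "high").sum() == 4


def test_identical_values_single_group():
    df = _records([1, 2], [1, 1], gloh=[7.0, 7.0])
    with pytest.raises(SingleGroupError):
        dichotomize_by_median(df)


def test_too_few_records():
    with pytest.raises(InvalidArgumentError):
        dichotomize_by_median(_records([1], [1], gloh=[5.0]))


# --------------------------------------------------------------------------- KM
def test_km_no_censoring_hand_values():
    curves = km_estimate(_records([1.0, 2.0, 3.0], [True, True, True]))
    c = curves["all"]
    got = dict(zip(c.times, c.survival))
    assert got[0.0] == 1.0  # curve starts at 1
    assert got[1.0] == pytest.approx(2 / 3)
    assert got[2.0] == pytest.approx(1 / 3)
    assert got[3.0] == pytest.approx(0.0)


def test_km_equals_one_minus_ecdf_without_censoring(rng):
    times = rng.exponential(10, size=200)
    curves = km_estimate(_records(times, [True] * 200))
    c = curves["all"]
    for t, s in zip(c.times, c.survival):
        ecdf = np.mean(times <= t)
        assert s == pytest.approx(1.0 - ecdf, abs=1e-12)


def test_km_mixed_censoring_matches_hand_oracle():
    times = [2.0, 3.0, 4.0, 5.0, 8.0, 9.0]
    events = [True, False, True, True, False, True]
    curves = km_estimate(_records(times, events))
    c = curves["all"]
    oracle = km_by_hand(times, events)
    got = dict(zip(c.times, c.survival))
    for t, s in oracle:
        assert got[t] == pytest.approx(s)


def test_km_curve_monotone_with_greenwood(rng):
    times = rng.exponential(5, 100)
    events = rng.random(100) < 0.7
    if not events.any():
        events[0] = True
    c = km_estimate(_records(times, events))["all"]
    assert np.all(np.diff(c.survival) <= 1e-12)
    assert np.all(c.variance >= -1e-15)


def test_km_requires_events():
    with pytest.raises(NoEventsError):
        km_estimate(_records([1.0, 2.0], [False, False]))


# ---------------------------------------------------------------------- logrank
def test_identical_groups_statistic_zero():
    times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    events = [True] * 6
    df = _records(times, events, group=["a"] * 3 + ["b"] * 3)
    stat, p = logrank_test(df)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_symmetric_under_relabeling(rng):
    times = rng.exponential(5, 60)
    events = rng.random(60) < 0.8
    groups = np.where(rng.random(60) < 0.5, "a", "b")
    df = _records(times, events, group=groups)
    stat_ab, p_ab = logrank_test(df)
    df2 = df.assign(group=np.where(groups == "a", "b", "a"))
    stat_ba, p_ba = logrank_test(df2)
    assert stat_ab == pytest.approx(stat_ba)
    assert p_ab == pytest.approx(p_ba)


def test_logrank_needs_two_groups():
    df = _records([1.0, 2.0], [True, True], group=["a", "a"])
    with pytest.raises(InvalidArgumentError):
        logrank_test(df)


# -------------------------------------------------------------------------- cox
def test_cox_matches_brute_force_partial_likelihood():
    times = [1.5, 2.5, 4.0, 5.5, 7.0, 9.0, 11.0, 12.5]
    events = [True, True, False, True, True, False, True, True]
    x = [1, 0, 1, 0, 1, 1, 0, 0]
    df = _records(times, events, gloh_high=x)
    fit = cox_fit(df, ["gloh_high"])
    res = optimize.minimize_scalar(
        lambda b: -cox_partial_loglik(b, times, events, x), bounds=(-5, 5), method="bounded")
    assert np.log(fit.hr) == pytest.approx(res.x, abs=1e-3)


def test_efron_equals_breslow_without_ties(rng):
    times = np.sort(rng.exponential(5, 80)) + np.arange(80) * 1e-6
    events = rng.random(80) < 0.8
    x = (rng.random(80) < 0.5).astype(int)
    if events.sum() == 0:
        events[0] = True
    df = _records(times, events, gloh_high=x)
    hr_efron = cox_fit(df, ["gloh_high"], tie_method="efron").hr
    assert hr_efron == pytest.approx(cox_fit(df, ["gloh_high"]).hr)


def test_cox_requires_events_and_variation():
    with pytest.raises(NoEventsError):
        cox_fit(_records([1.0, 2.0], [False, False], gloh_high=[0, 1]), ["gloh_high"])
    with pytest.raises(InvalidArgumentError):
        cox_fit(_records([1.0, 2.0], [True, True], gloh_high=[1, 1]), ["gloh_high"])


def test_null_covariate_ci_covers_one(rng):
    covered = 0
    reps = 60
    for rep in range(reps):
        r = np.random.default_rng(rep)
        times = r.exponential(10, 150)
        x = (r.random(150) < 0.5).astype(int)
        df = _records(times, [True] * 150, gloh_high=x)
        fit = cox_fit(df, ["gloh_high"])
        covered += fit.ci_low <= 1.0 <= fit.ci_high
    assert covered / reps >= 0.88


# -------------------------------------------------------------------- composite
def test_run_survival_analysis_bundles_everything(rng):
    n = 120
    gloh = rng.lognormal(2.4, 0.5, n)
    high = gloh > np.median(gloh)
    times = rng.exponential(np.where(high, 30, 10))
    df = _records(times, [True] * n, gloh=gloh)
    fit = run_survival_analysis(df)
    assert fit.hr < 1.0
    assert fit.logrank_p < 0.05
    assert set(fit.km_curves) == {"high", "low"}
    assert fit.median_cutoff == pytest.approx(np.median(gloh))
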