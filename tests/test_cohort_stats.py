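import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lohscape.cohort_stats import (classify_gloh_high, find_inflection_point,
                                   summarize_cohort, summarize_distribution)
from lohscape.errors import (InsufficientDataError, InvalidArgumentError,
                             NoInflectionError)
from lohscape.synthetic_data import lognormal_params_from_moments


# ------------------------------------------------------------- inflection point
def test_sigmoid_quantile_inflection_found():
    """Ranked curve planted as a logistic sigmoid: analytic inflection at
    rank 0.5, value L/2."""
    n = 20_000
    L, k = 40.0, 12.0
    ranks = (np.arange(n) + 0.5) / n
    values = L / (1.0 + np.exp(-k * (ranks - 0.5)))
    res = find_inflection_point(values)
    assert abs(res.cutoff_percent - L / 2) / (L / 2) < 0.02
    assert not res.boundary


def test_linear_ramp_has_no_inflection():
    with pytest.raises(NoInflectionError):
        find_inflection_point(np.linspace(1.0, 50.0, 500))


def test_identical_values_rejected():
    with pytest.raises(NoInflectionError):
        find_inflection_point(np.full(100, 7.0))


def test_small_samples_rejected():
    with pytest.raises(InsufficientDataError):
        find_inflection_point(np.arange(49, dtype=float))


def test_lognormal_cutoff_lands_in_upper_tail():
    mu, sigma = lognormal_params_from_moments(12.9, 6.9)
    values = np.random.default_rng(2).lognormal(mu, sigma, 50_000)
    res = find_inflection_point(values)
    assert res.cutoff_percent > np.quantile(values, 0.90)
    assert values.min() <= res.cutoff_percent <= values.max()


def test_duplication_invariance():
    n = 5_000
    ranks = (np.arange(n) + 0.5) / n
    values = 30.0 / (1.0 + np.exp(-10.0 * (ranks - 0.5)))
    single = find_inflection_point(values)
    doubled = find_inflection_point(np.concatenate([values, values]))
    assert abs(single.cutoff_percent - doubled.cutoff_percent) < 0.02 * 30.0


def test_error_shrinks_with_n():
    L, k = 40.0, 12.0
    errors = []
    for n in (500, 5_000, 50_000):
        ranks = (np.arange(n) + 0.5) / n
        values = L / (1.0 + np.exp(-k * (ranks - 0.5)))
        res = find_inflection_point(values)
        errors.append(abs(res.cutoff_percent - L / 2))
    assert errors[2] <= errors[0] + 1e-9


# --------------------------------------------------------------- classification
def test_paper_counts_reproduce_headline_fraction():
    """1658 tumors, 65 at or above the cutoff: 3.9% after rounding."""
    values = np.concatenate([np.full(65, 30.0), np.full(1658 - 65, 10.0)])
    cls = classify_gloh_high(values, 26.1)
    assert cls.n_high == 65 and cls.n_total == 1658
    assert round(100 * cls.fraction_high, 1) == 3.9


def test_cutoff_below_minimum_is_all_high():
    cls = classify_gloh_high([5.0, 6.0], 1.0)
    assert cls.fraction_high == 1.0


def test_infinite_cutoff_is_none_high():
    cls = classify_gloh_high([5.0, 6.0], np.inf)
    assert cls.fraction_high == 0.0


def test_ties_count_as_high():
    assert classify_gloh_high([14.0, 13.9], 14.0).n_high == 1


def test_empty_input_rejected():
    with pytest.raises(InvalidArgumentError):
        classify_gloh_high([], 10.0)


@settings(max_examples=40, deadline=None)
@given(st.lists(st.floats(0, 100), min_size=1, max_size=50),
       st.floats(0, 100), st.floats(0, 100))
def test_fraction_high_monotone_in_cutoff(values, c1, c2):
    lo, hi = sorted((c1, c2))
    assert classify_gloh_high(values, lo).fraction_high >= \
        classify_gloh_high(values, hi).fraction_high


# ------------------------------------------------------------------ distribution
def test_constant_values_summary():
    s = summarize_distribution([3.0, 3.0, 3.0])
    assert s.mean == 3.0 and s.sd == 0.0


def test_lognormal_mle_consistent():
    rng = np.random.default_rng(4)
    mu, sigma = 2.3, 0.6
    values = rng.lognormal(mu, sigma, 50_000)
    s = summarize_distribution(values)
    se_mu = sigma / np.sqrt(len(values))
    se_sigma = sigma / np.sqrt(2 * len(values))
    assert abs(s.lognormal_mu - mu) < 3 * se_mu
    assert abs(s.lognormal_sigma - sigma) < 3 * se_sigma
    assert s.gof_p > 0.01


def test_non_lognormal_mixture_rejected():
    rng = np.random.default_rng(5)
    values = np.concatenate([rng.uniform(1, 2, 2500), rng.uniform(40, 41, 2500)])
    assert summarize_distribution(values).gof_p < 0.01


def test_insufficient_data():
    with pytest.raises(InsufficientDataError):
        summarize_distribution([1.0, 2.0])


def test_zeros_handled_with_offset():
    s = summarize_distribution([0.0, 1.0, 2.0, 4.0])
    assert np.isfinite(s.lognormal_mu)


# ------------------------------------------------------------------ cohort table
def test_summarize_cohort_percentages():
    import pandas as pd
    df = pd.DataFrame({
        "sex": ["male"] * 327 + ["female"] * 1331,
        "uterine": [True] * 651 + [False] * 1007,
        "gloh": np.linspace(1, 30, 1658),
    })
    out = summarize_cohort(df)
    assert out["sex"]["male"] == {"n": 327, "pct": 19.7}
    assert out["sex"]["female"] == {"n": 1331, "pct": 80.3}
    assert out["uterine"] == {"n": 651, "pct": 39.3}
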