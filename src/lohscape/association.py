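"""Cohort association analyses linking gLOH to genomic alterations.

Covers: homologous-recombination (HR) group assignment and contrasts,
the pathway-agnostic univariate screen with Bonferroni q-values and a
prevalence filter, the joint multivariate fit with uterine status, the
uterine vs non-uterine differential-prevalence test, and pairwise mutual
exclusivity / co-occurrence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, SingularDesignError
from .synthetic_data.cohort import Key, alteration_columns, column_key, key_column

# HR pathway genes named across the source literature; user-overridable.
DEFAULT_HR_GENES = (
    "BRCA1", "BRCA2", "ATM", "ATR", "BRIP1", "CHEK2", "NBN", "PALB2",
    "RAD51", "RAD51B", "RAD51C", "RAD51D",
    "FANCA", "FANCC", "FANCD2", "FANCE", "FANCF", "FANCG", "FANCL",
)

HR_GROUPS = ("HR_intact", "HR_mutation", "non_BRCA2_homdel", "BRCA2_homdel")

ODDS_RATIO_CAP = 1e6


@dataclass(frozen=True)
class RegressionFit:
    key: str  # "GENE:class" or a covariate name
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float | None = None
    prevalence: float | None = None
    m_tests: int | None = None


@dataclass
class GroupContrast:
    group_n: dict[str, int]
    group_mean: dict[str, float]
    group_sd: dict[str, float]
    anova_f: float
    anova_p: float
    pairwise: list[dict] = field(default_factory=list)  # label, t, p_raw, p_adj


def assign_hr_groups(cohort: pd.DataFrame, hr_genes=DEFAULT_HR_GENES) -> pd.Series:
    """Per-sample HR group with precedence
    BRCA2_homdel > non_BRCA2_homdel > HR_mutation > HR_intact."""
    hr_genes = list(hr_genes)
    cols = alteration_columns(cohort)
    genes_present = {column_key(c)[0] for c in cols}
    unknown = [g for g in hr_genes if g not in genes_present]
    if unknown:
        warnings.warn(f"HR genes absent from the cohort matrix: {unknown}", stacklevel=2)

    def cols_of(pred):
        return [c for c in cols if pred(*column_key(c))]

    brca2_del = cols_of(lambda g, a: g == "BRCA2" and g in hr_genes and a == "homozygous_deletion")
    other_del = cols_of(lambda g, a: g in hr_genes and g != "BRCA2" and a == "homozygous_deletion")
    hr_mut = cols_of(lambda g, a: g in hr_genes and a != "homozygous_deletion")

    def any_of(columns):
        if not columns:
            return np.zeros(len(cohort), dtype=bool)
        return cohort[columns].to_numpy().sum(axis=1) > 0

    group = np.full(len(cohort), "HR_intact", dtype=object)
    group[any_of(hr_mut)] = "HR_mutation"
    group[any_of(other_del)] = "non_BRCA2_homdel"
    group[any_of(brca2_del)] = "BRCA2_homdel"
    return pd.Series(group, index=cohort.index, name="hr_group")


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and two-sided p (means a - b)."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def group_contrast(
    groups: dict[str, np.ndarray],
    control: str = "HR_intact",
    method: str = "dunnett",
    seed: int = 0,
    n_mc: int = 50_000,
) -> GroupContrast:
    """One-way ANOVA plus pairwise comparisons with multiplicity adjustment.

    ``method='dunnett'`` compares each group to the control with Welch t
    statistics; the max-|t| null for the adjustment is evaluated by seeded
    Monte Carlo (the comparisons share the control arm, so they are
    correlated).  ``method='tukey'`` runs the all-pairs test instead.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    for k in set(groups) - set(usable):
        warnings.warn(f"group {k!r} has < 2 samples; its comparisons are skipped", stacklevel=2)
    if len(usable) < 2:
        raise InvalidArgumentError("need >= 2 groups with >= 2 samples each")

    arrays = list(usable.values())
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        anova_f, anova_p = 0.0, 1.0
    else:
        anova_f, anova_p = stats.f_oneway(*arrays)
        if np.isnan(anova_f):  # zero within-group variance with equal means
            anova_f, anova_p = 0.0, 1.0

    out = GroupContrast(
        group_n={k: len(v) for k, v in groups.items()},
        group_mean={k: float(np.mean(v)) if len(v) else float("nan") for k, v in groups.items()},
        group_sd={k: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan") for k, v in groups.items()},
        anova_f=float(anova_f),
        anova_p=float(anova_p),
    )

    if method == "tukey":
        keys = list(usable)
        res = stats.tukey_hsd(*[usable[k] for k in keys])
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                t, p_raw = _welch_t(usable[keys[i]], usable[keys[j]])
                out.pairwise.append({
                    "label": f"{keys[i]} vs {keys[j]}", "t": t, "p_raw": p_raw,
                    "p_adj": float(res.pvalue[i, j]),
                })
        return out

    if method != "dunnett":
        raise InvalidArgumentError(f"unknown method {method!r}")
    if control not in usable:
        raise InvalidArgumentError(f"control group {control!r} missing or too small")
    others = [k for k in usable if k != control]
    ctrl = usable[control]
    tstats, praws, ses = [], [], []
    for k in others:
        t, p = _welch_t(usable[k], ctrl)
        tstats.append(t)
        praws.append(p)
        ses.append((np.std(usable[k], ddof=1) / np.sqrt(len(usable[k])),
                    np.std(ctrl, ddof=1) / np.sqrt(len(ctrl))))
    if others:
        rng = np.random.default_rng(seed)
        z0 = rng.standard_normal(n_mc)
        max_t = np.zeros(n_mc)
        for se_k, se_c in ses:
            denom = np.sqrt(se_k**2 + se_c**2)
            if denom == 0:
                continue
            zk = rng.standard_normal(n_mc)
            max_t = np.maximum(max_t, np.abs(zk * se_k - z0 * se_c) / denom)
        for k, t, p_raw in zip(others, tstats, praws):
            if len(others) == 1:
                p_adj = p_raw  # the max-|t| adjustment is the identity at k = 1
            elif np.isinf(t):
                p_adj = 0.0
            elif t == 0.0 and p_raw == 1.0:
                p_adj = 1.0
            else:
                p_adj = float((1 + np.sum(max_t >= abs(t))) / (n_mc + 1))
            out.pairwise.append({"label": f"{k} vs {control}", "t": t,
                                 "p_raw": p_raw, "p_adj": p_adj})
    return out


def univariate_screen(
    cohort: pd.DataFrame,
    keys: list[Key] | None = None,
    q_threshold: float = 0.1,
    prevalence_threshold: float = 0.005,
) -> tuple[list[RegressionFit], list[str]]:
    """Per-key OLS of gLOH on the binary indicator, Bonferroni-corrected.

    Only keys with prevalence > 0 (and < 1) are tested; the Bonferroni m is
    the number of keys actually tested and is recorded on every fit.
    Returns all fits plus the candidate columns passing
    q < ``q_threshold`` and prevalence >= ``prevalence_threshold``.
    """
    y = cohort["gloh"].to_numpy(dtype=float)
    n = len(y)
    if np.ptp(y) == 0:
        raise InvalidArgumentError("gLOH is constant; regression undefined")
    cols = [key_column(k) for k in keys] if keys is not None else alteration_columns(cohort)
    X = cohort[cols].to_numpy(dtype=float)
    n1 = X.sum(axis=0)
    testable = (n1 > 0) & (n1 < n)
    cols = [c for c, ok in zip(cols, testable) if ok]
    X = X[:, testable]
    n1 = n1[testable]
    m = len(cols)
    if m == 0:
        return [], []

    n0 = n - n1
    sum1 = X.T @ y
    sumsq1 = X.T @ (y**2)
    mean1 = sum1 / n1
    mean0 = (y.sum() - sum1) / n0
    ss1 = sumsq1 - n1 * mean1**2
    ss0 = ((y**2).sum() - sumsq1) - n0 * mean0**2
    est = mean1 - mean0
    dof = n - 2
    s2 = (ss1 + ss0) / dof
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    q = np.minimum(1.0, p * m)
    tcrit = stats.t.ppf(0.975, dof)
    prev = n1 / n

    fits = [
        RegressionFit(
            key=c,
            estimate=float(est[i]),
            ci_low=float(est[i] - tcrit * se[i]),
            ci_high=float(est[i] + tcrit * se[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            prevalence=float(prev[i]),
            m_tests=m,
        )
        for i, c in enumerate(cols)
    ]
    candidates = [f.key for f in fits
                  if f.q_value < q_threshold and f.prevalence >= prevalence_threshold]
    return fits, candidates


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedy full-rank column subset; duplicated/collinear columns dropped."""
    kept: list[str] = []
    dropped: list[str] = []
    basis = np.ones((len(X), 1))
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)[:, None]
        trial = np.hstack([basis, v])
        if np.linalg.matrix_rank(trial) > basis.shape[1]:
            basis = trial
            kept.append(col)
        else:
            dropped.append(col)
    return X[kept], dropped


def multivariate_fit(
    cohort: pd.DataFrame,
    candidate_keys: list[str],
    include_uterine: bool = True,
) -> list[RegressionFit]:
    """Joint OLS of gLOH on the candidate indicators plus uterine status.

    Collinear candidate columns are dropped with a warning (mirrors the
    near-identity of co-deleted neighbouring genes); if nothing estimable
    remains a :class:`SingularDesignError` is raised.
    """
    import statsmodels.api as sm

    y = cohort["gloh"].to_numpy(dtype=float)
    design = cohort[list(candidate_keys)].astype(float).copy()
    # exact duplicates of earlier columns (same name would confuse pandas)
    design = design.loc[:, ~design.columns.duplicated()]
    if include_uterine:
        design["uterine"] = cohort["uterine"].to_numpy(dtype=float)
    design, dropped = _drop_collinear(design)
    if dropped:
        warnings.warn(f"dropped collinear columns: {dropped}", stacklevel=2)
    if design.shape[1] == 0:
        raise SingularDesignError("no estimable columns remain after collinearity drops")

    X = sm.add_constant(design)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    fits = []
    for name in design.columns:
        fits.append(RegressionFit(
            key=name,
            estimate=float(res.params[name]),
            ci_low=float(ci.loc[name, 0]),
            ci_high=float(ci.loc[name, 1]),
            p_value=float(res.pvalues[name]),
            prevalence=float(design[name].mean()) if set(design[name].unique()) <= {0.0, 1.0} else None,
        ))
    return fits


def differential_prevalence(
    cohort: pd.DataFrame,
    keys: list[str] | None = None,
    strata_col: str = "uterine",
    delta_threshold: float = 0.10,
    p_threshold: float = 5e-5,
) -> pd.DataFrame:
    """Per-key 2x2 chi-squared between strata; significant iff
    |prevalence difference| > ``delta_threshold`` AND p < ``p_threshold``."""
    strat = cohort[strata_col].astype(bool).to_numpy()
    n_in, n_out = int(strat.sum()), int((~strat).sum())
    if n_in == 0 or n_out == 0:
        raise InvalidArgumentError(f"both {strata_col} strata must be non-empty")
    cols = keys if keys is not None else alteration_columns(cohort)
    rows = []
    for col in cols:
        x = cohort[col].to_numpy(dtype=int)
        a, b = int(x[strat].sum()), int(x[~strat].sum())
        table = np.array([[a, n_in - a], [b, n_out - b]])
        expected = stats.contingency.expected_freq(table) if table.sum() else np.ones((2, 2))
        if np.min(expected) < 1:
            warnings.warn(f"{col}: expected cell < 1; using exact test", stacklevel=2)
            p = float(stats.fisher_exact(table)[1])
            chi2 = float("nan")
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        prev_in, prev_out = a / n_in, b / n_out
        rows.append({
            "key": col,
            "prev_uterine": prev_in,
            "prev_non_uterine": prev_out,
            "delta": prev_in - prev_out,
            "chi2": float(chi2),
            "p": float(p),
            "significant": bool(abs(prev_in - prev_out) > delta_threshold and p < p_threshold),
        })
    return pd.DataFrame(rows)


def mutual_exclusivity(cohort: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Two-sided Fisher exact test on each pair's 2x2 co-occurrence table.

    Direction is 'exclusive' for odds ratio < 1, 'co_occurring' for > 1;
    infinite odds ratios are reported capped at ``ODDS_RATIO_CAP``.
    """
    cols = set(alteration_columns(cohort))
    rows = []
    for key_a, key_b in pairs:
        if key_a not in cols or key_b not in cols:
            warnings.warn(f"pair ({key_a}, {key_b}) skipped: key absent from cohort", stacklevel=2)
            continue
        a = cohort[key_a].to_numpy(dtype=bool)
        b = cohort[key_b].to_numpy(dtype=bool)
        table = np.array([
            [int(np.sum(a & b)), int(np.sum(a & ~b))],
            [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
        ])
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        if np.isinf(odds):
            odds = ODDS_RATIO_CAP
        direction = "exclusive" if odds < 1 else ("co_occurring" if odds > 1 else "none")
        rows.append({"key_a": key_a, "key_b": key_b, "odds_ratio": float(odds),
                     "p": float(p), "direction": direction,
                     "n_both": int(table[0, 0])})
    return pd.DataFrame(rows)
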