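"""Independent reference implementations used only by the tests.

Each oracle is written from the mathematical definition, deliberately not
sharing code with the package paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- changepoints
def _segment_cost_matrix(x: np.ndarray) -> np.ndarray:
    """C[s, t] = within-segment sum of squares of x[s:t), summed over dims."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    n = x.shape[0]
    C = np.full((n + 1, n + 1), np.inf)
    for s in range(n):
        cs = np.cumsum(x[s:], axis=0)
        cs2 = np.cumsum(x[s:] ** 2, axis=0)
        lens = np.arange(1, n - s + 1, dtype=float)
        costs = np.sum(cs2 - cs**2 / lens[:, None], axis=1)
        C[s, s + 1:] = costs
    return C


def dp_changepoint_oracle(signal, penalty: float, k_max: int = 25) -> list[int]:
    """Exhaustive DP over the number of segments; returns interior breakpoints
    minimizing total L2 cost + penalty * n_segments."""
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    n = x.shape[0]
    C = _segment_cost_matrix(x)
    k_max = min(k_max, n)
    # D[k][t]: best cost of covering x[:t] with exactly k segments
    D = np.full((k_max + 1, n + 1), np.inf)
    back = np.zeros((k_max + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for k in range(1, k_max + 1):
        for t in range(k, n + 1):
            cand = D[k - 1, :t] + C[:t, t]
            s = int(np.argmin(cand))
            D[k, t] = cand[s]
            back[k, t] = s
    totals = [D[k, n] + penalty * k for k in range(1, k_max + 1)]
    k_star = int(np.argmin(totals)) + 1
    bps = []
    t = n
    for k in range(k_star, 0, -1):
        s = back[k, t]
        if s > 0:
            bps.append(int(s))
        t = s
    return sorted(bps)


def best_single_breakpoint(signal) -> int:
    """Exhaustive scan for the best single split of a 1-segment signal."""
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    n = x.shape[0]

    def sse(a):
        return float(np.sum((a - a.mean(axis=0)) ** 2))

    costs = [sse(x[:t]) + sse(x[t:]) for t in range(1, n)]
    return int(np.argmin(costs)) + 1


# ------------------------------------------------------------------- (Ci, Mi)
def brute_force_cn_oracle(mean_log_ratio: float, folded_baf: float,
                          purity: float, psi: float, ci_max: int = 8,
                          denom_floor: float = 0.05) -> tuple[int, int]:
    """Plain double loop over all states; ties toward smaller ci, larger mi."""
    best = None
    for ci in range(ci_max + 1):
        for mi in range(ci // 2 + 1):
            num = max(purity * ci + 2 * (1 - purity), denom_floor)
            den = max(purity * psi + 2 * (1 - purity), denom_floor)
            exp_lr = math.log2(num / den)
            exp_fb = abs((purity * mi + (1 - purity)) / num - 0.5)
            cost = (mean_log_ratio - exp_lr) ** 2 + (folded_baf - exp_fb) ** 2
            key = (cost, ci, -mi)
            if best is None or key < best[0]:
                best = (key, (ci, mi))
    return best[1]


# ---------------------------------------------------------------- percent gLOH
def interval_gloh_oracle(intervals) -> float:
    """intervals: iterable of (length, is_loh, excluded).  Direct arithmetic."""
    loh = sum(length for length, is_loh, excluded in intervals if is_loh and not excluded)
    tot = sum(length for length, _, excluded in intervals if not excluded)
    return 100.0 * loh / tot


# -------------------------------------------------------------------- survival
def km_by_hand(times, events):
    """Product-limit estimate at each distinct event time."""
    order = np.argsort(times)
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=bool)[order]
    out = []
    s = 1.0
    n = len(times)
    for t in sorted(set(times[events])):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / at_risk
        out.append((t, s))
        _ = n
    return out


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Breslow partial log-likelihood for one covariate, no ties assumed."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


# -------------------------------------------------------------- exact 2x2 test
def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    from math import comb

    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(k):
        return comb(row1, k) * comb(row2, col1 - k) / denom

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form OLS coefficients (with intercept prepended)."""
    Xd = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
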