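"""Purity/ploidy grid fit and per-segment integer (Ci, Mi) assignment.

The commercial pipeline's fit procedure is unpublished; this module uses a
standard allele-specific copy-number grid search: for each candidate
(purity, psi) every segment is assigned its best integer state, and the
candidate minimizing the weighted squared residual between observed and
model-expected (log-ratio, folded BAF) wins.

Two well-known failure modes are handled explicitly:

* the purity/ploidy aliasing family (half purity, multiplied ploidy states
  reproduce the same signals) — resolved by preferring higher purity, then
  lower psi, among candidates within a small cost slack of the optimum;
* segments that straddle a missed breakpoint carry intermediate statistics
  that a dense low-purity lattice fits spuriously well — their influence is
  bounded by capping each segment's cost contribution.

When per-segment standard errors are supplied the cost is a capped
chi-squared; without them it falls back to plain length-weighted squared
error (exact-tie semantics), which is the mode used by noiseless contracts.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from ..errors import UnestimableError
from .states import expected_folded_baf, expected_log_ratio, state_grid

DEFAULT_PURITY_GRID = np.round(np.arange(0.10, 1.0001, 0.02), 2)
DEFAULT_PSI_GRID = np.round(np.arange(1.0, 6.0001, 0.1), 1)

CHI2_CAP = 50.0  # per-segment cap on the chi-squared contribution
BAND_FRACTION = 1.0  # cost band (fraction above the optimum) searched for the canonical member
BAND_ABSOLUTE = 30.0
BAND_MIN_PURITY = 0.20  # ultra-low-purity lattices are dense enough to fit anything
SHELF_PSI_WIDTH = 0.25  # candidates within this psi of the band's lowest psi
SHELF_COST_FRACTION = 0.15  # high-purity preference slack within the shelf
SHELF_COST_ABSOLUTE = 10.0


class StateAssignment(NamedTuple):
    ci: int
    mi: int
    margin: float  # cost(second-best state) - cost(best state)


def folded_baf_mle(alt_counts, depths) -> float:
    """MLE of the folded BAF deviation |b - 0.5| under a symmetric binomial
    mixture: alt_i ~ 1/2 Bin(d_i, b) + 1/2 Bin(d_i, 1-b).

    Folding per site with a plain mean(|alt/d - 0.5|) is biased upward by
    half-normal noise near b = 0.5; the mixture MLE is not, which matters for
    purity fitting at low tumor content.
    """
    k = np.asarray(alt_counts, dtype=float)
    d = np.asarray(depths, dtype=float)
    ok = d > 0
    k, d = k[ok], d[ok]
    if len(k) == 0:
        return 0.0

    def nll(dev: float) -> float:
        b = 0.5 - dev
        la = stats.binom.logpmf(k, d, np.clip(b, 1e-9, 1 - 1e-9))
        lb = stats.binom.logpmf(k, d, np.clip(1 - b, 1e-9, 1 - 1e-9))
        return -float(np.sum(np.logaddexp(la, lb) - np.log(2.0)))

    res = optimize.minimize_scalar(nll, bounds=(0.0, 0.5), method="bounded",
                                   options={"xatol": 1e-4})
    return float(res.x)


def _state_expectations(states, purity: float, psi: float):
    ci = np.array([s[0] for s in states], dtype=float)
    mi = np.array([s[1] for s in states], dtype=float)
    return expected_log_ratio(ci, purity, psi), expected_folded_baf(ci, mi, purity)


def _state_costs(mean_log_ratio, folded_baf, purity, psi, states,
                 se_lr=None, se_fb=None) -> np.ndarray:
    exp_lr, exp_fb = _state_expectations(states, purity, psi)
    lr_res = np.asarray(mean_log_ratio, dtype=float) - exp_lr
    fb_res = np.asarray(folded_baf, dtype=float) - exp_fb
    if se_lr is None:
        return lr_res**2 + fb_res**2
    return (lr_res / se_lr) ** 2 + (fb_res / se_fb) ** 2


def estimate_allele_specific_cn(
    mean_log_ratio: float,
    folded_baf: float,
    purity: float,
    psi: float,
    ci_max: int = 8,
    se_lr: float | None = None,
    se_fb: float | None = None,
) -> StateAssignment:
    """Best integer (ci, mi) for one segment at a fitted (purity, psi).

    Brute force over the full grid 0 <= ci <= ci_max, 0 <= mi <= ci // 2;
    ties resolve toward smaller ci then larger mi.  The returned margin
    (cost gap to the second-best state) is the downstream ambiguity score;
    it is on the chi-squared scale when standard errors are given, else on
    the raw squared-residual scale.
    """
    states = state_grid(ci_max)
    cost = _state_costs(mean_log_ratio, folded_baf, purity, psi, states,
                        se_lr=se_lr, se_fb=se_fb)
    best = int(np.argmin(cost))  # state_grid order makes argmin the tie-break winner
    sorted_cost = np.sort(cost)
    margin = float(sorted_cost[1] - sorted_cost[0]) if len(cost) > 1 else np.inf
    ci, mi = states[best]
    return StateAssignment(ci=ci, mi=mi, margin=margin)


def fit_purity_ploidy(
    mean_log_ratios,
    folded_bafs,
    lengths,
    se_lr=None,
    se_fb=None,
    purity_grid=DEFAULT_PURITY_GRID,
    psi_grid=DEFAULT_PSI_GRID,
    ci_max: int = 8,
    chi2_cap: float = CHI2_CAP,
) -> tuple[float, float]:
    """Grid-search (purity, psi); ties and near-ties break toward higher
    purity, then lower psi.

    With ``se_lr``/``se_fb`` per-segment arrays the objective is a capped
    chi-squared and the parsimony preference applies within a
    ``SLACK_FRACTION``/``SLACK_ABSOLUTE`` band of the optimum (this is what
    collapses the purity/ploidy aliasing family onto its high-purity
    member).  Without them the objective is length-weighted squared error
    with exact-tie semantics.  Raises :class:`UnestimableError` when no
    segment is usable.
    """
    lr = np.asarray(mean_log_ratios, dtype=float)
    fb = np.asarray(folded_bafs, dtype=float)
    w = np.asarray(lengths, dtype=float)
    chi2_mode = se_lr is not None
    if chi2_mode:
        se_lr = np.asarray(se_lr, dtype=float)
        se_fb = np.asarray(se_fb, dtype=float)
    ok = np.isfinite(lr) & np.isfinite(fb) & (w > 0)
    if chi2_mode:
        ok &= (se_lr > 0) & (se_fb > 0)
    if not np.any(ok):
        raise UnestimableError("no segments with usable statistics")
    lr, fb, w = lr[ok], fb[ok], w[ok]
    if chi2_mode:
        se_lr, se_fb = se_lr[ok], se_fb[ok]
    w = w / w.sum()

    states = state_grid(ci_max)
    candidates = []  # (cost, purity, psi)
    for purity in sorted(np.asarray(purity_grid, dtype=float), reverse=True):
        for psi in sorted(np.asarray(psi_grid, dtype=float)):
            exp_lr, exp_fb = _state_expectations(states, purity, psi)
            if chi2_mode:
                cost = ((lr[:, None] - exp_lr) / se_lr[:, None]) ** 2 \
                     + ((fb[:, None] - exp_fb) / se_fb[:, None]) ** 2
                total = float(np.minimum(cost.min(axis=1), chi2_cap).sum())
            else:
                cost = (lr[:, None] - exp_lr) ** 2 + (fb[:, None] - exp_fb) ** 2
                total = float(np.sum(w * cost.min(axis=1)))
            candidates.append((total, float(purity), float(psi)))

    best_cost = min(c[0] for c in candidates)
    if chi2_mode:
        # Aliasing: states scaled or shifted at another (purity, psi)
        # reproduce near-identical signals, always at HIGHER psi than the
        # canonical solution, and a dense alias lattice absorbs the misfit of
        # boundary-straddling segments, so the raw argmin is frequently an
        # alias.  Selection: within a generous cost band, move to the lowest
        # psi shelf, then prefer the highest purity among near-minimal
        # candidates on that shelf.
        band = [c for c in candidates
                if c[0] <= best_cost * (1.0 + BAND_FRACTION) + BAND_ABSOLUTE
                and c[1] >= BAND_MIN_PURITY]
        if not band:
            band = [min(candidates, key=lambda c: c[0])]
        psi_floor = min(c[2] for c in band)
        shelf = [c for c in band if c[2] <= psi_floor + SHELF_PSI_WIDTH]
        shelf_min = min(c[0] for c in shelf)
        finalists = [c for c in shelf
                     if c[0] <= shelf_min * (1.0 + SHELF_COST_FRACTION) + SHELF_COST_ABSOLUTE]
        _, purity, psi = max(finalists, key=lambda c: (c[1], -c[2], -c[0]))
        return purity, psi
    # exact ties only: candidates were generated purity-descending then
    # psi-ascending, so the first minimal entry is the tie-break winner
    for total, purity, psi in candidates:
        if total <= best_cost + 1e-12:
            return purity, psi
    raise UnestimableError("empty candidate grid")  # pragma: no cover
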