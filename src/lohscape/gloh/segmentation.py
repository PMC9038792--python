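"""Penalized changepoint segmentation of the joint (log-ratio, folded-BAF) signal.

Per chromosome, an exact Bellman dynamic program minimizes

    sum over segments of L2 cost  +  penalty * (number of segments)

where the L2 cost of a segment is the within-segment sum of squared
deviations summed over both signal dimensions.  The optimizer is exact (no
pruning), so it coincides with an exhaustive changepoint search under the
same cost and penalty.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from ..errors import InvalidArgumentError
from ..genome import GenomeModel


class SegmentSpan(NamedTuple):
    """A breakpoint-delimited segment with its site index range [i0, i1)."""

    chrom: int
    start: int  # bp, half-open
    end: int
    i0: int  # global index into the sorted site arrays
    i1: int


DEFAULT_PENALTY_FACTOR = 6.0
LR_SIGMA_FLOOR = 0.05
FB_SIGMA_FLOOR = 0.015


def robust_noise_sigma(x: np.ndarray) -> float:
    """Per-site noise SD from first differences (changepoints are sparse)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(x))) / (0.6745 * np.sqrt(2.0)))


def default_penalty(signal: np.ndarray, factor: float = DEFAULT_PENALTY_FACTOR) -> float:
    """BIC-style penalty for a *standardized* (unit-noise) signal: factor * log(n)."""
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    n = max(signal.shape)
    return max(factor * np.log(max(n, 2)), 1e-8)


def optimal_breakpoints(signal: np.ndarray, penalty: float) -> list[int]:
    """Interior breakpoints (site indices) of the optimal penalized partition.

    ``signal`` is (n, d); a breakpoint at t means segments split between
    sites t-1 and t.  Exact O(n^2) Bellman recursion.
    """
    if penalty <= 0:
        raise InvalidArgumentError(f"penalty must be > 0; got {penalty}")
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and signal.ndim == 1:
        x = x.T
    n = x.shape[0]
    if n <= 1:
        return []
    # prefix sums with a leading zero row: S1[t] = sum x[:t]
    s1 = np.vstack([np.zeros(x.shape[1]), np.cumsum(x, axis=0)])
    s2 = np.vstack([np.zeros(x.shape[1]), np.cumsum(x**2, axis=0)])

    best = np.empty(n + 1)
    best[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    t_idx = np.arange(n + 1, dtype=float)
    for t in range(1, n + 1):
        # cost of segment [s, t) for all s < t, summed over dimensions
        lens = t - t_idx[:t]
        d1 = s1[t] - s1[:t]
        d2 = s2[t] - s2[:t]
        seg_cost = np.sum(d2 - d1**2 / lens[:, None], axis=1)
        cand = best[:t] + seg_cost + penalty
        s_star = int(np.argmin(cand))
        best[t] = cand[s_star]
        prev[t] = s_star
    bps = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            bps.append(int(s))
        t = s
    return sorted(bps)


def _merge_small(bounds: list[int], signal: np.ndarray, min_snps: int) -> list[int]:
    """Merge segments with < min_snps sites into the neighbor with closer mean."""
    bounds = list(bounds)
    while True:
        sizes = np.diff(bounds)
        if len(sizes) <= 1 or np.all(sizes >= min_snps):
            return bounds
        k = int(np.argmin(sizes))
        lo, hi = bounds[k], bounds[k + 1]
        mean_k = signal[lo:hi].mean(axis=0)
        d_left = np.inf if k == 0 else float(np.sum((signal[bounds[k - 1]:lo].mean(axis=0) - mean_k) ** 2))
        d_right = np.inf if k == len(sizes) - 1 else float(np.sum((signal[hi:bounds[k + 2]].mean(axis=0) - mean_k) ** 2))
        drop = k if d_left <= d_right else k + 1  # remove the shared boundary
        del bounds[drop]


def segment_profile(
    chroms,
    positions,
    log_ratios,
    folded_bafs,
    genome: GenomeModel,
    penalty: float | None = None,
    min_snps: int = 5,
    depths=None,
    penalty_factor: float = DEFAULT_PENALTY_FACTOR,
) -> list[SegmentSpan]:
    """Segment each chromosome; boundaries fall at SNP midpoints.

    Sites must be sorted by (chromosome, position) with NaN-free signals.
    Both dimensions are standardized by a pooled robust noise estimate
    (floored at assay-physics levels so an almost-constant dimension cannot
    blow the scale up); ``penalty=None`` then uses the BIC-style
    ``penalty_factor * log(n)`` per chromosome.  Segments with fewer than
    ``min_snps`` sites are merged into the nearer neighbor.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    lr = np.asarray(log_ratios, dtype=float)
    fb = np.asarray(folded_bafs, dtype=float)
    if not (len(chroms) == len(positions) == len(lr) == len(fb)):
        raise InvalidArgumentError("input arrays must share a length")
    if penalty is not None and penalty <= 0:
        raise InvalidArgumentError(f"penalty must be > 0; got {penalty}")

    fb_floor = FB_SIGMA_FLOOR
    if depths is not None and len(depths):
        fb_floor = max(0.25 / np.sqrt(max(float(np.median(depths)), 1.0)), 1e-3)
    sigma_lr = max(robust_noise_sigma(lr), LR_SIGMA_FLOOR)
    sigma_fb = max(robust_noise_sigma(fb), fb_floor)
    signal_all = np.column_stack([lr / sigma_lr, fb / sigma_fb])

    spans: list[SegmentSpan] = []
    for chrom in sorted(np.unique(chroms).tolist()):
        idx = np.flatnonzero(chroms == chrom)
        if np.any(np.diff(positions[idx]) < 0):
            raise InvalidArgumentError(f"chromosome {chrom}: positions not sorted")
        sig = signal_all[idx]
        pen_c = penalty if penalty is not None else default_penalty(sig, penalty_factor)
        bps = optimal_breakpoints(sig, pen_c)
        bounds = _merge_small([0] + bps + [len(idx)], sig, min_snps)
        chrom_len = genome.chrom_lengths[int(chrom)]
        pos_c = positions[idx]
        for j, (a, b) in enumerate(zip(bounds, bounds[1:])):
            start = 0 if j == 0 else (int(pos_c[a - 1]) + int(pos_c[a])) // 2
            end = chrom_len if j == len(bounds) - 2 else (int(pos_c[b - 1]) + int(pos_c[b])) // 2
            spans.append(SegmentSpan(int(chrom), start, end, int(idx[a]), int(idx[b - 1]) + 1))
    return spans
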