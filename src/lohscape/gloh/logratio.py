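"""Median-centered log2 coverage ratio against a process-matched reference."""

from __future__ import annotations

import numpy as np

from ..errors import InvalidArgumentError, MissingReferenceError


def compute_log_ratio_profile(tumor_depths, reference_depths):
    """Per-site log2(tumor/reference), centered so the genome-wide median is 0.

    Parameters
    ----------
    tumor_depths, reference_depths : array-like of equal length
        Reference depths must be > 0 everywhere; a NaN/absent reference is a
        :class:`MissingReferenceError`.  Sites with zero tumor depth carry no
        ratio information and are returned masked (NaN) — callers drop them.

    Returns
    -------
    log_ratios : ndarray (NaN at zero-depth tumor sites)
    n_flagged : int, count of zero-depth tumor sites omitted from centering
    """
    t = np.asarray(tumor_depths, dtype=float)
    r = np.asarray(reference_depths, dtype=float)
    if t.shape != r.shape:
        raise InvalidArgumentError(f"tumor and reference depth arrays differ in length: {t.shape} vs {r.shape}")
    if np.any(np.isnan(r)) or np.any(r <= 0):
        bad = int(np.sum(np.isnan(r) | (r <= 0)))
        raise MissingReferenceError(f"{bad} sites lack a positive reference depth")
    ok = t > 0
    if not np.any(ok):
        raise InvalidArgumentError("no sites with positive tumor depth")
    lr = np.full(t.shape, np.nan)
    lr[ok] = np.log2(t[ok] / r[ok])
    lr[ok] -= np.median(lr[ok])
    return lr, int(np.sum(~ok))
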