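"""Model-expected signals for integer allele-specific copy-number states.

For tumor purity p, tumor ploidy psi and a state with Ci total / Mi minor
copies, the bulk specimen mixes tumor and diploid-heterozygous normal:

    expected copy ratio   r  = (p*Ci + 2(1-p)) / (p*psi + 2(1-p))
    expected minor BAF    b  = (p*Mi + (1-p))  / (p*Ci  + 2(1-p))

Log-ratio is log2(r); the BAF signal is used folded, |b - 0.5|.
"""

from __future__ import annotations

import numpy as np

# Floor on the tumor-fraction denominator so Ci=0 at high purity maps to a
# large negative log-ratio instead of -inf.
DENOM_FLOOR = 0.05


def state_grid(ci_max: int = 8) -> list[tuple[int, int]]:
    """All (ci, mi) with 0 <= mi <= ci // 2, in tie-break order.

    Ordered by smaller ci, then larger mi, so a first-strict-improvement scan
    resolves cost ties conservatively against LOH over-calling.
    """
    states = []
    for ci in range(ci_max + 1):
        for mi in range(ci // 2, -1, -1):
            states.append((ci, mi))
    return states


def expected_log_ratio(ci, purity: float, psi: float) -> np.ndarray | float:
    ci = np.asarray(ci, dtype=float)
    num = np.maximum(purity * ci + 2.0 * (1.0 - purity), DENOM_FLOOR)
    den = max(purity * psi + 2.0 * (1.0 - purity), DENOM_FLOOR)
    out = np.log2(num / den)
    return out if out.ndim else float(out)


def expected_folded_baf(ci, mi, purity: float) -> np.ndarray | float:
    ci = np.asarray(ci, dtype=float)
    mi = np.asarray(mi, dtype=float)
    den = np.maximum(purity * ci + 2.0 * (1.0 - purity), DENOM_FLOOR)
    baf = (purity * mi + (1.0 - purity)) / den
    out = np.abs(baf - 0.5)
    return out if out.ndim else float(out)
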