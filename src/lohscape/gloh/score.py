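"""The percent-gLOH formula and its exclusion accounting."""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import QCFailureError, UndefinedScoreError
from ..genome import GenomeModel
from .exclusions import apply_exclusions
from .segments import CNSegment, call_loh


@dataclass(frozen=True)
class GLOHResult:
    """Percent gLOH plus the length bookkeeping behind it (bp)."""

    percent_gloh: float
    loh_len_included: int
    total_len_included: int
    len_excluded_arm: int
    len_excluded_ambiguous: int

    @property
    def total_len(self) -> int:
        return self.total_len_included + self.len_excluded_arm + self.len_excluded_ambiguous


def percent_gloh_from_segments(segments: list[CNSegment]) -> GLOHResult:
    """100 x (non-excluded LOH length) / (non-excluded total length).

    Segments must already carry LOH calls and exclusion flags.
    """
    loh_len = total_len = excl_arm = excl_amb = 0
    for seg in segments:
        if seg.excluded:
            if seg.exclusion_reason == "whole_chrom_or_arm":
                excl_arm += seg.length
            else:
                excl_amb += seg.length
            continue
        total_len += seg.length
        if seg.is_loh:
            loh_len += seg.length
    if total_len == 0:
        raise UndefinedScoreError("all genome length excluded; percent gLOH undefined")
    return GLOHResult(
        percent_gloh=100.0 * loh_len / total_len,
        loh_len_included=loh_len,
        total_len_included=total_len,
        len_excluded_arm=excl_arm,
        len_excluded_ambiguous=excl_amb,
    )


def compute_percent_gloh(profile) -> GLOHResult:
    """Score a fitted :class:`~lohscape.gloh.pipeline.TumorProfile`.

    Raises :class:`QCFailureError` (carrying the reason) unless the profile
    passed QC or its config allows scoring anyway.
    """
    if not profile.qc_pass and not getattr(profile, "score_on_qc_fail", False):
        raise QCFailureError(profile.qc_reason)
    return percent_gloh_from_segments(profile.segments)


def truth_segments(planted, genome: GenomeModel, arm_span_threshold: float = 0.90) -> list[CNSegment]:
    """Ground-truth segments from planted (ci, mi) states, exclusions applied.

    Ambiguity exclusions do not apply to noiseless truth; only the
    whole-chromosome/arm rule does.  Shares the same LOH rule, exclusion and
    formula code paths as the estimation pipeline.
    """
    segs = [
        CNSegment(chrom=p.chrom, start=p.start, end=p.end, ci=p.ci, mi=p.mi, n_snps=10**9)
        for p in planted
    ]
    for seg in segs:
        seg.is_loh = call_loh(seg)
    return apply_exclusions(segs, genome, arm_span_threshold=arm_span_threshold, check_ambiguity=False)


def true_percent_gloh(planted, genome: GenomeModel, arm_span_threshold: float = 0.90) -> GLOHResult:
    """Percent gLOH of a planted profile (the generator's ground truth)."""
    return percent_gloh_from_segments(truth_segments(planted, genome, arm_span_threshold))
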