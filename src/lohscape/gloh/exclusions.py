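"""Exclusion of whole-chromosome/arm LOH runs and ambiguous segments.

Adjacent LOH segments are merged into maximal runs before the span test, so
the rule is invariant to how the segmenter happened to split an LOH region.
Exclusion removes length from both the numerator and denominator of the
percent-gLOH formula.
"""

from __future__ import annotations

from ..errors import InvalidArgumentError
from ..genome import GenomeModel
from .segments import CNSegment


def merge_loh_runs(segments: list[CNSegment]) -> list[tuple[int, int, int]]:
    """Maximal contiguous LOH runs as (chrom, start, end), half-open bp."""
    runs: list[tuple[int, int, int]] = []
    by_chrom: dict[int, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom in sorted(by_chrom):
        segs = sorted(by_chrom[chrom], key=lambda s: s.start)
        run_start = run_end = None
        for seg in segs:
            if not seg.is_loh:
                if run_start is not None:
                    runs.append((chrom, run_start, run_end))
                    run_start = run_end = None
                continue
            if run_start is not None and seg.start == run_end:
                run_end = seg.end
            else:
                if run_start is not None:
                    runs.append((chrom, run_start, run_end))
                run_start, run_end = seg.start, seg.end
        if run_start is not None:
            runs.append((chrom, run_start, run_end))
    return runs


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def apply_exclusions(
    segments: list[CNSegment],
    genome: GenomeModel,
    arm_span_threshold: float = 0.90,
    min_snps: int = 5,
    margin_threshold: float = 0.05,
    check_ambiguity: bool = True,
) -> list[CNSegment]:
    """Return new segments with exclusion flags set.

    An LOH run covering >= ``arm_span_threshold`` of its whole chromosome, or
    of either arm it overlaps, is excluded in full (reason
    ``whole_chrom_or_arm``).  Independently, any segment with too few SNPs or
    a (ci, mi) confidence margin below ``margin_threshold`` is excluded as
    ``ambiguous`` (set ``check_ambiguity=False`` for noiseless ground truth).
    """
    if genome is None:
        raise InvalidArgumentError("arm definitions required: genome is None")
    for seg in segments:
        if seg.chrom not in genome.chrom_lengths:
            raise InvalidArgumentError(f"no arm definition for chromosome {seg.chrom}")

    excluded_intervals: dict[int, list[tuple[int, int]]] = {}
    for chrom, start, end in merge_loh_runs(segments):
        chrom_len = genome.chrom_lengths[chrom]
        spans = (end - start) >= arm_span_threshold * chrom_len
        if not spans:
            for arm_start, arm_end in genome.arms(chrom):
                arm_len = arm_end - arm_start
                if arm_len > 0 and _overlap(start, end, arm_start, arm_end) >= arm_span_threshold * arm_len:
                    spans = True
                    break
        if spans:
            excluded_intervals.setdefault(chrom, []).append((start, end))

    out: list[CNSegment] = []
    for seg in segments:
        new = seg.copy(excluded=False, exclusion_reason="none")
        runs = excluded_intervals.get(seg.chrom, ())
        if new.is_loh and any(_overlap(seg.start, seg.end, s, e) == seg.length for s, e in runs):
            new = new.copy(excluded=True, exclusion_reason="whole_chrom_or_arm")
        elif check_ambiguity and (seg.n_snps < min_snps or seg.margin < margin_threshold):
            new = new.copy(excluded=True, exclusion_reason="ambiguous")
        out.append(new)
    return out
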