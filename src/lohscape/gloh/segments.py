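"""Copy-number segment records and the LOH call rule."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from ..errors import InvalidArgumentError

EXCLUSION_REASONS = ("none", "whole_chrom_or_arm", "ambiguous")


@dataclass
class CNSegment:
    """A genomic interval with copy-number state and exclusion bookkeeping.

    Coordinates are 0-based half-open bp. ``ci`` is the integer total copy
    number, ``mi`` the minor-allele copy count (0 <= mi <= ci // 2).
    """

    chrom: int
    start: int
    end: int
    mean_log_ratio: float = 0.0
    folded_baf: float = 0.0  # observed deviation of BAF from 0.5, in [0, 0.5]
    n_snps: int = 0
    ci: int | None = None
    mi: int | None = None
    margin: float = math.inf  # cost gap to the second-best (ci, mi) state
    is_loh: bool = False
    excluded: bool = False
    exclusion_reason: str = "none"
    mean_depth: float = float("nan")
    lr_se: float = float("nan")  # standard error of mean_log_ratio
    fb_se: float = float("nan")  # standard error of folded_baf

    def __post_init__(self):
        if self.end <= self.start:
            raise InvalidArgumentError(f"segment end must exceed start: [{self.start}, {self.end})")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise InvalidArgumentError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.excluded and self.exclusion_reason == "none":
            raise InvalidArgumentError("excluded segment must carry a reason")
        if self.ci is not None and self.ci < 0:
            raise InvalidArgumentError("ci must be >= 0")
        if self.mi is not None:
            if self.ci is None:
                raise InvalidArgumentError("mi set without ci")
            if not (0 <= self.mi <= self.ci // 2):
                raise InvalidArgumentError(f"mi must satisfy 0 <= mi <= ci // 2; got ci={self.ci}, mi={self.mi}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def copy(self, **changes) -> "CNSegment":
        return replace(self, **changes)


def call_loh(segment_or_ci, mi: int | None = None) -> bool:
    """A segment is in LOH iff total copies Ci != 0 and minor copies Mi == 0.

    Homozygous deletion (Ci = 0) is *not* LOH under this rule.
    Accepts either a :class:`CNSegment` or an explicit ``(ci, mi)`` pair.
    """
    if isinstance(segment_or_ci, CNSegment):
        ci, mi = segment_or_ci.ci, segment_or_ci.mi
    else:
        ci = segment_or_ci
    if ci is None or mi is None:
        raise InvalidArgumentError("LOH call requires assigned (ci, mi)")
    return ci != 0 and mi == 0


def validate_tiling(segments: list[CNSegment], chrom_lengths: dict[int, int]) -> None:
    """Check segments per chromosome are sorted, disjoint and cover [0, length)."""
    by_chrom: dict[int, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        if chrom not in chrom_lengths:
            raise InvalidArgumentError(f"segment on unknown chromosome {chrom}")
        segs = sorted(segs, key=lambda s: s.start)
        if segs[0].start != 0:
            raise InvalidArgumentError(f"chromosome {chrom}: segments do not start at 0")
        for prev, cur in zip(segs, segs[1:]):
            if cur.start != prev.end:
                raise InvalidArgumentError(
                    f"chromosome {chrom}: gap or overlap between {prev.end} and {cur.start}"
                )
        if segs[-1].end != chrom_lengths[chrom]:
            raise InvalidArgumentError(
                f"chromosome {chrom}: segments end at {segs[-1].end}, expected {chrom_lengths[chrom]}"
            )
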