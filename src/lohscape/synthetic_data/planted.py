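"""Planted ground-truth copy-number profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidArgumentError
from ..genome import GenomeModel


@dataclass(frozen=True)
class PlantedSegment:
    """True copy-number state on a half-open interval [start, end)."""

    chrom: int
    start: int
    end: int
    ci: int
    mi: int

    def __post_init__(self):
        if self.end <= self.start:
            raise InvalidArgumentError("planted segment end must exceed start")
        if self.ci < 0 or not (0 <= self.mi <= self.ci // 2):
            raise InvalidArgumentError(f"invalid state (ci={self.ci}, mi={self.mi})")

    @property
    def length(self) -> int:
        return self.end - self.start


def validate_planted(planted: list[PlantedSegment], genome: GenomeModel) -> None:
    """Planted segments must tile every chromosome without gaps or overlaps."""
    by_chrom: dict[int, list[PlantedSegment]] = {}
    for seg in planted:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    if set(by_chrom) != set(genome.chromosomes):
        missing = set(genome.chromosomes) - set(by_chrom)
        raise InvalidArgumentError(f"planted segments leave whole chromosomes uncovered: {sorted(missing)}")
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        if segs[0].start != 0 or segs[-1].end != genome.chrom_lengths[chrom]:
            raise InvalidArgumentError(f"chromosome {chrom}: planted segments do not span [0, length)")
        for prev, cur in zip(segs, segs[1:]):
            if cur.start != prev.end:
                raise InvalidArgumentError(f"chromosome {chrom}: gap/overlap at {prev.end}..{cur.start}")


def plant_diploid(genome: GenomeModel) -> list[PlantedSegment]:
    """A fully diploid-heterozygous genome: (ci, mi) = (2, 1) everywhere."""
    return [
        PlantedSegment(chrom=c, start=0, end=genome.chrom_lengths[c], ci=2, mi=1)
        for c in genome.chromosomes
    ]


def _arm_pieces(start: int, end: int, rng: np.random.Generator, target_piece: int) -> list[tuple[int, int]]:
    """Cut an arm into pieces of roughly target_piece bp with +-25% jitter."""
    length = end - start
    k = max(1, round(length / target_piece))
    cuts = np.linspace(0, length, k + 1)
    if k > 1:
        jitter = rng.uniform(-0.25, 0.25, size=k - 1) * (length / k)
        cuts[1:-1] = np.sort(cuts[1:-1] + jitter)
    bounds = start + np.round(cuts).astype(int)
    bounds[0], bounds[-1] = start, end
    return [(int(a), int(b)) for a, b in zip(bounds, bounds[1:]) if b > a]


def plant_profile_for_gloh(
    genome: GenomeModel,
    target_gloh: float,
    seed: int,
    loh_states: tuple[tuple[int, int], ...] = ((1, 0), (2, 0)),
    n_gains: int = 3,
    target_piece: int = 30_000_000,
    max_arm_loh_fraction: float = 0.80,
) -> list[PlantedSegment]:
    """Random tiling whose LOH content approximates ``target_gloh`` percent.

    LOH is planted as sub-arm blocks capped at ``max_arm_loh_fraction`` of any
    arm so none of it falls to the whole-chromosome/arm exclusion; a few gain
    segments add the aneuploidy needed for the purity/ploidy fit.  The exact
    ground truth of the result is whatever the shared scoring formula says.
    """
    if not (0 <= target_gloh <= 100):
        raise InvalidArgumentError("target_gloh must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    pieces: list[tuple[int, int, int]] = []  # (chrom, start, end)
    arm_of_piece: list[int] = []
    arm_len: list[int] = []
    for arm_idx, (chrom, start, end) in enumerate(genome.all_arms()):
        for a, b in _arm_pieces(start, end, rng, target_piece):
            pieces.append((chrom, a, b))
            arm_of_piece.append(arm_idx)
            arm_len.append(end - start)

    order = rng.permutation(len(pieces))
    target_len = target_gloh / 100.0 * genome.total_length
    loh_budget_per_arm = {i: 0 for i in set(arm_of_piece)}
    states: dict[int, tuple[int, int]] = {}
    loh_total = 0
    s = 0
    for idx in order:
        if loh_total >= target_len:
            break
        chrom, a, b = pieces[idx]
        arm = arm_of_piece[idx]
        if loh_budget_per_arm[arm] + (b - a) > max_arm_loh_fraction * arm_len[idx]:
            continue
        states[idx] = loh_states[s % len(loh_states)]
        s += 1
        loh_budget_per_arm[arm] += b - a
        loh_total += b - a

    free = [i for i in range(len(pieces)) if i not in states]
    rng.shuffle(free)
    for idx in free[:n_gains]:
        states[idx] = (3, 1)

    return [
        PlantedSegment(chrom=chrom, start=a, end=b,
                       ci=states.get(i, (2, 1))[0], mi=states.get(i, (2, 1))[1])
        for i, (chrom, a, b) in enumerate(pieces)
    ]
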