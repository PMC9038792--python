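"""Coordinate-only genome model: 22 autosomes with centromere positions.

Only interval arithmetic is needed downstream (the whole-chromosome /
whole-arm exclusion rule), so the model carries lengths and centromere
coordinates, never sequence.  The bundled default uses GRCh38-proportional
autosome lengths and approximate centromere midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidArgumentError

AUTOSOMES = tuple(range(1, 23))

# GRCh38 autosome lengths (bp).
_GRCH38_LENGTHS = {
    1: 248_956_422, 2: 242_193_529, 3: 198_295_559, 4: 190_214_555,
    5: 181_538_259, 6: 170_805_979, 7: 159_345_973, 8: 145_138_636,
    9: 138_394_717, 10: 133_797_422, 11: 135_086_622, 12: 133_275_309,
    13: 114_364_328, 14: 107_043_718, 15: 101_991_189, 16: 90_338_345,
    17: 83_257_441, 18: 80_373_285, 19: 58_617_616, 20: 64_444_167,
    21: 46_709_983, 22: 50_818_468,
}

# Approximate centromere midpoints (bp); acrocentric p-arms are short.
_CENTROMERES = {
    1: 123_400_000, 2: 93_900_000, 3: 90_900_000, 4: 50_000_000,
    5: 48_800_000, 6: 59_800_000, 7: 60_100_000, 8: 45_200_000,
    9: 43_000_000, 10: 39_800_000, 11: 53_400_000, 12: 35_500_000,
    13: 17_700_000, 14: 17_200_000, 15: 19_000_000, 16: 36_800_000,
    17: 25_100_000, 18: 18_500_000, 19: 26_200_000, 20: 28_100_000,
    21: 12_000_000, 22: 15_000_000,
}


@dataclass(frozen=True)
class GenomeModel:
    """Autosome lengths and centromere positions, all coordinates 0-based bp."""

    chrom_lengths: dict[int, int] = field(default_factory=lambda: dict(_GRCH38_LENGTHS))
    centromere_pos: dict[int, int] = field(default_factory=lambda: dict(_CENTROMERES))

    def __post_init__(self):
        if set(self.chrom_lengths) != set(self.centromere_pos):
            raise InvalidArgumentError("chrom_lengths and centromere_pos cover different chromosomes")
        for chrom, length in self.chrom_lengths.items():
            cen = self.centromere_pos[chrom]
            if not (0 < cen < length):
                raise InvalidArgumentError(
                    f"centromere of chromosome {chrom} must lie strictly inside (0, {length}); got {cen}"
                )

    @property
    def chromosomes(self) -> tuple[int, ...]:
        return tuple(sorted(self.chrom_lengths))

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def arms(self, chrom: int) -> tuple[tuple[int, int], tuple[int, int]]:
        """Return ((p_start, p_end), (q_start, q_end)) half-open intervals."""
        cen = self.centromere_pos[chrom]
        return (0, cen), (cen, self.chrom_lengths[chrom])

    def all_arms(self) -> list[tuple[int, int, int]]:
        """All arms as (chrom, start, end) half-open intervals."""
        out = []
        for chrom in self.chromosomes:
            for start, end in self.arms(chrom):
                out.append((chrom, start, end))
        return out

    @property
    def mean_arm_length(self) -> float:
        arms = self.all_arms()
        return sum(end - start for _, start, end in arms) / len(arms)


def default_genome() -> GenomeModel:
    """The bundled GRCh38-proportional 22-autosome genome."""
    return GenomeModel()


def toy_genome(n_chrom: int = 2, length: int = 100, centromere: int = 50) -> GenomeModel:
    """Tiny uniform genome for unit tests and worked examples."""
    chroms = range(1, n_chrom + 1)
    return GenomeModel(
        chrom_lengths={c: length for c in chroms},
        centromere_pos={c: centromere for c in chroms},
    )
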