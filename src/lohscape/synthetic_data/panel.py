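"""Germline-heterozygous SNP panel placement.

Homozygous sites carry no LOH information, so the panel models only sites
that are heterozygous in the (implicit) matched normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidArgumentError
from ..genome import GenomeModel


@dataclass(frozen=True)
class SnpPanel:
    """Sorted panel sites; all sites are germline heterozygous by design."""

    chrom: np.ndarray
    pos: np.ndarray  # 0-based bp

    def __len__(self) -> int:
        return len(self.chrom)


def make_snp_panel(genome: GenomeModel, n_snps: int, seed: int) -> SnpPanel:
    """Place ``n_snps`` sites approximately uniformly by genome length.

    Every arm at least one tenth of the mean arm length is guaranteed >= 1
    site; the remainder is allocated multinomially by arm length.  Output is
    sorted by (chromosome, position) and fully determined by ``seed``.
    """
    n_chrom = len(genome.chromosomes)
    if n_snps < n_chrom:
        raise InvalidArgumentError(
            f"n_snps={n_snps} is below the number of chromosomes ({n_chrom})"
        )
    rng = np.random.default_rng(seed)
    arms = genome.all_arms()
    arm_lens = np.array([end - start for _, start, end in arms], dtype=float)
    guaranteed = arm_lens >= genome.mean_arm_length / 10.0
    base = guaranteed.astype(int)
    n_left = n_snps - int(base.sum())
    if n_left < 0:
        raise InvalidArgumentError("n_snps too small to cover the guaranteed arms")
    extra = rng.multinomial(n_left, arm_lens / arm_lens.sum())
    counts = base + extra

    chroms, positions = [], []
    for (chrom, start, end), k in zip(arms, counts):
        if k == 0:
            continue
        pos = np.sort(rng.integers(start, end, size=k))
        chroms.append(np.full(k, chrom))
        positions.append(pos)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    order = np.lexsort((pos_arr, chrom_arr))
    return SnpPanel(chrom=chrom_arr[order], pos=pos_arr[order])
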