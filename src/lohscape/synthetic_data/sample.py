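"""Forward model of panel read counts for one tumor specimen.

At a germline-het site inside a planted (Ci, Mi) segment, a specimen of
purity p against a diploid normal background yields

    expected alt fraction  BAF* = (p*Mi + (1-p)) / (p*Ci + 2(1-p))
    relative copy ratio    r    = (p*Ci + 2(1-p)) / (p*psi + 2(1-p))

with psi the length-weighted mean planted Ci.  Depth is Poisson around
``depth_mean * r`` with multiplicative log-ratio noise, and the alt read
count is binomial with the major/minor role of the alt allele randomized
per site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidArgumentError
from ..genome import GenomeModel
from ..gloh.score import true_percent_gloh
from ..observations import SnpObservations
from .panel import SnpPanel
from .planted import PlantedSegment, validate_planted


@dataclass
class SimulatedSample:
    """Observed read counts plus the planted truth that generated them."""

    obs: SnpObservations
    purity: float
    ploidy_true: float
    planted: list[PlantedSegment]
    gloh_true: float
    depth_mean: float

    @property
    def ref_depth(self) -> np.ndarray:
        return self.obs.ref_depth


def _states_at_sites(panel: SnpPanel, planted: list[PlantedSegment]) -> tuple[np.ndarray, np.ndarray]:
    ci = np.empty(len(panel), dtype=int)
    mi = np.empty(len(panel), dtype=int)
    by_chrom: dict[int, list[PlantedSegment]] = {}
    for seg in planted:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        starts = np.array([s.start for s in segs])
        mask = panel.chrom == chrom
        if not np.any(mask):
            continue
        which = np.searchsorted(starts, panel.pos[mask], side="right") - 1
        ci[mask] = np.array([s.ci for s in segs])[which]
        mi[mask] = np.array([s.mi for s in segs])[which]
    return ci, mi


def simulate_sample(
    genome: GenomeModel,
    panel: SnpPanel,
    planted: list[PlantedSegment],
    purity: float,
    depth_mean: float,
    seed: int,
    lr_noise_sd: float = 0.15,
    sample_id: str = "sim",
) -> SimulatedSample:
    """Draw read counts at every panel site given a planted profile."""
    if not (0 < purity <= 1):
        raise InvalidArgumentError(f"purity must lie in (0, 1]; got {purity}")
    if depth_mean <= 0:
        raise InvalidArgumentError("depth_mean must be > 0")
    validate_planted(planted, genome)
    rng = np.random.default_rng(seed)

    total = sum(s.length for s in planted)
    psi = sum(s.length * s.ci for s in planted) / total
    ci, mi = _states_at_sites(panel, planted)

    tumor_frac = purity * ci + 2.0 * (1.0 - purity)
    ratio = tumor_frac / (purity * psi + 2.0 * (1.0 - purity))
    noise = 2.0 ** rng.normal(0.0, lr_noise_sd, size=len(panel)) if lr_noise_sd > 0 else 1.0
    depth = rng.poisson(depth_mean * ratio * noise)

    with np.errstate(invalid="ignore", divide="ignore"):
        baf_minor = np.where(tumor_frac > 0, (purity * mi + (1.0 - purity)) / tumor_frac, 0.5)
    flip = rng.random(len(panel)) < 0.5
    baf = np.where(flip, 1.0 - baf_minor, baf_minor)
    alt = rng.binomial(depth, np.clip(baf, 0.0, 1.0))

    obs = SnpObservations(
        chrom=panel.chrom.copy(), pos=panel.pos.copy(), depth=depth, alt_count=alt,
        sample_id=sample_id, ref_depth=np.full(len(panel), float(depth_mean)),
    )
    gloh_true = true_percent_gloh(planted, genome).percent_gloh
    return SimulatedSample(
        obs=obs, purity=purity, ploidy_true=psi, planted=list(planted),
        gloh_true=gloh_true, depth_mean=depth_mean,
    )
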