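"""End-to-end per-sample scoring: observations in, percent gLOH out."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import QCFailureError, UnestimableError
from ..genome import GenomeModel
from ..observations import SnpObservations
from .exclusions import apply_exclusions
from .logratio import compute_log_ratio_profile
from .purity import (DEFAULT_PSI_GRID, DEFAULT_PURITY_GRID,
                     estimate_allele_specific_cn, fit_purity_ploidy, folded_baf_mle)
from .score import GLOHResult, compute_percent_gloh
from .segmentation import segment_profile
from .segments import CNSegment, call_loh

QC_REASONS = ("none", "low_tumor_content", "low_aneuploidy")


@dataclass
class EngineConfig:
    """Tunable thresholds of the scoring pipeline.

    The QC cutoffs and the ambiguity criterion are documented proxies: the
    source assay names these failure modes and exclusions without publishing
    thresholds.
    """

    min_snps: int = 5
    # (ci, mi) margin below which a segment is ambiguous, on the SE-normalized
    # (chi-squared) scale used by the pipeline; ~9 means the best state beats
    # the runner-up by about 3 sigma
    margin_threshold: float = 9.0
    arm_span_threshold: float = 0.90
    penalty: float | None = None  # None = BIC-style automatic
    penalty_factor: float = 6.0  # multiplies log(n) on the standardized signal
    ci_max: int = 8
    purity_grid: tuple = tuple(DEFAULT_PURITY_GRID)
    psi_grid: tuple = tuple(DEFAULT_PSI_GRID)
    low_purity_threshold: float = 0.20
    aneuploid_fraction_threshold: float = 0.02
    # When the fit is near-diploid, a genome-wide excess-variance test on
    # site BAFs separates "weak but real imbalance" (low tumor content) from
    # a genuinely quiet genome (low aneuploidy).
    imbalance_z_threshold: float = 3.0
    score_on_qc_fail: bool = False


@dataclass
class TumorProfile:
    """One sample's fitted state: segments, purity/ploidy and QC status."""

    sample_id: str
    segments: list[CNSegment] = field(default_factory=list)
    purity: float = float("nan")
    psi: float = float("nan")  # grid ploidy used by the state model
    ploidy: float = float("nan")  # length-weighted mean fitted Ci
    qc_pass: bool = True
    qc_reason: str = "none"
    n_sites: int = 0
    n_zero_depth_sites: int = 0
    score_on_qc_fail: bool = False

    def __post_init__(self):
        if self.qc_reason not in QC_REASONS:
            raise ValueError(f"unknown qc reason {self.qc_reason!r}")
        if self.qc_pass != (self.qc_reason == "none"):
            raise ValueError("qc_pass must agree with qc_reason")


def segment_observations(
    obs: SnpObservations,
    reference_depths,
    genome: GenomeModel,
    config: EngineConfig,
) -> list[CNSegment]:
    """Log-ratio + folded-BAF segmentation with per-segment statistics.

    Returns raw segments (no states assigned yet).  Zero-depth sites are
    dropped before segmentation.
    """
    ref = np.broadcast_to(np.asarray(reference_depths, dtype=float), (len(obs),))
    lr, _n_flagged = compute_log_ratio_profile(obs.depth, ref)
    keep = ~np.isnan(lr)
    kept = obs.subset(keep)
    lr = lr[keep]
    folded = np.abs(kept.alt_count / kept.depth - 0.5)

    spans = segment_profile(
        kept.chrom, kept.pos, lr, folded, genome,
        penalty=config.penalty,
        min_snps=config.min_snps,
        depths=kept.depth,
        penalty_factor=config.penalty_factor,
    )
    segments = []
    for span in spans:
        sl = slice(span.i0, span.i1)
        n = span.i1 - span.i0
        mean_depth = float(np.mean(kept.depth[sl]))
        lr_sd = float(np.std(lr[sl], ddof=1)) if n > 1 else 0.3
        segments.append(CNSegment(
            chrom=span.chrom,
            start=span.start,
            end=span.end,
            mean_log_ratio=float(np.mean(lr[sl])),
            folded_baf=folded_baf_mle(kept.alt_count[sl], kept.depth[sl]),
            n_snps=n,
            mean_depth=mean_depth,
            lr_se=max(lr_sd / np.sqrt(n), 1e-3),
            fb_se=max(0.5 / np.sqrt(max(mean_depth, 1.0) * n), 1e-3),
        ))
    return segments


def imbalance_excess_variance_z(obs: SnpObservations) -> float:
    """Genome-wide z-score for allelic imbalance anywhere in the genome.

    Under a fully balanced genome, (baf - 1/2)^2 at depth d has mean 1/(4d)
    and variance ~2/(4d)^2; any imbalanced region adds its squared deviation.
    This aggregate statistic detects imbalance far too weak to support
    per-segment integer states (i.e. low tumor content).
    """
    ok = obs.depth > 0
    d = obs.depth[ok].astype(float)
    if len(d) == 0:
        return 0.0
    baf = obs.alt_count[ok] / d
    x = (baf - 0.5) ** 2 - 0.25 / d
    var = 2.0 * (0.25 / d) ** 2
    return float(np.sum(x) / np.sqrt(np.sum(var)))


def _qc(profile: TumorProfile, config: EngineConfig, imbalance_z: float) -> tuple[bool, str]:
    if profile.purity < config.low_purity_threshold:
        return False, "low_tumor_content"
    total = sum(s.length for s in profile.segments)
    aneuploid = sum(s.length for s in profile.segments if (s.ci, s.mi) != (2, 1))
    if total and aneuploid / total >= config.aneuploid_fraction_threshold:
        return True, "none"
    # near-diploid fit: decide between a genuinely quiet genome and one whose
    # signal is drowned by normal contamination
    if imbalance_z >= config.imbalance_z_threshold:
        return False, "low_tumor_content"
    return False, "low_aneuploidy"


def run_gloh(
    obs: SnpObservations,
    reference_depths,
    genome: GenomeModel,
    config: EngineConfig | None = None,
) -> tuple[GLOHResult | None, TumorProfile]:
    """Full scoring chain; returns (score-or-None, fitted profile).

    The score is ``None`` when QC fails, unless ``config.score_on_qc_fail``.
    """
    config = config or EngineConfig()
    profile = TumorProfile(sample_id=obs.sample_id, score_on_qc_fail=config.score_on_qc_fail)
    profile.n_sites = len(obs)
    profile.n_zero_depth_sites = int(np.sum(obs.depth == 0))
    try:
        segments = segment_observations(obs, reference_depths, genome, config)
        lrs = [s.mean_log_ratio for s in segments]
        fbs = [s.folded_baf for s in segments]
        lens = [s.length if s.n_snps >= config.min_snps else 0 for s in segments]
        if not any(lens):
            raise UnestimableError("all segments below min_snps")
        purity, psi = fit_purity_ploidy(
            lrs, fbs, lens,
            se_lr=[s.lr_se for s in segments],
            se_fb=[s.fb_se for s in segments],
            purity_grid=np.asarray(config.purity_grid),
            psi_grid=np.asarray(config.psi_grid),
            ci_max=config.ci_max,
        )
    except UnestimableError:
        # nothing to score even under the QC override
        profile.qc_pass, profile.qc_reason = False, "low_tumor_content"
        return None, profile

    profile.purity, profile.psi = purity, psi
    for seg in segments:
        state = estimate_allele_specific_cn(
            seg.mean_log_ratio, seg.folded_baf, purity, psi, ci_max=config.ci_max,
            se_lr=seg.lr_se, se_fb=seg.fb_se,
        )
        seg.ci, seg.mi, seg.margin = state.ci, state.mi, state.margin
        seg.is_loh = call_loh(seg)
    profile.segments = segments
    total = sum(s.length for s in segments)
    profile.ploidy = sum(s.length * s.ci for s in segments) / total if total else float("nan")

    profile.qc_pass, profile.qc_reason = _qc(profile, config, imbalance_excess_variance_z(obs))
    profile.segments = apply_exclusions(
        segments, genome,
        arm_span_threshold=config.arm_span_threshold,
        min_snps=config.min_snps,
        margin_threshold=config.margin_threshold,
    )
    try:
        result = compute_percent_gloh(profile)
    except QCFailureError:
        return None, profile
    return result, profile
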