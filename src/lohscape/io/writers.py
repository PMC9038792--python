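"""Writers for the package's tabular artifacts (1-based inclusive on disk)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ..gloh.score import GLOHResult
from ..gloh.segments import CNSegment
from ..observations import SnpObservations


def write_snp_observations(obs: SnpObservations, path) -> None:
    df = pd.DataFrame({
        "sample": obs.sample_id,
        "chrom": obs.chrom,
        "pos": obs.pos + 1,  # 1-based on disk
        "depth": obs.depth,
        "alt_count": obs.alt_count,
    })
    df.to_csv(path, sep="\t", index=False)


def write_snp_vcf(obs: SnpObservations, path, chrom_lengths: dict[int, int] | None = None) -> None:
    """Minimal single-sample VCF with DP and AD; dummy REF/ALT alleles."""
    lines = ["##fileformat=VCFv4.2"]
    if chrom_lengths:
        for chrom in sorted(chrom_lengths):
            lines.append(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>")
    lines += [
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + obs.sample_id,
    ]
    for chrom, pos, depth, alt in zip(obs.chrom, obs.pos, obs.depth, obs.alt_count):
        ref_reads = int(depth) - int(alt)
        lines.append(
            f"{chrom}\t{pos + 1}\t.\tA\tC\t.\tPASS\t.\tDP:AD\t{depth}:{ref_reads},{alt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_seg_table(segments: list[CNSegment], path, sample_id: str = "sample") -> None:
    """SEG-like TSV; 1-based inclusive coordinates."""
    rows = []
    for s in segments:
        rows.append({
            "sample": sample_id,
            "chrom": s.chrom,
            "start": s.start + 1,
            "end": s.end,  # half-open end == 1-based inclusive end
            "n_snps": s.n_snps,
            "log_ratio": round(s.mean_log_ratio, 6),
            "Ci": "" if s.ci is None else s.ci,
            "Mi": "" if s.mi is None else s.mi,
            "is_loh": int(s.is_loh),
            "excluded": int(s.excluded),
            "reason": s.exclusion_reason,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cohort_table(cohort: pd.DataFrame, path) -> None:
    df = cohort.copy()
    if "uterine" in df:
        df["uterine"] = df["uterine"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def write_survival_table(records: pd.DataFrame, path) -> None:
    df = records.copy()
    df["event"] = df["event"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def write_alteration_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_gloh_report(result: GLOHResult | None, profile, path) -> None:
    """Per-sample JSON report: purity/ploidy, QC, exclusion accounting, score."""
    payload = {
        "sample_id": profile.sample_id,
        "purity": None if np.isnan(profile.purity) else profile.purity,
        "psi": None if np.isnan(profile.psi) else profile.psi,
        "ploidy": None if np.isnan(profile.ploidy) else profile.ploidy,
        "qc_pass": profile.qc_pass,
        "qc_reason": profile.qc_reason,
        "n_sites": profile.n_sites,
        "n_zero_depth_sites": profile.n_zero_depth_sites,
        "n_segments": len(profile.segments),
        "result": None if result is None else asdict(result),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
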