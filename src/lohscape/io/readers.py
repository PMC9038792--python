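"""Readers with schema validation; all coordinates converted to 0-based."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import SchemaError
from ..observations import SnpObservations
from ..synthetic_data.cohort import ALT_CLASSES

log = logging.getLogger("lohscape")

VALID_PATHOGENICITY = ("known", "likely")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_autosome(value) -> int | None:
    """Autosome number, or None for anything else (X, Y, MT, contigs)."""
    text = str(value)
    if text.lower().startswith("chr"):
        text = text[3:]
    try:
        chrom = int(text)
    except ValueError:
        return None
    return chrom if 1 <= chrom <= 22 else None


def read_alteration_table(path) -> pd.DataFrame:
    """Load (sample, gene, alt_class, pathogenicity) records.

    Rows that are not known/likely pathogenic are dropped (count logged and
    recorded in ``df.attrs['n_excluded_vus']``).  An unknown alteration class
    is a schema error naming the offending line(s).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("sample", "gene", "alt_class", "pathogenicity"), path)
    bad = ~df["alt_class"].isin(ALT_CLASSES)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header line plus 1-based
        raise SchemaError(
            f"{path}: unknown alt_class value(s) {sorted(df.loc[bad, 'alt_class'].unique())} "
            f"at line(s) {lines}"
        )
    keep = df["pathogenicity"].isin(VALID_PATHOGENICITY)
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.info("%s: %d non-pathogenic (VUS or other) rows excluded", path, n_excluded)
    out = df[keep].reset_index(drop=True)
    out.attrs["n_excluded_vus"] = n_excluded
    return out


def _read_snp_tsv(path) -> tuple[SnpObservations, int]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("sample", "chrom", "pos", "depth", "alt_count"), path)
    chroms, pos, depth, alt = [], [], [], []
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        chrom = _parse_autosome(row.chrom)
        if chrom is None:
            n_skipped += 1
            continue
        try:
            p = int(row.pos)
            if p < 1:
                raise ValueError
        except (TypeError, ValueError):
            raise SchemaError(f"{path}: malformed coordinate {row.pos!r} at line {i}") from None
        chroms.append(chrom)
        pos.append(p - 1)
        depth.append(int(row.depth))
        alt.append(int(row.alt_count))
    sample_id = df["sample"].iloc[0] if len(df) else "sample"
    obs = SnpObservations(chrom=np.array(chroms, dtype=int), pos=np.array(pos, dtype=int),
                          depth=np.array(depth, dtype=int), alt_count=np.array(alt, dtype=int),
                          sample_id=str(sample_id))
    return obs, n_skipped


def _read_snp_vcf(path) -> tuple[SnpObservations, int]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_id = vcf.samples[0] if vcf.samples else "sample"
    chroms, pos, depth, alt = [], [], [], []
    n_skipped = 0
    for variant in vcf:
        chrom = _parse_autosome(variant.CHROM)
        if chrom is None:
            n_skipped += 1
            continue
        ad = variant.format("AD")
        if ad is None:
            raise SchemaError(f"{path}: record {variant.CHROM}:{variant.POS} lacks the AD format field")
        ad = np.asarray(ad[0], dtype=int)
        dp = variant.format("DP")
        total = int(dp[0][0]) if dp is not None else int(ad.sum())
        chroms.append(chrom)
        pos.append(int(variant.POS) - 1)
        depth.append(total)
        alt.append(int(ad[1]) if len(ad) > 1 else 0)
    obs = SnpObservations(chrom=np.array(chroms, dtype=int), pos=np.array(pos, dtype=int),
                          depth=np.array(depth, dtype=int), alt_count=np.array(alt, dtype=int),
                          sample_id=sample_id)
    return obs, n_skipped


def read_snp_observations(path) -> tuple[SnpObservations, int]:
    """Read SNP observations from TSV or VCF (by extension).

    Returns ``(observations, n_skipped)`` where ``n_skipped`` counts
    non-autosomal records dropped (the score uses autosomes only).
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        obs, n_skipped = _read_snp_vcf(path)
    else:
        obs, n_skipped = _read_snp_tsv(path)
    if n_skipped:
        log.info("%s: skipped %d non-autosomal record(s)", path, n_skipped)
    return obs, n_skipped


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("sample_id", "gloh"), path)
    if "uterine" in df:
        df["uterine"] = df["uterine"].astype(bool)
    return df


def read_survival_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("sample_id", "time", "event"), path)
    df["event"] = df["event"].astype(bool)
    return df


def read_seg_table(path) -> pd.DataFrame:
    """SEG-like table back to 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("sample", "chrom", "start", "end"), path)
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df
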