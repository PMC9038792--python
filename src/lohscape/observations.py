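"""In-memory SNP observation table shared by the simulator, engine and IO.

Coordinates are 0-based internally; on-disk formats are 1-based inclusive
and converted at the IO boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError


@dataclass
class SnpObservations:
    """Read counts at germline-heterozygous SNP sites for one sample."""

    chrom: np.ndarray
    pos: np.ndarray  # 0-based bp
    depth: np.ndarray
    alt_count: np.ndarray
    sample_id: str = "sample"
    ref_depth: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=int)
        self.pos = np.asarray(self.pos, dtype=int)
        self.depth = np.asarray(self.depth, dtype=int)
        self.alt_count = np.asarray(self.alt_count, dtype=int)
        n = len(self.chrom)
        if not (len(self.pos) == len(self.depth) == len(self.alt_count) == n):
            raise InvalidArgumentError("observation arrays must share a length")
        if self.ref_depth is not None:
            self.ref_depth = np.asarray(self.ref_depth, dtype=float)
            if len(self.ref_depth) != n:
                raise InvalidArgumentError("ref_depth length mismatch")
        if np.any(self.depth < 0) or np.any(self.alt_count < 0):
            raise InvalidArgumentError("depths and alt counts must be >= 0")
        if np.any(self.alt_count > self.depth):
            raise InvalidArgumentError("alt_count exceeds depth")
        order = np.lexsort((self.pos, self.chrom))
        if not np.all(order == np.arange(n)):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.depth = self.depth[order]
            self.alt_count = self.alt_count[order]
            if self.ref_depth is not None:
                self.ref_depth = self.ref_depth[order]

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def baf(self) -> np.ndarray:
        """Alt-allele fraction; NaN where depth is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.depth > 0, self.alt_count / np.maximum(self.depth, 1), np.nan)

    def subset(self, mask: np.ndarray) -> "SnpObservations":
        return SnpObservations(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            depth=self.depth[mask],
            alt_count=self.alt_count[mask],
            sample_id=self.sample_id,
            ref_depth=None if self.ref_depth is None else self.ref_depth[mask],
        )
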