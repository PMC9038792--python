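"""Cohort-level generator: gLOH scores, metadata and alteration indicators.

The generative model is additive on the percent scale:

    gLOH_i = clamp( LogNormal(mu, sigma)
                    + sum of planted per-alteration effects
                    + uterine effect * 1[uterine_i], 0, 100 )

with alteration carriership Bernoulli(prevalence) per (gene, class) key,
independent across keys unless exact carrier counts are requested.
Default prevalences and effects follow the published univariate estimates
so power/level simulations can run at realistic parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import InvalidArgumentError

ALT_CLASSES = ("amplification", "homozygous_deletion", "rearrangement", "truncation", "missense")

Key = tuple[str, str]

# (gene, class) -> cohort prevalence; effect in gLOH percentage points
DEFAULT_PREVALENCES: dict[Key, float] = {
    ("FBXW7", "amplification"): 0.005,
    ("NF1", "homozygous_deletion"): 0.012,
    ("BRCA2", "homozygous_deletion"): 0.021,
    ("RB1", "homozygous_deletion"): 0.311,
    ("CDKN2A", "homozygous_deletion"): 0.071,
    ("CDKN2B", "homozygous_deletion"): 0.059,
    ("MYC", "amplification"): 0.018,
    ("DAXX", "homozygous_deletion"): 0.005,
    ("RAD51B", "homozygous_deletion"): 0.023,
    ("ATM", "missense"): 0.020,
    ("TP53", "missense"): 0.40,
    ("TP53", "truncation"): 0.30,
    ("RB1", "truncation"): 0.25,
}

DEFAULT_EFFECTS: dict[Key, float] = {
    ("FBXW7", "amplification"): 18.75,
    ("NF1", "homozygous_deletion"): 10.67,
    ("BRCA2", "homozygous_deletion"): 6.13,
    ("RB1", "homozygous_deletion"): 1.9,
    ("CDKN2A", "homozygous_deletion"): 3.13,
    ("CDKN2B", "homozygous_deletion"): 3.11,
    ("MYC", "amplification"): 5.44,
    ("DAXX", "homozygous_deletion"): 9.54,
}


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD on the raw scale."""
    if mean <= 0 or sd <= 0:
        raise InvalidArgumentError("mean and sd must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


_DEFAULT_MU, _DEFAULT_SIGMA = lognormal_params_from_moments(12.9, 6.9)


@dataclass
class CohortSpec:
    n_samples: int = 1658
    uterine_fraction: float = 0.393
    gloh_lognormal_mu: float = _DEFAULT_MU
    gloh_lognormal_sigma: float = _DEFAULT_SIGMA
    alteration_prevalences: dict[Key, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    alteration_effects: dict[Key, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    uterine_effect: float = 0.86
    seed: int = 0
    exact_counts: bool = False  # plant round(prev * n) carriers instead of Bernoulli draws
    male_fraction: float = 0.197
    age_mean: float = 58.0
    age_sd: float = 11.9
    msi_high_fraction: float = 0.004
    msi_not_performed_fraction: float = 0.005
    tmb_mean: float = 2.4
    tmb_sd: float = 4.0

    def validate(self) -> None:
        for name in ("uterine_fraction", "male_fraction", "msi_high_fraction",
                     "msi_not_performed_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidArgumentError(f"{name} must lie in [0, 1]; got {v}")
        if self.gloh_lognormal_sigma <= 0:
            raise InvalidArgumentError("gloh_lognormal_sigma must be > 0")
        if self.n_samples <= 0:
            raise InvalidArgumentError("n_samples must be > 0")
        for key, prev in self.alteration_prevalences.items():
            if not (0.0 <= prev <= 1.0):
                raise InvalidArgumentError(f"prevalence of {key} outside [0, 1]: {prev}")
            gene, alt_class = key
            if alt_class not in ALT_CLASSES:
                raise InvalidArgumentError(f"unknown alteration class {alt_class!r} for {gene}")


def key_column(key: Key) -> str:
    return f"{key[0]}:{key[1]}"


def column_key(column: str) -> Key:
    gene, alt_class = column.split(":", 1)
    return gene, alt_class


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per sample: metadata, gLOH and binary alteration indicators."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    uterine = rng.random(n) < spec.uterine_fraction
    sex = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    age = np.clip(np.round(rng.normal(spec.age_mean, spec.age_sd, size=n)), 19, 85).astype(int)
    u = rng.random(n)
    msi = np.where(u < spec.msi_high_fraction, "high",
                   np.where(u < spec.msi_high_fraction + spec.msi_not_performed_fraction,
                            "not_performed", "stable"))
    tmb_mu, tmb_sigma = lognormal_params_from_moments(spec.tmb_mean, spec.tmb_sd)
    tmb = np.round(rng.lognormal(tmb_mu, tmb_sigma, size=n), 1)

    gloh = rng.lognormal(spec.gloh_lognormal_mu, spec.gloh_lognormal_sigma, size=n)
    gloh = gloh + spec.uterine_effect * uterine

    indicators: dict[str, np.ndarray] = {}
    for key in sorted(spec.alteration_prevalences):
        prev = spec.alteration_prevalences[key]
        if spec.exact_counts:
            count = int(round(prev * n))
            ind = np.zeros(n, dtype=int)
            if count:
                ind[rng.choice(n, size=min(count, n), replace=False)] = 1
        else:
            ind = (rng.random(n) < prev).astype(int)
        indicators[key_column(key)] = ind
        effect = spec.alteration_effects.get(key, 0.0)
        if effect:
            gloh = gloh + effect * ind

    return pd.DataFrame({
        "sample_id": [f"S{i:05d}" for i in range(n)],
        "gloh": np.round(np.clip(gloh, 0.0, 100.0), 6),
        "uterine": uterine,
        "sex": sex,
        "age": age,
        "msi": msi,
        "tmb": tmb,
        **indicators,
    })


def alteration_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if ":" in c]


def cohort_to_alteration_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Long-form (sample, gene, alt_class, pathogenicity) table from indicators."""
    rows = []
    for col in alteration_columns(cohort):
        gene, alt_class = column_key(col)
        for sample in cohort.loc[cohort[col] == 1, "sample_id"]:
            rows.append((sample, gene, alt_class, "known"))
    return pd.DataFrame(rows, columns=["sample", "gene", "alt_class", "pathogenicity"])
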