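"""Time-to-event simulator with a planted hazard ratio for gLOH-high."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import InvalidArgumentError


@dataclass
class SurvivalSpec:
    """Exponential event model: hazard = baseline * hr_gloh_high^x, with
    x = 1[gLOH > cohort median].  ``censoring_rate`` is the target marginal
    censoring fraction in the baseline group (1.0 censors everything)."""

    baseline_hazard: float = 0.02  # events per month
    hr_gloh_high: float = 0.31
    censoring_rate: float = 0.2

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise InvalidArgumentError("baseline_hazard must be > 0")
        if self.hr_gloh_high <= 0:
            raise InvalidArgumentError("hazard ratio must be > 0")
        if not (0.0 <= self.censoring_rate <= 1.0):
            raise InvalidArgumentError("censoring_rate must lie in [0, 1]")


def simulate_survival(cohort: pd.DataFrame, spec: SurvivalSpec, seed: int) -> pd.DataFrame:
    """Per-sample (time, event) records with covariates carried through.

    Event times are exponential; censoring times are independent
    exponentials calibrated so the baseline group's expected censored
    fraction equals ``censoring_rate``.
    """
    spec.validate()
    if len(cohort) == 0:
        raise InvalidArgumentError("cohort is empty")
    rng = np.random.default_rng(seed)
    gloh = cohort["gloh"].to_numpy(dtype=float)
    median = float(np.median(gloh))
    high = gloh > median

    hazard = spec.baseline_hazard * np.where(high, spec.hr_gloh_high, 1.0)
    event_time = rng.exponential(1.0 / hazard)

    if spec.censoring_rate >= 1.0:
        time = rng.exponential(1.0 / spec.baseline_hazard, size=len(cohort))
        event = np.zeros(len(cohort), dtype=bool)
    elif spec.censoring_rate <= 0.0:
        time, event = event_time, np.ones(len(cohort), dtype=bool)
    else:
        # P(censored) = c / (h + c) in the baseline group
        censor_hazard = spec.baseline_hazard * spec.censoring_rate / (1.0 - spec.censoring_rate)
        censor_time = rng.exponential(1.0 / censor_hazard, size=len(cohort))
        event = event_time <= censor_time
        time = np.minimum(event_time, censor_time)

    out = pd.DataFrame({
        "sample_id": cohort["sample_id"].to_numpy(),
        "time": np.maximum(time, 1e-9),
        "event": event,
        "gloh": gloh,
        "gloh_high": high.astype(int),
    })
    if "uterine" in cohort:
        out["uterine"] = cohort["uterine"].to_numpy().astype(int)
    return out
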