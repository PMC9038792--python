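"""Run configuration and the reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ..association import DEFAULT_HR_GENES
from ..errors import InvalidArgumentError


@dataclass
class RunConfig:
    """Top-level configuration of the `report` pipeline.

    One seed drives every stage; per-stage generators are spawned from it
    deterministically (see :func:`lohscape.io.report.stage_seeds`).
    """

    seed: int = 0
    n_samples: int = 1658
    panel_size: int = 3500
    n_gloh_demo_samples: int = 2
    depth_mean: float = 250.0
    cutoffs: tuple = (14.0, 16.0)
    use_inflection_cutoff: bool = True
    q_threshold: float = 0.1
    prevalence_threshold: float = 0.005
    hr_genes: tuple = tuple(DEFAULT_HR_GENES)
    min_snps: int = 5
    margin_threshold: float = 0.05
    arm_span_threshold: float = 0.90
    survival_n: int = 40
    survival_baseline_hazard: float = 0.02
    survival_hr: float = 0.31
    survival_censoring_rate: float = 0.2
    outdir: str = "lohscape_out"

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise InvalidArgumentError("n_samples must be > 0")
        if self.panel_size < 22:
            raise InvalidArgumentError("panel_size must cover all 22 autosomes")
        if not (0 < self.q_threshold <= 1):
            raise InvalidArgumentError("q_threshold must lie in (0, 1]")
        if not (0 <= self.prevalence_threshold <= 1):
            raise InvalidArgumentError("prevalence_threshold must lie in [0, 1]")
        if not (0 < self.arm_span_threshold <= 1):
            raise InvalidArgumentError("arm_span_threshold must lie in (0, 1]")
        if self.depth_mean <= 0:
            raise InvalidArgumentError("depth_mean must be > 0")
        if self.survival_n < 2:
            raise InvalidArgumentError("survival_n must be >= 2")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        d["hr_genes"] = list(self.hr_genes)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(data)
        if "cutoffs" in kwargs:
            kwargs["cutoffs"] = tuple(float(c) for c in kwargs["cutoffs"])
        if "hr_genes" in kwargs:
            kwargs["hr_genes"] = tuple(kwargs["hr_genes"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> {files: {name: sha256}, seconds: float}

    def add_stage(self, name: str, files: dict[str, Path], seconds: float) -> None:
        checksums = {}
        for label, path in files.items():
            digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
            checksums[label] = digest
        self.stages[name] = {"files": checksums, "seconds": round(seconds, 3)}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
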