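"""Pipeline configuration.

One flat dataclass holds every tunable threshold of the pipeline, each with
its documented default: score cutoff (chosen from the discovery run's
signal-to-noise table), BLAST significance E-value (1e-6), repeat-locus
limit (>5 loci rejects; a stricter >50 preset matches highly repetitive
hits), novel-validation evidence thresholds, the 10-kb cluster gap, the
read-length floor (18 nt) and the testing parameters (alpha, number of
tests).  Unknown keys in a YAML config file are rejected outright.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range threshold values."""


@dataclass
class PipelineConfig:
    score_cutoff: float = 4.0
    evalue: float = 1e-6
    max_loci: int = 5
    min_samples: int = 2
    min_arm_reads: int = 5
    consistency_frac: float = 0.9
    max_gap: int = 10_000
    gap_mode: str = "edge"
    min_read_len: int = 18
    alpha: float = 0.05
    n_tests: int = 0  # 0 = use the number of tests actually performed
    n_reference_individuals: int = 4  # per reference tissue in the DE design
    promotion_rule: str = "median_below_target_max"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ConfigError("evalue must be positive")
        if self.max_loci < 1:
            raise ConfigError("max_loci must be >= 1")
        if self.min_samples < 1:
            raise ConfigError("min_samples must be >= 1")
        if self.min_arm_reads < 0:
            raise ConfigError("min_arm_reads must be >= 0")
        if not 0 < self.consistency_frac <= 1:
            raise ConfigError("consistency_frac must be in (0, 1]")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")
        if self.gap_mode not in ("edge", "start"):
            raise ConfigError("gap_mode must be 'edge' or 'start'")
        if self.min_read_len < 1:
            raise ConfigError("min_read_len must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_tests < 0:
            raise ConfigError("n_tests must be >= 0")
        if self.promotion_rule not in (
            "median_below_target_max",
            "median_below_target_median",
            "none",
        ):
            raise ConfigError(f"unknown promotion_rule {self.promotion_rule!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
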