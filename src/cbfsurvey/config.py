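"""Pipeline configuration: a flat, validated parameter/paths block.

Configs are plain YAML; unknown keys are rejected, CLI flags override
file values, and the merged effective config is always echoed into the
output directory so every reported number is reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError", "stage_seed"]


class ConfigError(ValueError):
    """Raised on schema violations (unknown keys, bad thresholds)."""


@dataclass
class PipelineConfig:
    """Paths and parameters of the end-to-end survey pipeline.

    Parameter defaults are the study settings: 1000-bp promoters, a
    2-fold expression criterion, the RCCGAC (G/ACCGAC) CRT/DRE motif,
    1000 bootstrap replicates.
    """

    # paths (any may be None when the stage is skipped or simulated)
    genome: str | None = None
    gff: str | None = None
    proteins: str | None = None
    seeds: str | None = None
    counts: str | None = None
    totals: str | None = None
    qpcr: str | None = None
    catalogue: str | None = None
    categories: str | None = None
    terms: str | None = None
    annotations: str | None = None
    outdir: str = "cbfsurvey_out"
    # parameters
    promoter_len: int = 1000
    fold_threshold: float = 2.0
    fpkm_floor: float = 0.1
    motif: str = "RCCGAC"
    both_strands: bool = True
    bootstrap_reps: int = 1000
    seed: int = 20191017
    min_score_frac: float = 0.4
    sep_lo: int = 40
    sep_hi: int = 120
    cond_a: str = "winter_mature_leaf"
    cond_b: str = "summer_mature_leaf"
    calibrator: str | None = None
    # synthetic mode: generate inputs instead of reading them
    simulate: bool = False
    n_genes: int = 200

    def __post_init__(self) -> None:
        positive = {
            "promoter_len": self.promoter_len,
            "fold_threshold": self.fold_threshold,
            "fpkm_floor": self.fpkm_floor,
            "bootstrap_reps": self.bootstrap_reps,
            "min_score_frac": self.min_score_frac,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive (got {value})")
        if self.sep_lo < 0 or self.sep_hi < self.sep_lo:
            raise ConfigError("require 0 <= sep_lo <= sep_hi")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def stage_seed(master: int, stage: str) -> int:
    """Fan the master seed out per stage (stable name hash, < 2^31)."""
    return (int(master) ^ zlib.crc32(stage.encode())) % (2**31)
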