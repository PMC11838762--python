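"""Run configuration: every tunable threshold of the pipeline in one place.

Most of the thresholds a stoichiometry-prediction run depends on (the
residue cap of the scoring backend, enumeration ranges, template
E-value schedule, integration precedence) have defensible defaults but
must stay visible and overridable; this dataclass is loadable from YAML
and maps 1:1 onto CLI flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .candidates import DEFAULT_HETEROMER_RANGE, DEFAULT_HOMOMER_RANGE, DEFAULT_RESIDUE_CAP
from .integration import IntegrationPolicy
from .templates import DEFAULT_E_THRESHOLD, DEFAULT_RELAX_SCHEDULE

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    residue_cap: float = DEFAULT_RESIDUE_CAP  # math.inf for local AlphaFold3
    homomer_range: tuple[int, int] = DEFAULT_HOMOMER_RANGE
    heteromer_range: tuple[int, int] = DEFAULT_HETEROMER_RANGE
    e_threshold: float = DEFAULT_E_THRESHOLD
    relax_schedule: tuple[float, ...] = DEFAULT_RELAX_SCHEDULE
    af_preference: str = "max"  # preferred aggregate when AF modes disagree
    tb_override_grade: str = "medium"
    top_k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.af_preference not in ("max", "avg"):
            raise ValueError(f"af_preference must be 'max' or 'avg', got {self.af_preference!r}")
        if self.tb_override_grade not in ("medium", "high"):
            raise ValueError(f"tb_override_grade must be 'medium' or 'high'")
        if self.residue_cap <= 0:
            raise ValueError("residue_cap must be positive (use inf to disable)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        for lo, hi in (self.homomer_range, self.heteromer_range):
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid copy range ({lo}, {hi})")
        if list(self.relax_schedule) != sorted(self.relax_schedule):
            raise ValueError("relax_schedule must be increasing")

    @property
    def policy(self) -> IntegrationPolicy:
        return IntegrationPolicy(
            preferred_af=self.af_preference,
            tb_override_grade=self.tb_override_grade,
            top_n=self.top_k,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "residue_cap" in raw and raw["residue_cap"] in ("inf", "none", None):
            raw["residue_cap"] = math.inf
        for key in ("homomer_range", "heteromer_range", "relax_schedule"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
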