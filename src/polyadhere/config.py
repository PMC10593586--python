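"""Run configuration: pipeline and simulation settings with validated defaults."""
from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

log = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Settings for one adherence/outcome analysis run.

    Defaults encode the study design this package implements: new users of
    multidrug antihypertensive therapy in an index year, a 1-year washout,
    a 3-year (1,095-day) adherence-assessment window, a minimum of 90
    total days' supply, an 80% adherence cut-off, and administrative
    censoring at the end of 2015.
    """

    model_config = ConfigDict(extra="forbid")

    index_year: int = 2007
    washout_days: int = 365
    assessment_window_days: int = 1095
    min_use_days: int = 90
    adherence_threshold: float = 0.80
    carryover: Literal["shift_forward", "discard"] = "shift_forward"
    followup_end: dt.date = dt.date(2015, 12, 31)
    adjustment_sets: tuple[Literal["unadjusted", "age_sex", "full"], ...] = (
        "unadjusted",
        "age_sex",
        "full",
    )
    seed: int = 0

    @field_validator("adherence_threshold")
    @classmethod
    def _threshold_in_unit_interval(cls, v: float) -> float:
        if not (0.0 < v <= 1.0):
            raise ValueError(f"adherence_threshold must be in (0, 1], got {v}")
        return v

    @model_validator(mode="after")
    def _window_exceeds_min_use(self) -> "PipelineConfig":
        if self.assessment_window_days <= self.min_use_days:
            raise ValueError("assessment_window_days must exceed min_use_days")
        return self


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML pipeline config; unspecified fields take the defaults.

    Unknown keys are rejected rather than silently ignored. The fully
    resolved configuration is echoed to the run log.
    """
    if path is None:
        cfg = PipelineConfig()
    else:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = PipelineConfig(**raw)
    log.info("resolved config: %s", cfg.model_dump())
    return cfg
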