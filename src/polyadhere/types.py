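"""Core domain records shared across the pipeline.

All internal time axes are integer day offsets from each patient's index
date (day 0, the first qualifying prescription fill); intervals are
half-open ``[start, end)`` so that ``end - start`` is always a day count.
Calendar dates appear only at the I/O boundary.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: The closed set of antihypertensive drug classes handled by this package:
#: ACE inhibitors, angiotensin receptor blockers, beta-blockers, calcium
#: channel blockers and diuretics. Unknown labels are rejected, not coerced.
DRUG_CLASSES = ("ACEI", "ARB", "BB", "CCB", "DIU")

#: Adherence measures: PDC counting days with >=1 class available,
#: duration-weighted mean of per-class PDCs, and the daily polypharmacy
#: possession ratio.
MEASURES = ("pdc_with1", "pdc_wm", "dppr")

#: Observation-window conventions: PxM ends when the last dispensed supply
#: runs out; FxM always spans the full fixed assessment window.
METHODS = ("PxM", "FxM")

#: The six (measure, method) estimate keys, PxM block first.
ESTIMATE_KEYS = tuple((m, w) for w in METHODS for m in MEASURES)

OUTCOME_TYPES = ("composite", "all_cause_death", "cvd_death", "cvd_hosp")
ADJUSTMENTS = ("unadjusted", "age_sex", "full")

SEXES = ("male", "female")
AGE_BANDS = ("20-49", "50-69", "70+")
INSURANCE_TYPES = ("NHI", "MedicalAid")
SES_LEVELS = ("high", "middle", "low", "missing")
INSTITUTIONS = ("tertiary", "secondary", "clinic", "public_health_center")
THERAPY_TYPES = ("dual", "triple_plus")
CCI_CATEGORIES = ("0", "1", "2+")


def estimate_column(measure: str, method: str) -> str:
    """Column name used for a (measure, method) estimate in tables."""
    return f"{measure}_{method.lower()}"


def flag_column(measure: str, method: str) -> str:
    return f"adherent_{measure}_{method.lower()}"


def age_band_of(age_years: int) -> str:
    if age_years < 50:
        return "20-49"
    if age_years < 70:
        return "50-69"
    return "70+"


@dataclass(frozen=True)
class Fill:
    """One pharmacy claim: a dispensation of one drug class."""

    patient_id: str
    drug_class: str
    fill_date: dt.date
    days_supply: int

    def __post_init__(self) -> None:
        if self.drug_class not in DRUG_CLASSES:
            raise ValueError(
                f"unknown drug class {self.drug_class!r}; expected one of {DRUG_CLASSES}"
            )
        if self.days_supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {self.days_supply}")


@dataclass(frozen=True)
class ObservationWindow:
    """Half-open day window ``[start_day, end_day)`` under PxM or FxM."""

    end_day: int
    method: str
    start_day: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.end_day <= self.start_day:
            raise ValueError("window must have positive length")

    @property
    def length(self) -> int:
        return self.end_day - self.start_day


@dataclass
class CoverageTimeline:
    """Per-class covered-day intervals after carry-over resolution.

    ``intervals`` are sorted, pairwise disjoint, half-open and already
    truncated to the assessment window. The episode — the span over which
    the class is considered "to be taken" — runs from the first fill day to
    the end of the last supply.
    """

    drug_class: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for a, b in self.intervals:
            if b <= a:
                raise ValueError(f"empty or inverted interval [{a}, {b})")
            if a < prev_end:
                raise ValueError("intervals must be sorted and disjoint")
            prev_end = b

    @property
    def episode_start(self) -> int:
        return self.intervals[0][0]

    @property
    def episode_end(self) -> int:
        return self.intervals[-1][1]

    @property
    def covered_days(self) -> int:
        return sum(b - a for a, b in self.intervals)

    def covered_days_in(self, start: int, end: int) -> int:
        """Covered days intersecting ``[start, end)``."""
        return sum(
            max(0, min(b, end) - max(a, start)) for a, b in self.intervals
        )

    def availability(self, n_days: int) -> np.ndarray:
        """0/1 vector of supply availability on days ``0..n_days-1``."""
        out = np.zeros(n_days, dtype=np.int64)
        for a, b in self.intervals:
            out[max(a, 0) : min(b, n_days)] = 1
        return out


@dataclass
class DailyCounts:
    """Per-day class counts over one observation window.

    ``available[d]`` counts classes with supply on day d; ``expected[d]``
    counts classes whose episode spans day d. Both have length equal to
    the window length, and 0 <= available <= expected holds wherever
    expected > 0.
    """

    available: np.ndarray
    expected: np.ndarray

    def __post_init__(self) -> None:
        if self.available.shape != self.expected.shape:
            raise ValueError("available and expected must have equal length")


@dataclass
class AdherenceProfile:
    """The six adherence estimates and dichotomized flags for one patient."""

    patient_id: str
    estimates: Mapping[tuple[str, str], float]
    adherent_flags: Mapping[tuple[str, str], bool]

    def as_row(self) -> dict:
        row: dict = {"patient_id": self.patient_id}
        for key in ESTIMATE_KEYS:
            row[estimate_column(*key)] = self.estimates[key]
            row[flag_column(*key)] = self.adherent_flags[key]
        return row


@dataclass
class CoxFit:
    """A fitted proportional-hazards model for one outcome/estimate cell."""

    outcome_type: str
    estimate_key: tuple[str, str]
    adjustment: str
    hr: float
    ci95: tuple[float, float]
    loglik: float
    aic: float
    harrell_c: float
    uno_c: float
    n: int
    n_events: int
    n_params: int
    p_value: float = float("nan")

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.hr <= hi):
            raise ValueError("confidence interval must bracket the hazard ratio")
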