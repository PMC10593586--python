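"""The three multidrug adherence measures under both window conventions.

For a patient on several drug classes over an observation window the
package computes:

* ``pdc_with1`` — proportion of days covered by at least one class,
* ``pdc_wm``   — duration-weighted mean of per-class PDCs, each class
  weighted by the length of its own class window,
* ``dppr``     — daily polypharmacy possession ratio: the mean over days of
  (classes available that day) / (classes expected that day), crediting
  partial possession day by day.

Each is evaluated under PxM (window ends with the last supply) and FxM
(full fixed window), yielding six estimates per patient, dichotomized at
the configured threshold (adherent iff estimate >= threshold, inclusive).
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .config import PipelineConfig
from .coverage import DayFill, build_patient_timelines, daily_counts, determine_window
from .types import (
    ESTIMATE_KEYS,
    AdherenceProfile,
    CoverageTimeline,
    DailyCounts,
    ObservationWindow,
)


def pdc_with_at_least_one(counts: DailyCounts, window: ObservationWindow) -> float:
    """Fraction of window days on which at least one class has supply."""
    if window.length <= 0:
        raise ValueError("observation window must have positive length")
    return float(np.count_nonzero(counts.available >= 1)) / window.length


def per_class_pdc(
    timeline: CoverageTimeline, method: str, window: ObservationWindow
) -> tuple[float, int]:
    """One class's PDC and its duration weight.

    The class window starts at the class's first fill day (not the patient
    index date, so late add-on therapy is not penalized for the days before
    it was prescribed) and ends at the class's episode end under PxM or at
    the patient window end under FxM. The weight is the class-window length
    in days.
    """
    if not timeline.intervals:
        raise ValueError("timeline has no coverage")
    start = timeline.episode_start
    end = timeline.episode_end if method == "PxM" else window.end_day
    length = end - start
    if length <= 0:
        raise ValueError(f"class window [{start}, {end}) has no days")
    return timeline.covered_days_in(start, end) / length, length


def pdc_weighted_mean(per_class: Sequence[tuple[float, int]]) -> float:
    """Duration-weighted mean of per-class PDCs.

    Algebraically identical to (total covered days) / (total class-window
    days) across classes.
    """
    if not per_class:
        raise ValueError("need at least one class PDC")
    total_weight = sum(w for _, w in per_class)
    if total_weight <= 0:
        raise ValueError("all class-window weights are zero")
    return sum(p * w for p, w in per_class) / total_weight


def dppr(counts: DailyCounts, window: ObservationWindow) -> float:
    """Daily polypharmacy possession ratio over the window.

    Day score = min(available/expected, 1) on days with expected > 0, else
    0 (the cap is defensive: availability cannot exceed expectation by
    construction of episodes). DPPR is the mean day score.
    """
    if window.length <= 0:
        raise ValueError("observation window must have positive length")
    expected = counts.expected.astype(float)
    available = counts.available.astype(float)
    scores = np.zeros(window.length)
    active = expected > 0
    scores[active] = np.minimum(available[active] / expected[active], 1.0)
    return float(scores.sum()) / window.length


def classify(estimate: float, threshold: float) -> bool:
    """Adherent iff the estimate reaches the threshold (inclusive >=)."""
    if not (0.0 <= estimate <= 1.0):
        raise ValueError(f"estimate must lie in [0, 1], got {estimate}")
    return estimate >= threshold


def profile_patient(
    patient_id: str,
    class_fills: Mapping[str, Sequence[DayFill]],
    config: PipelineConfig,
) -> AdherenceProfile:
    """Compute all six (measure x window-method) estimates for one patient."""
    window_days = config.assessment_window_days
    timelines = build_patient_timelines(
        class_fills, window_days, carryover=config.carryover
    )
    if not timelines:
        raise ValueError(f"patient {patient_id} has no in-window coverage")

    estimates: dict[tuple[str, str], float] = {}
    for method in ("PxM", "FxM"):
        window = determine_window(timelines, method, window_days)
        counts = daily_counts(timelines, window)
        estimates[("pdc_with1", method)] = pdc_with_at_least_one(counts, window)
        estimates[("pdc_wm", method)] = pdc_weighted_mean(
            [per_class_pdc(t, method, window) for t in timelines.values()]
        )
        estimates[("dppr", method)] = dppr(counts, window)

    flags = {
        key: classify(estimates[key], config.adherence_threshold)
        for key in ESTIMATE_KEYS
    }
    return AdherenceProfile(
        patient_id=patient_id, estimates=estimates, adherent_flags=flags
    )
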