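"""Coverage engine: fills -> per-class covered-day intervals and windows.

Converts a sequence of pharmacy fills of one drug class into disjoint
half-open coverage intervals under an explicit carry-over policy, builds
the PxM/FxM observation windows, and counts per-day class availability.

Carry-over policies
-------------------
``shift_forward``
    An early refill is stockpiled: its supply begins the day the previous
    supply is exhausted, so coverage extends (uncapped within the window).
``discard``
    Leftover supply is thrown away at each refill: a fill's coverage is cut
    short at the next fill day, so overlapping days are lost.

A day-by-day pill-queue simulator (:func:`oracle_daily_availability`)
provides an independent reference for both policies; the interval
construction must agree with it exactly on every day.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import CoverageTimeline, DailyCounts, ObservationWindow

log = logging.getLogger(__name__)

DayFill = tuple[int, int]  # (fill day offset, days' supply)


def _aggregate_fills(fills: Iterable[DayFill], window_days: int) -> list[DayFill]:
    """Sort fills by day, summing same-day duplicates of the class.

    Same-day fills are indistinguishable from one larger dispensation at
    day resolution. Fills on or after the window end cannot contribute any
    covered day and are dropped with a logged notice; pre-index fills are a
    caller error (the washout filter should have consumed them).
    """
    agg: dict[int, int] = {}
    for day, supply in fills:
        if supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {supply}")
        if day < 0:
            raise ValueError(f"fill day {day} precedes the index date")
        if day >= window_days:
            log.info("ignoring fill on day %d at/after window end %d", day, window_days)
            continue
        agg[day] = agg.get(day, 0) + supply
    return sorted(agg.items())


def build_class_timeline(
    fills: Iterable[DayFill],
    window_days: int,
    carryover: str = "shift_forward",
    drug_class: str = "",
) -> CoverageTimeline | None:
    """Resolve one class's fills into disjoint covered intervals.

    Returns ``None`` when no fill falls inside ``[0, window_days)``.
    Coverage is truncated at the window end under both policies.
    """
    if carryover not in ("shift_forward", "discard"):
        raise ValueError(f"unknown carryover policy {carryover!r}")
    ordered = _aggregate_fills(fills, window_days)
    if not ordered:
        return None

    raw: list[list[int]] = []
    if carryover == "shift_forward":
        cursor = 0
        for day, supply in ordered:
            start = max(day, cursor)
            cursor = start + supply
            raw.append([start, cursor])
    else:  # discard: leftover pills are lost at the next fill
        for i, (day, supply) in enumerate(ordered):
            end = day + supply
            if i + 1 < len(ordered):
                end = min(end, ordered[i + 1][0])
            raw.append([day, end])

    merged: list[list[int]] = []
    for a, b in raw:
        b = min(b, window_days)
        if b <= a:
            continue
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    if not merged:
        return None
    return CoverageTimeline(
        drug_class=drug_class, intervals=tuple((a, b) for a, b in merged)
    )


def oracle_daily_availability(
    fills: Iterable[DayFill], window_days: int, carryover: str = "shift_forward"
) -> np.ndarray:
    """Day-by-day pill-queue reference for one class's availability.

    Each day, if pills remain in the queue, one is consumed and the day is
    marked covered. A refill appends its pills to the queue under
    ``shift_forward`` and resets the queue under ``discard``. This simulator
    is deliberately naive — it is the independent oracle the interval
    construction is verified against, not a production path.
    """
    if carryover not in ("shift_forward", "discard"):
        raise ValueError(f"unknown carryover policy {carryover!r}")
    by_day = dict(_aggregate_fills(fills, window_days))
    covered = np.zeros(window_days, dtype=np.int64)
    queue = 0
    for day in range(window_days):
        if day in by_day:
            if carryover == "shift_forward":
                queue += by_day[day]
            else:
                queue = by_day[day]
        if queue > 0:
            covered[day] = 1
            queue -= 1
    return covered


def determine_window(
    timelines: Mapping[str, CoverageTimeline], method: str, window_days: int
) -> ObservationWindow:
    """Build the observation window for one patient.

    FxM spans the full fixed assessment window. PxM ends when the last
    dispensed supply runs out — the maximum episode end over the patient's
    classes — truncated to the assessment window.
    """
    real = {c: t for c, t in timelines.items() if t is not None and t.intervals}
    if not real:
        raise ValueError("cannot define an observation window without any coverage")
    if method == "FxM":
        return ObservationWindow(end_day=window_days, method="FxM")
    if method == "PxM":
        end = min(max(t.episode_end for t in real.values()), window_days)
        return ObservationWindow(end_day=end, method="PxM")
    raise ValueError(f"unknown window method {method!r}")


def daily_counts(
    timelines: Mapping[str, CoverageTimeline], window: ObservationWindow
) -> DailyCounts:
    """Count available and expected classes on each day of the window.

    ``expected[d]`` counts classes whose episode (first fill day to end of
    last supply) spans day d — refill cessation is the only discontinuation
    signal observable in claims, so a class stops being "expected" when its
    last supply runs out.
    """
    n = window.length
    available = np.zeros(n, dtype=np.int64)
    expected = np.zeros(n, dtype=np.int64)
    for timeline in timelines.values():
        if timeline is None or not timeline.intervals:
            continue
        for a, b in timeline.intervals:
            lo, hi = max(a, window.start_day), min(b, window.end_day)
            if hi > lo:
                available[lo - window.start_day : hi - window.start_day] += 1
        lo = max(timeline.episode_start, window.start_day)
        hi = min(timeline.episode_end, window.end_day)
        if hi > lo:
            expected[lo - window.start_day : hi - window.start_day] += 1
    return DailyCounts(available=available, expected=expected)


def build_patient_timelines(
    class_fills: Mapping[str, Sequence[DayFill]],
    window_days: int,
    carryover: str = "shift_forward",
) -> dict[str, CoverageTimeline]:
    """Resolve every class of one patient; classes without in-window fills drop out."""
    out: dict[str, CoverageTimeline] = {}
    for drug_class, fills in class_fills.items():
        timeline = build_class_timeline(
            fills, window_days, carryover=carryover, drug_class=drug_class
        )
        if timeline is not None:
            out[drug_class] = timeline
    return out
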