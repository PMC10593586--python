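"""New-user multidrug cohort selection with an attrition table.

Candidates are patients with at least one antihypertensive fill in the
index year; the index date is the first such fill. Exclusion filters are
then applied in a fixed order (age, hypertension diagnosis, multidrug
requirement, washout, minimum use, prior CVD/cancer hospitalization,
death/CVD/cancer within the assessment window). Every violation is
evaluated independently, so the final cohort is invariant under filter
reordering; only the attribution of an exclusion to its first applicable
filter depends on the order.
"""
from __future__ import annotations

import datetime as dt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .outcomes import CANCER_PREFIXES, OutcomeCodeSets, codes_match_any

FILTER_ORDER = (
    "age_le_20",
    "no_hypertension_dx",
    "monotherapy",
    "washout",
    "under_min_use",
    "prior_cvd_cancer_hosp",
    "event_in_window",
)


def identify_index_date(fill_dates: Iterable[dt.date], index_year: int) -> dt.date | None:
    """Earliest fill date within the index year, or None (not a candidate)."""
    in_year = [d for d in fill_dates if d.year == index_year]
    return min(in_year) if in_year else None


def identify_index_dates(fills: pd.DataFrame, index_year: int) -> pd.DataFrame:
    """Per-patient index dates for all candidates (>=1 fill in index year)."""
    dates = pd.to_datetime(fills["fill_date"].astype("string"))
    in_year = fills[dates.dt.year.values == index_year]
    idx = in_year.groupby("patient_id")["fill_date"].min()
    return idx.rename("index_date").reset_index()


def _any_code_match(codes: str, prefixes: tuple[str, ...]) -> bool:
    return codes_match_any(codes.split(";"), prefixes)


def apply_filters(
    fills: pd.DataFrame,
    covariates: pd.DataFrame,
    events: pd.DataFrame | None,
    config: PipelineConfig,
    code_sets: OutcomeCodeSets | None = None,
    filter_order: Sequence[str] = FILTER_ORDER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study filters; returns (cohort, attrition table).

    The cohort frame carries patient_id, index_date, the set of classes
    filled in the index year, a derived therapy type, and the covariates.
    The attrition table lists, per filter in application order, how many
    candidates were excluded there (first applicable filter) and how many
    remain.
    """
    if sorted(filter_order) != sorted(FILTER_ORDER):
        raise ValueError(f"filter_order must be a permutation of {FILTER_ORDER}")
    needs_events = {"prior_cvd_cancer_hosp", "event_in_window"} & set(filter_order)
    if needs_events and events is None:
        raise ValueError("events table is required while exclusion filters are enabled")
    if "hypertension_dx" not in covariates.columns:
        raise ValueError("covariates table must carry a hypertension_dx flag column")
    code_sets = code_sets or OutcomeCodeSets()
    exclusion_prefixes = code_sets.cvd_prefixes + CANCER_PREFIXES

    candidates = identify_index_dates(fills, config.index_year)
    candidates = candidates.merge(covariates, on="patient_id", how="left", validate="1:1")
    if candidates["age_years"].isna().any():
        missing = candidates.loc[candidates["age_years"].isna(), "patient_id"].tolist()[:5]
        raise ValueError(f"candidates missing covariate rows: {missing}")
    candidates = candidates.sort_values("patient_id", kind="mergesort").reset_index(drop=True)

    fills = fills.merge(candidates[["patient_id", "index_date"]], on="patient_id")
    fill_offset = (
        pd.to_datetime(fills["fill_date"].astype("string"))
        - pd.to_datetime(fills["index_date"].astype("string"))
    ).dt.days
    fills = fills.assign(day=fill_offset)

    index_year_classes = (
        fills[pd.to_datetime(fills["fill_date"].astype("string")).dt.year.values == config.index_year]
        .groupby("patient_id")["drug_class"]
        .agg(lambda s: tuple(sorted(set(s))))
    )
    n_classes = index_year_classes.map(len).reindex(candidates["patient_id"]).fillna(0)

    washout_hit = (
        fills[(fills["day"] < 0) & (fills["day"] >= -config.washout_days)]
        .groupby("patient_id")
        .size()
        .reindex(candidates["patient_id"])
        .fillna(0)
        > 0
    )
    window_supply = (
        fills[(fills["day"] >= 0) & (fills["day"] < config.assessment_window_days)]
        .groupby("patient_id")["days_supply"]
        .sum()
        .reindex(candidates["patient_id"])
        .fillna(0)
    )

    prior_hosp = pd.Series(False, index=candidates["patient_id"])
    event_in_window = pd.Series(False, index=candidates["patient_id"])
    if events is not None and not events.empty:
        ev = events.merge(candidates[["patient_id", "index_date"]], on="patient_id")
        ev_day = (
            pd.to_datetime(ev["event_date"].astype("string"))
            - pd.to_datetime(ev["index_date"].astype("string"))
        ).dt.days
        ev = ev.assign(day=ev_day)
        is_excl_code = ev["icd10_codes"].map(
            lambda c: _any_code_match(str(c), exclusion_prefixes)
        )
        prior = ev[
            (ev["event_kind"] == "hospitalization")
            & (ev["day"] < 0)
            & (ev["day"] >= -config.washout_days)
            & is_excl_code
        ]
        prior_hosp.loc[prior["patient_id"].unique()] = True
        in_window = ev[
            (ev["day"] >= 0)
            & (ev["day"] < config.assessment_window_days)
            & ((ev["event_kind"] == "death") | is_excl_code)
        ]
        event_in_window.loc[in_window["patient_id"].unique()] = True

    violations = pd.DataFrame(
        {
            "age_le_20": (candidates["age_years"] <= 20).values,
            "no_hypertension_dx": (candidates["hypertension_dx"].fillna(0).astype(int) != 1).values,
            "monotherapy": (n_classes < 2).values,
            "washout": washout_hit.values,
            "under_min_use": (window_supply < config.min_use_days).values,
            "prior_cvd_cancer_hosp": prior_hosp.values,
            "event_in_window": event_in_window.values,
        },
        index=candidates["patient_id"],
    )

    rows = [{"filter_name": "candidates", "n_excluded": 0, "n_remaining": len(candidates)}]
    remaining = pd.Series(True, index=candidates["patient_id"])
    for name in filter_order:
        hit = remaining & violations[name]
        remaining = remaining & ~violations[name]
        rows.append(
            {
                "filter_name": name,
                "n_excluded": int(hit.sum()),
                "n_remaining": int(remaining.sum()),
            }
        )
    attrition = pd.DataFrame(rows)

    keep = candidates["patient_id"].map(remaining).values
    cohort = candidates[keep].copy()
    classes = index_year_classes.reindex(cohort["patient_id"])
    cohort["classes_in_index_year"] = classes.values
    cohort["therapy_type"] = [
        "dual" if len(c) == 2 else "triple_plus" for c in classes
    ]
    cohort["age_band"] = cohort["age_years"].map(
        lambda a: "20-49" if a < 50 else ("50-69" if a < 70 else "70+")
    )
    return cohort.reset_index(drop=True), attrition
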