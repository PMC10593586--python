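"""End-to-end orchestration: cohort -> adherence profiles -> survival models."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .cohort import apply_filters
from .config import PipelineConfig
from .io import profiles_to_frame, summarize_profiles
from .measures import profile_patient
from .outcomes import (
    OutcomeCodeSets,
    build_survival_dataset,
    fit_cox,
    resolve_outcomes,
)
from .types import ESTIMATE_KEYS, OUTCOME_TYPES, AdherenceProfile, CoxFit

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    attrition: pd.DataFrame
    profiles: pd.DataFrame
    summary: pd.DataFrame
    fits: list[CoxFit] = field(default_factory=list)


def compute_profiles(
    cohort: pd.DataFrame, fills: pd.DataFrame, config: PipelineConfig
) -> list[AdherenceProfile]:
    """Adherence profiles for every cohort member.

    Only fills on or after each patient's index date enter coverage;
    pre-index fills were consumed by the washout filter.
    """
    fills = fills.merge(cohort[["patient_id", "index_date"]], on="patient_id")
    day = (
        pd.to_datetime(fills["fill_date"].astype("string"))
        - pd.to_datetime(fills["index_date"].astype("string"))
    ).dt.days
    fills = fills.assign(day=day)
    fills = fills[fills["day"] >= 0]

    profiles = []
    grouped = fills.groupby("patient_id")
    for pid in cohort["patient_id"]:
        g = grouped.get_group(pid)
        class_fills = {
            c: list(zip(sub["day"], sub["days_supply"]))
            for c, sub in g.groupby("drug_class")
        }
        profiles.append(profile_patient(pid, class_fills, config))
    return profiles


def run_survival_analysis(
    cohort: pd.DataFrame,
    profiles: pd.DataFrame,
    events: pd.DataFrame,
    config: PipelineConfig,
    outcome_types: tuple[str, ...] = OUTCOME_TYPES,
    code_sets: OutcomeCodeSets | None = None,
) -> list[CoxFit]:
    """Fit Cox models for every outcome x estimate x adjustment cell."""
    outcomes = resolve_outcomes(
        events, cohort[["patient_id", "index_date"]], code_sets
    )
    fits: list[CoxFit] = []
    for outcome_type in outcome_types:
        for key in ESTIMATE_KEYS:
            dataset = build_survival_dataset(
                cohort, profiles, outcomes, key, outcome_type, config.followup_end
            )
            for adjustment in config.adjustment_sets:
                try:
                    fits.append(
                        fit_cox(dataset, adjustment, outcome_type, key)
                    )
                except ValueError as err:
                    log.warning(
                        "skipping %s/%s/%s: %s", outcome_type, key, adjustment, err
                    )
    return fits


def run_pipeline(
    fills: pd.DataFrame,
    covariates: pd.DataFrame,
    events: pd.DataFrame | None,
    config: PipelineConfig,
    with_survival: bool = True,
) -> PipelineResult:
    """Run cohort selection, adherence measurement and (optionally) survival models."""
    cohort, attrition = apply_filters(fills, covariates, events, config)
    log.info("attrition:\n%s", attrition.to_string(index=False))
    if cohort.empty:
        raise ValueError("no patients remain after cohort selection")
    profile_objs = compute_profiles(cohort, fills, config)
    profiles = profiles_to_frame(profile_objs)
    summary = summarize_profiles(profiles, config.adherence_threshold)
    fits: list[CoxFit] = []
    if with_survival and events is not None:
        fits = run_survival_analysis(cohort, profiles, events, config)
    return PipelineResult(
        cohort=cohort, attrition=attrition, profiles=profiles, summary=summary, fits=fits
    )
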