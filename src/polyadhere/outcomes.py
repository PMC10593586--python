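"""Outcome definition and Cox proportional-hazards modelling.

Outcomes are defined from ICD-10-coded hospitalizations and deaths:

* ``composite``       — earliest CVD-coded hospitalization or death from
  any cause (the primary outcome),
* ``all_cause_death`` — death from any cause,
* ``cvd_death``       — death whose cause code falls in a CVD set,
* ``cvd_hosp``        — earliest CVD-coded hospitalization.

Patients are followed from the index date to their first event of the
given type or administrative censoring. Cox models (Efron tie handling,
via lifelines) are fitted at three adjustment levels with the dichotomized
non-adherence flag as the exposure; model fit is compared with AIC and
with Harrell's and Uno's (IPCW) concordance indexes.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index as _lifelines_cindex
from sksurv.metrics import concordance_index_ipcw
from sksurv.util import Surv

from .types import ADJUSTMENTS, OUTCOME_TYPES, CoxFit

#: Cancer hospitalizations/events (any C-chapter code) trigger the cohort
#: exclusion filters together with the CVD sets below.
CANCER_PREFIXES = ("C",)


def _span(prefix: str, lo: int, hi: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{k:02d}" for k in range(lo, hi + 1))


@dataclass(frozen=True)
class OutcomeCodeSets:
    """ICD-10 prefix sets defining the CVD outcome components.

    Matching is by code prefix: I21.9 matches the I21 prefix. The four
    sets are pairwise disjoint.
    """

    ihd: tuple[str, ...] = _span("I", 20, 25)
    cardiovascular: tuple[str, ...] = (
        _span("I", 5, 9) + _span("I", 26, 28) + _span("I", 30, 52)
    )
    stroke: tuple[str, ...] = _span("I", 60, 64)
    cerebrovascular: tuple[str, ...] = _span("I", 65, 69) + _span("G", 45, 46)

    def __post_init__(self) -> None:
        sets = [self.ihd, self.cardiovascular, self.stroke, self.cerebrovascular]
        flat = [p for s in sets for p in s]
        if len(flat) != len(set(flat)):
            raise ValueError("outcome code sets must be pairwise disjoint")

    @property
    def cvd_prefixes(self) -> tuple[str, ...]:
        return self.ihd + self.cardiovascular + self.stroke + self.cerebrovascular


def codes_match_any(codes: Iterable[str], prefixes: tuple[str, ...]) -> bool:
    """True if any code starts with any prefix (case-insensitive)."""
    for code in codes:
        c = code.strip().upper()
        if c and any(c.startswith(p) for p in prefixes):
            return True
    return False


def resolve_outcomes(
    events: pd.DataFrame,
    index_dates: pd.DataFrame,
    code_sets: OutcomeCodeSets | None = None,
) -> pd.DataFrame:
    """First event date per patient per outcome type.

    Returns a frame indexed by patient_id with one (nullable) date column
    per outcome type. Only events on or after the index date count; a
    death strictly before a patient's index date is a validation error.
    """
    code_sets = code_sets or OutcomeCodeSets()
    idx = index_dates.set_index("patient_id")["index_date"]
    out = pd.DataFrame(
        index=idx.index, columns=list(OUTCOME_TYPES), dtype=object
    )
    ev = events[events["patient_id"].isin(idx.index)]
    for _, row in ev.iterrows():
        pid = row["patient_id"]
        date = row["event_date"]
        if row["event_kind"] == "death" and date < idx[pid]:
            raise ValueError(f"death before index date for patient {pid}")
        if date < idx[pid]:
            continue
        codes = str(row["icd10_codes"]).split(";")
        is_cvd = codes_match_any(codes, code_sets.cvd_prefixes)
        hits = []
        if row["event_kind"] == "hospitalization" and is_cvd:
            hits += ["cvd_hosp", "composite"]
        if row["event_kind"] == "death":
            hits += ["all_cause_death", "composite"]
            if is_cvd:
                hits.append("cvd_death")
        for kind in hits:
            cur = out.at[pid, kind]
            if cur is None or pd.isna(cur) or date < cur:
                out.at[pid, kind] = date
    return out


def build_survival_dataset(
    cohort: pd.DataFrame,
    profiles: pd.DataFrame,
    outcomes: pd.DataFrame,
    estimate_key: tuple[str, str],
    outcome_type: str,
    followup_end: dt.date,
) -> pd.DataFrame:
    """One survival record per cohort member for one estimate and outcome.

    Exposure is the *non*-adherent flag for the chosen estimate; follow-up
    runs from the index date to the first event of ``outcome_type`` or to
    administrative censoring at ``followup_end``.
    """
    from .types import flag_column

    if outcome_type not in OUTCOME_TYPES:
        raise ValueError(f"unknown outcome type {outcome_type!r}")
    flag_col = flag_column(*estimate_key)
    if flag_col not in profiles.columns:
        raise ValueError(f"profiles table lacks column {flag_col}")
    merged = cohort.merge(
        profiles[["patient_id", flag_col]], on="patient_id", how="left", validate="1:1"
    )
    if merged[flag_col].isna().any():
        missing = merged.loc[merged[flag_col].isna(), "patient_id"].tolist()[:5]
        raise ValueError(f"missing adherence profile for patient(s) {missing}")

    event_date = outcomes[outcome_type].reindex(merged["patient_id"]).values
    index_date = merged["index_date"].values
    time_days = np.empty(len(merged), dtype=int)
    event = np.zeros(len(merged), dtype=bool)
    for i, (idx_d, ev_d) in enumerate(zip(index_date, event_date)):
        if ev_d is not None and not pd.isna(ev_d) and ev_d <= followup_end:
            time_days[i] = (ev_d - idx_d).days
            event[i] = True
        else:
            time_days[i] = (followup_end - idx_d).days
    if (time_days <= 0).any():
        raise ValueError("non-positive follow-up time encountered")

    out = merged.copy()
    out["time_days"] = time_days
    out["event"] = event
    out["non_adherent"] = ~merged[flag_col].astype(bool)
    return out


# Reference levels for categorical covariates (the base categories of the
# cohort description tables): adherent, male, age 20-49, NHI insurance,
# high SES, clinic, dual therapy, CCI 0, no diabetes, no dyslipidemia.
_CATEGORICALS = {
    "sex": ("male", ("female",)),
    "age_band": ("20-49", ("50-69", "70+")),
    "insurance": ("NHI", ("MedicalAid",)),
    "ses": ("high", ("middle", "low", "missing")),
    "institution": ("clinic", ("tertiary", "secondary", "public_health_center")),
    "therapy_type": ("dual", ("triple_plus",)),
    "cci_category": ("0", ("1", "2+")),
}
_BINARY_FULL = ("disability", "diabetes", "dyslipidemia")


def _design_matrix(dataset: pd.DataFrame, adjustment: str) -> pd.DataFrame:
    X = pd.DataFrame(index=dataset.index)
    X["non_adherent"] = dataset["non_adherent"].astype(float)
    if adjustment in ("age_sex", "full"):
        for var in ("sex", "age_band"):
            _, levels = _CATEGORICALS[var]
            col = dataset[var].astype(str)
            for level in levels:
                X[f"{var}_{level}"] = (col == level).astype(float)
    if adjustment == "full":
        for var in ("insurance", "ses", "institution", "therapy_type", "cci_category"):
            _, levels = _CATEGORICALS[var]
            col = dataset[var].astype(str)
            for level in levels:
                X[f"{var}_{level}"] = (col == level).astype(float)
        for var in _BINARY_FULL:
            X[var] = dataset[var].astype(float)
    # drop empty indicator columns (level absent in this dataset)
    return X.loc[:, (X.std() > 0) | (X.columns == "non_adherent")]


def fit_cox(
    dataset: pd.DataFrame,
    adjustment: str = "unadjusted",
    outcome_type: str = "composite",
    estimate_key: tuple[str, str] = ("pdc_with1", "PxM"),
    uno_tau: float | None = None,
    compute_concordance: bool = True,
) -> CoxFit:
    """Fit a Cox model for non-adherent vs adherent at one adjustment level.

    Uses the partial likelihood with Efron tie handling (day-resolution
    times are heavily tied). Categorical covariates enter as indicator
    columns against the stated reference levels. AIC is computed as
    -2 loglik + 2k from the partial log-likelihood.
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"adjustment must be one of {ADJUSTMENTS}")
    n_events = int(dataset["event"].sum())
    if n_events < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    groups = dataset["non_adherent"].astype(bool)
    if groups.all() or (~groups).all():
        raise ValueError("both exposure groups must be non-empty")

    X = _design_matrix(dataset, adjustment)
    df = X.copy()
    df["time_days"] = dataset["time_days"].astype(float)
    df["event"] = dataset["event"].astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time_days", event_col="event")

    coef = float(cph.params_["non_adherent"])
    se = float(cph.standard_errors_["non_adherent"])
    hr = float(np.exp(coef))
    ci = (float(np.exp(coef - 1.959963984540054 * se)), float(np.exp(coef + 1.959963984540054 * se)))
    loglik = float(cph.log_likelihood_)
    k = X.shape[1]
    aic = -2.0 * loglik + 2.0 * k

    if compute_concordance:
        risk = X.values @ cph.params_.values  # linear predictor
        time = dataset["time_days"].to_numpy(float)
        event = dataset["event"].to_numpy(bool)
        harrell = concordance(risk, time, event, flavor="harrell")
        uno = concordance(risk, time, event, flavor="uno", tau=uno_tau)
    else:
        harrell = uno = float("nan")
    pval = float(cph.summary.loc["non_adherent", "p"])

    return CoxFit(
        outcome_type=outcome_type,
        estimate_key=estimate_key,
        adjustment=adjustment,
        hr=hr,
        ci95=ci,
        loglik=loglik,
        aic=aic,
        harrell_c=harrell,
        uno_c=uno,
        n=len(dataset),
        n_events=n_events,
        n_params=k,
        p_value=pval,
    )


def concordance(
    risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    flavor: str = "harrell",
    tau: float | None = None,
) -> float:
    """Rank concordance between risk scores and survival times.

    ``harrell``: usable-pair concordance with tied risks counted 1/2.
    ``uno``: inverse-probability-of-censoring-weighted concordance
    truncated at ``tau`` (default: the 95th percentile of observed
    follow-up). Uno's variant corrects the upward bias of Harrell's C
    under heavy censoring.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if flavor == "harrell":
        # lifelines orders by predicted survival time; higher risk = shorter
        return float(_lifelines_cindex(time, -risk, event))
    if flavor == "uno":
        if tau is None:
            tau = float(np.quantile(time, 0.95))
        if tau > time.max():
            raise ValueError(f"tau {tau} exceeds the maximum observed follow-up")
        surv = Surv.from_arrays(event=event, time=time)
        cindex, *_ = concordance_index_ipcw(surv, surv, risk, tau=tau)
        return float(cindex)
    raise ValueError(f"unknown concordance flavor {flavor!r}")


def diagnostics_grid(fits: Sequence[CoxFit], good_threshold: float = 0.7) -> pd.DataFrame:
    """AIC and concordance per (outcome, estimate, adjustment) cell.

    Cells whose Harrell's and Uno's C both exceed ``good_threshold`` are
    flagged as good models.
    """
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for f in fits:
        measure, method = f.estimate_key
        rows.append(
            {
                "outcome": f.outcome_type,
                "method": method,
                "measure": measure,
                "adjustment": f.adjustment,
                "aic": f.aic,
                "harrell_c": f.harrell_c,
                "uno_c": f.uno_c,
                "good_model": bool(f.harrell_c > good_threshold and f.uno_c > good_threshold),
            }
        )
    return pd.DataFrame(rows)
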