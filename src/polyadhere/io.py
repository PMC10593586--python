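"""Readers and writers for the delimited-text interchange formats.

Fills, covariates and events travel as plain CSV; the report writer emits
the per-patient estimate table, the population summary, and (when survival
models were fitted) the hazard-ratio table and the AIC/concordance grid.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    DRUG_CLASSES,
    ESTIMATE_KEYS,
    AdherenceProfile,
    CoxFit,
    estimate_column,
    flag_column,
)

log = logging.getLogger(__name__)

FILL_COLUMNS = ("patient_id", "drug_class", "fill_date", "days_supply")
EVENT_COLUMNS = ("patient_id", "event_date", "event_kind", "icd10_codes")
COVARIATE_REQUIRED = (
    "patient_id",
    "sex",
    "age_years",
    "disability",
    "insurance",
    "ses",
    "institution",
    "cci_category",
    "diabetes",
    "dyslipidemia",
)


@dataclass(frozen=True)
class Dialect:
    """Delimiter / date-format / header-mapping spec for input tables."""

    delimiter: str = ","
    date_format: str | None = None  # None -> ISO-8601
    columns: dict = field(default_factory=dict)  # canonical field -> file header


def _read_table(path: str | Path, dialect: Dialect, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    rename = {header: canon for canon, header in dialect.columns.items()}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_dates(series: pd.Series, dialect: Dialect, path, column: str) -> pd.Series:
    fmt = dialect.date_format or "%Y-%m-%d"
    parsed = pd.to_datetime(series, format=fmt, errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        rows = (series.index[bad] + 2).tolist()[:5]  # 1-based incl. header
        raise ValueError(f"{path}: unparseable {column} at file line(s) {rows}")
    return parsed.dt.date


def read_fills(path: str | Path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read a fills table; returns rows sorted by (patient_id, fill_date).

    Validates the closed drug-class set and positive days' supply, naming
    the offending file line on failure.
    """
    dialect = dialect or Dialect()
    df = _read_table(path, dialect, FILL_COLUMNS)
    df["fill_date"] = _parse_dates(df["fill_date"], dialect, path, "fill_date")
    df["days_supply"] = pd.to_numeric(df["days_supply"], errors="coerce")
    bad_supply = df["days_supply"].isna() | (df["days_supply"] < 1)
    if bad_supply.any():
        rows = (df.index[bad_supply] + 2).tolist()[:5]
        raise ValueError(f"{path}: days_supply must be a positive integer at line(s) {rows}")
    df["days_supply"] = df["days_supply"].astype(int)
    unknown = ~df["drug_class"].isin(DRUG_CLASSES)
    if unknown.any():
        rows = (df.index[unknown] + 2).tolist()[:5]
        labels = sorted(df.loc[unknown, "drug_class"].unique())
        raise ValueError(f"{path}: unknown drug class(es) {labels} at line(s) {rows}")
    return (
        df[list(FILL_COLUMNS)]
        .sort_values(["patient_id", "fill_date"], kind="mergesort")
        .reset_index(drop=True)
    )


def read_covariates(path: str | Path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read the per-patient covariate table (one row per patient)."""
    dialect = dialect or Dialect()
    df = _read_table(path, dialect, COVARIATE_REQUIRED)
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()[:5]
        raise ValueError(f"{path}: duplicate patient_id(s) {dupes}")
    df["age_years"] = pd.to_numeric(df["age_years"]).astype(int)
    for col in ("disability", "diabetes", "dyslipidemia", "hypertension_dx"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).astype(int)
    return df.sort_values("patient_id", kind="mergesort").reset_index(drop=True)


def read_events(path: str | Path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read hospitalization/death events; ICD-10 codes are semicolon-joined."""
    dialect = dialect or Dialect()
    df = _read_table(path, dialect, EVENT_COLUMNS)
    df["event_date"] = _parse_dates(df["event_date"], dialect, path, "event_date")
    bad_kind = ~df["event_kind"].isin(("hospitalization", "death"))
    if bad_kind.any():
        rows = (df.index[bad_kind] + 2).tolist()[:5]
        raise ValueError(f"{path}: event_kind must be hospitalization/death at line(s) {rows}")
    df["icd10_codes"] = df["icd10_codes"].fillna("")
    empty_hosp = (df["event_kind"] == "hospitalization") & (df["icd10_codes"] == "")
    if empty_hosp.any():
        rows = (df.index[empty_hosp] + 2).tolist()[:5]
        raise ValueError(f"{path}: hospitalization without ICD-10 codes at line(s) {rows}")
    deaths = df[df["event_kind"] == "death"]
    if deaths["patient_id"].duplicated().any():
        raise ValueError(f"{path}: more than one death record for a patient")
    return (
        df[list(EVENT_COLUMNS)]
        .sort_values(["patient_id", "event_date"], kind="mergesort")
        .reset_index(drop=True)
    )


def write_fills(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    df["fill_date"] = df["fill_date"].map(lambda d: d.isoformat())
    df[list(FILL_COLUMNS)].to_csv(path, index=False)


def profiles_to_frame(profiles: Sequence[AdherenceProfile]) -> pd.DataFrame:
    """Stack per-patient profiles into the per-patient estimate table."""
    return pd.DataFrame([p.as_row() for p in profiles])


def summarize_profiles(profiles_df: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Population summary per estimate: mean, SD, median, IQR, adherent n (%).

    Estimates are reported as percentages, one row per (method, measure) in
    the conventional PxM-block-first order.
    """
    rows = []
    n = len(profiles_df)
    for measure, method in ESTIMATE_KEYS:
        pct = profiles_df[estimate_column(measure, method)] * 100.0
        n_adh = int(profiles_df[flag_column(measure, method)].sum())
        rows.append(
            {
                "method": method,
                "measure": measure,
                "mean": pct.mean(),
                "sd": pct.std(ddof=1),
                "median": pct.median(),
                "q1": pct.quantile(0.25),
                "q3": pct.quantile(0.75),
                "adherent_n": n_adh,
                "adherent_pct": 100.0 * n_adh / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def fits_to_frame(fits: Sequence[CoxFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        measure, method = f.estimate_key
        rows.append(
            {
                "outcome": f.outcome_type,
                "method": method,
                "measure": measure,
                "adjustment": f.adjustment,
                "hr": f.hr,
                "ci_low": f.ci95[0],
                "ci_high": f.ci95[1],
                "hr_formatted": f"{f.hr:.2f} ({f.ci95[0]:.2f}, {f.ci95[1]:.2f})",
                "loglik": f.loglik,
                "aic": f.aic,
                "harrell_c": f.harrell_c,
                "uno_c": f.uno_c,
                "n": f.n,
                "n_events": f.n_events,
            }
        )
    return pd.DataFrame(rows)


def write_report(
    profiles: Sequence[AdherenceProfile] | pd.DataFrame,
    fits: Sequence[CoxFit],
    outdir: str | Path,
    threshold: float = 0.80,
    attrition: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the report tables to ``outdir``; returns the paths written.

    Always emits the per-patient six-estimate table and the population
    summary. The hazard-ratio table and the AIC/concordance grid are
    emitted only when fits are supplied (their absence is logged, not an
    error). An empty profile collection is an error.
    """
    from .outcomes import diagnostics_grid  # local import to avoid a cycle

    if not isinstance(profiles, pd.DataFrame):
        profiles = profiles_to_frame(list(profiles))
    if profiles.empty:
        raise ValueError("cannot write a report for zero patients")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    per_patient = outdir / "per_patient_estimates.csv"
    profiles.to_csv(per_patient, index=False, float_format="%.10g")
    written["per_patient"] = per_patient

    summary = outdir / "adherence_summary.csv"
    summarize_profiles(profiles, threshold).to_csv(
        summary, index=False, float_format="%.6g"
    )
    written["summary"] = summary

    if attrition is not None:
        attr_path = outdir / "attrition.csv"
        attrition.to_csv(attr_path, index=False)
        written["attrition"] = attr_path

    if fits:
        fits_df = fits_to_frame(fits)
        hr_path = outdir / "hazard_ratios.csv"
        fits_df.drop(columns=["loglik", "aic", "harrell_c", "uno_c"]).to_csv(
            hr_path, index=False, float_format="%.6g"
        )
        written["hazard_ratios"] = hr_path
        diag_path = outdir / "model_diagnostics.csv"
        diagnostics_grid(fits).to_csv(diag_path, index=False, float_format="%.6g")
        written["diagnostics"] = diag_path
    else:
        log.info("no survival fits supplied; hazard-ratio and diagnostics tables omitted")
    return written
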