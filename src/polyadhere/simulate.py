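"""Synthetic pharmacy-claims generator with known ground truth.

Emulates the structure of a national claims extract for new users of
multidrug antihypertensive therapy: per-patient covariates drawn from the
marginal frequencies of the study population description, refill sequences
driven by a latent adherence propensity theta (gaps, stockpiling,
discontinuation, staggered add-on classes), and outcome events generated
from a proportional-hazards model with a configurable true hazard ratio
for non-adherence.

Non-adherence acts on the outcome hazard through the *true* behavioural
flag derived from theta, not through any measured estimate, so the
attenuation introduced by a particular adherence measurement is itself
observable in experiments.

Everything is driven by a single integer seed; identical (config, seed)
pairs produce byte-identical output files.
"""
from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .types import DRUG_CLASSES

# ---------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class CovariateMarginals:
    """Marginal frequencies for covariate sampling (study Table-1 scale).

    Age is Normal(55.72, 12.49) truncated below at 20 and banded
    afterwards; all other covariates are independent categorical draws.
    """

    female: float = 0.474
    age_mean: float = 55.72
    age_sd: float = 12.49
    age_min: float = 20.0
    disability: float = 0.074
    medical_aid: float = 0.056
    ses: tuple[float, ...] = (0.379, 0.339, 0.217, 0.065)  # high/middle/low/missing
    institution: tuple[float, ...] = (0.044, 0.102, 0.763, 0.091)  # tert/sec/clinic/phc
    cci: tuple[float, ...] = (0.727, 0.189, 0.084)  # 0 / 1 / 2+
    diabetes: float = 0.154
    dyslipidemia: float = 0.310

    def __post_init__(self) -> None:
        for name in ("ses", "institution", "cci"):
            p = getattr(self, name)
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"{name} marginal probabilities must sum to 1, got {sum(p)}")


@dataclass(frozen=True)
class BehaviorParams:
    """Refill-behaviour model parameters.

    Refills happen on shared pharmacy visits: one days'-supply length is
    drawn per patient and every active class is refilled on the same visit
    days, which keeps a patient's classes synchronized the way real
    multidrug refills are. A patient's adherence propensity
    theta ~ Beta(theta_a, theta_b) sets the mean delay between supply
    depletion and the next visit — Geometric with mean
    ``gap_scale * (1 - theta)`` days — and the per-class, per-visit
    discontinuation probability ``discontinue_scale * (1 - theta)``.
    theta = 1 therefore implies zero gaps and no discontinuation. Early
    visits (stockpiling) occur with probability ``early_refill_prob``, up
    to ``early_refill_max_days`` before depletion. The number of drug
    classes follows the dual/triple+ split of the study population;
    add-on classes start uniformly within the first
    ``addon_start_max_day`` days and join the visit schedule thereafter.
    """

    theta_a: float = 2.2
    theta_b: float = 0.7
    supply_choices: tuple[int, ...] = (30, 60, 90)
    supply_probs: tuple[float, ...] = (0.60, 0.25, 0.15)
    gap_scale: float = 70.0
    early_refill_prob: float = 0.20
    early_refill_max_days: int = 7
    discontinue_scale: float = 0.04
    n_classes_choices: tuple[int, ...] = (2, 3, 4, 5)
    n_classes_probs: tuple[float, ...] = (0.774, 0.180, 0.036, 0.010)
    addon_start_max_day: int = 90

    def mean_supply(self) -> float:
        return float(np.dot(self.supply_choices, self.supply_probs))

    def mean_gap(self, theta: float) -> float:
        return self.gap_scale * (1.0 - theta)

    def expected_coverage(
        self, theta: float | np.ndarray, supply: float | np.ndarray | None = None
    ) -> float | np.ndarray:
        """Long-run covered fraction implied by the renewal gap model."""
        s = self.mean_supply() if supply is None else np.asarray(supply, dtype=float)
        return s / (s + self.gap_scale * (1.0 - np.asarray(theta, dtype=float)))


@dataclass(frozen=True)
class OutcomeGenParams:
    """Event-time generator: exponential hazards under proportional hazards.

    ``baseline_hazard`` is the daily event rate of the (truly) adherent
    group; non-adherent patients have hazard ``baseline_hazard * true_hr``.
    Events are labelled CVD hospitalization vs death (and deaths CVD-cause
    vs other) by the configured fractions; administrative censoring applies
    at ``admin_censor_date``.
    """

    baseline_hazard: float = 8.5e-5
    true_hr: float = 1.4
    hosp_fraction: float = 0.70
    cvd_death_fraction: float = 0.24
    admin_censor_date: dt.date = dt.date(2015, 12, 31)

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.true_hr <= 0:
            raise ValueError("rates and the true hazard ratio must be positive")


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 4226
    index_year: int = 2007
    assessment_window_days: int = 1095
    adherent_coverage_threshold: float = 0.80
    marginals: CovariateMarginals = field(default_factory=CovariateMarginals)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    outcome: OutcomeGenParams = field(default_factory=OutcomeGenParams)
    #: optional injected filter violations: filter name -> number of patients
    violators: tuple[tuple[str, int], ...] = ()


@dataclass
class SimulatedStudy:
    fills: pd.DataFrame
    covariates: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame
    meta: dict


# ---------------------------------------------------------------------------
# samplers

_CVD_HOSP_CODES = (
    "I20.0", "I21.9", "I25.1", "I48", "I50.0", "I63.9", "I61.0", "G45.9", "I67.2",
)
_CVD_DEATH_CODES = ("I21.9", "I50.9", "I63.9", "I61.9")
_OTHER_DEATH_CODES = ("C34.9", "J18.9", "E11.9", "R99")


def sample_covariates(
    n: int,
    rng: np.random.Generator,
    marginals: CovariateMarginals | None = None,
) -> pd.DataFrame:
    """Draw n patients' covariates independently from the marginals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    m = marginals or CovariateMarginals()
    a = (m.age_min - m.age_mean) / m.age_sd
    age = stats.truncnorm.rvs(a, np.inf, loc=m.age_mean, scale=m.age_sd, size=n, random_state=rng)
    age_years = np.floor(age).astype(int)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(1, n + 1)],
            "sex": np.where(rng.random(n) < m.female, "female", "male"),
            "age_years": age_years,
            "disability": (rng.random(n) < m.disability).astype(int),
            "insurance": np.where(rng.random(n) < m.medical_aid, "MedicalAid", "NHI"),
            "ses": rng.choice(["high", "middle", "low", "missing"], size=n, p=m.ses),
            "institution": rng.choice(
                ["tertiary", "secondary", "clinic", "public_health_center"],
                size=n,
                p=m.institution,
            ),
            "cci_category": rng.choice(["0", "1", "2+"], size=n, p=m.cci),
            "diabetes": (rng.random(n) < m.diabetes).astype(int),
            "dyslipidemia": (rng.random(n) < m.dyslipidemia).astype(int),
            "hypertension_dx": np.ones(n, dtype=int),
        }
    )
    df["age_band"] = np.select(
        [df["age_years"] < 50, df["age_years"] < 70], ["20-49", "50-69"], "70+"
    )
    return df


def simulate_refills(
    rng: np.random.Generator,
    theta: float,
    classes: tuple[str, ...],
    behavior: BehaviorParams,
    window_days: int,
    addon_start_max_day: int | None = None,
    supply: int | None = None,
) -> list[tuple[str, int, int]]:
    """One patient's fill sequence: (drug_class, day offset, days' supply).

    A shared visit schedule alternates the patient's supply length with
    theta-dependent geometric gaps (or early stockpiling visits). The
    first class starts on day 0 — the index fill; add-on classes first
    fill on their own staggered start day, then refill at the shared
    visits. Each class can discontinue permanently at any visit.
    """
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must lie in [0, 1]")
    if addon_start_max_day is None:
        addon_start_max_day = behavior.addon_start_max_day
    if supply is None:
        supply = int(rng.choice(behavior.supply_choices, p=behavior.supply_probs))
    gap_p = 1.0 / (1.0 + behavior.mean_gap(theta))
    stop_p = behavior.discontinue_scale * (1.0 - theta)

    visits = [0]
    day = 0
    while True:
        if rng.random() < behavior.early_refill_prob:
            nxt = day + supply - int(rng.integers(1, behavior.early_refill_max_days + 1))
            nxt = max(nxt, day + 1)
        else:
            nxt = day + supply + int(rng.geometric(gap_p)) - 1  # mean gap_scale*(1-theta)
        if nxt >= window_days:
            break
        visits.append(nxt)
        day = nxt

    fills: list[tuple[str, int, int]] = []
    for k, drug_class in enumerate(classes):
        if k == 0:
            class_visits = visits
        else:
            start = int(rng.integers(0, addon_start_max_day + 1))
            class_visits = [start] + [v for v in visits if v > start]
        for v in class_visits:
            if v >= window_days:
                break
            fills.append((drug_class, v, supply))
            if rng.random() < stop_p:
                break
    fills.sort(key=lambda f: (f[0], f[1]))
    return fills


def simulate_outcomes(
    index_dates: pd.Series,
    non_adherent: pd.Series,
    params: OutcomeGenParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential event times under the configured true hazard ratio.

    Returns an events table (hospitalizations and deaths) for patients
    whose simulated event precedes administrative censoring; censored
    patients simply have no row.
    """
    hazards = params.baseline_hazard * np.where(non_adherent.values, params.true_hr, 1.0)
    t_days = np.ceil(rng.exponential(1.0 / hazards))
    index_ts = pd.to_datetime(pd.Series(index_dates.values))
    # anything past the censoring horizon is censored; clip so that extreme
    # exponential tails cannot overflow the timestamp range
    horizon = (pd.Timestamp(params.admin_censor_date) - index_ts).dt.days + 1
    t_days = np.minimum(t_days, horizon.to_numpy()).astype(np.int64)
    event_date = index_ts + pd.to_timedelta(t_days, unit="D")
    observed = (event_date <= pd.Timestamp(params.admin_censor_date)).to_numpy()

    m = int(observed.sum())
    is_hosp = rng.random(m) < params.hosp_fraction
    is_cvd_death = rng.random(m) < params.cvd_death_fraction
    hosp_codes = np.asarray(_CVD_HOSP_CODES)[rng.integers(0, len(_CVD_HOSP_CODES), m)]
    cvd_death_codes = np.asarray(_CVD_DEATH_CODES)[
        rng.integers(0, len(_CVD_DEATH_CODES), m)
    ]
    other_death_codes = np.asarray(_OTHER_DEATH_CODES)[
        rng.integers(0, len(_OTHER_DEATH_CODES), m)
    ]
    codes = np.where(is_hosp, hosp_codes, np.where(is_cvd_death, cvd_death_codes, other_death_codes))
    return pd.DataFrame(
        {
            "patient_id": np.asarray(index_dates.index)[observed],
            "event_date": [d.date() for d in event_date[observed]],
            "event_kind": np.where(is_hosp, "hospitalization", "death"),
            "icd10_codes": codes,
        }
    )


# ---------------------------------------------------------------------------
# end-to-end study generation

_INJECTABLE = (
    "age_le_20",
    "no_hypertension_dx",
    "monotherapy",
    "washout",
    "under_min_use",
    "prior_cvd_cancer_hosp",
    "event_in_window",
)


def generate_study(config: SimConfig | None = None, seed: int = 0) -> SimulatedStudy:
    """Generate a complete synthetic study dataset with ground truth.

    Returns fills, covariates and events tables ready for the pipeline,
    plus a per-patient truth table (theta, true adherence flag, any
    injected filter violation) and run metadata.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    n = config.n_patients
    covariates = sample_covariates(n, rng, config.marginals)
    pids = covariates["patient_id"].tolist()

    year_start = dt.date(config.index_year, 1, 1)
    year_days = (dt.date(config.index_year + 1, 1, 1) - year_start).days
    index_dates = pd.Series(
        [year_start + dt.timedelta(days=int(d)) for d in rng.integers(0, year_days, size=n)],
        index=pids,
        name="index_date",
    )

    b = config.behavior
    theta = rng.beta(b.theta_a, b.theta_b, size=n)
    n_classes = rng.choice(b.n_classes_choices, size=n, p=b.n_classes_probs)
    supplies = rng.choice(b.supply_choices, size=n, p=b.supply_probs)
    true_adherent = (
        np.asarray(b.expected_coverage(theta, supplies))
        >= config.adherent_coverage_threshold
    )

    # injected filter violations, assigned to the last patients in id order
    violation = np.array(["clean"] * n, dtype=object)
    cursor = n
    for name, count in config.violators:
        if name not in _INJECTABLE:
            raise ValueError(f"unknown violator filter {name!r}")
        cursor -= count
        if cursor < 0:
            raise ValueError("more violators requested than patients")
        violation[cursor : cursor + count] = name

    fill_rows: list[tuple[str, str, dt.date, int]] = []
    extra_events: list[tuple[str, dt.date, str, str]] = []
    class_sets: list[tuple[str, ...]] = []
    for i, pid in enumerate(pids):
        v = violation[i]
        k = 1 if v == "monotherapy" else int(n_classes[i])
        classes = tuple(rng.choice(DRUG_CLASSES, size=k, replace=False))
        class_sets.append(classes)
        idx_date = index_dates[pid]
        if v == "under_min_use":
            fills = [(c, 0, 30) for c in classes[:2]]  # 60 total days' supply
        else:
            # keep add-on starts inside the index year so clean patients
            # satisfy the multidrug-in-index-year requirement
            days_left = (dt.date(config.index_year, 12, 31) - idx_date).days
            fills = simulate_refills(
                rng,
                theta[i],
                classes,
                b,
                config.assessment_window_days,
                addon_start_max_day=min(b.addon_start_max_day, days_left),
                supply=int(supplies[i]),
            )
        for drug_class, day, supply in fills:
            fill_rows.append((pid, drug_class, idx_date + dt.timedelta(days=day), supply))
        if v == "age_le_20":
            covariates.loc[i, "age_years"] = int(rng.integers(15, 21))
            covariates.loc[i, "age_band"] = "20-49"
        elif v == "no_hypertension_dx":
            covariates.loc[i, "hypertension_dx"] = 0
        elif v == "washout":
            fill_rows.append(
                (pid, classes[0], idx_date - dt.timedelta(days=int(rng.integers(30, 330))), 30)
            )
        elif v == "prior_cvd_cancer_hosp":
            extra_events.append(
                (pid, idx_date - dt.timedelta(days=int(rng.integers(30, 330))),
                 "hospitalization", "I21.9")
            )
        elif v == "event_in_window":
            extra_events.append(
                (pid, idx_date + dt.timedelta(days=int(rng.integers(30, config.assessment_window_days))),
                 "death", "I50.9")
            )

    fills = pd.DataFrame(
        fill_rows, columns=["patient_id", "drug_class", "fill_date", "days_supply"]
    ).sort_values(["patient_id", "fill_date", "drug_class"], kind="mergesort").reset_index(drop=True)

    clean = violation != "event_in_window"
    events = simulate_outcomes(
        index_dates[clean], pd.Series(~true_adherent[clean], index=index_dates.index[clean]),
        config.outcome, rng,
    )
    if extra_events:
        events = pd.concat(
            [events, pd.DataFrame(extra_events, columns=events.columns)], ignore_index=True
        )
    events = events.sort_values(["patient_id", "event_date"], kind="mergesort").reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "patient_id": pids,
            "theta": theta,
            "true_adherent": true_adherent,
            "n_classes": [len(c) for c in class_sets],
            "injected_violation": violation,
        }
    )
    meta = {
        "seed": int(seed),
        "true_hr": config.outcome.true_hr,
        "n_patients": n,
        "index_year": config.index_year,
    }
    return SimulatedStudy(
        fills=fills, covariates=covariates, events=events, truth=truth, meta=meta
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated dataset as the pipeline's CSV interchange files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fills": outdir / "fills.csv",
        "covariates": outdir / "covariates.csv",
        "events": outdir / "events.csv",
        "truth": outdir / "truth.csv",
        "meta": outdir / "meta.json",
    }
    fills = study.fills.copy()
    fills["fill_date"] = fills["fill_date"].map(lambda d: d.isoformat())
    fills.to_csv(paths["fills"], index=False)
    study.covariates.to_csv(paths["covariates"], index=False)
    events = study.events.copy()
    if not events.empty:
        events["event_date"] = events["event_date"].map(lambda d: d.isoformat())
    events.to_csv(paths["events"], index=False)
    study.truth.to_csv(paths["truth"], index=False, float_format="%.17g")
    paths["meta"].write_text(json.dumps(study.meta, sort_keys=True, indent=1))
    return paths
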