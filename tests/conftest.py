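import datetime as dt

import numpy as np
import pandas as pd
import pytest

from polyadhere.config import PipelineConfig


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


def _monthly_fills(pid, drug_class, start, n_fills, supply=30, step=None):
    step = step or supply
    return [
        (pid, drug_class, start + dt.timedelta(days=i * step), supply)
        for i in range(n_fills)
    ]


@pytest.fixture
def constructed_cohort_tables():
    """A hand-built 50-patient claims dataset with known filter violations.

    38 clean patients plus 2 violators each for six exclusion filters
    (age, monotherapy, washout, minimum use, prior CVD/cancer
    hospitalization, death/CVD event inside the assessment window).
    Every violator trips exactly one filter.
    """
    index = dt.date(2007, 3, 1)
    fills, cov_rows, event_rows = [], [], []

    def covrow(pid, age=55, htn=1):
        return {
            "patient_id": pid,
            "sex": "male",
            "age_years": age,
            "age_band": "50-69" if 50 <= age < 70 else ("20-49" if age < 50 else "70+"),
            "disability": 0,
            "insurance": "NHI",
            "ses": "high",
            "institution": "clinic",
            "cci_category": "0",
            "diabetes": 0,
            "dyslipidemia": 0,
            "hypertension_dx": htn,
        }

    def clean_fills(pid):
        return _monthly_fills(pid, "ACEI", index, 6) + _monthly_fills(pid, "CCB", index, 6)

    labels = {}
    pid_n = 0

    def next_pid():
        nonlocal pid_n
        pid_n += 1
        return f"T{pid_n:03d}"

    for _ in range(38):
        pid = next_pid()
        labels[pid] = "clean"
        fills += clean_fills(pid)
        cov_rows.append(covrow(pid))
    for _ in range(2):
        pid = next_pid()
        labels[pid] = "age_le_20"
        fills += clean_fills(pid)
        cov_rows.append(covrow(pid, age=19))
    for _ in range(2):
        pid = next_pid()
        labels[pid] = "monotherapy"
        fills += _monthly_fills(pid, "ACEI", index, 6)  # 180 supply days, one class
        cov_rows.append(covrow(pid))
    for _ in range(2):
        pid = next_pid()
        labels[pid] = "washout"
        fills += clean_fills(pid)
        fills.append((pid, "ACEI", index - dt.timedelta(days=200), 30))
        cov_rows.append(covrow(pid))
    for _ in range(2):
        pid = next_pid()
        labels[pid] = "under_min_use"
        fills += [(pid, "ACEI", index, 30), (pid, "CCB", index, 30)]  # 60 days
        cov_rows.append(covrow(pid))
    for _ in range(2):
        pid = next_pid()
        labels[pid] = "prior_cvd_cancer_hosp"
        fills += clean_fills(pid)
        event_rows.append((pid, index - dt.timedelta(days=100), "hospitalization", "I21.9"))
        cov_rows.append(covrow(pid))
    for _ in range(2):
        pid = next_pid()
        labels[pid] = "event_in_window"
        fills += clean_fills(pid)
        event_rows.append((pid, index + dt.timedelta(days=500), "death", "I50.9"))
        cov_rows.append(covrow(pid))

    fills_df = pd.DataFrame(
        fills, columns=["patient_id", "drug_class", "fill_date", "days_supply"]
    )
    covariates = pd.DataFrame(cov_rows)
    events = pd.DataFrame(
        event_rows, columns=["patient_id", "event_date", "event_kind", "icd10_codes"]
    )
    return fills_df, covariates, events, labels
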