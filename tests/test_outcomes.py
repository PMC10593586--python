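"""Outcome-model tests: code matching, Cox recovery, concordance oracles."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from polyadhere.outcomes import (
    OutcomeCodeSets,
    build_survival_dataset,
    codes_match_any,
    concordance,
    diagnostics_grid,
    fit_cox,
    resolve_outcomes,
)
from polyadhere.types import ESTIMATE_KEYS, OUTCOME_TYPES


def make_index(pids, date=dt.date(2007, 1, 1)):
    return pd.DataFrame({"patient_id": pids, "index_date": [date] * len(pids)})


def events_frame(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "event_date", "event_kind", "icd10_codes"]
    )


class TestCodeSets:
    def test_prefix_matching(self):
        cs = OutcomeCodeSets()
        assert codes_match_any(["I21.9"], cs.cvd_prefixes)
        assert codes_match_any(["i21"], cs.cvd_prefixes)  # case-insensitive
        assert not codes_match_any(["C34.9"], cs.cvd_prefixes)
        assert codes_match_any(["G45"], cs.cerebrovascular)
        assert not codes_match_any(["I29"], cs.cvd_prefixes)  # gap between ranges

    def test_sets_pairwise_disjoint(self):
        cs = OutcomeCodeSets()
        all_prefixes = cs.ihd + cs.cardiovascular + cs.stroke + cs.cerebrovascular
        assert len(all_prefixes) == len(set(all_prefixes))


class TestResolveOutcomes:
    def test_cvd_hospitalization_feeds_composite(self):
        ev = events_frame([("p1", dt.date(2010, 5, 1), "hospitalization", "I21.0")])
        out = resolve_outcomes(ev, make_index(["p1"]))
        assert out.at["p1", "cvd_hosp"] == dt.date(2010, 5, 1)
        assert out.at["p1", "composite"] == dt.date(2010, 5, 1)
        assert pd.isna(out.at["p1", "all_cause_death"])

    def test_non_cvd_death_not_cvd_death(self):
        ev = events_frame([("p1", dt.date(2011, 1, 1), "death", "C34")])
        out = resolve_outcomes(ev, make_index(["p1"]))
        assert out.at["p1", "all_cause_death"] == dt.date(2011, 1, 1)
        assert out.at["p1", "composite"] == dt.date(2011, 1, 1)
        assert pd.isna(out.at["p1", "cvd_death"])

    def test_composite_takes_earliest_event(self):
        idx = dt.date(2007, 1, 1)
        ev = events_frame(
            [
                ("p1", idx + dt.timedelta(days=1200), "hospitalization", "G45"),
                ("p1", idx + dt.timedelta(days=1500), "death", "I50"),
            ]
        )
        out = resolve_outcomes(ev, make_index(["p1"]))
        assert out.at["p1", "composite"] == idx + dt.timedelta(days=1200)
        assert out.at["p1", "cvd_death"] == idx + dt.timedelta(days=1500)

    def test_death_before_index_rejected(self):
        ev = events_frame([("p1", dt.date(2006, 1, 1), "death", "I50")])
        with pytest.raises(ValueError, match="death before index"):
            resolve_outcomes(ev, make_index(["p1"]))


@pytest.fixture
def survival_inputs():
    pids = ["p1", "p2"]
    cohort = pd.DataFrame(
        {
            "patient_id": pids,
            "index_date": [dt.date(2007, 1, 1)] * 2,
            "sex": ["male", "female"],
            "age_band": ["20-49", "50-69"],
            "insurance": ["NHI", "NHI"],
            "ses": ["high", "low"],
            "institution": ["clinic", "clinic"],
            "therapy_type": ["dual", "dual"],
            "cci_category": ["0", "1"],
            "disability": [0, 0],
            "diabetes": [0, 1],
            "dyslipidemia": [0, 0],
        }
    )
    profiles = pd.DataFrame(
        {
            "patient_id": pids,
            **{f"adherent_{m}_{w}": [True, False] for m, w in
               [(m, w.lower()) for m, w in ESTIMATE_KEYS]},
        }
    )
    ev = events_frame([("p2", dt.date(2010, 7, 27), "hospitalization", "I63.9")])
    outcomes = resolve_outcomes(ev, cohort[["patient_id", "index_date"]])
    return cohort, profiles, outcomes


class TestBuildSurvivalDataset:
    def test_censor_and_event_rules(self, survival_inputs):
        cohort, profiles, outcomes = survival_inputs
        ds = build_survival_dataset(
            cohort, profiles, outcomes, ("pdc_with1", "PxM"), "composite",
            dt.date(2015, 12, 31),
        )
        p1 = ds[ds.patient_id == "p1"].iloc[0]
        assert not p1["event"]
        assert p1["time_days"] == (dt.date(2015, 12, 31) - dt.date(2007, 1, 1)).days
        assert not p1["non_adherent"]
        p2 = ds[ds.patient_id == "p2"].iloc[0]
        assert p2["event"] and p2["time_days"] == 1303 and p2["non_adherent"]

    def test_full_cross_product_is_24_datasets(self, survival_inputs):
        cohort, profiles, outcomes = survival_inputs
        datasets = [
            build_survival_dataset(
                cohort, profiles, outcomes, key, outcome, dt.date(2015, 12, 31)
            )
            for key in ESTIMATE_KEYS
            for outcome in OUTCOME_TYPES
        ]
        assert len(datasets) == 24

    def test_missing_profile_names_patient(self, survival_inputs):
        cohort, profiles, outcomes = survival_inputs
        with pytest.raises(ValueError, match="p2"):
            build_survival_dataset(
                cohort, profiles.iloc[:1], outcomes, ("pdc_with1", "PxM"),
                "composite", dt.date(2015, 12, 31),
            )


def exponential_two_group(rng, n_per_arm, rate0, rate1, censor=None):
    non_adherent = np.repeat([False, True], n_per_arm)
    rates = np.where(non_adherent, rate1, rate0)
    t = rng.exponential(1.0 / rates)
    if censor is None:
        time, event = t, np.ones_like(t, dtype=bool)
    else:
        time, event = np.minimum(t, censor), t <= censor
    return pd.DataFrame({"time_days": time, "event": event, "non_adherent": non_adherent})


class TestFitCox:
    def test_recovers_rate_ratio_of_two(self, rng):
        ds = exponential_two_group(rng, 2000, 0.01, 0.02)
        fit = fit_cox(ds, "unadjusted", compute_concordance=False)
        assert fit.hr == pytest.approx(2.0, rel=0.10)
        assert fit.ci95[0] < fit.hr < fit.ci95[1]

    def test_null_exposure_hr_near_one(self, rng):
        ds = exponential_two_group(rng, 2000, 0.01, 0.01)
        fit = fit_cox(ds, "unadjusted", compute_concordance=False)
        assert fit.hr == pytest.approx(1.0, rel=0.10)

    def test_all_censored_rejected(self, rng):
        ds = exponential_two_group(rng, 50, 0.01, 0.02)
        ds["event"] = False
        with pytest.raises(ValueError, match="events"):
            fit_cox(ds, "unadjusted")

    def test_single_exposure_group_rejected(self, rng):
        ds = exponential_two_group(rng, 50, 0.01, 0.02)
        ds["non_adherent"] = True
        with pytest.raises(ValueError, match="exposure"):
            fit_cox(ds, "unadjusted")

    def test_aic_identity_and_nested_loglik(self, rng):
        n = 600
        ds = exponential_two_group(rng, n // 2, 0.01, 0.02)
        ds["sex"] = rng.choice(["male", "female"], n)
        ds["age_band"] = rng.choice(["20-49", "50-69", "70+"], n)
        unadj = fit_cox(ds, "unadjusted", compute_concordance=False)
        adj = fit_cox(ds, "age_sex", compute_concordance=False)
        assert unadj.aic == pytest.approx(-2 * unadj.loglik + 2 * unadj.n_params, abs=1e-9)
        assert adj.aic == pytest.approx(-2 * adj.loglik + 2 * adj.n_params, abs=1e-9)
        assert adj.loglik >= unadj.loglik - 1e-8  # nested models

    def test_pure_noise_covariates_typically_worsen_aic(self, rng):
        deltas = []
        for _ in range(30):
            ds = exponential_two_group(rng, 150, 0.01, 0.02)
            ds["sex"] = rng.choice(["male", "female"], len(ds))
            ds["age_band"] = rng.choice(["20-49", "50-69", "70+"], len(ds))
            unadj = fit_cox(ds, "unadjusted", compute_concordance=False)
            noisy = fit_cox(ds, "age_sex", compute_concordance=False)
            deltas.append(noisy.aic - unadj.aic)
        # each noise coefficient costs ~ 2 - chi2(1) AIC units, positive in mean
        assert np.mean(deltas) > 0


def brute_force_harrell(risk, time, event):
    """O(n^2) usable-pair concordance with tied risks counted 1/2."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


class TestConcordance:
    def test_harrell_matches_brute_force_oracle(self, rng):
        n = 500
        time = rng.exponential(100, n)
        event = rng.random(n) < 0.7
        risk = 0.3 * -np.log(time) + rng.normal(0, 1, n)
        assert concordance(risk, time, event, "harrell") == pytest.approx(
            brute_force_harrell(risk, time, event), abs=1e-12
        )

    def test_perfect_ordering_scores_one(self, rng):
        time = rng.exponential(100, 200)
        event = np.ones(200, bool)
        assert concordance(-time, time, event, "harrell") == 1.0
        assert concordance(-time, time, event, "uno") == 1.0

    def test_constant_score_is_half(self, rng):
        time = rng.exponential(100, 200)
        event = np.ones(200, bool)
        assert concordance(np.zeros(200), time, event, "harrell") == 0.5
        assert concordance(np.zeros(200), time, event, "uno") == 0.5

    def test_tau_beyond_followup_rejected(self, rng):
        time = rng.exponential(100, 50)
        event = np.ones(50, bool)
        with pytest.raises(ValueError, match="tau"):
            concordance(-time, time, event, "uno", tau=time.max() + 1)

    def test_harrell_exceeds_uno_under_outcome_dependent_censoring(self, rng):
        """Harrell's C inflates when high-risk subjects are censored early."""
        diffs = []
        for _ in range(20):
            n = 800
            x = rng.normal(0, 1, n)
            t = rng.exponential(1.0 / np.exp(0.8 * x))
            c = rng.exponential(0.35 / np.exp(0.8 * x))
            time = np.minimum(t, c)
            event = t <= c
            tau = float(np.quantile(time, 0.9))
            diffs.append(
                concordance(x, time, event, "harrell")
                - concordance(x, time, event, "uno", tau=tau)
            )
        assert np.mean(diffs) > 0


class TestDiagnosticsGrid:
    def test_grid_shape_and_flag(self, rng):
        ds = exponential_two_group(rng, 400, 0.01, 0.02)
        fits = [fit_cox(ds, "unadjusted", estimate_key=key) for key in ESTIMATE_KEYS]
        grid = diagnostics_grid(fits)
        assert len(grid) == 6
        assert set(grid.columns) >= {"aic", "harrell_c", "uno_c", "good_model"}
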