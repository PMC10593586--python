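# Methods

## Problem

Pharmacy-claims databases record *dispensations*, not ingestion. For a
patient on several antihypertensive drug classes at once, "adherence" is
not a single number: it depends on how multidrug coverage is aggregated
and on when the observation window is deemed to end. `polyadhere`
implements the three standard multidrug aggregations and both window
conventions, so the same refill history yields six comparable estimates,
and carries the estimates into a survival analysis of clinical outcomes.

## Time axis and coverage model

All computation happens on integer day offsets from the patient's index
date (day 0, the first qualifying fill); intervals are half-open
`[start, end)`. A fill of `s` days' supply of class *c* on day *d*
contributes `s` covered days for *c*, resolved under a carry-over policy:

- **shift_forward** (default): an early refill is stockpiled — its supply
  starts when the previous supply is exhausted. Equivalent to a pill
  queue to which every refill appends.
- **discard**: leftover pills are thrown away at each refill, so a fill's
  coverage is cut short at the next fill day. Equivalent to a pill queue
  that each refill resets. Offered for sensitivity analysis.

Same-day duplicate fills of one class are summed (indistinguishable from
one larger dispensation at day resolution). Coverage is truncated at the
fixed assessment window end (default 1,095 days) under both window
conventions, which guarantees FxM ≤ PxM below. A deliberately naive
day-by-day pill-queue simulator ships alongside the interval engine and
the two are required to agree exactly, day for day, under both policies;
the equivalence is enforced by randomized tests.

A class's **episode** — the span over which it counts as "to be taken" —
runs from its first fill day to the end of its last supply. Refill
cessation is the only discontinuation signal observable in claims, so
nothing after the last supply is demanded of the patient for that class.

## Observation windows

- **PxM** (prescription-based): the window ends when the last dispensed
  supply of any class runs out, truncated to the assessment window.
- **FxM** (fixed-period): the window is the full assessment window.

## The six estimates

With `available[d]` = number of classes with supply on day *d* and
`expected[d]` = number of classes whose episode spans day *d*:

- **PDC_with≥1** = #{d : available[d] ≥ 1} / window length.
- **PDC_wm**: each class's PDC over its own class window (first fill day
  to episode end under PxM, to the patient window end under FxM),
  averaged with weights equal to the class-window lengths. Algebraically
  identical to Σ covered_c / Σ window_c; the identity is asserted to
  1e-12 in the tests.
- **DPPR** = mean over window days of min(available/expected, 1) on days
  with expected > 0 (else 0). The cap is defensive; availability cannot
  exceed expectation by construction of episodes.

Class windows for PDC_wm start at each class's first fill, not at the
patient index date: the duration weight is class-specific, and starting
at index would penalize late add-on therapy twice. Patients are
dichotomized at a configurable threshold, 0.80 by default, inclusive
(estimate ≥ 0.80 is adherent).

These rules imply, for every patient: all six estimates lie in [0, 1];
FxM ≤ PxM for each measure (shared numerators, larger FxM denominators);
and DPPR ≤ PDC_with≥1 within a window (a day's fractional score never
exceeds the any-coverage indicator).

## Cohort selection

Candidates are patients with ≥ 1 antihypertensive fill in the index year;
the index date is the earliest such fill. Exclusions, applied in order
(age ≤ 20, no hypertension diagnosis flag, fewer than 2 classes in the
index year, any fill in the 365-day washout, < 90 total days' supply in
the assessment window, CVD/cancer hospitalization in the prior year,
death or CVD/cancer event within the assessment window), each record one
attrition row. "< 90 days of use" is interpreted as total days' supply
summed across classes — computable without coverage resolution.
"Multidrug" requires ≥ 2 distinct classes each with ≥ 1 fill in the index
year; concurrency is not required. Violations are evaluated
independently, so the cohort is invariant under filter reordering; only
the attribution of an excluded patient to a (first applicable) filter is
order-dependent.

## Outcomes and survival models

Outcomes are resolved from ICD-10 prefix sets — ischemic heart disease
I20–I25; other cardiovascular I05–I09, I26–I28, I30–I52; stroke I60–I64;
cerebrovascular I65–I69, G45–G46 — matched by code prefix (I21.9 matches
I21). The composite outcome is the earliest CVD-coded hospitalization or
death from any cause; secondary outcomes are all-cause death, CVD-cause
death and CVD hospitalization, each taken at its own first event, with
administrative censoring at the configured end of follow-up
(2015-12-31 by default).

Cox proportional-hazards models (partial likelihood, Efron tie handling —
day-resolution times are heavily tied) are fitted with the dichotomized
*non*-adherence flag as exposure at three adjustment levels: unadjusted;
sex + age band; fully adjusted (plus disability, insurance, socioeconomic
status, institution type, therapy type, comorbidity-index category,
diabetes, dyslipidemia). Categorical covariates enter as indicators
against reference levels: adherent, male, age 20–49, National Health
Insurance, high SES, clinic, dual therapy, CCI 0, no diabetes, no
dyslipidemia. Age is banded (20–49 / 50–69 / 70+) rather than continuous.
AIC is −2·loglik + 2k on the partial likelihood. Model discrimination is
reported as Harrell's C (usable-pair concordance, tied risks ½) and
Uno's C (inverse-probability-of-censoring-weighted concordance,
truncated by default at the 95th percentile of observed follow-up), the
latter correcting Harrell's upward bias under heavy censoring.

## Synthetic claims generator

The generator emulates the structure of a national single-payer claims
extract for new users of multidrug antihypertensive therapy, with ground
truth recorded per patient.

**Covariates** are independent draws from the marginal frequencies of the
emulated study population (female 47.4%, age ~ Normal(55.72, 12.49)
truncated at 20, disability 7.4%, Medical Aid 5.6%, SES
37.9/33.9/21.7/6.5%, institution 4.4/10.2/76.3/9.1%, CCI 72.7/18.9/8.4%,
diabetes 15.4%, dyslipidemia 31.0%; class count 2 with probability
77.4%). No covariate correlation structure is imposed.

**Refills** follow a shared-pharmacy-visit model. One days'-supply length
(30/60/90, probabilities 0.60/0.25/0.15) is drawn per patient, and all
active classes are refilled on shared visit days — real multidrug
refills are synchronized, and this is what makes the three measures
track each other closely, as observed in practice. A latent adherence
propensity θ ~ Beta(2.2, 0.7) drives behaviour: the delay between supply
depletion and the next visit is Geometric with mean 70·(1−θ) days; each
class independently discontinues for good at any visit with probability
0.04·(1−θ); with probability 0.2 a visit happens up to 7 days *early*
(stockpiling). θ = 1 therefore implies gapless, never-discontinuing
refills and all six estimates equal to 1. Add-on classes start uniformly
within the first 90 days, capped at the index-year end so that clean
patients satisfy the multidrug-in-index-year inclusion. These defaults
were fixed once so that the simulated population's mean adherence,
adherent fractions and medians land in the ranges typical of
antihypertensive multidrug cohorts (means in the 70s–low 80s %, roughly
55–65% adherent at the 80% threshold); they are ordinary dataclass
fields, not hidden constants.

**Outcomes** are exponential event times under proportional hazards:
daily hazard 8.5e-5 for truly adherent patients times a configurable
hazard ratio (default 1.4) for non-adherent ones, administratively
censored at the end of 2015. Events are labelled hospitalization vs
death (70/30) and deaths CVD-cause vs other (24/76). Crucially, the
hazard acts on the *true* behavioural flag (derived from θ and the
patient's supply length via the renewal-theory coverage expectation
s/(s + 70·(1−θ)) ≥ 0.8), not on any measured estimate — so the
attenuation a given measurement induces in the fitted hazard ratio is
itself observable, which is precisely the methodological question the
package exists to study.

Determinism: one integer seed drives everything; identical
(configuration, seed) pairs produce byte-identical CSV output.

### What the generator does not emulate

Covariates are independent of each other and of outcome hazard, so
covariate adjustment neither confounds nor adds discrimination —
adjusted hazard ratios match unadjusted ones in expectation, and
adjusted C-indexes stay near the exposure-only value (~0.56) instead of
the ~0.72 seen in real cohorts where age and comorbidity predict events.
There are no fixed-dose combination pills, no dose-level information, no
hospitalization-day supply suspension, no seasonal or calendar effects,
and a patient has at most one generated outcome event. Passing tests
therefore certify the measurement and modelling machinery, not any
clinical claim about real populations.

## Numerical and degenerate-input choices

Fills on or after the window end are ignored with a logged notice;
pre-index fills reaching the coverage engine are an error (the washout
filter consumes them). A patient with no in-window coverage has no
defined PxM window and is an error at profiling (cannot arise for cohort
members, whose index fill is day 0). Zero-length windows, empty profile
collections, all-censored datasets, single-group exposures and
out-of-range thresholds all raise instead of degrading. Exponential
event-time draws are clipped one day past the censoring horizon (they
are censored regardless) to keep extreme tails inside the timestamp
range. Wald confidence intervals use ±1.959963984540054 standard errors.

## Problem sizes used in the checks

The randomized oracle-equivalence check uses 1,000 fill sequences per
carry-over policy (≤ 10 fills, supplies in {7, 30, 60, 90}, windows up
to 400 days). Measure-algebra and qualitative-pattern checks use
populations of 300–400 simulated patients over the full 1,095-day
window. The Cox calibration experiment runs 1,000 replications per arm
at n = 4,000 with ~19% composite events — enough that the empirical
coverage and rejection rates sit well inside their acceptance bands
whenever the underlying method is calibrated, rather than hinging on a
particular seed. The acceptance script runs the full pipeline at the
default population size of 4,226.
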