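# Methods

## Model structure

The core is a proportional multistate life table (MSLT). A closed cohort —
both sexes, single-year ages 20–80 at baseline 2019, no new entrants — is
advanced in annual cycles to 2030. Each of the eleven BMI-related diseases
has its own four-state life table (healthy, diseased, dead from the
disease, dead from other causes) run independently of the others
(proportional-MSLT assumption: no comorbidity interactions). Within a
cycle, person-year rates are converted to annual probabilities,
q = 1 − exp(−rate), and events are applied in the order incidence →
remission → case fatality → other-cause death. This discretisation and
ordering is the standard life-table convention; state mass is conserved to
1e−9 (relative) every stratum-year, and the engine is verified against an
independent step-by-step bookkeeping oracle and against the closed-form
cumulative-incidence limit N(1 − e^(−iT)) when case fatality and remission
are zero.

Other-cause mortality for disease *d* is the cause-deleted rate
max(m_all − p_d·f_d, 0), with p_d the input prevalence at the cohort's
current age. The main life table's total mortality is the all-cause rate
with every disease's p·f share deleted, plus the disease tables' evolving
per-capita disease mortality — so scenario-induced changes in disease
occurrence feed back into how many people remain alive.

Cohorts age past 80 during the horizon. Epidemiological and mortality
rates above age 80 reuse the age-80 values; relative-risk age lookups are
capped at 89, the oldest published band. Burden is reported by the year in
which each cycle ends (2020–2030), so period totals cover eleven cycles.

## Exposure, risk and the impact fraction

Stratum BMI is modelled as normal (mean, sd). The published uncertainty
spans around the survey means are treated as population spread, not
standard errors of the mean — they are far too wide for a national survey
mean — but the spread actually used is solved from the second published
anchor, the overweight prevalence: two printed anchors identify the
two-parameter family.

Relative-risk curves come in two forms. Per-5-kg/m² log-linear curves,
RR(x) = rr^((x − TMREL)/5), use the band matching sex and age; ages 20–34
borrow the youngest printed band and ages above the oldest band use the
oldest, except where the source restricts applicability (liver cancer
35–79, breast cancer women over 60), where RR = 1 outside the window.
Below the TMREL of 22 kg/m² the log-linear RR is floored at 1: risk
reversal below normal weight is not modelled, a conservative choice.
Categorical curves (hypertensive heart disease, diabetes, chronic kidney
disease, cirrhosis) are step functions over the printed BMI bands, used as
printed — including sub-unity values in the 15–25 band.

The potential impact fraction is evaluated on a BMI grid of 10–60 kg/m² at
0.1 steps (midpoint rule, truncated tails renormalised); halving the step
changes the PIF by well under 1e−4 against a 10×-finer oracle grid. Point
masses (the TMREL counterfactual) are evaluated exactly, off-grid. The
incidence multiplier applied in the engine is the complement 1 − PIF,
computed as a single ratio so the two are complementary to machine
precision. For the four per-5-unit diseases the continuous (gridded normal)
evaluation is the default; the categorical step curves make the same
machinery categorical automatically.

## Scenarios

All four trajectories share the 2019 baseline and leave each stratum's sd
unchanged:

* **BAU** and **S1** compound the stratum mean by 0.4 %/yr and 0.2 %/yr.
* **S2** ("hold current prevalence") holds each stratum's own 2019
  overweight prevalence constant. A mean shift with fixed sd has a fixed
  point at the current prevalence, so S2 is exactly the frozen baseline.
  The published pooled figure (76.9 % "on average") is kept in the config
  as documentation of the pooled anchor; imposing it uniformly on every
  stratum would move the 2019 distributions themselves and break the
  common-baseline anchor of the four scenarios.
* **S3** reduces each stratum's overweight prevalence linearly by 0.61 % of
  its 2019 value per year (6.7 % relative by 2030), realised as a mean
  shift with fixed sd: mean = 25 + sd·Φ⁻¹(target). Whether the original
  spreadsheet model shifted means, category prevalences, or both is not
  recoverable; the mean shift is the simplest one-parameter mechanism
  consistent with a population-wide intervention, and it is isolated in
  `scenarios.py` behind `prevalence_to_mean_shift` so it is swappable.

"Reduced by 6.7 %" is read as a *relative* reduction of prevalence
(matching 0.61 %/yr × 11 ≈ 6.7 %), applied on the prevalence scale. Growth
rates apply uniformly across age and sex (no stratum-specific trends are
published).

## Lags and the multiplier timeline

The multiplier for the cycle starting in year *t* compares the scenario's
BMI distribution at *t* + 1 — the exposure reached over that cycle — with
the frozen 2019 baseline, then delays the series by the disease lag
(5 years; 10 for cancers), holding the trajectory's start-year value
before the lag completes. Consequences:

* the four scenarios (whose 2019 distribution *is* the baseline) are
  mutually indistinguishable until the shortest lag completes, and first
  diverge in the 2024→2025 cycle (2029→2030 for cancers);
* BAU's own multipliers exceed 1 after its lag — rising BMI raises inflow
  even in the no-intervention run;
* the TMREL counterfactual, whose exposure was already at 22 kg/m² before
  the horizon, keeps its full multiplier from the first cycle, so
  attributable burden accrues from 2019 onward.

Attributable burden is run(trajectory) − run(TMREL held all years);
averted burden is attributable(BAU) − attributable(scenario), in which the
TMREL run cancels. "Cases averted" counts incident cases, not
prevalence-years.

## Uncertainty

Monte Carlo draws sample (a) the relative risks — lognormal with median at
the point estimate and log-sd (ln rr_high − ln rr_low)/3.92, one shared
standard-normal deviate per disease across its bands, since the bands come
from a single meta-analysis and independence would understate uncertainty —
and (b) the baseline BMI means, a common normal shift per sex with a
0.1 kg/m² standard error (no exposure spread is published; this is a
documented assumption). Disease rates are held fixed: input-rate
uncertainty is not propagated, a known limitation. Each draw rebuilds the
scenario trajectories from its shifted baseline and re-runs the whole
model, so draws are paired across scenarios and averted-burden intervals
come from per-draw differences. Intervals are 2.5th/97.5th percentiles
(bootstrap-percentile convention). The point estimate is the
central-parameter run; percentile intervals may exclude it in skewed
settings, which is recorded rather than corrected. A fixed seed gives
bit-identical intervals.

## Synthetic inputs

The generator emulates the study inputs that cannot be redistributed:

* **Population**: 1e5 persons per sex, counts declining ~1.5 %/year of
  age, Gompertz all-cause mortality (male 8.0e−4·e^(0.075·(a−20)), female
  4.5e−4·e^(0.080·(a−20)) — roughly 0.07/0.05 per person-year at 80).
* **BMI**: stratum means with a mild age gradient (0.02 kg/m²/yr) centred
  so the count-weighted sex means equal the published anchors exactly
  (28.1 men, 29.4 women); a single sd per sex solved by root-finding so
  pooled overweight prevalence is 0.757.
* **Disease rates**: exponential age-increasing incidence with
  order-of-magnitude plausible bases (e.g. diabetes 4e−4/py at 20 growing
  3.5 %/yr of age; pancreatic cancer 5e−7 growing 10 %/yr), flat case
  fatality, remission only for cancers, mild seeded lognormal jitter
  (sd 0.05) per stratum, and prevalence set to the illness-death steady
  state p solving f·p² − (i+r+f)·p + i = 0 — the closed-form stand-in used
  in place of a full rate-balancing adjustment, which is out of scope.

What the synthetic bundle does *not* emulate: real GBD 2019 Chilean rate
levels, survey sampling design, cohort-specific secular BMI trends, or
open-cohort entry. Passing tests on it therefore demonstrate the engine's
arithmetic, invariants and qualitative scenario structure (ordering, lag
onset, dominance), not Chile's absolute burden magnitudes; the published
absolute numbers are covered separately by exact arithmetic on the shipped
results fixture.

## Numerical choices and degenerate inputs

BMI grid 10–60 at 0.1; tails truncated and renormalised. Rates are
validated non-negative; prevalence in [0, 1]; a lag longer than the horizon
yields an all-neutral multiplier series (valid, no effect); zero incidence
yields an empty disease state; scenario growth rates must be non-negative
(reductions go through the prevalence mechanisms); a prevalence target of 0
or 1 is rejected as infeasible. Shares are rounded to one decimal and
counts to integers only at presentation.

## Problem sizes used in the checks

The shipped test-and-acceptance configuration runs the full 122-stratum
bundle (2 sexes × 61 ages, 2×1e5 persons) for all scenarios, and Monte
Carlo at 100 draws in the acceptance script (smaller draw counts in unit
tests, 1000 as the production default in `ModelConfig`). One full
five-trajectory point run takes well under a second; 100 paired draws about
half a minute.

## Known limitations

Closed cohort (no 2020+ birth-cohort entry, so late-horizon totals omit
newly adult strata); no comorbidity interaction; RRs transported unadjusted
from the meta-analysis; no extra dispersion for residual confounding or RR
portability; disease-rate uncertainty not propagated; the published
uncertainty intervals in the fixture are carried verbatim (they derive
from draw-level data that is not available) and are never recomputed.
Two garbled printed cells are repaired by the column-sum identities and
flagged in the fixture; one printed share (38.2 %) computes to 38.3 % from
the printed cells, and the package reports the computed value.
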