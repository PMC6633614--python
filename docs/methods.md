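# Methods

This note records the model's assumptions, the conventions adopted where the
underlying literature leaves a choice open, the defaults and why, and what
the synthetic data generator does and does not establish.

## Model structure

The engine is a proportional multistate life table. A closed cohort of
adults aged 15–100 is simulated by single year of age and sex; there are no
births or migration, and survivors past age 100 leave the simulation. Each
modelled disease (ischaemic heart disease, stroke, type 2 diabetes, seven
cancers, liver cirrhosis) has an independent three-state illness-death
process — never diseased, prevalent, dead of the disease — parameterised by
annual incidence and case fatality (the annual mortality rate among
prevalent cases). Remission is fixed at zero.

Diseases are assumed independent except for one explicit coupling: diabetes
prevalence feeds back into IHD and stroke incidence each simulated year via
the multiplier `(1 + p_s(RR−1)) / (1 + p_b(RR−1))`, the ratio of
population-average cardiovascular risk between scenario and baseline, using
sex-specific RRs of CVD given diabetes. The model cannot distinguish
comorbidity within a person from co-prevalence across people; utility
decrements are therefore additive with no interaction term (testing the
extreme comorbidity assumptions changes results negligibly).

Interventions act on disease **incidence only**, never on case fatality; if
a real intervention also improved survival after diagnosis, the model
understates its benefit.

## Numerical choices

* **Within-year transitions** use the exact solution of the constant-rate
  illness-death generator over one year (`h' = h e^{-i}`,
  `p' = p e^{-f} + h i (e^{-i}−e^{-f})/(f−i)`, with the series limit at
  `i ≈ f`). This is oracle-checked against fine-substep Euler integration.
* **Person-years** credit the start-of-year alive count for the whole year
  (deaths at year end); no half-cycle correction is applied. With constant
  mortality this makes cohort life years an exact geometric sum, which the
  tests exploit.
* **Other-cause mortality** is derived once at baseline as all-cause minus
  the disease mortality implied by the input tables, floored at zero; both
  runs then rebuild all-cause mortality from their own disease states.
* **PIF integration**: exposure densities are normal, truncated to
  [0, mean + 4 SD] and renormalised, integrated by 201-point trapezoid
  (configurable). Zero-SD inputs collapse to point masses with the
  closed-form PIF. Fruit/vegetable non-consumers are a point mass at zero
  intake mixed with the consumer normal; the non-consumer share is held
  fixed under interventions.
* **Dose-response clamping**: RR is floored at 1 beyond the
  theoretical-minimum exposure — moving past the minimum-risk point earns
  no additional benefit. Exposure-banded BMI risks form a continuous
  piecewise log-linear curve anchored at the minimum before clamping.
* **Age bands** apply as step functions (no interpolation). Ages above the
  last band of a banded RR reuse the nearest band; ages below the first
  band carry no effect.
* **Discounting**: PV = Σ v_y/(1+r)^y with year 0 undiscounted
  (config-settable convention); default 1.5%/year on both costs and health.
* **Trends** are annual multiplicative drifts on incidence and case
  fatality compounding from simulation year 0, applied identically to both
  runs; a configurable decay year can freeze them.

## Parameter conventions

Where the source material states a relationship but not its exact functional
form, the following conventions are used (all configurable):

* **Quarter-power physical activity**: `RR(x) = exp(β (x/11.25)^0.25)` so
  RR(0) = 1 (sedentary reference) and RR equals `exp(β)` at the 11.25
  MET h/wk reference dose. Activity categories: sedentary (0 min moderate
  activity/week), under-active (0–60), active (60–150), recommended
  (≥150; the 150 boundary is assigned to "recommended").
* **Salt → sodium**: 17.1 mmol sodium per gram of salt (NaCl is 40% Na,
  molar mass 23), feeding the 5.80 mmHg per 100 mmol/24 h coefficient.
* **Energy → BMI**: the external energy-balance equations are replaced by a
  deliberately simple linear steady-state stand-in — 0.010 kg body weight
  per kJ/day of sustained intake change (≈1/100 kJ·kg⁻¹·day⁻¹ adult
  estimates), divided by squared reference height (1.75 m men, 1.62 m
  women). This is the model's weakest link and is prominently
  config-exposed (`EnergyBalanceConfig`).
* **Mediation factors** are stored with positive coefficients describing
  the harmful direction (BMI up; fruit/vegetables down). Fruit/vegetable
  mediation units are per 80 g/day portion (the source table does not state
  the unit). Adjustment divides the total RR by the RR implied by the
  mediated intermediate change, so firing both pathways reproduces the
  total effect exactly (identity-tested to 1e-9).
* **PA → CVD diabetes deconfounding**: the share of the physical-activity
  effect on IHD/stroke mediated by diabetes is stripped linearly at the
  reference dose (`β_direct = β_total (1 − fraction)`); the life table
  restores the mediated share dynamically. Default fraction 0.10 — a
  deliberately modest value since the dynamic coupling supplies the
  remainder; the exact published adjustment lives in a cited work and is
  not reproduced here (`pa_diabetes_mediated_fraction`).
* **Case fatality from mortality**: `f = m/P` with the illness-death
  residual `dP/da − [i(1−P) − fP]` reported as a diagnostic; the full
  external consistency-fitting tool is intentionally not reimplemented.
* **PSA distributions**: lognormal RRs with `σ = SE/value` (log-scale delta
  method) so the sample median equals the point estimate; normal betas,
  minima, pathway and mediation coefficients, and utility decrements;
  gamma(mean 1, SD 0.1) multipliers on health and on societal costs. Age
  bands of one exposure-disease pair share a z-score (fully correlated) by
  default. Substreams are keyed by (seed, run, hash of parameter id), so
  adding a parameter never reshuffles the others. Default 2000 runs;
  intervals are empirical 2.5th/97.5th percentiles.

## Costs and utilities

Modelled-disease costs are per prevalent case per year (top-down programme
budgeting totals divided by prevalence), so they do not vary with time
since diagnosis or proximity to death. Unrelated-disease costs accrue per
person-year alive from an age/sex spend profile; the packaged profile is
**synthetic** (a smooth logistic rise with age, file
`unrelated_costs_synthetic.csv`) and should be replaced with a real cost
curve for applied work. Social care applies from age 75 at 12 × £4826 per
person-year, scaled by a need function of age and utility; the packaged
default is the utility shortfall `clip(1 − u, 0, 1)`, replaceable via
`need_function`. Productivity and wider-societal costs are pass-through
user-supplied streams toggled by the sensitivity perspectives; their
internals are not modelled.

Baseline utilities already embed all diseases in the population, including
the modelled ones — a known mild double-count that is left uncorrected.
Where incident and prevalent decrements both exist (IHD, stroke), the newly
incident fraction receives the incident value in its first year
(toggleable).

## Synthetic data: what a green test establishes

The generator emulates the *shape* of real inputs — Gompertz all-cause
mortality, exponentially age-increasing incidence and case fatality,
survey-style exposure means/SDs (salt ≈ 8.4/6.8 g/day men/women, BMI ≈
23.5 rising with age, physical activity truncated at 200 MET h/wk,
fruit/vegetable non-consumer shares of 22%/10%) — and is internally
consistent by construction: prevalence is the forward RK4 integral of
`dP/da = i(1−P) − fP`, so the case-fatality identity holds with ~zero
residual. It is **not** calibrated to any real population: green end-to-end
tests establish that the machinery is arithmetically correct and
directionally sensible, not that absolute QALY or cost magnitudes match any
country. Two profiles exist: `small` (IHD + stroke, ages 60–69; sub-second
lifetime runs, used throughout the tests) and `full` (11 diseases, ages
15–100).

## Known limitations

* Cohort (not microsimulation) structure: no population heterogeneity
  beyond age/sex, no interactions between individuals; subgroup results
  require separate runs with subgroup inputs.
* Disease independence outside the diabetes→CVD coupling.
* The free-sugars → cholesterol pathway is not included.
* Per-prevalent-case costing and the synthetic unrelated-cost profile limit
  absolute cost accuracy until replaced with jurisdiction-specific data.
* The energy→BMI stand-in is linear and static; do not use it for
  energy-intake interventions without substituting a proper energy-balance
  model.
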