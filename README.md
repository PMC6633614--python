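# msltce

A multistate life table cost-effectiveness engine for population interventions
on diet and physical activity.

Public-health decision makers need to compare, on a common footing, how
different preventive policies — reformulating salt out of food, shifting fruit
and vegetable intake, raising physical activity — would change chronic-disease
burden, quality-adjusted life years (QALYs), and health and social care
spending. `msltce` answers that with a proportional multistate life table:
a closed adult cohort (ages 15–100, by single year of age and sex) is
simulated under a baseline and an intervention scenario, and the difference
in discounted costs and QALYs yields an incremental cost-effectiveness ratio
(ICER) or, for cost-saving interventions, a return on investment (ROI).

## The model

**Risk → incidence.** An intervention shifts the population distribution of
one or more risk factors (means shift, SDs are preserved). For each disease
the proportional change in incidence is the potential impact fraction

```
PIF = ( ∫ RR(x) f_base(x) dx − ∫ RR(x) f_scen(x) dx ) / ∫ RR(x) f_base(x) dx
```

with log-linear dose-response curves `RR(x) = RR_unit^((x − x_min)/unit)`
anchored at each factor's theoretical-minimum-risk exposure and clamped at 1
beyond it. Diet factors act directly (fruit, vegetables, fibre, red and
processed meat) and/or through three intermediates — systolic blood pressure,
total cholesterol, BMI (e.g. salt → sodium → SBP at 5.80 mmHg per 100 mmol
Na/24 h). Physical activity uses a quarter-power dose-response,
`RR = exp(β·(METh/11.25)^0.25)`. Mediation factors strip the intermediate
share out of fruit/vegetable/BMI relative risks on IHD and stroke so firing
both pathways never double counts, and a dynamic diabetes→CVD coupling
rescales IHD/stroke incidence by the ratio of population-average diabetes
risk, `(1 + p·(RR_dm − 1))`, between scenario and baseline.

**The life table.** Each disease carries a three-state illness-death process
(healthy, prevalent, dead-of-disease) with annual incidence and case fatality
(the annual mortality rate among prevalent cases) and zero remission, stepped
with the exact constant-rate transition each year. All-cause mortality is
rebuilt every year as baseline other-cause mortality plus the
disease-specific mortality implied by current disease states, so incidence
changes propagate to survival and person-years.

**Valuation.** Person-years are weighted by EQ-5D utilities (baseline by
age/sex plus additive per-disease decrements) to give QALYs. Costs comprise
per-prevalent-case NHS disease costs derived from programme budgeting,
age/sex unrelated-disease spend, social care from age 75 (12 × £4826/month,
scaled by a replaceable need function of lost utility), and intervention
costs. Streams are discounted at 1.5%/year (first year undiscounted) and
compared as `ICER = (C_b − C_a)/(E_b − E_a)`; when ΔC < 0,
`ROI = |C_b − C_a| / C_i`. Parameter uncertainty is propagated by Monte
Carlo (lognormal RRs median-pinned at the point estimate, normal betas and
coefficients, gamma(mean 1, SD 0.1) cost multipliers; default 2000 runs) and
reported as 2.5th–97.5th percentile uncertainty intervals.

## Worked example

A sustained 1 g/day salt reduction in a small synthetic cohort (two
diseases, ages 60–69), costing £250,000 in year one, over the primary
settings (10-year horizon, 1.5% discount, NHS + social care perspective):

```python
from msltce import load_catalogue, run_pipeline, Intervention
from msltce.synthetic_data import generate_baseline_epi, generate_exposure_survey

ps = load_catalogue()
epi, mlt = generate_baseline_epi(seed=42, profile="small")
exp = generate_exposure_survey(seed=42, ages=epi.ages, profile="small")
res = run_pipeline(ps, epi, mlt, exp,
                   [Intervention("salt", "absolute", -1.0)],
                   horizon=10, intervention_cost=250_000.0)
print(res.econ.to_dict())
```

prints

```
delta_cost      -527873.18      # discounted, GBP
delta_qalys          63.89
classification   dominant       # cheaper and more effective
roi                   2.11      # £2.11 saved per £1 spent
```

Salt reduction lowers blood pressure, which cuts IHD and stroke incidence
(PIF ≈ 0.029 for IHD at age 60 in men); treatment costs fall by ~£735k,
partly offset by ~£127k extra unrelated-disease spend from longer survival,
leaving the intervention dominant.

## Command line

```sh
msltce run --config scenario.yaml --out results/      # one scenario bundle
msltce psa --config scenario.yaml --runs 2000 --out results/psa
msltce sensitivity --config scenario.yaml --out results/sens   # 12 variants
msltce synth --profile full --out inputs/             # synthetic baseline CSVs
msltce validate                                       # catalogue invariants
```

Scenario files are YAML; unset keys take the primary-analysis defaults
(horizon 10 y, discount 1.5%, NHS + social care perspective). The
sensitivity harness covers horizons 1/5/20/100 y, NHS-only and
social-care-only perspectives, productivity and wider-societal add-ons, a
3.5% discount rate, no-unrelated-costs, no-cancer, and
directly-related-diseases-only variants.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the synthetic baseline, runs a combined salt + physical-activity
scenario through the full pipeline with the packaged parameter catalogue,
runs a probabilistic sensitivity analysis, and writes the results JSON.

See `docs/methods.md` for modelling assumptions, parameter conventions, and
known limitations.
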