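# underdx

Estimating the burden of **undiagnosed chronic disease** from linked
individual-level health records.

Underdiagnosis — the probability of being undiagnosed given diseased — is by
definition unobservable in healthcare data. `underdx` implements a
mortality-driven back-calculation: people who die *with* a condition listed
on their death certificate but *without* a prior recorded diagnosis reveal
the size of the undiagnosed pool, once an assumption is made about how
deadly the disease is before diagnosis.

## The model

A discrete annual six-state model per condition:

```
        A           B
  H ───────▶ X ───────▶ Y          H  healthy
  │          │          │          X  diseased, undiagnosed
  │ E        │ D, E     │ C, E     Y  diseased, diagnosed
  ▼          ▼          ▼
  Z₀         Z_U        Z_D        deaths: other / undiagnosed / diagnosed
```

A is disease incidence, B the diagnosis rate, C the case fatality among the
diagnosed, D among the undiagnosed, E other-cause mortality. Z_U and Y are
observed in the records; X is back-calculated as

```
X = Z_U / D,        underdiagnosis p = X / (X + Y)
```

with D equated to the **first-year post-diagnosis case fatality** (main
assumption: the mortality risk when a disease first becomes diagnosable), or
to the overall case fatality of the diagnosed (sensitivity). X is
lower-bounded so the pool can supply the observed flows out of it.

Everything is stratified by sex (2) × age group (5: 30–49, 50–59, 60–69,
70–79, 80+) × deprivation quintile (5) × region (9) × year — 450 strata per
year. Undiagnosed deaths are rare at that resolution, so a binomial
logistic model (age, sex, deprivation, calendar year — deliberately no
region) smooths the observed counts and imputes positive expected counts
for strata that recorded none; first-year case fatality is smoothed the
same way. Stratum probabilities are then projected onto small-area
population tables and aggregated to health planning areas
(indirect small-area estimation), and three sensitivity scenarios
(primary-cause-only deaths, deaths diagnosed within the last year counted
as undiagnosed, overall-CFR assumption) can be compared across areas.

Real linked primary-care/hospital/mortality extracts are access-restricted,
so the package ships a synthetic-cohort generator that simulates
individual-level event logs (persons, dated diagnoses, dated deaths with
primary/contributing cause lists) from known per-stratum transition rates
and records an exact truth table of state occupancies — the whole pipeline
is validated by parameter recovery against that truth.

## Worked example

```bash
cat > example.yaml << 'YAML'
conditions: [hypertension, t2dm, chd, copd, lung_cancer]
years: [2008, 2018]
cohort_size: 100000
seed: 7
n_areas_per_region: 20
areas_per_health_area: 4
YAML
underdx run-all --config example.yaml --out demo/
```

This simulates a 100,000-person cohort observed 2008–2018, runs
extraction → rate estimation → back-calculation → small-area projection for
five conditions, and writes every stage as CSV plus a manifest
(`run complete: 26 outputs in demo/`). The headline table,
`demo/report_national.csv`, gives the estimated percentage of diseased
people who are undiagnosed, nationally, in the first and last study year:

```
condition,2008,2018
hypertension,27.2,29.1
t2dm,26.2,23.9
chd,23.9,26.0
copd,44.6,33.7
lung_cancer,45.6,44.4
```

Read: of everyone alive with COPD in 2008, an estimated 44.6% had no
recorded diagnosis, falling to 33.7% by 2018 (the synthetic cohort's
diagnosis rates improve 3%/year). `demo/estimates_<condition>.csv` holds
the full per-stratum X, Y and p with diagnostic flags,
`demo/health_area_estimates.csv` the population-weighted health-area values,
and `demo/truth.csv` the generator's ground truth for comparison. Stages
can equally be run one at a time (`simulate`, `extract`, `rates`,
`estimate`, `small-area`, `validate`, `report`) and rerun from saved CSVs.

## Limitations worth knowing

The method is driven by mortality: conditions with very low case fatality
(e.g. depression/anxiety at small sample sizes) yield few undiagnosed
deaths and few first-year deaths among the diagnosed, so D is poorly
identified and estimates become unstable — strata whose D had to be floored
are flagged `d_floored` and should be pooled or excluded downstream. See
`docs/methods.md` for the full model description, conventions and numerical
choices.
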