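# Methods

## Model

`underdx` estimates underdiagnosis — the probability of being undiagnosed
given diseased, p = X/(X+Y) — per condition from individual-level event
logs, using a discrete-time six-state model with one-year steps. The living
states are healthy (H), diseased-undiagnosed (X) and diseased-diagnosed
(Y); the absorbing states are disease-specific death from the undiagnosed
state (Z_U), from the diagnosed state (Z_D), and other-cause death (Z_0).
One-year transition probabilities: incidence A (H→X), diagnosis B (X→Y),
diagnosed case fatality C (Y→Z_D, split into a first post-diagnosis year
level C1 and a later-years level), undiagnosed case fatality D (X→Z_U) and
other-cause mortality E (any living state → Z_0). Every person passes
through X before Y; diseases are treated as lifelong (no recovery
transition out of Y).

Y, Z_U, Z_D, incident diagnoses and first-year case fatality are observable
in linked records; X is not. The back-calculation uses that the undiagnosed
pool generates undiagnosed deaths at rate D:

    X = Z_U / D.

D is unobservable by construction, so it is defined from the case fatality
of the diagnosed. The main assumption sets D equal to the first-year
post-diagnosis case fatality — mortality risk around the time the disease
becomes diagnosable — with the overall case fatality among all diagnosed
cases as a sensitivity assumption. X is additionally lower-bounded so the
pool is large enough to supply its observed outflows (next year's incident
diagnoses plus the year's undiagnosed deaths).

All quantities are stratified by sex (2) × age group (30–49, 50–59, 60–69,
70–79, 80+) × deprivation quintile (1 = least deprived) × region (9) ×
calendar year: 450 strata per year.

## Conventions

These conventions make the simulator, the extraction stage and the
back-calculation exactly consistent; they are the package's own choices and
are configurable where noted.

* **Stratum membership** uses attained age on 1 July of the year (exact
  calendar birthdays, not day counts / 365.25); people move age groups at
  their simulated birthday.
* **Person-years and prevalence** follow a year-entry convention: a person
  contributes year t when registered before 1 January of t, still
  registered and alive entering t, and aged ≥30 at mid-year. Diagnosed
  prevalence Y is point prevalence at the start of the year (diagnosed
  strictly before 1 January). With annual dynamics, start-of-year occupancy
  is the risk set generating the year's events, so E[Z_U] = X·D holds
  exactly and the truth table, the tabulated counts and the
  back-calculation target the same quantity. A mid-year point-prevalence
  alternative is available (`prevalence="mid_year"`) but breaks that
  exactness.
* **Eligibility**: more than one year of registration overlapping the study
  window; censor date not before registration; reaches age 30 during
  observed follow-up; mandatory demographics present (rows failing are
  logged with a reason).
* **Death classification** (per condition): *main* — the condition appears
  as primary or contributing cause and no diagnosis event precedes the
  death; *primary_cause_only* — primary position required;
  *expanded_last_year* — additionally reclassifies deaths whose first
  diagnosis falls within 365 days before death as undiagnosed. A diagnosis
  dated after death is a data error.
* **First-year case fatality**: the risk set is persons with an incident
  diagnosis and complete 365-day follow-up (death observed within the
  window, or censor at or beyond diagnosis + 365 days); events are
  disease-specific deaths within the window; both are attributed to the
  stratum-year of diagnosis. The simulator indexes the first-year fatality
  a person faces to their diagnosis-year stratum, matching that
  attribution.
* A per-condition `min_event_count` (default 1) represents
  concentration-of-diagnoses phenotypes for relapsing conditions: the
  diagnosis date is the date of the k-th recorded event.

## Rate estimation and smoothing

At 450 strata per year undiagnosed deaths are rare events and many strata
record none. Two binomial-logistic models with additive main effects —
age group (categorical), sex, deprivation quintile (categorical) and
calendar year (linear, centred at the fitted years' mean) — are fitted per
condition:

1. **Undiagnosed deaths** against total person-years at risk. Fitted
   probabilities × person-years give Z_U_smoothed, strictly positive for
   every populated stratum including those with zero observed deaths
   (imputation and smoothing in one step). An `observed_where_available`
   switch substitutes observed counts where any were recorded.
2. **First-year case fatality** against the incident risk set (and,
   analogously, overall case fatality against diagnosed prevalence). The
   smoothed first-year surface is the default source for D: raw stratified
   ratios at realistic sample sizes have relative sampling errors far too
   large to divide by.

Region is deliberately excluded from both models: it keeps the degrees of
freedom low enough to fit conditions with few events, and D is assumed not
to vary by region. The per-person-year undiagnosed-death probability is
(X/N)·D, approximately multiplicative in the demographic factors when
event probabilities are small, so the additive-logit specification is close
to well-specified; age, sex and deprivation are saturated (categorical),
leaving the linear year term as the only smoothness assumption.

The denominator of the undiagnosed-death model is total person-years
(not disease deaths): this is what lets the model impute a positive
expected count for strata with no recorded deaths at all.

A plain stratified ratio estimator with hierarchical pooling is also
provided (`cfr_source="pooled"`, and as the automatic fallback when a CFR
model cannot be fitted, e.g. zero events): cells whose denominator is below
a floor (default 10) take the pooled ratio with region collapsed, then
deprivation, then age, then the condition-level ratio (with a warning).

Incident-diagnosis counts are smoothed with the same apparatus to provide
an expectation-level feasibility bound: the default lower bound on X is
smoothed next-year incident diagnoses plus smoothed undiagnosed deaths
(final study year substitutes its own diagnoses; a `same_year` mode and an
`observed` source are switchable). The bound uses expected rather than raw
counts because max(smoothed X, noisy integer count) is an upward-biased
operator wherever events are sparse — with raw counts the bound alone can
inflate national undiagnosed prevalence by several percent.

**Numerical choices.** D is floored at a configurable epsilon
(default 1e-4) to keep X finite; floored strata carry a `d_floored` flag.
X is kept as a real number; rounding happens only in rendered reports.
p = X/(X+Y) with X = Y = 0 is emitted as NaN with a `p_undefined` flag.
Logistic fits use IRLS (statsmodels GLM); non-convergence, all-zero events,
or coefficient magnitudes above 30 on the logit scale (separation) raise a
condition-named error rather than returning a silent model.

## Small-area estimation

Stratum-level probabilities are linked to small-area population tables
(area × year × sex × age group counts, with each area carrying one
deprivation quintile, one region and one parent health area): the area
value is the population-weighted mean over its demographic groups, and
health-area values are population-weighted means over constituent areas —
algebraically identical to a one-step weighted mean over all underlying
groups, so the two-level construction is exact. National and subgroup
summaries weight strata by estimated diseased counts (X+Y), so aggregates
remain probabilities of being undiagnosed given diseased
(Σ X / Σ (X+Y)); at the health-area level a diseased-count weighting is
also available (`weighting="diseased"`), since the appropriate weighting
there is a genuinely open choice. Populated area groups without a usable
stratum estimate raise by default; the pipeline uses an explicit
`on_missing="drop"` policy so empty cohort cells (possible at small
simulated sample sizes) do not abort national-scale runs.

## Validation and sensitivity

There is no gold standard for underdiagnosis, so validation is ecological:
Pearson correlations (two-sided p from the t transform with n−2 df;
pairwise-complete; fewer than three pairs or zero variance → flagged
undefined) between area-level estimates and external comparator series,
consumed as generic id/value tables. A synthetic-comparator generator with
a configurable population correlation supports testing. Sensitivity
scenarios rerun the whole pipeline (`primary_cause_only`,
`expanded_last_year`, `overall_cfr`) and are compared to the main run by
the correlation of the across-area distributions. p-values are reported
without multiple-testing adjustment.

## The synthetic cohort

The generator emulates a linked primary-care/hospital/mortality extract
for a closed cohort aged ≥30 at baseline, observed over calendar years
2008–2018 by default. Per person-year, a single competing-risk multinomial
resolves the year's outcome; with several conditions sharing the cohort,
each condition's fatal hazard (given its current state) enters one
cause-specific death draw alongside shared other-cause mortality, and
non-fatal transitions are drawn per condition among the year's survivors
with conditional probabilities chosen so the marginal one-year incidence
and diagnosis probabilities equal A and B exactly. Cause-specific one-year
death probabilities equal the configured rates exactly, which is what makes
truth-relative parameter recovery unbiased. In the rare person-years where
summed death probabilities would exceed 1 (several simultaneous
high-fatality diseases) they are rescaled proportionally and counted, with
a warning above 0.1% of person-years.

Events are emitted at day resolution, uniform within the year, with one
exception: a first-post-diagnosis-year disease death is placed within 365
days of the diagnosis date, so the extraction's first-year CFR window
measures C1 without bias. Death certificates list only the fatal condition
— as primary cause with probability `p_primary` (default 0.7), otherwise as
a contributing cause under an unspecific primary — so classification from
the logs reproduces the truth table exactly. Initial states come from a
demographic profile: the annual update equations run from an all-healthy
state at age 30 up to each person's baseline age (an `initial_state=
"healthy"` option supports limit experiments); initially diagnosed persons
receive pre-baseline diagnosis events consistent with their state.

**Default study conditions.** Eleven chronic conditions with multiplicative
rate profiles in sex, age and deprivation (reference: female, 30–49,
quintile 1), magnitudes chosen to be epidemiologically plausible (incidence
rising steeply with age for cardiovascular disease, dementia and cancers;
deprivation gradients strongest for COPD and type 2 diabetes; first-year
case fatality from ~0.2% for depression/anxiety to ~32% for lung cancer).
Diagnosis rates improve log-linearly at 3%/year over the window, so true
underdiagnosis declines over time; all other rates are constant in time.
The generator sets D = C1, so the main estimation assumption holds exactly
in the synthetic data. Rates do not vary by region — the estimation method
itself assumes the undiagnosed-death surface and D carry no region signal,
and the synthetic study conditions respect that assumption (all 450 strata
remain populated and region-labelled). Sex-specific cancers are represented
with compressed sex ratios (male breast-cancer factor 0.15, female
prostate-cancer factor 1/20) rather than zeros, so every condition
populates all 450 strata and logistic fits cannot separate — a deliberate
synthetic simplification. A twelfth profile, `synthetic_severe`, is not a
named disease: it is a severely underdiagnosed, high-fatality stress
profile (incidence 5%/yr, diagnosis 2.5%/yr, first-year CFR 9%) used for
parameter-recovery validation, because only in that regime do individual
strata accumulate enough undiagnosed deaths (≥20 expected) for a
stratum-level comparison against realized truth to be informative rather
than noise-dominated.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: no misdiagnosis or imperfect death-certificate
coding (cause lists contain exactly the fatal condition); no comorbidity
correlation beyond competing mortality; no practice-level clustering,
consultation records or code granularity; no migration or late cohort
entry; no region-level variation in any rate; death certificates never list
non-fatal comorbid conditions, so the main-definition classification is
exact by construction. Parameter recovery demonstrates that the estimation
machinery inverts the model it assumes — not that the model is correct for
real records.

## Problem sizes used in the checks

Parameter recovery runs 130,000 persons over 2008–2018 (~10^6 person-years
after mortality) on the stress profile; smoothing recovery uses ~200,000
person-years drawn from a known logistic surface; the analytic fixed point
of the update equations is checked against a 100,000-person constant-rate
simulation run for 60 years; the structural and report checks run all 11
conditions on a 20,000-person cohort. The full test suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

* The estimator is mortality-driven. For conditions with very low case
  fatality the first-year risk sets contain few deaths, D is weakly
  identified, and X = Z_U/D is unstable; at small sample sizes whole
  conditions can degenerate (D floored everywhere → p near 1). The flags
  (`d_floored`, `lower_bound_applied`, `p_undefined`) mark exactly where
  this happened and downstream aggregation should treat flagged strata with
  suspicion.
* Strata with population but no incident-diagnosis flow (e.g. ages at which
  everyone with the disease was diagnosed long ago) leave the corresponding
  CFR coefficient essentially unidentified; the epsilon floor keeps X
  finite there but the flagged values are not estimates in any meaningful
  sense.
* The national ±-few-percent recovery accuracy is condition-dependent: its
  sampling floor is ~1/√(first-year deaths) from D plus ~1/√(total Z_U)
  from the numerator; named-disease profiles at 10^6 person-years sit at
  2–4% national sampling error before any bias.
* Calendar-year discretisation (two strata changes — age group and year —
  happen at fixed dates) is a modelling convention; results at the
  stratum-year level inherit it.
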