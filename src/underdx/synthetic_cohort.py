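"""Synthetic linked-health-record cohort with known six-state dynamics.

Generates individual-level event logs (persons, dated diagnoses, dated
deaths with primary/contributing cause lists) from a discrete annual
six-state model:

    H  healthy                      --A-->  X
    X  diseased, undiagnosed        --B-->  Y,  --D--> Z_U
    Y  diseased, diagnosed          --C--> Z_D
    any living state                --E--> Z_0

A is the disease incidence rate, B the diagnosis rate, C the case fatality
among the diagnosed (split into a first post-diagnosis year probability C1
and a later-years probability), D the case fatality among the undiagnosed,
and E other-cause mortality.  Changes of state are resolved in discrete
one-year steps: each person-year draws a single multinomial outcome from
the one-year probabilities.  Alongside the event logs the generator emits a
TruthTable of exact state occupancies and event counts per stratum-year, so
the whole estimation pipeline can be validated by parameter recovery.

Conventions (documented in docs/methods.md):

* A person's stratum for calendar year t uses their attained age at 1 July
  of t; ageing across group boundaries happens at the simulated birthday.
* Occupancies in the truth table are taken at the start of the year — the
  risk set that generates that year's events.
* The first post-diagnosis year's case-fatality probability is indexed to
  the stratum-year of diagnosis, and the corresponding death date is placed
  within 365 days of the diagnosis date.
* Conditions share one cohort and one death per person: each condition's
  fatal hazard enters a single cause-specific competing-risk draw, while
  incidence and diagnosis are drawn independently per condition among the
  year's survivors.  Cause-specific one-year death probabilities equal the
  configured rates exactly.
* Death records list only the fatal condition (as primary cause with
  probability ``p_primary``, otherwise as a contributing cause under an
  unspecific primary), or a bare other-cause row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .strata import (
    AGE_GROUPS,
    KEY_COLUMNS,
    N_STRATA,
    QIMD_LEVELS,
    REGIONS,
    SEXES,
    full_key_frame,
    stratum_index,
    year_start,
)

RATE_COLUMNS = ["A", "B", "C1", "C_later", "D", "E"]

# Baseline cohort composition: English adult population, roughly.
DEFAULT_AGE_GROUP_WEIGHTS = (0.45, 0.20, 0.16, 0.12, 0.07)
DEFAULT_REGION_WEIGHTS = (0.05, 0.13, 0.10, 0.09, 0.10, 0.11, 0.16, 0.16, 0.10)
DEFAULT_P_MALE = 0.49

# Other-cause annual mortality by age group (female, least deprived base).
_E_AGE = np.array([0.002, 0.005, 0.012, 0.035, 0.11])
_E_SEX_MALE = 1.3
_E_QIMD_TOP = 1.4  # geometric gradient from quintile 1 to 5


class ParameterError(ValueError):
    """Raised when rates are invalid after one-year discretisation."""


@dataclass
class SimulationParams:
    """Inputs to :func:`generate_cohort`.

    strata_rates maps condition label -> DataFrame with the five key
    columns (sex, age_group, qimd, region, year) and one-year transition
    probabilities A, B, C1, C_later, D, E.  Every condition table must
    cover exactly 450 strata for every year in ``years`` (inclusive range).
    """

    conditions: Sequence[str]
    years: tuple[int, int]
    strata_rates: dict[str, pd.DataFrame]
    cohort_size: int = 50_000
    seed: int = 0
    p_primary: float = 0.7
    initial_state: str = "demographic"  # or "healthy"
    age_group_weights: Sequence[float] = DEFAULT_AGE_GROUP_WEIGHTS
    region_weights: Sequence[float] = DEFAULT_REGION_WEIGHTS
    p_male: float = DEFAULT_P_MALE

    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


class EquilibriumResult(NamedTuple):
    h: float
    x: float
    y: float
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

# Per-condition multiplicative rate profiles.  Reference cell is
# (female, 30-49, quintile 1).  age entries multiply across the five age
# groups; sex is the male rate ratio; qimd_top the quintile-5/quintile-1
# ratio applied geometrically across quintiles.  b_trend is a log-linear
# annual improvement in the diagnosis rate.  D defaults to C1 (the
# first-year assumption holds exactly in the generated data).
_PROFILES: dict[str, dict] = {
    "hypertension": dict(a0=0.020, a_age=(1, 2, 3, 4, 4.5), a_sex=1.1, a_qimd=1.3,
                         b0=0.12, c1=0.010, c1_age=(1, 1, 1.2, 1.5, 2.0), cl_ratio=1.0),
    "t2dm": dict(a0=0.006, a_age=(1, 2, 3, 3.5, 3.5), a_sex=1.3, a_qimd=1.7,
                 b0=0.18, c1=0.015, c1_age=(1, 1, 1.2, 1.5, 2.0), cl_ratio=0.9),
    "chd": dict(a0=0.004, a_age=(1, 2.5, 5, 8, 12), a_sex=1.8, a_qimd=1.5,
                b0=0.25, c1=0.080, c1_age=(1, 1, 1.1, 1.3, 1.6), cl_ratio=0.5),
    "stroke": dict(a0=0.0015, a_age=(1, 2.5, 6, 12, 20), a_sex=1.3, a_qimd=1.4,
                   b0=0.38, c1=0.15, c1_age=(1, 1, 1.1, 1.3, 1.6), cl_ratio=0.5),
    "copd": dict(a0=0.003, a_age=(1, 2.5, 5, 7, 8), a_sex=1.2, a_qimd=2.0,
                 b0=0.15, c1=0.060, c1_age=(1, 1, 1.1, 1.3, 1.6), cl_ratio=0.8),
    "dementia": dict(a0=0.0004, a_age=(1, 4, 12, 40, 110), a_sex=0.9, a_qimd=1.3,
                     b0=0.22, c1=0.15, c1_age=(1, 1, 1, 1.1, 1.2), cl_ratio=0.8),
    "depression_anxiety": dict(a0=0.020, a_age=(1, 0.8, 0.6, 0.5, 0.5), a_sex=0.7,
                               a_qimd=1.5, b0=0.20, c1=0.002,
                               c1_age=(1, 1, 1.2, 1.5, 2.0), cl_ratio=1.0),
    "breast_cancer": dict(a0=0.0015, a_age=(1, 1.5, 2.0, 2.5, 3.0), a_sex=0.15,
                          a_qimd=0.9, b0=0.45, c1=0.12, c1_age=(1, 1, 1, 1.1, 1.2),
                          cl_ratio=0.4),
    "prostate_cancer": dict(a0=0.0002, a_age=(1, 4, 10, 16, 18), a_sex=20.0,
                            a_qimd=0.9, b0=0.30, c1=0.10, c1_age=(1, 1, 1, 1.1, 1.2),
                            cl_ratio=0.35),
    "lung_cancer": dict(a0=0.0004, a_age=(1, 3, 7, 10, 10), a_sex=1.6, a_qimd=2.0,
                        b0=0.32, c1=0.32, c1_age=(1, 1, 1, 1, 1), cl_ratio=0.55),
    "colorectal_cancer": dict(a0=0.0004, a_age=(1, 2.5, 6, 10, 12), a_sex=1.3,
                              a_qimd=1.1, b0=0.35, c1=0.20, c1_age=(1, 1, 1, 1.1, 1.2),
                              cl_ratio=0.45),
    # Not a named disease: a severely underdiagnosed, high-fatality stress
    # profile (high incidence, low diagnosis rate) used for parameter-recovery
    # validation, where strata accumulate enough undiagnosed deaths for the
    # recovered prevalence to be compared against truth with low noise.
    "synthetic_severe": dict(a0=0.05, a_age=(1, 1.3, 1.6, 1.9, 2.1), a_sex=1.2,
                             a_qimd=1.4, b0=0.025, c1=0.09,
                             c1_age=(1, 1, 1.2, 1.4, 1.6), cl_ratio=0.6),
}

DEFAULT_CONDITIONS = tuple(c for c in _PROFILES if c != "synthetic_severe")
DEFAULT_B_TREND = 0.03  # diagnosis rates improve ~3%/year over the window
DEFAULT_YEARS = (2008, 2018)


def other_mortality_table(years: Sequence[int]) -> pd.DataFrame:
    """Shared other-cause one-year mortality probabilities per stratum-year."""
    keys = full_key_frame(years)
    age_idx = keys["age_group"].map({g: i for i, g in enumerate(AGE_GROUPS)})
    e = _E_AGE[age_idx.to_numpy()]
    e = e * np.where(keys["sex"].to_numpy() == "male", _E_SEX_MALE, 1.0)
    e = e * _E_QIMD_TOP ** ((keys["qimd"].to_numpy() - 1) / 4.0)
    keys = keys.copy()
    keys["E"] = e
    return keys


def default_rate_table(condition: str, years: Sequence[int],
                       b_trend: float = DEFAULT_B_TREND) -> pd.DataFrame:
    """Build the default per-stratum rate table for one condition."""
    if condition not in _PROFILES:
        raise KeyError(f"no default profile for condition {condition!r}")
    p = _PROFILES[condition]
    tab = other_mortality_table(years)
    age_idx = tab["age_group"].map({g: i for i, g in enumerate(AGE_GROUPS)}).to_numpy()
    male = (tab["sex"].to_numpy() == "male").astype(float)
    qfrac = (tab["qimd"].to_numpy() - 1) / 4.0
    yr = tab["year"].to_numpy()

    a = p["a0"] * np.asarray(p["a_age"])[age_idx]
    a *= np.where(male == 1, p["a_sex"], 1.0)
    a *= p["a_qimd"] ** qfrac
    b = p["b0"] * np.exp(b_trend * (yr - yr.min()))
    c1 = p["c1"] * np.asarray(p["c1_age"])[age_idx]
    tab["A"] = np.clip(a, 0.0, 1.0)
    tab["B"] = np.clip(b, 0.0, 1.0)
    tab["C1"] = np.clip(c1, 0.0, 1.0)
    tab["C_later"] = np.clip(c1 * p["cl_ratio"], 0.0, 1.0)
    tab["D"] = tab["C1"]  # main assumption holds exactly in the generator
    return tab[KEY_COLUMNS + RATE_COLUMNS]


def uniform_rate_table(years: Sequence[int], A: float, B: float, C1: float,
                       C_later: float, D: float, E: float) -> pd.DataFrame:
    """Rate table with the same one-year probabilities in every stratum.

    Useful for limit cases and for comparing the simulator against the
    constant-rate fixed point, where stratum structure is irrelevant.
    """
    tab = full_key_frame(years)
    for k, v in zip(RATE_COLUMNS, (A, B, C1, C_later, D, E)):
        tab[k] = float(v)
    return tab[KEY_COLUMNS + RATE_COLUMNS]


def default_params(conditions: Sequence[str] | None = None,
                   years: tuple[int, int] = DEFAULT_YEARS,
                   cohort_size: int = 50_000, seed: int = 0,
                   **overrides) -> SimulationParams:
    """Default study conditions: 11 chronic diseases, 2008-2018 cohort."""
    conditions = list(conditions if conditions is not None else DEFAULT_CONDITIONS)
    yr = list(range(years[0], years[1] + 1))
    rates = {c: default_rate_table(c, yr) for c in conditions}
    return SimulationParams(conditions=conditions, years=years,
                            strata_rates=rates, cohort_size=cohort_size,
                            seed=seed, **overrides)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_params(params: SimulationParams) -> None:
    """Check rate tables: coverage, [0,1] ranges, one-year outcome sums."""
    years = params.year_list()
    expected = full_key_frame(years)
    n_expected = len(expected)
    ref_e = None
    for cond in params.conditions:
        if cond not in params.strata_rates:
            raise ParameterError(f"no rate table for condition {cond!r}")
        tab = params.strata_rates[cond]
        missing = [c for c in KEY_COLUMNS + RATE_COLUMNS if c not in tab.columns]
        if missing:
            raise ParameterError(f"{cond}: rate table missing columns {missing}")
        if len(tab) != n_expected or tab.duplicated(KEY_COLUMNS).any():
            raise ParameterError(
                f"{cond}: rate table must cover exactly {N_STRATA} strata "
                f"per year for years {years[0]}-{years[-1]}")
        vals = tab[RATE_COLUMNS].to_numpy(float)
        if not np.isfinite(vals).all() or (vals < 0).any() or (vals > 1).any():
            raise ParameterError(f"{cond}: rates outside [0,1] after discretisation")
        srt = tab.sort_values(KEY_COLUMNS)
        if (srt["A"] + srt["E"] > 1 + 1e-12).any():
            raise ParameterError(f"{cond}: A + E exceeds 1 in some stratum")
        if (srt["B"] + srt["D"] + srt["E"] > 1 + 1e-12).any():
            raise ParameterError(f"{cond}: B + D + E exceeds 1 in some stratum")
        if (srt[["C1", "C_later"]].max(axis=1) + srt["E"] > 1 + 1e-12).any():
            raise ParameterError(f"{cond}: C + E exceeds 1 in some stratum")
        e_sorted = srt["E"].to_numpy(float)
        if ref_e is None:
            ref_e = e_sorted
        elif not np.allclose(e_sorted, ref_e, atol=1e-12):
            raise ParameterError(
                "other-cause mortality E must be identical across condition "
                "tables: the cohort has a single other-cause process")
    if params.cohort_size <= 0:
        raise ParameterError("cohort_size must be positive")


# ---------------------------------------------------------------------------
# equilibrium of the annual update
# ---------------------------------------------------------------------------

def _iterate_equilibrium(a, b, c1, cl, d, e, n_iter=500, tol=1e-13):
    """Fixed point of the annual update on living-state proportions.

    Works on arrays (vectorised across strata).  The diagnosed state is
    split into first post-diagnosis year and later years so that the two
    case-fatality levels are handled exactly.
    """
    a, b, c1, cl, d, e = np.broadcast_arrays(
        *(np.asarray(v, float) for v in (a, b, c1, cl, d, e)))
    h = np.ones_like(a)
    x = np.zeros_like(a)
    y1 = np.zeros_like(a)
    y2 = np.zeros_like(a)
    converged = np.zeros(a.shape, bool)
    it = 0
    for it in range(1, n_iter + 1):
        hn = h * (1 - a - e)
        xn = x * (1 - b - d - e) + h * a
        y1n = x * b
        y2n = y1 * (1 - c1 - e) + y2 * (1 - cl - e)
        live = hn + xn + y1n + y2n
        live = np.where(live <= 0, np.nan, live)
        hn, xn, y1n, y2n = hn / live, xn / live, y1n / live, y2n / live
        delta = np.max(np.stack([np.abs(hn - h), np.abs(xn - x),
                                 np.abs(y1n - y1), np.abs(y2n - y2)]), axis=0)
        h, x, y1, y2 = hn, xn, y1n, y2n
        converged = delta < tol
        if converged.all():
            break
    return h, x, y1, y2, converged, it


def equilibrium_occupancy(rates, n_iter: int = 2000, tol: float = 1e-13) -> EquilibriumResult:
    """Long-run (H*, X*, Y*) proportions for one stratum under constant rates.

    ``rates`` is any mapping with keys A, B, C1, C_later, D, E (a dict, a
    pandas Series, or a rate-table row).  Non-convergence within ``n_iter``
    steps, or a parameterisation with no surviving population, is flagged
    on the returned result rather than raised.
    """
    vals = {k: float(rates[k]) for k in RATE_COLUMNS}
    h, x, y1, y2, conv, it = _iterate_equilibrium(
        vals["A"], vals["B"], vals["C1"], vals["C_later"], vals["D"], vals["E"],
        n_iter=n_iter, tol=tol)
    ok = bool(conv) and np.isfinite(h)
    return EquilibriumResult(float(h), float(x), float(y1 + y2),
                             ok, it)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _demographic_profile(r: dict[str, np.ndarray], max_age: int = 96) -> np.ndarray:
    """Baseline state distribution by attained age, conditional on alive.

    For every sex x deprivation x region combination, runs the annual update
    from an all-healthy state at age 30 up to ``max_age`` using the
    baseline-year rates of the age group attained at each step.  Returns an
    array of shape (2, 5_quintiles... flattened as (2*5*9, n_ages, 4)) —
    indexed by combo = (sex*5 + qimd)*9 + region and age-30 — giving the
    (H, X, Y1, Y2) proportions among the living.
    """
    combos = [(s, q, rg) for s in range(2) for q in range(5) for rg in range(9)]
    n_ages = max_age - 30 + 1
    prof = np.zeros((len(combos), n_ages, 4))
    state = np.zeros((len(combos), 4))
    state[:, 0] = 1.0
    ages = np.arange(30, max_age + 1)
    age_idx = np.searchsorted(np.array([30, 50, 60, 70, 80]), ages, side="right") - 1
    combo_arr = np.array(combos)
    for i, a in enumerate(ages):
        prof[:, i, :] = state
        flat = ((combo_arr[:, 0] * 5 + age_idx[i]) * 5
                + combo_arr[:, 1]) * 9 + combo_arr[:, 2]
        a_, b_, c1_, cl_, d_, e_ = (r[k][0][flat] for k in
                                    ("A", "B", "C1", "C_later", "D", "E"))
        h, x, y1, y2 = state.T
        hn = h * (1 - a_ - e_)
        xn = x * (1 - b_ - d_ - e_) + h * a_
        y1n = x * b_
        y2n = y1 * (1 - c1_ - e_) + y2 * (1 - cl_ - e_)
        live = hn + xn + y1n + y2n
        live = np.where(live <= 0, 1.0, live)
        state = np.column_stack([hn, xn, y1n, y2n]) / live[:, None]
    return prof


def _rate_arrays(tab: pd.DataFrame, years: list[int]) -> dict[str, np.ndarray]:
    """Rate table -> arrays of shape (n_years, 450) in flat stratum order."""
    tab = tab.copy()
    tab["_idx"] = stratum_index(tab["sex"], tab["age_group"], tab["qimd"], tab["region"])
    out = {k: np.zeros((len(years), N_STRATA)) for k in RATE_COLUMNS}
    ymap = {y: i for i, y in enumerate(years)}
    yi = tab["year"].map(ymap).to_numpy()
    si = tab["_idx"].to_numpy()
    for k in RATE_COLUMNS:
        out[k][yi, si] = tab[k].to_numpy(float)
    return out


def _uniform_dates(rng, starts: np.ndarray, n_days: np.ndarray) -> np.ndarray:
    """Uniform datetime64[D] dates in [start, start + n_days)."""
    offs = (rng.random(len(starts)) * n_days).astype(np.int64)
    return starts.astype("datetime64[D]") + offs


def generate_cohort(params: SimulationParams):
    """Simulate the cohort; returns (persons, diagnoses, deaths, truth).

    persons:   person_id, sex, birth_date, qimd, region,
               registration_start, registration_end
    diagnoses: person_id, condition, diagnosis_date
    deaths:    person_id, death_date, cause, position  (one primary row per
               death, plus a contributing row when the fatal condition is
               certified as contributing)
    truth:     condition x stratum-year table of H, X, Y occupancies (start
               of year), Z_U, Z_D, Z_0 event counts, person_years and the
               true underdiagnosis probability X/(X+Y).
    """
    validate_params(params)
    rng = np.random.default_rng(params.seed)
    years = params.year_list()
    n_years = len(years)
    n = params.cohort_size
    conds = list(params.conditions)
    y0 = years[0]

    # --- demographics -----------------------------------------------------
    sex_i = (rng.random(n) < params.p_male).astype(np.int8)  # 0 female 1 male
    qimd_i = rng.integers(0, 5, n).astype(np.int8)
    region_i = rng.choice(len(REGIONS), size=n,
                          p=np.asarray(params.region_weights, float)
                          / np.sum(params.region_weights)).astype(np.int8)
    ag = rng.choice(5, size=n, p=np.asarray(params.age_group_weights, float)
                    / np.sum(params.age_group_weights))
    lo = np.array([30, 50, 60, 70, 80])[ag]
    hi = np.array([50, 60, 70, 80, 96])[ag]
    base_age = (lo + rng.random(n) * (hi - lo)).astype(np.int64)
    # birth date such that attained age at 1 July y0 equals base_age exactly
    birth = (np.array([np.datetime64(f"{y0 - a}-07-01") for a in range(30, 97)]
                      )[base_age - 30]
             - (rng.random(n) * 365).astype(np.int64))
    reg_start = (np.datetime64(f"{y0}-01-01")
                 - (9 * 365 + (rng.random(n) * 3 * 365).astype(np.int64)))

    rates = {c: _rate_arrays(params.strata_rates[c], years) for c in conds}

    # --- initial states from per-stratum equilibrium ----------------------
    age_idx0 = np.searchsorted(np.array([30, 50, 60, 70, 80]), base_age, side="right") - 1
    strat0 = ((sex_i.astype(np.int64) * 5 + age_idx0) * 5 + qimd_i) * 9 + region_i

    state = {}
    diag_year = {}
    diag_date = {}
    c1_first = {}
    pre_diag = {c: [] for c in conds}  # (person ids, dates) before baseline
    if params.initial_state not in ("demographic", "healthy"):
        raise ParameterError(f"unknown initial_state {params.initial_state!r}")
    combo0 = (sex_i.astype(np.int64) * 5 + qimd_i) * 9 + region_i
    for c in conds:
        r = rates[c]
        if params.initial_state == "healthy":
            probs = np.zeros((n, 4))
            probs[:, 0] = 1.0
        else:
            prof = _demographic_profile(r)
            probs = prof[combo0, np.minimum(base_age, 96) - 30]  # (n, 4)
        u = rng.random(n)
        cum = np.cumsum(probs, axis=1)
        st4 = np.minimum((u[:, None] >= cum).sum(axis=1), 3)  # 0 H, 1 X, 2 Y1, 3 Y2
        state[c] = np.where(st4 >= 2, 2, st4).astype(np.int8)
        diag_year[c] = np.full(n, -(10 ** 6), np.int64)
        diag_date[c] = np.full(n, np.datetime64("NaT"), "datetime64[D]")
        c1_first[c] = np.zeros(n)
        # initial diagnosed need a pre-baseline diagnosis event
        is_y1 = st4 == 2  # diagnosed in y0-1: first post-diagnosis year is y0
        is_y2 = st4 == 3
        if is_y1.any():
            ids = np.nonzero(is_y1)[0]
            d = _uniform_dates(rng, np.full(len(ids), np.datetime64(f"{y0 - 1}-01-01")),
                               np.full(len(ids), 365))
            diag_year[c][ids] = y0 - 1
            diag_date[c][ids] = d
            c1_first[c][ids] = r["C1"][0][strat0[ids]]
            pre_diag[c].append((ids, d))
        if is_y2.any():
            ids = np.nonzero(is_y2)[0]
            start = np.datetime64(f"{y0 - 8}-01-01")
            d = _uniform_dates(rng, np.full(len(ids), start), np.full(len(ids), 7 * 365))
            diag_year[c][ids] = y0 - 9  # well before baseline
            diag_date[c][ids] = d
            pre_diag[c].append((ids, d))

    alive = np.ones(n, bool)
    death_date = np.full(n, np.datetime64("NaT"), "datetime64[D]")
    death_cause = np.full(n, -1, np.int64)  # 0 other, 1.. condition index+1
    death_primary = np.zeros(n, bool)

    shape = (n_years, N_STRATA)
    truth = {c: {k: np.zeros(shape, np.int64)
                 for k in ("H", "X", "Y", "Z_U", "Z_D", "Z_0")} for c in conds}

    diag_pid = {c: [] for c in conds}
    diag_dates_out = {c: [] for c in conds}
    n_rescaled = 0
    n_person_years = 0

    # --- annual loop -------------------------------------------------------
    for j, year in enumerate(years):
        ids = np.nonzero(alive)[0]
        if len(ids) == 0:
            break
        n_person_years += len(ids)
        age = base_age[ids] + j
        age_idx = np.searchsorted(np.array([30, 50, 60, 70, 80]), age, side="right") - 1
        strat = ((sex_i[ids].astype(np.int64) * 5 + age_idx) * 5
                 + qimd_i[ids]) * 9 + region_i[ids]

        # occupancy at start of year
        for c in conds:
            st = state[c][ids]
            t = truth[c]
            t["H"][j] += np.bincount(strat[st == 0], minlength=N_STRATA)
            t["X"][j] += np.bincount(strat[st == 1], minlength=N_STRATA)
            t["Y"][j] += np.bincount(strat[st == 2], minlength=N_STRATA)

        # cause-specific death probabilities
        e = rates[conds[0]]["E"][j][strat]
        p_fatal = np.empty((len(ids), len(conds)))
        for k, c in enumerate(conds):
            r = rates[c]
            st = state[c][ids]
            first = diag_year[c][ids] == year - 1
            p_y = np.where(first, c1_first[c][ids], r["C_later"][j][strat])
            p_fatal[:, k] = np.where(st == 1, r["D"][j][strat],
                                     np.where(st == 2, p_y, 0.0))
        total = e + p_fatal.sum(axis=1)
        over = total > 1.0
        if over.any():
            n_rescaled += int(over.sum())
            scl = np.where(over, 1.0 / total, 1.0)
            e = e * scl
            p_fatal = p_fatal * scl[:, None]

        u = rng.random(len(ids))
        cum = np.cumsum(np.column_stack([e, p_fatal]), axis=1)
        cause = (u[:, None] >= cum).sum(axis=1)  # 0 other, 1..K cond, K+1 survive
        died = cause <= len(conds)

        # death dates and certificates
        if died.any():
            didx = np.nonzero(died)[0]
            dcause = cause[didx]
            dstart = np.full(len(didx), year_start(year), "datetime64[D]")
            ndays = np.full(len(didx), 365, np.int64)
            # first-year diagnosed disease deaths fall within 365 days of dx
            for k, c in enumerate(conds):
                m = (dcause == k + 1) & (state[c][ids[didx]] == 2) \
                    & (diag_year[c][ids[didx]] == year - 1)
                if m.any():
                    lim = (diag_date[c][ids[didx[m]]] + 365
                           - dstart[m].astype("datetime64[D]")).astype(np.int64)
                    ndays[m] = np.maximum(np.minimum(lim, 365), 1)
            ddate = _uniform_dates(rng, dstart, ndays)
            gids = ids[didx]
            death_date[gids] = ddate
            death_cause[gids] = dcause  # 0 = other cause, k = conds[k-1]
            death_primary[gids] = rng.random(len(gids)) < params.p_primary
            alive[gids] = False

            # truth event counts
            for k, c in enumerate(conds):
                t = truth[c]
                st = state[c][ids[didx]]
                is_c = dcause == k + 1
                t["Z_U"][j] += np.bincount(strat[didx[is_c & (st == 1)]],
                                           minlength=N_STRATA)
                t["Z_D"][j] += np.bincount(strat[didx[is_c & (st == 2)]],
                                           minlength=N_STRATA)
                t["Z_0"][j] += np.bincount(strat[didx[~is_c]], minlength=N_STRATA)

        # non-fatal transitions among survivors.  The one-year incidence and
        # diagnosis probabilities are competing outcomes of the same annual
        # multinomial, so conditional on surviving the year they are divided
        # by the survival probability — the marginal rates then equal A and
        # B exactly, as in the update equations.
        surv = ~died
        sidx = np.nonzero(surv)[0]
        p_surv = 1.0 - np.minimum(total[sidx], 1.0)
        denom = np.where(p_surv > 0, p_surv, 1.0)
        for k, c in enumerate(conds):
            r = rates[c]
            st = state[c][ids[sidx]]
            u2 = rng.random(len(sidx))
            inc = (st == 0) & (u2 < np.minimum(r["A"][j][strat[sidx]] / denom, 1.0))
            dxm = (st == 1) & (u2 < np.minimum(r["B"][j][strat[sidx]] / denom, 1.0))
            if inc.any():
                state[c][ids[sidx[inc]]] = 1
            if dxm.any():
                gids = ids[sidx[dxm]]
                d = _uniform_dates(rng, np.full(len(gids), year_start(year)),
                                   np.full(len(gids), 365))
                state[c][gids] = 2
                diag_year[c][gids] = year
                diag_date[c][gids] = d
                c1_first[c][gids] = r["C1"][j][strat[sidx[dxm]]]
                diag_pid[c].append(gids)
                diag_dates_out[c].append(d)

    if n_rescaled > 0.001 * max(n_person_years, 1):
        warnings.warn(f"competing death probabilities rescaled for "
                      f"{n_rescaled} person-years (> 0.1% of cohort)")

    # --- assemble outputs ---------------------------------------------------
    study_end = np.datetime64(f"{years[-1]}-12-31")
    persons = pd.DataFrame({
        "person_id": np.arange(n),
        "sex": np.asarray(SEXES, object)[sex_i],
        "birth_date": birth.astype("datetime64[ns]"),
        "qimd": qimd_i.astype(int) + 1,
        "region": np.asarray(REGIONS, object)[region_i],
        "registration_start": reg_start.astype("datetime64[ns]"),
        "registration_end": np.where(np.isnat(death_date), study_end,
                                     death_date).astype("datetime64[ns]"),
    })

    diag_rows = []
    for c in conds:
        pids, dts = [], []
        for arr_ids, arr_d in pre_diag[c]:
            pids.append(arr_ids)
            dts.append(arr_d)
        pids.extend(diag_pid[c])
        dts.extend(diag_dates_out[c])
        if pids:
            pid = np.concatenate(pids)
            dat = np.concatenate(dts)
            diag_rows.append(pd.DataFrame({"person_id": pid, "condition": c,
                                           "diagnosis_date": dat.astype("datetime64[ns]")}))
    if diag_rows:
        diagnoses = pd.concat(diag_rows, ignore_index=True)
        diagnoses = diagnoses.sort_values(["person_id", "condition", "diagnosis_date"],
                                          kind="mergesort").reset_index(drop=True)
    else:
        diagnoses = pd.DataFrame({"person_id": pd.Series(dtype=np.int64),
                                  "condition": pd.Series(dtype=object),
                                  "diagnosis_date": pd.Series(dtype="datetime64[ns]")})

    dead_ids = np.nonzero(~np.isnat(death_date))[0]
    rows = []
    for pid in dead_ids:
        cz = death_cause[pid]
        dd = death_date[pid]
        if cz == 0:
            rows.append((pid, dd, "other", "primary"))
        else:
            cond = conds[cz - 1]
            if death_primary[pid]:
                rows.append((pid, dd, cond, "primary"))
            else:
                rows.append((pid, dd, "other", "primary"))
                rows.append((pid, dd, cond, "contributing"))
    deaths = pd.DataFrame(rows, columns=["person_id", "death_date", "cause", "position"])
    if len(deaths):
        deaths["death_date"] = deaths["death_date"].astype("datetime64[ns]")
    else:
        deaths = pd.DataFrame({"person_id": pd.Series(dtype=np.int64),
                               "death_date": pd.Series(dtype="datetime64[ns]"),
                               "cause": pd.Series(dtype=object),
                               "position": pd.Series(dtype=object)})

    key = full_key_frame(years)
    key["_idx"] = stratum_index(key["sex"], key["age_group"], key["qimd"], key["region"])
    ymap = {y: i for i, y in enumerate(years)}
    yi = key["year"].map(ymap).to_numpy()
    si = key["_idx"].to_numpy()
    truth_frames = []
    for c in conds:
        f = key.drop(columns="_idx").copy()
        f.insert(0, "condition", c)
        for k in ("H", "X", "Y", "Z_U", "Z_D", "Z_0"):
            f[k] = truth[c][k][yi, si]
        f["person_years"] = f["H"] + f["X"] + f["Y"]
        denom = (f["X"] + f["Y"]).to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f["p_undx_true"] = np.where(denom > 0, f["X"] / denom, np.nan)
        truth_frames.append(f)
    truth_df = pd.concat(truth_frames, ignore_index=True)

    return persons, diagnoses, deaths, truth_df


# ---------------------------------------------------------------------------
# synthetic geography
# ---------------------------------------------------------------------------

def generate_area_tables(params: SimulationParams, n_areas_per_region: int,
                         seed: int, areas_per_health_area: int = 4,
                         national_population: int = 1_000_000) -> pd.DataFrame:
    """Synthetic small-area population table with an area->health-area nesting.

    Each small area sits in one region, carries one deprivation quintile,
    and maps to exactly one health area; health areas never span regions.
    Populations by area x year x sex x age group are positive integers that
    sum to ``national_population`` in every year exactly.
    """
    if n_areas_per_region < 1:
        raise ValueError("n_areas_per_region must be >= 1")
    if national_population <= 0:
        raise ValueError("zero or negative total population")
    rng = np.random.default_rng(seed)
    years = params.year_list()

    areas = []
    for ri, region in enumerate(REGIONS):
        for a in range(n_areas_per_region):
            area_id = f"A{ri:02d}{a:04d}"
            health_area = f"HA{ri:02d}{a // areas_per_health_area:03d}"
            qimd = int(rng.integers(1, 6))
            areas.append((area_id, region, qimd, health_area))
    area_df = pd.DataFrame(areas, columns=["area_id", "region", "qimd",
                                           "health_area_id"])

    n_areas = len(area_df)
    cells = n_areas * len(SEXES) * len(AGE_GROUPS)
    if national_population < cells:
        raise ValueError("national_population too small to give every "
                         "area/sex/age cell a positive count")
    agw = np.asarray(DEFAULT_AGE_GROUP_WEIGHTS, float)
    # relative size weights per cell: area size x sex split x age profile
    area_w = rng.lognormal(0.0, 0.35, n_areas)
    w = (area_w[:, None, None]
         * np.array([1 - DEFAULT_P_MALE, DEFAULT_P_MALE])[None, :, None]
         * agw[None, None, :]).ravel()
    w /= w.sum()

    frames = []
    base = pd.MultiIndex.from_product(
        [area_df["area_id"], SEXES, AGE_GROUPS],
        names=["area_id", "sex", "age_group"]).to_frame(index=False)
    for y in years:
        counts = 1 + rng.multinomial(national_population - cells, w)
        f = base.copy()
        f["year"] = y
        f["population"] = counts
        frames.append(f)
    pop = pd.concat(frames, ignore_index=True)
    out = pop.merge(area_df, on="area_id", how="left")
    return out[["area_id", "year", "sex", "age_group", "population",
                "qimd", "region", "health_area_id"]]


# ---------------------------------------------------------------------------
# known logistic surface (for validating the smoothing stage)
# ---------------------------------------------------------------------------

def logistic_surface_events(coefficients: dict[str, float], years: Sequence[int],
                            person_years_per_stratum: float, seed: int) -> pd.DataFrame:
    """Stratum-year table of binomial event counts from a known logistic surface.

    ``coefficients`` uses the smoothing model's own parameter names
    (Intercept, age_group[50-59].., sex[male], qimd[2].., year_c); missing
    names default to zero.  Exposures are Poisson around the requested mean
    so strata differ realistically in size.
    """
    from .strata_rates import design_matrix  # local import: avoids a cycle

    rng = np.random.default_rng(seed)
    tab = full_key_frame(years)
    X, names, _ = design_matrix(tab)
    beta = np.array([coefficients.get(nm, 0.0) for nm in names])
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    py = rng.poisson(person_years_per_stratum, len(tab)).astype(np.int64)
    py = np.maximum(py, 1)
    tab["person_years"] = py
    tab["Z_U"] = rng.binomial(py, p)
    tab["p_true"] = p
    return tab
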