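"""Eligibility filtering, death classification, and stratified tabulation.

Takes the three individual-level event tables (persons, dated condition
diagnoses, dated deaths with primary/contributing cause lists) and produces
per-stratum counts for one condition: person-years, incident diagnoses,
diagnosed prevalence Y, undiagnosed and diagnosed disease-specific deaths
Z_U and Z_D, other-cause deaths Z_0, and the first-year case-fatality risk
set.

Death-classification definitions:

``main``
    a disease-specific death (condition listed as primary OR contributing
    cause) with no diagnosis event on or before the death date counts as an
    undiagnosed death.
``primary_cause_only``
    as ``main`` but the condition must be the primary cause.
``expanded_last_year``
    as ``main``, and deaths whose first diagnosis falls within 365 days
    before death are additionally reclassified as undiagnosed.

Person-year and prevalence conventions: a person contributes year t when
they are registered before the year starts, still registered and alive
entering the year, and aged >=30 at mid-year; their stratum uses attained
age on 1 July.  Diagnosed prevalence Y is point prevalence at the start of
the year (diagnosed strictly before 1 January); a mid-year alternative is
available via ``prevalence="mid_year"``.
"""

from __future__ import annotations

import logging
from enum import Enum

import numpy as np
import pandas as pd

from .strata import (
    KEY_COLUMNS,
    age_group_index,
    age_on,
    full_key_frame,
    mid_year,
    stratum_index,
    year_start,
    N_STRATA,
    AGE_GROUPS,
    SEXES,
    REGIONS,
)

logger = logging.getLogger(__name__)

ONE_YEAR_DAYS = 365

COUNT_COLUMNS = ["person_years", "incident_diagnoses", "Y", "Z_U", "Z_D", "Z_0",
                 "first_year_at_risk", "first_year_deaths"]

MANDATORY_PERSON_FIELDS = ["person_id", "sex", "birth_date", "qimd", "region",
                           "registration_start", "registration_end"]


class DeathDefinition(str, Enum):
    MAIN = "main"
    PRIMARY_CAUSE_ONLY = "primary_cause_only"
    EXPANDED_LAST_YEAR = "expanded_last_year"


class DataError(ValueError):
    """Inconsistent event dates (e.g. diagnosis after death)."""


def filter_eligible(persons: pd.DataFrame, study_start, study_end,
                    return_log: bool = False):
    """Apply the study eligibility filters to the person table.

    Keeps persons with more than one year of registration that overlaps the
    study window, who reach age 30 during their observed follow-up, and
    whose censor date is not before their registration date.  Rows with a
    missing mandatory demographic field are rejected with a logged reason.
    """
    study_start = np.datetime64(study_start)
    study_end = np.datetime64(study_end)
    p = persons.copy()
    reasons = pd.Series("", index=p.index, dtype=object)

    missing = p[MANDATORY_PERSON_FIELDS].isna().any(axis=1)
    reasons[missing] = "missing mandatory demographic field"

    start = pd.to_datetime(p["registration_start"])
    end = pd.to_datetime(p["registration_end"])
    ok = ~missing

    censor_before_reg = ok & (end < start)
    reasons[censor_before_reg] = "censor date before registration date"
    ok &= ~censor_before_reg

    short = ok & ((end - start) <= pd.Timedelta(days=ONE_YEAR_DAYS))
    reasons[short] = "one year or less of registration"
    ok &= ~short

    no_overlap = ok & ((end < study_start) | (start > study_end))
    reasons[no_overlap] = "registration does not overlap the study window"
    ok &= ~no_overlap

    # aged >=30 at some point during observed follow-up within the window
    follow_end = np.minimum(end.to_numpy(), study_end)
    age_at_end = age_on(follow_end, p["birth_date"].to_numpy())
    too_young = ok & (age_at_end < 30)
    reasons[too_young] = "aged under 30 throughout follow-up"
    ok &= ~too_young

    n_dropped = int((~ok).sum())
    if n_dropped:
        for reason, cnt in reasons[~ok].value_counts().items():
            logger.info("filter_eligible: dropped %d persons (%s)", cnt, reason)
    kept = p.loc[ok].reset_index(drop=True)
    if return_log:
        log = p.loc[~ok, ["person_id"]].assign(reason=reasons[~ok].to_numpy())
        return kept, log.reset_index(drop=True)
    return kept


def classify_death(death_date, causes, diagnosis_dates, condition,
                   definition=DeathDefinition.MAIN) -> str:
    """Classify one death for one condition.

    ``causes`` is an iterable of (cause_label, position) pairs with position
    in {"primary", "contributing"}; ``diagnosis_dates`` are the person's
    dated diagnosis events for the condition (possibly empty).

    Returns "undiagnosed_death", "diagnosed_death", or "other_cause".
    """
    definition = DeathDefinition(definition)
    death_date = np.datetime64(death_date, "D")
    dx = sorted(np.datetime64(d, "D") for d in diagnosis_dates)
    if dx and dx[0] > death_date:
        raise DataError("diagnosis event dated after death")

    if definition is DeathDefinition.PRIMARY_CAUSE_ONLY:
        specific = any(c == condition and pos == "primary" for c, pos in causes)
    else:
        specific = any(c == condition for c, _ in causes)
    if not specific:
        return "other_cause"
    if not dx:
        return "undiagnosed_death"
    if definition is DeathDefinition.EXPANDED_LAST_YEAR:
        if (death_date - dx[0]).astype(int) <= ONE_YEAR_DAYS:
            return "undiagnosed_death"
    return "diagnosed_death"


def _first_diagnosis(diagnoses: pd.DataFrame, condition: str,
                     min_event_count: int = 1) -> pd.Series:
    """Date each person first satisfies the diagnosis rule for `condition`.

    With ``min_event_count`` > 1 (the concentration-of-diagnoses rule used
    for relapsing conditions) the diagnosis date is the date of the k-th
    recorded event.
    """
    d = diagnoses.loc[diagnoses["condition"] == condition,
                      ["person_id", "diagnosis_date"]]
    if d.empty:
        return pd.Series(dtype="datetime64[ns]", name="first_diagnosis",
                         index=pd.Index([], name="person_id"))
    d = d.sort_values(["person_id", "diagnosis_date"], kind="mergesort")
    rank = d.groupby("person_id").cumcount()
    sel = d[rank == min_event_count - 1]
    return sel.set_index("person_id")["diagnosis_date"].rename("first_diagnosis")


def tabulate_strata(persons: pd.DataFrame, diagnoses: pd.DataFrame,
                    deaths: pd.DataFrame, condition: str,
                    definition=DeathDefinition.MAIN,
                    years=None, prevalence: str = "year_start",
                    min_event_count: int = 1) -> pd.DataFrame:
    """Stratified counts for one condition over the 450-strata design.

    Returns one row per StratumKey (sex x age group x qimd x region x year;
    450 rows per year, zero-filled) with the COUNT_COLUMNS.
    """
    definition = DeathDefinition(definition)
    if prevalence not in ("year_start", "mid_year"):
        raise ValueError(f"unknown prevalence convention {prevalence!r}")
    if years is None:
        raise ValueError("years (iterable of calendar years) is required")
    years = [int(y) for y in years]

    p = persons.reset_index(drop=True)
    n = len(p)
    birth = p["birth_date"].to_numpy("datetime64[ns]")
    reg_start = p["registration_start"].to_numpy("datetime64[ns]")
    reg_end = p["registration_end"].to_numpy("datetime64[ns]")

    # first qualifying diagnosis per person
    fdx = _first_diagnosis(diagnoses, condition, min_event_count)
    first_dx = p[["person_id"]].join(fdx, on="person_id")["first_diagnosis"] \
        .to_numpy("datetime64[ns]")

    # one death per person; cause flags for this condition
    death_date = np.full(n, np.datetime64("NaT"), "datetime64[ns]")
    is_specific = np.zeros(n, bool)
    if len(deaths):
        dd = deaths.groupby("person_id")["death_date"].min()
        death_date = pd.to_datetime(p["person_id"].map(dd)).to_numpy("datetime64[ns]")
        cond_rows = deaths[deaths["cause"] == condition]
        if definition is DeathDefinition.PRIMARY_CAUSE_ONLY:
            cond_rows = cond_rows[cond_rows["position"] == "primary"]
        flag = p["person_id"].isin(cond_rows["person_id"]).to_numpy()
        is_specific = flag

    has_death = ~np.isnat(death_date)
    if np.any(has_death & ~np.isnat(first_dx) & (first_dx > death_date)):
        raise DataError(f"{condition}: diagnosis event dated after death")

    died_undiagnosed = is_specific & np.isnat(first_dx)
    if definition is DeathDefinition.EXPANDED_LAST_YEAR:
        recent = (is_specific & ~np.isnat(first_dx)
                  & ((death_date - first_dx) <= np.timedelta64(ONE_YEAR_DAYS, "D")))
        died_undiagnosed |= recent
    died_diagnosed = is_specific & ~died_undiagnosed

    # NaT maps to a huge negative number, never equal to a study year
    dx_year = first_dx.astype("datetime64[Y]").astype(np.int64) + 1970
    death_year = death_date.astype("datetime64[Y]").astype(np.int64) + 1970

    # first-year CFR risk set: incident diagnosis with complete 365-day
    # follow-up (death observed within the window, or censor past it).
    # A disease-specific death within the window counts as a first-year
    # death regardless of the undiagnosed/diagnosed split, which only the
    # expanded_last_year definition can alter.
    window = np.timedelta64(ONE_YEAR_DAYS, "D")
    fy_complete = ~np.isnat(first_dx) & (
        (has_death & (death_date <= first_dx + window))
        | (reg_end >= first_dx + window))
    fy_death = (fy_complete & has_death & is_specific
                & (death_date <= first_dx + window))

    shape = (len(years), N_STRATA)
    counts = {k: np.zeros(shape, np.int64) for k in COUNT_COLUMNS}

    sex_idx = p["sex"].map({s: i for i, s in enumerate(SEXES)}).to_numpy(np.int64)
    qimd = p["qimd"].to_numpy(int)
    region_idx = p["region"].map({r: i for i, r in enumerate(REGIONS)}) \
        .to_numpy(np.int64)

    for j, year in enumerate(years):
        ys = np.datetime64(year_start(year))
        age_mid = age_on(np.full(n, mid_year(year)), birth)
        in_year = ((age_mid >= 30)
                   & (reg_start <= ys)
                   & (reg_end >= ys)
                   & (~has_death | (death_date >= ys)))
        if not in_year.any():
            continue
        idx = np.nonzero(in_year)[0]
        ai = age_group_index(age_mid[idx])
        si = ((sex_idx[idx] * len(AGE_GROUPS) + ai) * 5 + (qimd[idx] - 1)) \
            * len(REGIONS) + region_idx[idx]

        def add(col, mask):
            counts[col][j] += np.bincount(si[mask[idx]], minlength=N_STRATA)

        add("person_years", in_year)
        if prevalence == "year_start":
            prev = ~np.isnat(first_dx) & (first_dx < np.datetime64(ys))
        else:
            my = np.datetime64(mid_year(year))
            prev = (~np.isnat(first_dx) & (first_dx < my)
                    & (~has_death | (death_date >= my)))
        add("Y", prev & in_year)
        add("incident_diagnoses", (dx_year == year) & in_year)
        add("Z_U", died_undiagnosed & (death_year == year) & in_year)
        add("Z_D", died_diagnosed & (death_year == year) & in_year)
        add("Z_0", has_death & ~is_specific & (death_year == year) & in_year)
        add("first_year_at_risk", fy_complete & (dx_year == year) & in_year)
        add("first_year_deaths", fy_death & (dx_year == year) & in_year)

    key = full_key_frame(years)
    flat = stratum_index(key["sex"], key["age_group"], key["qimd"], key["region"])
    ymap = {y: i for i, y in enumerate(years)}
    yi = key["year"].map(ymap).to_numpy()
    for k in COUNT_COLUMNS:
        key[k] = counts[k][yi, flat]
    return key[KEY_COLUMNS + COUNT_COLUMNS]
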