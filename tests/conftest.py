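"""Shared fixtures: a hand-built 12-person cohort with a manually enumerated
count table, a small simulated cohort, and one full pipeline run."""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

from underdx import default_params, generate_cohort
from underdx.pipeline import RunConfig, run_pipeline

COND = "gout"
HAND_YEARS = [2015, 2016]
STUDY_END = "2016-12-31"


def _p(pid, sex, birth, qimd, region, reg_start="2010-01-01",
       reg_end=STUDY_END):
    return dict(person_id=pid, sex=sex, birth_date=birth, qimd=qimd,
                region=region, registration_start=reg_start,
                registration_end=reg_end)


@pytest.fixture(scope="session")
def hand_cohort():
    """Twelve hand-written persons exercising every classification rule.

    P6 (under 30 throughout) and P10 (censor before registration) are
    ineligible; the remaining ten generate the enumerated counts in
    ``hand_expected_counts``.
    """
    persons = pd.DataFrame([
        _p(1, "female", "1980-03-10", 1, "London"),
        _p(2, "female", "1950-06-15", 1, "London"),
        _p(3, "male", "1940-01-05", 3, "North West", reg_end="2016-03-10"),
        _p(4, "female", "1952-11-30", 1, "London", reg_end="2015-09-09"),
        _p(5, "male", "1938-07-02", 5, "South East", reg_end="2015-11-20"),
        _p(6, "female", "1990-02-01", 1, "London"),
        _p(7, "male", "1960-04-18", 2, "London", reg_start="2015-06-01"),
        _p(8, "female", "1935-09-09", 4, "Yorkshire and the Humber"),
        _p(9, "male", "1945-12-25", 1, "London", reg_end="2016-10-05"),
        _p(10, "female", "1970-01-01", 1, "London", reg_start="2012-01-01",
           reg_end="2011-06-30"),
        _p(11, "male", "1955-05-05", 2, "East of England",
           reg_end="2015-04-04"),
        _p(12, "female", "1948-08-08", 1, "London"),
    ])
    for c in ("birth_date", "registration_start", "registration_end"):
        persons[c] = pd.to_datetime(persons[c])

    diagnoses = pd.DataFrame(
        [(1, COND, "2014-05-01"), (2, COND, "2015-08-20"),
         (5, COND, "2015-03-15"), (8, COND, "2016-02-02"),
         (9, COND, "2013-01-10"), (12, COND, "2015-10-10"),
         (12, COND, "2016-01-05")],
        columns=["person_id", "condition", "diagnosis_date"])
    diagnoses["diagnosis_date"] = pd.to_datetime(diagnoses["diagnosis_date"])

    deaths = pd.DataFrame(
        [(3, "2016-03-10", COND, "primary"),
         (4, "2015-09-09", "other", "primary"),
         (4, "2015-09-09", COND, "contributing"),
         (5, "2015-11-20", COND, "primary"),
         (9, "2016-10-05", COND, "primary"),
         (11, "2015-04-04", "other", "primary")],
        columns=["person_id", "death_date", "cause", "position"])
    deaths["death_date"] = pd.to_datetime(deaths["death_date"])
    return persons, diagnoses, deaths


@pytest.fixture(scope="session")
def hand_expected_counts():
    """Manual enumeration of the non-zero strata of the hand cohort (main
    death definition, year-start prevalence).  Derivation, by person:

    2015 — P1 (f,35,q1,London): Y;  P2 (f,65) + P12 (f,66) + P4 (f,62) share
    (f,60-69,q1,London): 3 person-years, 2 incident (P2, P12), both in the
    first-year risk set, 1 undiagnosed death (P4, contributing cause, no
    prior diagnosis); P3 (m,75,q3,NW) alive; P5 (m,76,q5,SE) incident,
    at risk, dies of the condition 250 days after diagnosis -> diagnosed
    death and a first-year death; P8 (f,79,q4,Y&H) alive; P9 (m,69,q1,
    London) previously diagnosed -> Y; P11 (m,60,q2,EoE) other-cause death.

    2016 — P1 Y; P2+P12 (f,66/67) both Y; P3 (m,76,q3,NW) undiagnosed death
    (primary cause); P7 (m,56,q2,London) first contributing year
    (registered mid-2015); P8 (f,80,q4,Y&H) incident but censored within
    365 days -> not at risk; P9 (m,70,q1,London) Y, diagnosed death.
    """
    cols = ["sex", "age_group", "qimd", "region", "year", "person_years",
            "incident_diagnoses", "Y", "Z_U", "Z_D", "Z_0",
            "first_year_at_risk", "first_year_deaths"]
    rows = [
        ("female", "30-49", 1, "London", 2015, 1, 0, 1, 0, 0, 0, 0, 0),
        ("female", "60-69", 1, "London", 2015, 3, 2, 0, 1, 0, 0, 2, 0),
        ("male", "70-79", 3, "North West", 2015, 1, 0, 0, 0, 0, 0, 0, 0),
        ("male", "70-79", 5, "South East", 2015, 1, 1, 0, 0, 1, 0, 1, 1),
        ("female", "70-79", 4, "Yorkshire and the Humber", 2015,
         1, 0, 0, 0, 0, 0, 0, 0),
        ("male", "60-69", 1, "London", 2015, 1, 0, 1, 0, 0, 0, 0, 0),
        ("male", "60-69", 2, "East of England", 2015, 1, 0, 0, 0, 0, 1, 0, 0),
        ("female", "30-49", 1, "London", 2016, 1, 0, 1, 0, 0, 0, 0, 0),
        ("female", "60-69", 1, "London", 2016, 2, 0, 2, 0, 0, 0, 0, 0),
        ("male", "70-79", 3, "North West", 2016, 1, 0, 0, 1, 0, 0, 0, 0),
        ("male", "50-59", 2, "London", 2016, 1, 0, 0, 0, 0, 0, 0, 0),
        ("female", "80+", 4, "Yorkshire and the Humber", 2016,
         1, 1, 0, 0, 0, 0, 0, 0),
        ("male", "70-79", 1, "London", 2016, 1, 0, 1, 0, 1, 0, 0, 0),
    ]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture(scope="session")
def small_sim():
    """A 15k-person, five-year, two-condition cohort with its truth table."""
    params = default_params(conditions=["hypertension", "lung_cancer"],
                            years=(2008, 2012), cohort_size=15_000, seed=11)
    persons, diagnoses, deaths, truth = generate_cohort(params)
    return params, persons, diagnoses, deaths, truth


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full 11-condition pipeline run on a small simulated cohort."""
    out = tmp_path_factory.mktemp("pipeline_run")
    cfg = RunConfig(cohort_size=20_000, years=(2008, 2012), seed=3,
                    output_dir=str(out), n_areas_per_region=6,
                    areas_per_health_area=3, national_population=200_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_pipeline(cfg)
    return cfg, manifest
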