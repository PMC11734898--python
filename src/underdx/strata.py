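"""Demographic stratification shared by every stage of the pipeline.

The model is stratified by sex (2) x age group (5) x deprivation quintile
(5) x region (9): 450 strata per calendar year.  A person's stratum for a
year is determined by their attained age at mid-year (1 July); the
convention is deterministic so the simulator and the extraction stage agree
exactly.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

SEXES = ("female", "male")

AGE_GROUPS = ("30-49", "50-59", "60-69", "70-79", "80+")
# lower bound of each group; upper bound is the next lower bound (80+ open)
AGE_GROUP_LOWER = np.array([30, 50, 60, 70, 80])

QIMD_LEVELS = (1, 2, 3, 4, 5)  # 1 = least deprived

REGIONS = (
    "North East",
    "North West",
    "Yorkshire and the Humber",
    "East Midlands",
    "West Midlands",
    "East of England",
    "London",
    "South East",
    "South West",
)

N_STRATA = len(SEXES) * len(AGE_GROUPS) * len(QIMD_LEVELS) * len(REGIONS)

STRATIFIERS = ["sex", "age_group", "qimd", "region"]
KEY_COLUMNS = STRATIFIERS + ["year"]

_SEX_INDEX = {s: i for i, s in enumerate(SEXES)}
_AGE_INDEX = {g: i for i, g in enumerate(AGE_GROUPS)}
_REGION_INDEX = {r: i for i, r in enumerate(REGIONS)}


def assign_age_group(age_years):
    """Map attained age in whole years to its age-group label.

    Ages below 30 are outside the study population and raise ``ValueError``.
    Accepts a scalar or an array; vectorised inputs return an object array
    of labels.
    """
    ages = np.asarray(age_years)
    if np.any(ages < 30):
        raise ValueError("age below 30 is outside the eligible population")
    idx = np.searchsorted(AGE_GROUP_LOWER, ages, side="right") - 1
    if np.ndim(idx) == 0:
        return AGE_GROUPS[int(idx)]
    return np.asarray(AGE_GROUPS, dtype=object)[idx]


def age_group_index(age_years):
    """Vectorised age -> age-group index (0..4); ages <30 raise."""
    ages = np.asarray(age_years)
    if np.any(ages < 30):
        raise ValueError("age below 30 is outside the eligible population")
    return np.searchsorted(AGE_GROUP_LOWER, ages, side="right") - 1


def age_on(dates, birth_dates) -> np.ndarray:
    """Attained age in completed years on `dates` for `birth_dates`.

    Both arguments are datetime64-like arrays of equal length.  Uses exact
    calendar arithmetic (birthday reached or not), not day counts divided by
    365.25, so the simulator and extraction can never disagree.
    """
    d = pd.DatetimeIndex(np.asarray(dates, dtype="datetime64[ns]"))
    b = pd.DatetimeIndex(np.asarray(birth_dates, dtype="datetime64[ns]"))
    before_birthday = (d.month < b.month) | ((d.month == b.month) & (d.day < b.day))
    return (d.year - b.year - before_birthday.astype(int)).to_numpy()


def mid_year(year) -> np.datetime64:
    return np.datetime64(f"{int(year)}-07-01")


def year_start(year) -> np.datetime64:
    return np.datetime64(f"{int(year)}-01-01")


def year_end(year) -> np.datetime64:
    """First day of the following year (exclusive upper bound)."""
    return np.datetime64(f"{int(year) + 1}-01-01")


def stratum_index(sex, age_group, qimd, region) -> np.ndarray:
    """Flat stratum index in [0, 450) from the four stratifiers.

    Layout: sex-major, then age group, deprivation quintile, region.
    """
    s = np.vectorize(_SEX_INDEX.__getitem__)(np.asarray(sex, dtype=object))
    a = np.vectorize(_AGE_INDEX.__getitem__)(np.asarray(age_group, dtype=object))
    q = np.asarray(qimd, dtype=int) - 1
    r = np.vectorize(_REGION_INDEX.__getitem__)(np.asarray(region, dtype=object))
    return ((s * len(AGE_GROUPS) + a) * len(QIMD_LEVELS) + q) * len(REGIONS) + r


def stratum_frame() -> pd.DataFrame:
    """All 450 stratum keys in flat-index order (no year column)."""
    rows = []
    for s in SEXES:
        for a in AGE_GROUPS:
            for q in QIMD_LEVELS:
                for r in REGIONS:
                    rows.append((s, a, q, r))
    return pd.DataFrame(rows, columns=STRATIFIERS)


def full_key_frame(years: Iterable[int]) -> pd.DataFrame:
    """Complete StratumKey table: 450 rows per requested year."""
    base = stratum_frame()
    out = []
    for y in years:
        f = base.copy()
        f["year"] = int(y)
        out.append(f)
    return pd.concat(out, ignore_index=True)
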