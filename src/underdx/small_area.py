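"""Indirect small-area estimation of underdiagnosis.

Stratum-level probabilities (by sex, age group, deprivation quintile,
region, year) are linked to small-area population tables: each area's
demographic groups look up their stratum estimate, and the area value is
the population-weighted mean.  Small areas act as building blocks for
health planning areas — aggregating their estimates with population weights
is algebraically identical to a one-step weighted mean over all underlying
demographic groups, so the two-level construction loses nothing.

National and subgroup summaries weight strata by their estimated diseased
counts (X + Y) rather than raw population, so the aggregate remains the
probability of being undiagnosed given diseased: total X / total (X + Y).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .strata import KEY_COLUMNS

AREA_GROUP_KEYS = ["sex", "age_group", "qimd", "region", "year"]


def link_estimates_to_areas(estimates: pd.DataFrame, areas: pd.DataFrame,
                            on_missing: str = "error") -> pd.DataFrame:
    """Population-weighted underdiagnosis probability per small area-year.

    ``estimates`` must contain the five stratum keys and ``p_undx`` (and,
    optionally, ``diseased_per_capita`` = (X+Y)/person-years, which is then
    carried through as an expected diseased count for diseased-weighted
    aggregation).  Every populated demographic group in ``areas`` must have
    a stratum estimate; missing keys raise.  Zero-population area-years are
    emitted with a NaN probability and ``no_population`` flag.
    """
    need = {"area_id", "year", "sex", "age_group", "population", "qimd", "region"}
    if not need.issubset(areas.columns):
        raise ValueError(f"area table missing columns {sorted(need - set(areas.columns))}")

    cols = KEY_COLUMNS + ["p_undx"]
    has_diseased = "diseased_per_capita" in estimates.columns
    if has_diseased:
        cols = cols + ["diseased_per_capita"]
    merged = areas.merge(estimates[cols], on=AREA_GROUP_KEYS, how="left",
                         validate="many_to_one")
    populated = merged["population"] > 0
    unmatched = merged.loc[populated & merged["p_undx"].isna()]
    if len(unmatched):
        keys = unmatched[AREA_GROUP_KEYS].drop_duplicates().head(5).to_dict("records")
        if on_missing == "error":
            raise ValueError(
                f"no stratum estimate for {len(unmatched)} populated area "
                f"groups, e.g. {keys}")
        if on_missing != "drop":
            raise ValueError(f"unknown on_missing policy {on_missing!r}")
        # groups without a usable estimate carry no weight in the area mean
        merged = merged[~merged["p_undx"].isna()]

    merged["_wp"] = merged["population"] * merged["p_undx"]
    agg = {"population": "sum", "_wp": "sum"}
    if has_diseased:
        merged["_dis"] = merged["population"] * merged["diseased_per_capita"]
        merged["_dp"] = merged["_dis"] * merged["p_undx"]
        agg.update({"_dis": "sum", "_dp": "sum"})
    grouped = merged.groupby(["area_id", "year"], as_index=False).agg(agg)
    pop = grouped["population"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["p_undx"] = np.where(pop > 0, grouped["_wp"] / np.where(pop > 0, pop, 1),
                                     np.nan)
    grouped["no_population"] = pop <= 0
    out_cols = ["area_id", "year", "population", "p_undx", "no_population"]
    if has_diseased:
        grouped = grouped.rename(columns={"_dis": "diseased"})
        dis = grouped["diseased"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            grouped["p_undx_diseased_weighted"] = np.where(
                dis > 0, grouped["_dp"] / np.where(dis > 0, dis, 1), np.nan)
        out_cols = ["area_id", "year", "population", "diseased", "p_undx",
                    "p_undx_diseased_weighted", "no_population"]
    return grouped[out_cols]


def aggregate_to_health_areas(area_estimates: pd.DataFrame, areas: pd.DataFrame,
                              weighting: str = "population") -> pd.DataFrame:
    """Aggregate small-area estimates to their parent health areas.

    ``weighting`` is ``population`` (default) or ``diseased`` (requires the
    expected diseased counts produced by :func:`link_estimates_to_areas`
    when the stratum estimates carry ``diseased_per_capita``).  Small areas
    without a health-area mapping raise.
    """
    lookup = areas[["area_id", "health_area_id"]].drop_duplicates()
    if lookup["area_id"].duplicated().any():
        dup = lookup.loc[lookup["area_id"].duplicated(), "area_id"].tolist()[:5]
        raise ValueError(f"small areas mapped to multiple health areas: {dup}")
    merged = area_estimates.merge(lookup, on="area_id", how="left")
    orphan = merged["health_area_id"].isna()
    if orphan.any():
        ids = merged.loc[orphan, "area_id"].unique()[:5].tolist()
        raise ValueError(f"small areas without a health area: {ids}")

    if weighting == "population":
        wcol, pcol = "population", "p_undx"
    elif weighting == "diseased":
        if "diseased" not in merged.columns:
            raise ValueError("diseased weighting requires diseased counts from "
                             "link_estimates_to_areas")
        wcol, pcol = "diseased", "p_undx_diseased_weighted"
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    bad = merged[pcol].isna() & (merged[wcol] > 0)
    if bad.any():
        raise ValueError("missing probability for a positively weighted area")
    merged["_wp"] = merged[wcol] * merged[pcol].fillna(0.0)
    grouped = merged.groupby(["health_area_id", "year"], as_index=False).agg(
        weight=(wcol, "sum"), _wp=("_wp", "sum"))
    w = grouped["weight"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["p_undx"] = np.where(w > 0, grouped["_wp"] / np.where(w > 0, w, 1),
                                     np.nan)
    grouped = grouped.rename(columns={"weight": "population" if
                                      weighting == "population" else "diseased"})
    return grouped.drop(columns="_wp")


def aggregate_national(estimates: pd.DataFrame, by=None) -> pd.DataFrame:
    """National (or subgroup-margin) underdiagnosis per year.

    Weights strata by estimated diseased counts, so the result equals
    total X / total (X + Y) within each group.  ``by`` optionally adds
    margin columns (e.g. ``["qimd"]`` or ``["age_group"]``).
    """
    if estimates.empty:
        raise ValueError("empty estimate table")
    keys = ["year"] + (list(by) if by else [])
    g = estimates.groupby(keys, as_index=False)[["X", "Y"]].sum()
    denom = (g["X"] + g["Y"]).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        g["p_undx"] = np.where(denom > 0, g["X"] / np.where(denom > 0, denom, 1),
                               np.nan)
    g["diseased"] = denom
    return g
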