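"""Sensitivity scenarios and correlation-based validation.

There is no gold standard for underdiagnosis, so validation is ecological:
Pearson correlations between area-level underdiagnosis estimates and
external comparator series (survey-based undiagnosed prevalence, emergency
admission rates, late-stage diagnosis proportions — all consumed as generic
id/value series).  Sensitivity analysis re-runs the full pipeline under
alternative assumptions — restricting disease-specific deaths to the
primary cause, expanding undiagnosed deaths to include those diagnosed
within the year before death, or swapping the first-year case-fatality
assumption for the overall one — and correlates the resulting across-area
distributions with the main run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .event_extraction import DeathDefinition, tabulate_strata
from .state_model import DAssumption, run_state_model
from .strata_rates import build_rate_table


class CorrelationResult(NamedTuple):
    rho: float
    p_value: float
    n: int
    undefined: bool = False


@dataclass(frozen=True)
class Scenario:
    name: str
    death_definition: DeathDefinition
    d_assumption: DAssumption


SCENARIOS: dict[str, Scenario] = {
    "main": Scenario("main", DeathDefinition.MAIN, DAssumption.FIRST_YEAR),
    "primary_cause_only": Scenario("primary_cause_only",
                                   DeathDefinition.PRIMARY_CAUSE_ONLY,
                                   DAssumption.FIRST_YEAR),
    "expanded_last_year": Scenario("expanded_last_year",
                                   DeathDefinition.EXPANDED_LAST_YEAR,
                                   DAssumption.FIRST_YEAR),
    "overall_cfr": Scenario("overall_cfr", DeathDefinition.MAIN,
                            DAssumption.OVERALL),
}


def get_scenario(name) -> Scenario:
    if isinstance(name, Scenario):
        return name
    try:
        return SCENARIOS[str(name)]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"choose from {sorted(SCENARIOS)}") from None


def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson r with a two-sided p from the t transform (n-2 df).

    Pairs with a missing value in either series are dropped; fewer than
    three complete pairs, or zero variance in either series, yields an
    undefined result (NaN rho/p, flagged) rather than an exception.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must be paired (equal length)")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, True)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n, False)


def run_scenario(persons: pd.DataFrame, diagnoses: pd.DataFrame,
                 deaths: pd.DataFrame, condition: str, scenario,
                 years, **pipeline_options) -> pd.DataFrame:
    """Re-run extraction -> rates -> state model under one scenario.

    ``pipeline_options`` pass through to the underlying stages
    (prevalence, min_event_count, cfr_source, cfr_floor,
    observed_where_available, epsilon, lower_bound_mode, apply_lower_bound).
    Output rows are tagged with the scenario name.
    """
    sc = get_scenario(scenario)
    tab_kw = {k: pipeline_options[k] for k in ("prevalence", "min_event_count")
              if k in pipeline_options}
    rate_kw = {k: pipeline_options[k]
               for k in ("cfr_source", "cfr_floor", "observed_where_available")
               if k in pipeline_options}
    sm_kw = {k: pipeline_options[k]
             for k in ("epsilon", "lower_bound_mode", "lower_bound_source",
                       "apply_lower_bound")
             if k in pipeline_options}
    unknown = set(pipeline_options) - set(tab_kw) - set(rate_kw) - set(sm_kw)
    if unknown:
        raise TypeError(f"unknown pipeline options {sorted(unknown)}")

    counts = tabulate_strata(persons, diagnoses, deaths, condition,
                             definition=sc.death_definition, years=years, **tab_kw)
    rates = build_rate_table(counts, condition, **rate_kw)
    est = run_state_model(rates, assumption=sc.d_assumption, **sm_kw)
    est.insert(0, "scenario", sc.name)
    est.insert(1, "condition", condition)
    est["diseased_per_capita"] = np.where(
        rates["person_years"] > 0,
        (est["X"] + est["Y"]) / rates["person_years"].replace(0, 1), 0.0)
    return est


def compare_scenarios(est_a: pd.DataFrame, est_b: pd.DataFrame,
                      id_col: str = "health_area_id") -> CorrelationResult:
    """Correlate two across-area distributions of underdiagnosis.

    Both inputs are area-level estimate tables (``id_col`` [+ year] and
    ``p_undx``); they must cover the same units, otherwise the symmetric
    difference is reported.
    """
    keys = [id_col] + (["year"] if "year" in est_a.columns
                       and "year" in est_b.columns else [])
    a = est_a.set_index(keys)["p_undx"]
    b = est_b.set_index(keys)["p_undx"]
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            f"area mismatch between scenario tables; only in first: "
            f"{list(only_a[:5])}, only in second: {list(only_b[:5])}")
    b = b.reindex(a.index)
    return pearson_correlation(a.to_numpy(), b.to_numpy())


def correlate_with_comparator(area_estimates: pd.DataFrame,
                              comparator: pd.DataFrame,
                              id_col: str = "health_area_id") -> CorrelationResult:
    """Pearson correlation between area estimates and a comparator series.

    ``comparator`` has columns ``id_col`` and ``value``; units missing from
    either side are dropped (pairwise-complete), mirroring how external
    series rarely cover every area.
    """
    merged = area_estimates.merge(comparator[[id_col, "value"]], on=id_col,
                                  how="inner")
    return pearson_correlation(merged["p_undx"].to_numpy(),
                               merged["value"].to_numpy())


def make_synthetic_comparator(area_estimates: pd.DataFrame, true_rho: float,
                              seed: int, label: str = "synthetic",
                              id_col: str = "health_area_id") -> pd.DataFrame:
    """Synthetic comparator series with a configurable target correlation.

    Builds value = rho * z(p_undx) + sqrt(1 - rho^2) * noise, so the
    population correlation with the estimates equals ``true_rho``; the
    sample correlation fluctuates around it.
    """
    if not -1.0 <= true_rho <= 1.0:
        raise ValueError("true_rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    p = area_estimates["p_undx"].to_numpy(float)
    if np.ptp(p[np.isfinite(p)]) == 0:
        raise ValueError("estimates have zero variance; comparator undefined")
    z = (p - np.nanmean(p)) / np.nanstd(p)
    noise = rng.standard_normal(len(p))
    value = true_rho * z + np.sqrt(max(0.0, 1 - true_rho ** 2)) * noise
    return pd.DataFrame({id_col: area_estimates[id_col].to_numpy(),
                         "value": value, "label": label})
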