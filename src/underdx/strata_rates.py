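"""Per-stratum transition quantities, with logistic smoothing of sparse events.

Undiagnosed disease-specific deaths are rare at the 450-strata resolution,
so many strata record none at all.  A binomial logistic model of the
per-person-year undiagnosed-death probability — additive main effects of
age group and deprivation quintile (categorical), sex, and calendar year
(linear, centred) — imputes a positive expected count for every populated
stratum and smooths the observed counts across strata.  Region is
deliberately not a predictor: the degrees of freedom are kept low so the
model fits conditions with few events, and the back-calculated quantity D
is assumed not to vary by region.

First-year case fatality among the newly diagnosed (the quantity that
defines D under the main assumption) is estimated two ways: the plain
stratified ratio with hierarchical pooling of sparse cells (collapse
region, then deprivation, then age), and a smoothed version from the same
binomial-logistic specification.  The smoothed version is the pipeline
default because raw stratified ratios are far too noisy to divide by.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .strata import AGE_GROUPS, KEY_COLUMNS, QIMD_LEVELS, full_key_frame

CFR_FLOOR_DEFAULT = 10


class ModelFitError(RuntimeError):
    """Logistic smoothing failed (no events, separation, non-convergence)."""


def design_matrix(frame: pd.DataFrame, year_center: float | None = None):
    """Fixed-effects design for the smoothing models.

    Columns: intercept; age-group indicators (reference 30-49); male
    indicator; deprivation-quintile indicators (reference quintile 1);
    centred calendar year.  Region is intentionally absent.
    """
    if year_center is None:
        year_center = float(frame["year"].mean())
    cols = [np.ones(len(frame))]
    names = ["Intercept"]
    for g in AGE_GROUPS[1:]:
        cols.append((frame["age_group"] == g).to_numpy(float))
        names.append(f"age_group[{g}]")
    cols.append((frame["sex"] == "male").to_numpy(float))
    names.append("sex[male]")
    for q in QIMD_LEVELS[1:]:
        cols.append((frame["qimd"] == q).to_numpy(float))
        names.append(f"qimd[{q}]")
    cols.append(frame["year"].to_numpy(float) - year_center)
    names.append("year_c")
    return np.column_stack(cols), names, year_center


@dataclass
class SmoothingModel:
    """A fitted binomial-logistic event model for one condition.

    ``params``/``bse`` are indexed by design-column name; ``year_center``
    fixes the year centring used at fit time so predictions are consistent.
    """

    condition: str
    endpoint: str  # "undiagnosed_death" or "first_year_cfr" or "overall_cfr"
    params: pd.Series
    bse: pd.Series
    year_center: float
    converged: bool
    n_obs: int
    n_events: float
    deviance: float = float("nan")

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        X, names, _ = design_matrix(frame, self.year_center)
        beta = self.params.reindex(names)
        if beta.isna().any():
            raise ValueError("design/model column mismatch")
        return X @ beta.to_numpy()

    def predict_probability(self, frame: pd.DataFrame) -> np.ndarray:
        """Per-person-year event probability for each row's stratum."""
        eta = self.linear_predictor(frame)
        return 1.0 / (1.0 + np.exp(-eta))


def _fit_binomial(counts: pd.DataFrame, events_col: str, trials_col: str,
                  condition: str, endpoint: str) -> SmoothingModel:
    rows = counts[counts[trials_col] > 0]
    if rows.empty:
        raise ModelFitError(f"{condition}: no exposure for {endpoint} model")
    events = rows[events_col].to_numpy(float)
    trials = rows[trials_col].to_numpy(float)
    if np.any(events > trials):
        raise ModelFitError(f"{condition}: more events than trials in {endpoint}")
    total = events.sum()
    if total == 0:
        raise ModelFitError(
            f"{condition}: zero {endpoint} events overall; the logistic "
            "smoothing model is undefined")
    X, names, year_center = design_matrix(rows)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(np.column_stack([events, trials - events]), X,
                           family=sm.families.Binomial())
            res = model.fit(maxiter=200)
    except Exception as exc:  # statsmodels raises several flavours here
        raise ModelFitError(f"{condition}: {endpoint} model failed: {exc}") from exc
    params = np.asarray(res.params, float)
    converged = bool(getattr(res, "converged", True))
    if not np.isfinite(params).all() or np.abs(params).max() > 30:
        raise ModelFitError(
            f"{condition}: {endpoint} model shows separation "
            "(unbounded coefficients)")
    if not converged:
        raise ModelFitError(f"{condition}: {endpoint} model did not converge")
    return SmoothingModel(condition=condition, endpoint=endpoint,
                          params=pd.Series(params, index=names),
                          bse=pd.Series(np.asarray(res.bse, float), index=names),
                          year_center=year_center, converged=converged,
                          n_obs=len(rows), n_events=float(total),
                          deviance=float(res.deviance))


def fit_undiagnosed_death_model(counts: pd.DataFrame,
                                condition: str = "") -> SmoothingModel:
    """Fit the per-person-year undiagnosed-death probability surface.

    ``counts`` is a stratified count table with Z_U and person_years.
    Raises :class:`ModelFitError` when there are no events anywhere or the
    fit separates/does not converge.
    """
    return _fit_binomial(counts, "Z_U", "person_years", condition,
                         "undiagnosed_death")


def fit_case_fatality_model(counts: pd.DataFrame, condition: str = "",
                            window: str = "first_year") -> SmoothingModel:
    """Smoothed case-fatality surface among the diagnosed.

    ``first_year``: deaths within 365 days of incident diagnosis against the
    incident risk set.  ``overall``: disease-specific diagnosed deaths
    against diagnosed prevalence.
    """
    if window == "first_year":
        return _fit_binomial(counts, "first_year_deaths", "first_year_at_risk",
                             condition, "first_year_cfr")
    if window == "overall":
        return _fit_binomial(counts, "Z_D", "Y", condition, "overall_cfr")
    raise ValueError(f"unknown case-fatality window {window!r}")


def smooth_undiagnosed_deaths(model: SmoothingModel,
                              counts: pd.DataFrame) -> pd.Series:
    """Model-expected undiagnosed deaths per stratum-year.

    Z_U_smoothed = predicted event probability x person-years; strictly
    positive wherever person_years > 0, including strata with no observed
    deaths.  The count table must cover the complete 450-strata design for
    each of its years.
    """
    expected = full_key_frame(sorted(counts["year"].unique()))
    merged = expected.merge(counts[KEY_COLUMNS].drop_duplicates(), on=KEY_COLUMNS,
                            how="left", indicator=True)
    missing = merged[merged["_merge"] == "left_only"]
    if len(missing):
        keys = missing[KEY_COLUMNS].head(5).to_dict("records")
        raise ValueError(f"count table is missing {len(missing)} strata, "
                         f"e.g. {keys}")
    p = model.predict_probability(counts)
    return pd.Series(p * counts["person_years"].to_numpy(float),
                     index=counts.index, name="Z_U_smoothed")


# ---------------------------------------------------------------------------
# stratified case-fatality ratios with hierarchical pooling
# ---------------------------------------------------------------------------

_POOLING_LEVELS = [
    KEY_COLUMNS,                            # 0: no pooling
    ["sex", "age_group", "qimd", "year"],   # 1: collapse region
    ["sex", "age_group", "year"],           # 2: then deprivation
    ["sex", "year"],                        # 3: then age
]


def estimate_case_fatality(counts: pd.DataFrame, window: str = "first_year",
                           floor: int = CFR_FLOOR_DEFAULT) -> pd.DataFrame:
    """Stratified case-fatality probabilities with sparse-cell pooling.

    ``first_year`` uses deaths within 365 days of incident diagnosis over
    the incident risk set; ``overall`` uses diagnosed disease-specific
    deaths over diagnosed prevalence.  Cells whose denominator falls below
    ``floor`` take the pooled ratio with region collapsed, then deprivation,
    then age; cells still sparse after that take the condition-level ratio
    (with a warning when even that denominator is zero).

    Returns the stratum keys with columns ``cfr`` and ``pooling_level``
    (0 = cell's own ratio .. 4 = condition level).
    """
    if window == "first_year":
        num_col, den_col = "first_year_deaths", "first_year_at_risk"
    elif window == "overall":
        num_col, den_col = "Z_D", "Y"
    else:
        raise ValueError(f"unknown case-fatality window {window!r}")

    out = counts[KEY_COLUMNS].copy()
    num = counts[num_col].to_numpy(float)
    den = counts[den_col].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cfr = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    level = np.zeros(len(out), np.int64)
    unresolved = den < floor

    for lvl, keys in enumerate(_POOLING_LEVELS[1:], start=1):
        if not unresolved.any():
            break
        g = counts.groupby(keys, observed=True)[[num_col, den_col]].sum()
        pooled_num = counts[keys].apply(tuple, axis=1).map(g[num_col]).to_numpy(float) \
            if len(keys) > 1 else counts[keys[0]].map(g[num_col]).to_numpy(float)
        pooled_den = counts[keys].apply(tuple, axis=1).map(g[den_col]).to_numpy(float) \
            if len(keys) > 1 else counts[keys[0]].map(g[den_col]).to_numpy(float)
        use = unresolved & (pooled_den >= floor)
        with np.errstate(invalid="ignore", divide="ignore"):
            cfr = np.where(use, pooled_num / np.where(pooled_den > 0, pooled_den, 1), cfr)
        level = np.where(use, lvl, level)
        unresolved &= ~use

    if unresolved.any():
        tot_num, tot_den = float(num.sum()), float(den.sum())
        if tot_den == 0:
            warnings.warn("case-fatality denominator zero even at condition "
                          "level; estimates are undefined")
            cond_cfr = np.nan
        else:
            warnings.warn(f"{int(unresolved.sum())} strata fell back to the "
                          "condition-level case-fatality estimate")
            cond_cfr = tot_num / tot_den
        cfr = np.where(unresolved, cond_cfr, cfr)
        level = np.where(unresolved, 4, level)

    out["cfr"] = cfr
    out["pooling_level"] = level
    return out


# ---------------------------------------------------------------------------
# the assembled rate table
# ---------------------------------------------------------------------------

def build_rate_table(counts: pd.DataFrame, condition: str = "",
                     cfr_source: str = "smoothed",
                     cfr_floor: int = CFR_FLOOR_DEFAULT,
                     observed_where_available: bool = False) -> pd.DataFrame:
    """Turn stratified counts into the per-stratum transition quantities.

    Columns returned per StratumKey: person_years, Y, B_count (incident
    diagnoses), C_first, C_overall, E, Z_U_obs, Z_U_smoothed.

    ``cfr_source`` chooses how C_first / C_overall are produced:
    ``smoothed`` (binomial-logistic surface, default) or ``pooled``
    (stratified ratio with hierarchical pooling).  With
    ``observed_where_available`` the smoothed undiagnosed-death counts are
    replaced by the observed ones in strata that recorded any.
    """
    if cfr_source not in ("smoothed", "pooled"):
        raise ValueError(f"unknown cfr_source {cfr_source!r}")
    rt = counts[KEY_COLUMNS].copy()
    rt["person_years"] = counts["person_years"].to_numpy()
    rt["Y"] = counts["Y"].to_numpy()
    rt["B_count"] = counts["incident_diagnoses"].to_numpy()
    rt["Z_U_obs"] = counts["Z_U"].to_numpy()

    for window, col in (("first_year", "C_first"), ("overall", "C_overall")):
        if cfr_source == "smoothed":
            try:
                m = fit_case_fatality_model(counts, condition, window)
                rt[col] = m.predict_probability(counts)
                rt.attrs[f"{window}_cfr_model"] = m
                continue
            except ModelFitError as exc:
                warnings.warn(f"{condition}: falling back to pooled {window} "
                              f"case fatality ({exc})")
        rt[col] = estimate_case_fatality(counts, window, cfr_floor)["cfr"].to_numpy()

    py = counts["person_years"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rt["E"] = np.where(py > 0, counts["Z_0"] / np.where(py > 0, py, 1), np.nan)

    model = fit_undiagnosed_death_model(counts, condition)
    zs = smooth_undiagnosed_deaths(model, counts).to_numpy()
    if observed_where_available:
        zs = np.where(counts["Z_U"].to_numpy() > 0, counts["Z_U"].to_numpy(float), zs)
    rt["Z_U_smoothed"] = zs

    # expected incident-diagnosis counts, used by the state model's
    # feasibility bound on X (a bound built from raw integer counts would be
    # an upward-biased max() in sparse strata)
    bm = _fit_binomial(counts, "incident_diagnoses", "person_years",
                       condition, "incident_diagnosis")
    rt["B_count_smoothed"] = bm.predict_probability(counts) * py
    rt.attrs["undiagnosed_death_model"] = model
    rt.attrs["incident_diagnosis_model"] = bm
    return rt
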