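"""Back-calculation of undiagnosed prevalence from the six-state model.

The number of people alive and undiagnosed with a condition (X) is not
observable in health records, but the undiagnosed disease-specific deaths
they generate (Z_U) are.  Given a case-fatality probability D for the
undiagnosed, the undiagnosed prevalence is back-calculated as

    X = Z_U / D,

lower-bounded so that enough individuals exist each year to supply the
observed flows out of the undiagnosed state (next year's incident diagnoses
plus this year's undiagnosed deaths).  D is defined from the case fatality
among the diagnosed: the main assumption equates it to the first-year
post-diagnosis case fatality (the mortality risk around the time a disease
becomes diagnosable); a sensitivity assumption uses the overall case
fatality among all diagnosed cases.  The headline quantity is the
probability of being undiagnosed given diseased, X / (X + Y).
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

from .strata import KEY_COLUMNS, full_key_frame

D_EPSILON_DEFAULT = 1e-4

ESTIMATE_COLUMNS = ["X", "Y", "p_undx", "lower_bound_applied", "d_floored",
                    "p_undefined"]


class DAssumption(str, Enum):
    FIRST_YEAR = "first_year"   # main: D = first-year CFR of the diagnosed
    OVERALL = "overall"         # sensitivity: D = overall CFR of the diagnosed


def derive_undiagnosed_cfr(rates: pd.DataFrame, assumption=DAssumption.FIRST_YEAR,
                           epsilon: float = D_EPSILON_DEFAULT) -> pd.DataFrame:
    """Per-stratum undiagnosed case-fatality D under the chosen assumption.

    D is floored at ``epsilon`` (and NaN estimates replaced by it) so the
    back-calculated X stays finite; floored strata are flagged.
    """
    assumption = DAssumption(assumption)
    col = {DAssumption.FIRST_YEAR: "C_first", DAssumption.OVERALL: "C_overall"}[assumption]
    out = rates[KEY_COLUMNS].copy()
    c = rates[col].to_numpy(float)
    floored = ~np.isfinite(c) | (c < epsilon)
    out["D"] = np.where(floored, epsilon, c)
    out["d_floored"] = floored
    return out


def estimate_undiagnosed_prevalence(z_u, d, lower_bound=0.0):
    """X = max(Z_U / D, lower_bound); returns (X, bound_applied).

    All arguments broadcast; D must be strictly positive.
    """
    z_u = np.asarray(z_u, float)
    d = np.asarray(d, float)
    lb = np.asarray(lower_bound, float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("undiagnosed case fatality D must be positive; "
                         "apply the epsilon floor first")
    if np.any(z_u < 0) or np.any(lb < 0):
        raise ValueError("Z_U and lower bound must be non-negative")
    raw = z_u / d
    x = np.maximum(raw, lb)
    return x, x > raw


def underdiagnosis_probability(x, y):
    """X / (X + Y); 0/0 is undefined and returned as NaN."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("prevalence counts must be non-negative")
    denom = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(denom > 0, x / np.where(denom > 0, denom, 1), np.nan)
    return p


def compute_lower_bound(rates: pd.DataFrame, mode: str = "next_year",
                        source: str = "smoothed") -> np.ndarray:
    """Per-stratum-year lower bound on X: the undiagnosed pool must at least
    supply the flows out of it — next year's incident diagnoses plus this
    year's undiagnosed deaths.

    ``mode``: ``next_year`` (final study year substitutes its own incident
    diagnoses) or ``same_year``.  ``source``: ``smoothed`` uses the
    model-expected flows (B_count_smoothed, Z_U_smoothed); ``observed`` uses
    the raw counts.  The smoothed source is the default because taking a
    max() against raw integer counts systematically inflates X in strata
    where events are rare.
    """
    if mode not in ("next_year", "same_year"):
        raise ValueError(f"unknown lower-bound mode {mode!r}")
    if source == "smoothed" and "B_count_smoothed" in rates.columns:
        b_col, z_col = "B_count_smoothed", "Z_U_smoothed"
    elif source in ("smoothed", "observed"):
        b_col, z_col = "B_count", "Z_U_obs"
    else:
        raise ValueError(f"unknown lower-bound source {source!r}")
    z_u = rates[z_col].to_numpy(float)
    if mode == "same_year":
        return rates[b_col].to_numpy(float) + z_u
    nxt = rates[KEY_COLUMNS + [b_col]].copy()
    nxt["year"] -= 1
    merged = rates[KEY_COLUMNS].merge(
        nxt.rename(columns={b_col: "B_next"}), on=KEY_COLUMNS, how="left")
    b_next = merged["B_next"].to_numpy(float)
    b_next = np.where(np.isnan(b_next), rates[b_col].to_numpy(float), b_next)
    return b_next + z_u


def run_state_model(rates: pd.DataFrame, assumption=DAssumption.FIRST_YEAR,
                    epsilon: float = D_EPSILON_DEFAULT,
                    lower_bound_mode: str = "next_year",
                    lower_bound_source: str = "smoothed",
                    apply_lower_bound: bool = True) -> pd.DataFrame:
    """Per-stratum underdiagnosis estimates for one condition.

    Requires a complete rate table (every stratum of every year present);
    missing strata raise with the offending keys.  Returns the stratum keys
    with X, Y, p_undx and the diagnostic flags.
    """
    years = sorted(rates["year"].unique())
    expected = full_key_frame(years)
    merged = expected.merge(rates[KEY_COLUMNS].drop_duplicates(), on=KEY_COLUMNS,
                            how="left", indicator=True)
    missing = merged[merged["_merge"] == "left_only"]
    if len(missing):
        raise ValueError(
            f"rate table is missing {len(missing)} strata, e.g. "
            f"{missing[KEY_COLUMNS].head(5).to_dict('records')}")

    d_tab = derive_undiagnosed_cfr(rates, assumption, epsilon)
    lb = compute_lower_bound(rates, lower_bound_mode, lower_bound_source) \
        if apply_lower_bound else 0.0
    x, bounded = estimate_undiagnosed_prevalence(
        rates["Z_U_smoothed"].to_numpy(float), d_tab["D"].to_numpy(), lb)
    y = rates["Y"].to_numpy(float)
    p = underdiagnosis_probability(x, y)

    out = rates[KEY_COLUMNS].copy()
    out["X"] = x
    out["Y"] = y
    out["p_undx"] = p
    out["lower_bound_applied"] = np.broadcast_to(bounded, x.shape)
    out["d_floored"] = d_tab["d_floored"].to_numpy()
    out["p_undefined"] = ~np.isfinite(p)
    return out
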