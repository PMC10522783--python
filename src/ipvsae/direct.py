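"""Design-based (direct) district estimation of prevalence.

Survey-weighted proportions per district with first-stage (PSU-level)
with-replacement Taylor-linearised variances, the delta-method logit-scale
sampling variance psi used by the area-level model, logit-Wald confidence
intervals, and cohort-flow accounting for the violence-module subsample.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm


class CohortFlowError(ValueError):
    pass


@dataclass(frozen=True)
class CohortFlow:
    """Sample-flow accounting from full survey to analytic violence cohort."""

    n_interviewed: int
    n_dv_module: int
    n_excluded_never_married: int
    n_excluded_privacy: int
    n_analytic: int
    pct_dv_of_interviewed: float  # percent, 1 decimal
    pct_never_married: float
    pct_privacy: float


def cohort_flow(
    n_interviewed: int,
    n_dv_module: int,
    n_excluded_never_married: int,
    n_excluded_privacy: int,
) -> CohortFlow:
    """Derive the analytic sample size and exclusion percentages.

    Percentages are of the stage denominator (module uptake over all
    interviewed women; each exclusion over the module sample), rounded to one
    decimal as percent.
    """
    counts = (n_interviewed, n_dv_module, n_excluded_never_married, n_excluded_privacy)
    if any(c < 0 or int(c) != c for c in counts):
        raise CohortFlowError("counts must be non-negative integers")
    if n_excluded_never_married + n_excluded_privacy > n_dv_module:
        raise CohortFlowError("exclusions exceed the violence-module sample")
    if n_dv_module > n_interviewed:
        raise CohortFlowError("module sample exceeds interviewed count")
    n_analytic = n_dv_module - n_excluded_never_married - n_excluded_privacy
    return CohortFlow(
        n_interviewed=int(n_interviewed),
        n_dv_module=int(n_dv_module),
        n_excluded_never_married=int(n_excluded_never_married),
        n_excluded_privacy=int(n_excluded_privacy),
        n_analytic=int(n_analytic),
        pct_dv_of_interviewed=round(100.0 * n_dv_module / n_interviewed, 1),
        pct_never_married=round(100.0 * n_excluded_never_married / n_dv_module, 1),
        pct_privacy=round(100.0 * n_excluded_privacy / n_dv_module, 1),
    )


def weighted_proportion(y, w) -> float:
    """Survey-weighted proportion  sum(w*y) / sum(w)."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.size == 0:
        raise ValueError("no records")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(w * y) / np.sum(w))


def design_variance(y, w, psu) -> float:
    """With-replacement first-stage Taylor-linearised variance of p_hat.

    With m PSUs and PSU score totals z_j = sum_{i in j} w_i (y_i - p_hat),
    var = m/(m-1) * sum_j (z_j - zbar)^2 / (sum_i w_i)^2.  Requires m >= 2.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    psu = np.asarray(psu)
    p_hat = weighted_proportion(y, w)
    codes, _ = pd.factorize(psu)
    m = codes.max() + 1
    if m < 2:
        raise ValueError("design variance requires >= 2 PSUs")
    z = np.bincount(codes, weights=w * (y - p_hat), minlength=m)
    zbar = z.mean()
    return float(m / (m - 1) * np.sum((z - zbar) ** 2) / np.sum(w) ** 2)


def logit_variance(p_hat: float, var_p: float) -> float:
    """Delta-method sampling variance of logit(p_hat): var_p / (p(1-p))^2."""
    if not (0.0 < p_hat < 1.0):
        raise ValueError("psi undefined for p_hat in {0, 1}")
    return float(var_p / (p_hat * (1.0 - p_hat)) ** 2)


def direct_interval(p_hat: float, psi: float, level: float = 0.95) -> tuple[float, float]:
    """Wald interval on the logit scale, back-transformed; stays inside (0,1)."""
    if psi < 0:
        raise ValueError("psi must be >= 0")
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(psi)
    eta = logit(p_hat)
    return float(expit(eta - half)), float(expit(eta + half))


def direct_estimates(
    survey: pd.DataFrame,
    outcome: str,
    level: float = 0.95,
) -> pd.DataFrame:
    """Direct estimates for every sampled district, one row per district.

    Districts with a single PSU or with p_hat in {0, 1} are flagged
    ``usable=False``: their logit-scale sampling variance is undefined, so
    the area-level model treats them as unsampled (they still receive
    synthetic predictions).  CV is reported as NaN when p_hat = 0.
    """
    required = {"district_id", "psu_id", "weight", outcome}
    missing = required - set(survey.columns)
    if missing:
        raise ValueError(f"survey table missing columns {sorted(missing)}")
    rows = []
    for district, g in survey.groupby("district_id", sort=True):
        y = g[outcome].to_numpy(dtype=float)
        w = g["weight"].to_numpy(dtype=float)
        n_psus = g["psu_id"].nunique()
        p_hat = weighted_proportion(y, w)
        row = {
            "district_id": district,
            "outcome_name": outcome,
            "p_hat": p_hat,
            "n_respondents": len(g),
            "n_psus": n_psus,
            "var_p": np.nan,
            "se": np.nan,
            "cv": np.nan,
            "psi": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "usable": False,
        }
        if n_psus >= 2:
            var_p = design_variance(y, w, g["psu_id"].to_numpy())
            row["var_p"] = var_p
            row["se"] = np.sqrt(var_p)
            if p_hat > 0:
                row["cv"] = row["se"] / p_hat
            if 0.0 < p_hat < 1.0:
                psi = logit_variance(p_hat, var_p)
                lo, hi = direct_interval(p_hat, psi, level)
                row.update(psi=psi, ci_low=lo, ci_high=hi, usable=True)
        rows.append(row)
    return pd.DataFrame(rows)
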