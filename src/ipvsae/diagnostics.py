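"""Validity diagnostics for the area-level model and its estimates.

Two families: (i) model diagnostics on standardised logit-scale residuals
(normality by Shapiro-Wilk, homoskedasticity by Breusch-Pagan against the
predicted values); (ii) diagnostics for the small-area estimates themselves —
an OLS regression of direct on model-based estimates compared with the 45
degree line y = x, and per-district precision comparisons (CVs and CI
widths).  Judgement is left to the caller: the functions report statistics
and p-values, they do not decide.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from .areamodel import AreaModelFit, build_design


@dataclass(frozen=True)
class BiasDiagnostic:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    t_slope_vs_1: float
    p_slope_vs_1: float
    t_intercept_vs_0: float
    p_intercept_vs_0: float
    n_districts_used: int

    def to_dict(self) -> dict:
        return asdict(self)


def _matched(direct_table: pd.DataFrame, sae_table: pd.DataFrame) -> pd.DataFrame:
    usable = direct_table[direct_table["usable"]]
    merged = usable.merge(
        sae_table[sae_table["in_sample"]],
        on="district_id",
        suffixes=("_direct", "_model"),
        validate="1:1",
    )
    return merged.sort_values("district_id").reset_index(drop=True)


def residual_diagnostic(
    sae_table: pd.DataFrame,
    direct_table: pd.DataFrame,
    fit_result: AreaModelFit,
    aux_table: pd.DataFrame,
) -> dict:
    """Standardised residuals of the fitted model plus normality and
    homoskedasticity tests.

    residual_d = (logit(p_hat_d) - x_d' beta_hat) / sqrt(sigma2_u_hat + psi_d)
    over in-sample districts; Shapiro-Wilk tests normality, Breusch-Pagan
    (squared residuals against predicted values) tests constant variance.
    """
    usable = direct_table[direct_table["usable"]].merge(
        aux_table, on="district_id", validate="1:1"
    )
    if len(usable) < 10:
        raise ValueError("need at least 10 in-sample districts")
    X, _, _ = build_design(
        usable, fit_result.covariates, fit_result.include_states, fit_result.state_levels
    )
    est = fit_result.estimator
    predicted = est._design(X) @ est.beta_full_
    psi = usable["psi"].to_numpy(dtype=float)
    raw = logit(usable["p_hat"].to_numpy(dtype=float)) - predicted
    resid = raw / np.sqrt(fit_result.sigma2_u_hat + psi)

    if np.allclose(resid, resid[0]):
        shapiro_p = np.nan
        bp_p = np.nan
    else:
        shapiro_p = float(stats.shapiro(resid).pvalue)
        exog = sm.add_constant(predicted)
        bp_p = float(het_breuschpagan(resid, exog)[1])
    table = pd.DataFrame(
        {
            "district_id": usable["district_id"],
            "predicted": predicted,
            "residual": resid,
        }
    )
    return {
        "residuals": table,
        "shapiro_p": shapiro_p,
        "breusch_pagan_p": bp_p,
        "n_districts_used": len(usable),
    }


def bias_regression(
    direct_table: pd.DataFrame, sae_table: pd.DataFrame
) -> BiasDiagnostic:
    """OLS of direct estimates (y) on model-based estimates (x), proportion
    scale, with t-tests of slope = 1 and intercept = 0.

    An unbiased model should give a best-fit line statistically
    indistinguishable from the 45 degree line y = x.  When the fit is exact
    (zero residual variance) the t statistics are 0 and p-values 1 by
    convention.
    """
    m = _matched(direct_table, sae_table)
    if len(m) < 3:
        raise ValueError("need at least 3 matched districts")
    x = m["theta_hat"].to_numpy(dtype=float)
    y = m["p_hat"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("model-based estimates have zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    se_intercept, se_slope = res.bse
    df = res.df_resid

    def t_and_p(estimate: float, null: float, se: float) -> tuple[float, float]:
        if se < 1e-10 or not np.isfinite(se):  # exact fit up to roundoff
            if np.isclose(estimate, null):
                return 0.0, 1.0
            return np.inf, 0.0
        t = (estimate - null) / se
        return float(t), float(2 * stats.t.sf(abs(t), df))

    t_s, p_s = t_and_p(slope, 1.0, se_slope)
    t_i, p_i = t_and_p(intercept, 0.0, se_intercept)
    return BiasDiagnostic(
        slope=float(slope),
        intercept=float(intercept),
        se_slope=float(se_slope),
        se_intercept=float(se_intercept),
        t_slope_vs_1=t_s,
        p_slope_vs_1=p_s,
        t_intercept_vs_0=t_i,
        p_intercept_vs_0=p_i,
        n_districts_used=len(m),
    )


def precision_comparison(
    direct_table: pd.DataFrame, sae_table: pd.DataFrame
) -> dict:
    """Per-district CV and 95% CI-width comparison, direct vs model-based.

    ``share_cv_improved`` is the fraction of matched districts where the
    model-based CV is strictly smaller than the direct CV.
    """
    m = _matched(direct_table, sae_table)
    table = pd.DataFrame(
        {
            "district_id": m["district_id"],
            "cv_direct": m["cv_direct"],
            "cv_model": m["cv_model"],
            "ci_width_direct": m["ci_high_direct"] - m["ci_low_direct"],
            "ci_width_model": m["ci_high_model"] - m["ci_low_model"],
        }
    )
    improved = table["cv_model"] < table["cv_direct"]
    ratio = table["cv_model"] / table["cv_direct"]
    return {
        "per_district": table,
        "share_cv_improved": float(improved.mean()),
        "median_cv_ratio": float(ratio.median()),
        "n_districts_used": len(table),
    }


def state_variation(sae_table: pd.DataFrame, aux_table: pd.DataFrame) -> pd.DataFrame:
    """Per-state coefficient of variation of the model-based estimates.

    CV_s = population SD (divisor n) of theta_hat over the state's districts
    divided by their mean — a descriptive measure of intrastate spread.
    Single-district states report CV = 0 with ``single_district=True``.
    """
    merged = sae_table.merge(
        aux_table[["district_id", "state_id"]], on="district_id", validate="1:1"
    )
    rows = []
    for state, g in merged.groupby("state_id", sort=True):
        theta = g["theta_hat"].to_numpy(dtype=float)
        mean = theta.mean()
        sd = theta.std(ddof=0)
        rows.append(
            {
                "state_id": state,
                "n_districts": len(g),
                "mean_theta": mean,
                "cv": float(sd / mean) if mean > 0 else np.nan,
                "single_district": len(g) == 1,
            }
        )
    return pd.DataFrame(rows)
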