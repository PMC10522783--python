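"""Logit-scale area-level (Fay-Herriot) model and EBLUP small-area estimates.

The model links logit-transformed direct estimates to district auxiliary
covariates:

    logit(p_hat_d) = x_d' beta + u_d + e_d,   u_d ~ N(0, sigma_u^2),
                                              e_d ~ N(0, psi_d),

with the sampling variances psi_d treated as known (delta-method values from
the direct-estimation stage).  beta and sigma_u^2 are estimated by maximum
(or restricted maximum) likelihood via the profile likelihood in sigma_u^2,
with generalised least squares for beta at each candidate variance.  The
EBLUP for a sampled district shrinks the direct estimate towards the
covariate-based synthetic value with factor

    gamma_d = sigma_u^2 / (sigma_u^2 + psi_d);

unsampled districts receive the synthetic value (gamma = 0).  Uncertainty of
the back-transformed prevalence is assessed by a parametric bootstrap.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as scipy_linalg
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted


class AreaModelError(ValueError):
    pass


class LogitFayHerriot(BaseEstimator, RegressorMixin):
    """Area-level random-effects model with known sampling variances.

    Parameters
    ----------
    method : "ml" (default) or "reml".
    fit_intercept : prepend a constant column to the design.
    sigma2_upper_factor : upper bound of the variance search, as a multiple
        of the sample variance of the response.
    xatol : absolute tolerance of the 1-D variance optimisation.

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : GLS coefficients at the optimum.
    sigma2_u_ : area-effect variance estimate (0 allowed: boundary fit).
    se_beta_ : standard errors of (intercept, coef) from the GLS covariance.
    loglik_ : profile log-likelihood at the optimum (ML or REML criterion).
    n_iter_, converged_, boundary_ : optimisation metadata.
    """

    def __init__(
        self,
        method: str = "ml",
        fit_intercept: bool = True,
        sigma2_upper_factor: float = 10.0,
        xatol: float = 1e-10,
    ):
        self.method = method
        self.fit_intercept = fit_intercept
        self.sigma2_upper_factor = sigma2_upper_factor
        self.xatol = xatol

    def _design(self, X: np.ndarray) -> np.ndarray:
        if self.fit_intercept:
            return np.column_stack([np.ones(len(X)), X])
        return X

    @staticmethod
    def _gls(Xd: np.ndarray, y: np.ndarray, v: np.ndarray):
        """GLS beta and its covariance for diagonal variance v."""
        Xw = Xd / v[:, None]
        XtVX = Xd.T @ Xw
        beta = np.linalg.solve(XtVX, Xw.T @ y)
        return beta, XtVX

    def _neg_loglik(self, s2: float, Xd, y, psi) -> float:
        v = s2 + psi
        beta, XtVX = self._gls(Xd, y, v)
        r = y - Xd @ beta
        nll = 0.5 * (np.sum(np.log(v)) + np.sum(r**2 / v))
        if self.method == "reml":
            nll += 0.5 * np.linalg.slogdet(XtVX)[1]
        return float(nll)

    def fit(self, X, y, psi):
        if self.method not in ("ml", "reml"):
            raise AreaModelError(f"unknown method {self.method!r}")
        X = check_array(X, ensure_2d=True, dtype=float, ensure_min_features=0)
        y = np.asarray(y, dtype=float).ravel()
        psi = np.asarray(psi, dtype=float).ravel()
        if len(y) != len(X) or len(psi) != len(X):
            raise AreaModelError("X, y, psi must have matching lengths")
        if np.any(psi < 0) or not np.all(np.isfinite(psi)):
            raise AreaModelError("psi must be finite and non-negative")
        Xd = self._design(X)
        n, p = Xd.shape
        if n < p + 2:
            raise AreaModelError(
                f"need at least {p + 2} areas to fit {p} coefficients"
            )
        if np.linalg.matrix_rank(Xd) < p:
            raise AreaModelError("design matrix is rank deficient")

        upper = max(self.sigma2_upper_factor * float(np.var(y)), 10 * self.xatol)
        res = minimize_scalar(
            self._neg_loglik,
            bounds=(0.0, upper),
            args=(Xd, y, psi),
            method="bounded",
            options={"xatol": self.xatol},
        )
        s2 = float(res.x)
        # the bounded search can stall a hair inside the boundary: accept 0
        # when it is at least as good
        if self._neg_loglik(0.0, Xd, y, psi) <= res.fun + 1e-9:
            s2 = 0.0
        self.boundary_ = s2 == 0.0
        v = s2 + psi
        beta, XtVX = self._gls(Xd, y, v)
        cov_beta = np.linalg.inv(XtVX)

        self.sigma2_u_ = s2
        self.beta_full_ = beta
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        self.se_beta_ = np.sqrt(np.diag(cov_beta))
        self.cov_beta_ = cov_beta
        self.loglik_ = -self._neg_loglik(s2, Xd, y, psi)
        self.n_iter_ = int(res.nfev)
        # converged: boundary fit, or a local minimum of the profile
        # criterion (no neighbouring value beats it beyond roundoff)
        if self.boundary_ or s2 >= upper - 10 * self.xatol:
            self.converged_ = bool(res.success)
        else:
            h = max(1e-7 * (1 + s2), 1e-5 * s2)
            nll_here = self._neg_loglik(s2, Xd, y, psi)
            nll_nb = min(
                self._neg_loglik(s2 + h, Xd, y, psi),
                self._neg_loglik(max(s2 - h, 0.0), Xd, y, psi),
            )
            self.converged_ = bool(res.success) and nll_here <= nll_nb + 1e-6
        self.n_features_in_ = X.shape[1]
        self.psi_ = psi
        return self

    def gamma(self, psi) -> np.ndarray:
        """Shrinkage factor sigma_u^2 / (sigma_u^2 + psi)."""
        check_is_fitted(self, "sigma2_u_")
        psi = np.asarray(psi, dtype=float)
        denom = self.sigma2_u_ + psi
        out = np.zeros_like(psi, dtype=float)
        np.divide(self.sigma2_u_, denom, out=out, where=denom > 0)
        return out

    def predict(self, X, y=None, psi=None) -> np.ndarray:
        """Logit-scale prediction: synthetic x'beta, or the EBLUP when the
        direct estimate y and its variance psi are supplied."""
        check_is_fitted(self, "beta_full_")
        X = check_array(X, ensure_2d=True, dtype=float, ensure_min_features=0)
        eta = self._design(X) @ self.beta_full_
        if y is None:
            return eta
        y = np.asarray(y, dtype=float).ravel()
        g = self.gamma(psi)
        return eta + g * (y - eta)


def expit_mean(eta: np.ndarray, var: np.ndarray, n_nodes: int = 41) -> np.ndarray:
    """E[expit(Z)], Z ~ N(eta, var), by Gauss-Hermite quadrature.

    Bias-corrected back-transformation of logit-scale predictions.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    sd = np.sqrt(np.atleast_1d(np.asarray(var, dtype=float)))
    z = eta[:, None] + np.sqrt(2.0) * sd[:, None] * nodes[None, :]
    return (expit(z) @ weights) / np.sqrt(np.pi)


# ---------------------------------------------------------------------------
# DataFrame-level surface used by the pipeline
# ---------------------------------------------------------------------------

@dataclass
class AreaModelFit:
    """Fitted area-level model plus the design layout needed to predict."""

    outcome_name: str
    covariates: list[str]
    include_states: bool
    state_levels: list[str]
    beta_names: list[str]
    beta_hat: np.ndarray
    se_beta: np.ndarray
    sigma2_u_hat: float
    loglik: float
    n_iterations: int
    converged: bool
    boundary: bool
    n_insample: int
    estimator: LogitFayHerriot = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "covariates": self.covariates,
            "include_states": self.include_states,
            "state_levels": self.state_levels,
            "beta_names": self.beta_names,
            "beta_hat": self.beta_hat.tolist(),
            "se_beta": self.se_beta.tolist(),
            "sigma2_u_hat": self.sigma2_u_hat,
            "loglik": self.loglik,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_insample": self.n_insample,
        }


def build_design(
    aux: pd.DataFrame,
    covariates: list[str],
    include_states: bool,
    state_levels: list[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Design matrix (no intercept column): covariates then state dummies.

    State of residence enters as one-hot fixed effects with the first state
    id in sort order as reference.
    """
    missing = [c for c in covariates if c not in aux.columns]
    if missing:
        raise AreaModelError(f"aux table missing covariates {missing}")
    cols = [aux[c].to_numpy(dtype=float) for c in covariates]
    names = list(covariates)
    levels: list[str] = []
    if include_states:
        if "state_id" not in aux.columns:
            raise AreaModelError("include_states=True needs a state_id column")
        levels = (
            sorted(aux["state_id"].unique()) if state_levels is None else list(state_levels)
        )
        unknown = set(aux["state_id"]) - set(levels)
        if unknown:
            raise AreaModelError(f"unknown state ids {sorted(unknown)}")
        for lev in levels[1:]:
            cols.append((aux["state_id"] == lev).to_numpy(dtype=float))
            names.append(f"state[{lev}]")
    X = np.column_stack(cols) if cols else np.empty((len(aux), 0))
    return X, names, levels


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns involved in a rank deficiency (QR pivot heuristic)."""
    Xd = np.column_stack([np.ones(len(X)), X])
    _, R, piv = scipy_linalg.qr(Xd, pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    bad = piv[diag < 1e-10 * diag.max()]
    return [(["(intercept)"] + names)[j] for j in bad]


def fit(
    direct_estimates: pd.DataFrame,
    aux_table: pd.DataFrame,
    covariates: list[str] | None = None,
    include_states: bool = True,
    method: str = "ml",
) -> AreaModelFit:
    """Fit the logit Fay-Herriot model to usable direct estimates.

    Districts flagged unusable (single PSU or degenerate p_hat) are treated
    as unsampled and excluded from fitting.
    """
    if covariates is None:
        covariates = [
            c for c in aux_table.columns if c not in ("district_id", "state_id")
        ]
    usable = direct_estimates[direct_estimates["usable"]].copy()
    missing = set(usable["district_id"]) - set(aux_table["district_id"])
    if missing:
        raise AreaModelError(
            f"districts in direct estimates but not in aux: {sorted(missing)}"
        )
    merged = usable.merge(aux_table, on="district_id", validate="1:1")
    X, names, levels = build_design(merged, covariates, include_states)
    y = logit(merged["p_hat"].to_numpy(dtype=float))
    psi = merged["psi"].to_numpy(dtype=float)

    Xd = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise AreaModelError(
            f"rank-deficient design; collinear columns: {_collinear_columns(X, names)}"
        )
    est = LogitFayHerriot(method=method).fit(X, y, psi)
    outcome = (
        str(direct_estimates["outcome_name"].iloc[0])
        if "outcome_name" in direct_estimates.columns
        else "y"
    )
    return AreaModelFit(
        outcome_name=outcome,
        covariates=list(covariates),
        include_states=include_states,
        state_levels=levels,
        beta_names=["(intercept)"] + names,
        beta_hat=est.beta_full_.copy(),
        se_beta=est.se_beta_.copy(),
        sigma2_u_hat=est.sigma2_u_,
        loglik=est.loglik_,
        n_iterations=est.n_iter_,
        converged=est.converged_,
        boundary=est.boundary_,
        n_insample=len(merged),
        estimator=est,
    )


def predict(
    fit_result: AreaModelFit,
    direct_estimates: pd.DataFrame,
    aux_table: pd.DataFrame,
    back_transform: str = "naive",
) -> pd.DataFrame:
    """EBLUP predictions for every district in the aux table.

    In-sample districts get the shrinkage combination of direct and synthetic
    logit estimates; the rest get the synthetic value with gamma = 0.
    ``back_transform='naive'`` applies plain expit; ``'bias_corrected'``
    integrates expit over the bootstrap MSE (only meaningful after
    mse_bootstrap, which re-applies it).
    """
    if back_transform not in ("naive", "bias_corrected"):
        raise AreaModelError(f"unknown back_transform {back_transform!r}")
    est = fit_result.estimator
    aux = aux_table.reset_index(drop=True)
    X, _, _ = build_design(
        aux, fit_result.covariates, fit_result.include_states, fit_result.state_levels
    )
    synth_eta = est._design(X) @ est.beta_full_

    usable = direct_estimates[direct_estimates["usable"]]
    missing = set(usable["district_id"]) - set(aux["district_id"])
    if missing:
        raise AreaModelError(
            f"districts in direct estimates but not in aux: {sorted(missing)}"
        )
    dmap = usable.set_index("district_id")
    eta = synth_eta.copy()
    gamma = np.zeros(len(aux))
    in_sample = aux["district_id"].isin(dmap.index).to_numpy()
    for k, district in enumerate(aux["district_id"]):
        if in_sample[k]:
            psi_d = float(dmap.loc[district, "psi"])
            g = float(est.gamma(psi_d))
            gamma[k] = g
            eta[k] = synth_eta[k] + g * (
                logit(float(dmap.loc[district, "p_hat"])) - synth_eta[k]
            )
    out = pd.DataFrame(
        {
            "district_id": aux["district_id"],
            "outcome_name": fit_result.outcome_name,
            "eta_hat": eta,
            "theta_hat": expit(eta),
            "gamma": gamma,
            "in_sample": in_sample,
            "mse_eta": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "cv": np.nan,
        }
    )
    out.attrs["back_transform"] = back_transform
    return out


def mse_bootstrap(
    fit_result: AreaModelFit,
    direct_estimates: pd.DataFrame,
    aux_table: pd.DataFrame,
    B: int = 200,
    seed: int = 0,
    level: float = 0.95,
    back_transform: str = "naive",
    max_failure_rate: float = 0.10,
) -> pd.DataFrame:
    """Parametric-bootstrap MSE, CI and CV for the EBLUP predictions.

    For each replicate, area effects and sampling errors are redrawn from the
    fitted model (u* ~ N(0, sigma2_hat) for all districts, e* ~ N(0, psi_d)
    for sampled ones), the model is refitted, and the squared logit-scale
    prediction error against the replicate's own truth x'beta_hat + u* is
    accumulated.  CIs are Wald on the logit scale with the bootstrap MSE; CV
    is the delta-method root-MSE on the proportion scale over theta_hat.
    """
    if B < 50:
        raise AreaModelError("B must be >= 50")
    if not fit_result.converged:
        raise AreaModelError("refusing to bootstrap a non-converged fit")
    est = fit_result.estimator
    aux = aux_table.reset_index(drop=True)
    preds = predict(fit_result, direct_estimates, aux)
    X, _, _ = build_design(
        aux, fit_result.covariates, fit_result.include_states, fit_result.state_levels
    )
    synth_eta = est._design(X) @ est.beta_full_
    in_sample = preds["in_sample"].to_numpy()
    usable = (
        direct_estimates[direct_estimates["usable"]]
        .set_index("district_id")
        .reindex(aux["district_id"][in_sample])
    )
    psi_in = usable["psi"].to_numpy(dtype=float)
    s2 = fit_result.sigma2_u_hat
    rng = np.random.default_rng(seed)

    n_all = len(aux)
    sq_err = np.zeros(n_all)
    failures = 0
    done = 0
    for _ in range(B):
        u_star = rng.normal(0.0, np.sqrt(s2), size=n_all) if s2 > 0 else np.zeros(n_all)
        e_star = rng.normal(0.0, np.sqrt(psi_in))
        y_star = synth_eta[in_sample] + u_star[in_sample] + e_star
        try:
            refit = LogitFayHerriot(
                method=est.method, sigma2_upper_factor=est.sigma2_upper_factor
            ).fit(X[in_sample], y_star, psi_in)
        except (np.linalg.LinAlgError, AreaModelError):
            failures += 1
            continue
        eta_star = refit._design(X) @ refit.beta_full_
        g_star = refit.gamma(psi_in)
        eta_star[in_sample] += g_star * (y_star - eta_star[in_sample])
        truth_star = synth_eta + u_star
        sq_err += (eta_star - truth_star) ** 2
        done += 1
    if failures > max_failure_rate * B:
        raise AreaModelError(
            f"bootstrap refit failed in {failures}/{B} replicates"
        )
    mse = sq_err / done
    z = norm.ppf(0.5 + level / 2)
    eta_hat = preds["eta_hat"].to_numpy()
    half = z * np.sqrt(mse)
    out = preds.copy()
    out["mse_eta"] = mse
    out["ci_low"] = expit(eta_hat - half)
    out["ci_high"] = expit(eta_hat + half)
    if back_transform == "bias_corrected":
        out["theta_hat"] = expit_mean(eta_hat, mse)
    theta = out["theta_hat"].to_numpy()
    # delta method: root-MSE on the proportion scale divided by theta
    out["cv"] = np.sqrt(mse) * theta * (1 - theta) / theta
    out.attrs["bootstrap_failures"] = failures
    out.attrs["B"] = B
    return out
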