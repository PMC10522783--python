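"""Area-level model tests: closed-form ML in the balanced case, boundary
behaviour, EBLUP shrinkage algebra, and the parametric-bootstrap MSE against
the analytic leading term."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ipvsae.areamodel import (
    AreaModelError,
    LogitFayHerriot,
    build_design,
    expit_mean,
    fit as fit_area,
    mse_bootstrap,
    predict as predict_area,
)


def balanced_sample(n=60, beta0=-1.0, sigma_u=0.4, psi=0.05, seed=0):
    rng = np.random.default_rng(seed)
    y = beta0 + rng.normal(0, sigma_u, n) + rng.normal(0, np.sqrt(psi), n)
    return y, np.full(n, psi)


class TestLogitFayHerriot:
    def test_intercept_only_closed_form(self):
        """Balanced intercept-only ML: beta0 = mean(y) and
        sigma2 = max(0, biased sample variance - psi), verified against a
        grid search of the likelihood."""
        y, psi = balanced_sample(seed=3)
        est = LogitFayHerriot().fit(np.empty((len(y), 0)), y, psi)
        expected_s2 = max(0.0, np.var(y) - psi[0])
        assert est.intercept_ == pytest.approx(y.mean(), abs=1e-8)
        assert est.sigma2_u_ == pytest.approx(expected_s2, abs=1e-6)
        # grid search over (beta0, sigma2) never beats the optimum
        best = -np.inf
        for b0 in np.linspace(y.mean() - 0.2, y.mean() + 0.2, 41):
            for s2 in np.linspace(0, 1.0, 201):
                v = s2 + psi
                ll = -0.5 * (np.sum(np.log(v)) + np.sum((y - b0) ** 2 / v))
                best = max(best, ll)
        assert est.loglik_ >= best - 1e-6

    def test_null_variance_boundary_fit(self):
        """Data generated with sigma_u = 0: the fit hits the boundary in a
        majority of seeds."""
        boundary = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, psi = 80, 0.05
            y = -1.0 + rng.normal(0, np.sqrt(psi), n)
            est = LogitFayHerriot().fit(np.empty((n, 0)), y, np.full(n, psi))
            boundary += est.boundary_
        assert boundary > 10

    def test_reml_shrinks_less_than_ml(self):
        rng = np.random.default_rng(1)
        n = 40
        X = rng.normal(size=(n, 2))
        y = 0.5 + X @ [1.0, -0.5] + rng.normal(0, 0.3, n) + rng.normal(0, 0.2, n)
        psi = np.full(n, 0.04)
        ml = LogitFayHerriot(method="ml").fit(X, y, psi)
        reml = LogitFayHerriot(method="reml").fit(X, y, psi)
        assert reml.sigma2_u_ >= ml.sigma2_u_
        assert ml.converged_ and reml.converged_

    def test_too_few_areas_rejected(self):
        with pytest.raises(AreaModelError):
            LogitFayHerriot().fit(np.zeros((3, 2)), np.zeros(3), np.ones(3))

    def test_rank_deficiency_rejected(self):
        X = np.ones((20, 1))  # duplicates the intercept
        with pytest.raises(AreaModelError):
            LogitFayHerriot().fit(X, np.random.default_rng(0).normal(size=20), np.ones(20))

    def test_sklearn_param_interface(self):
        est = LogitFayHerriot(method="reml")
        assert est.get_params()["method"] == "reml"
        est.set_params(method="ml")
        assert est.method == "ml"


class TestEblup:
    @staticmethod
    def _manual(sigma2, beta):
        est = LogitFayHerriot()
        est.sigma2_u_ = sigma2
        est.beta_full_ = np.asarray(beta, dtype=float)
        est.intercept_ = float(beta[0])
        est.coef_ = np.asarray(beta[1:], dtype=float)
        return est

    def test_midpoint_arithmetic(self):
        """gamma = 0.5, direct logit 0, synthetic 2 -> eta 1, theta expit(1)."""
        est = self._manual(1.0, [2.0])  # intercept-only synthetic value 2
        eta = est.predict(np.empty((1, 0)), y=[0.0], psi=[1.0])  # gamma = 1/(1+1)
        assert eta[0] == pytest.approx(1.0, abs=1e-12)
        assert expit(eta[0]) == pytest.approx(0.7310586, abs=1e-6)

    def test_shrinkage_limits(self):
        est = self._manual(0.5, [1.0, 2.0])
        X = np.array([[0.3]])
        synth = 1.0 + 2.0 * 0.3
        # psi -> 0: EBLUP -> direct
        assert est.predict(X, y=[0.0], psi=[1e-12])[0] == pytest.approx(0.0, abs=1e-9)
        # sigma2 = 0: EBLUP -> synthetic
        est0 = self._manual(0.0, [1.0, 2.0])
        assert est0.predict(X, y=[0.0], psi=[0.05])[0] == pytest.approx(synth)

    def test_shrinkage_monotone_in_psi(self):
        est = self._manual(0.3, [0.0])
        y, synth = [1.0], 0.0
        etas = [est.predict(np.empty((1, 0)), y=y, psi=[p])[0] for p in (0.01, 0.1, 1.0)]
        # larger psi pulls the prediction towards the synthetic value 0
        assert etas[0] > etas[1] > etas[2] > synth

    def test_eblup_between_direct_and_synthetic(self):
        rng = np.random.default_rng(2)
        n = 50
        X = rng.normal(size=(n, 1))
        psi = np.full(n, 0.05)
        y = -1 + 0.8 * X[:, 0] + rng.normal(0, 0.3, n) + rng.normal(0, np.sqrt(psi))
        est = LogitFayHerriot().fit(X, y, psi)
        synth = est._design(X) @ est.beta_full_
        eta = est.predict(X, y=y, psi=psi)
        lo = np.minimum(synth, y) - 1e-12
        hi = np.maximum(synth, y) + 1e-12
        assert ((eta >= lo) & (eta <= hi)).all()


def _frame_pair(n=60, seed=0, p_covs=1):
    """direct-estimate + aux tables generated exactly from the model."""
    rng = np.random.default_rng(seed)
    aux = pd.DataFrame(
        {
            "district_id": [f"D{k:03d}" for k in range(n)],
            "state_id": ["S1"] * (n // 2) + ["S2"] * (n - n // 2),
            "x1": rng.normal(0.5, 0.8, n),
        }
    )
    psi = np.full(n, 0.05)
    eta = -1.0 + 0.9 * aux["x1"].to_numpy() + rng.normal(0, 0.3, n)
    y = eta + rng.normal(0, np.sqrt(psi))
    dt = pd.DataFrame(
        {
            "district_id": aux["district_id"],
            "outcome_name": "y",
            "p_hat": expit(y),
            "psi": psi,
            "cv": 0.1,
            "ci_low": expit(y) - 0.02,
            "ci_high": expit(y) + 0.02,
            "usable": True,
        }
    )
    return dt, aux


class TestTableSurface:
    def test_every_district_predicted_once(self):
        dt, aux = _frame_pair()
        # leave 5 districts unsampled
        dt.loc[dt.index[-5:], "usable"] = False
        fit = fit_area(dt, aux, covariates=["x1"], include_states=True)
        out = predict_area(fit, dt, aux)
        assert len(out) == len(aux)
        assert out["in_sample"].sum() == len(aux) - 5
        assert (out.loc[~out["in_sample"], "gamma"] == 0).all()
        synth_rows = out[~out["in_sample"]]
        X, _, _ = build_design(
            aux[~out["in_sample"].to_numpy()], ["x1"], True, fit.state_levels
        )
        expected = fit.estimator._design(X) @ fit.beta_hat
        assert np.allclose(synth_rows["eta_hat"], expected)

    def test_missing_aux_district_named(self):
        dt, aux = _frame_pair()
        with pytest.raises(AreaModelError, match="D000"):
            fit_area(dt, aux.iloc[1:], covariates=["x1"])

    def test_collinear_columns_reported(self):
        dt, aux = _frame_pair()
        aux["x2"] = 2 * aux["x1"]
        with pytest.raises(AreaModelError, match="collinear"):
            fit_area(dt, aux, covariates=["x1", "x2"])


class TestMseBootstrap:
    def test_deterministic_given_seed(self):
        dt, aux = _frame_pair(seed=4)
        fit = fit_area(dt, aux, covariates=["x1"], include_states=False)
        a = mse_bootstrap(fit, dt, aux, B=60, seed=11)
        b = mse_bootstrap(fit, dt, aux, B=60, seed=11)
        assert np.array_equal(a["mse_eta"], b["mse_eta"])
        c = mse_bootstrap(fit, dt, aux, B=60, seed=12)
        assert not np.array_equal(a["mse_eta"], c["mse_eta"])

    def test_vanishing_uncertainty_limit(self):
        """sigma2 = 0 and psi -> 0: bootstrap MSE -> 0."""
        rng = np.random.default_rng(0)
        n = 40
        aux = pd.DataFrame(
            {"district_id": [f"D{k}" for k in range(n)], "state_id": "S1",
             "x1": rng.normal(size=n)}
        )
        psi = np.full(n, 1e-8)
        y = 0.2 + 0.5 * aux["x1"].to_numpy() + rng.normal(0, 1e-4, n)
        dt = pd.DataFrame(
            {"district_id": aux["district_id"], "outcome_name": "y",
             "p_hat": expit(y), "psi": psi, "usable": True}
        )
        fit = fit_area(dt, aux, covariates=["x1"], include_states=False)
        out = mse_bootstrap(fit, dt, aux, B=60, seed=1)
        assert (out["mse_eta"] < 1e-4).all()

    def test_prasad_rao_leading_term(self):
        """Balanced intercept-only model: bootstrap MSE within 15% of the
        leading term gamma * psi."""
        rng = np.random.default_rng(9)
        n, sigma_u, psi_val = 100, 0.4, 0.05
        aux = pd.DataFrame(
            {"district_id": [f"D{k:03d}" for k in range(n)], "state_id": "S1"}
        )
        y = -1.0 + rng.normal(0, sigma_u, n) + rng.normal(0, np.sqrt(psi_val), n)
        dt = pd.DataFrame(
            {"district_id": aux["district_id"], "outcome_name": "y",
             "p_hat": expit(y), "psi": psi_val, "usable": True}
        )
        fit = fit_area(dt, aux, covariates=[], include_states=False)
        out = mse_bootstrap(fit, dt, aux, B=500, seed=2)
        gamma = fit.sigma2_u_hat / (fit.sigma2_u_hat + psi_val)
        leading = gamma * psi_val
        assert abs(out["mse_eta"].mean() / leading - 1) < 0.15

    def test_ci_contains_point_estimate(self):
        dt, aux = _frame_pair(seed=6)
        fit = fit_area(dt, aux, covariates=["x1"], include_states=False)
        out = mse_bootstrap(fit, dt, aux, B=60, seed=3)
        assert ((out["ci_low"] <= out["theta_hat"]) & (out["theta_hat"] <= out["ci_high"])).all()
        assert out[["ci_low", "theta_hat", "ci_high"]].gt(0).all().all()
        assert out[["ci_low", "theta_hat", "ci_high"]].lt(1).all().all()


class TestBackTransform:
    def test_gauss_hermite_matches_numerical_integral(self):
        from scipy.integrate import quad
        from scipy.stats import norm as normal

        eta, var = 0.7, 0.3
        num, _ = quad(lambda z: expit(z) * normal.pdf(z, eta, np.sqrt(var)), -10, 10)
        assert expit_mean([eta], [var])[0] == pytest.approx(num, abs=1e-10)

    def test_zero_variance_reduces_to_expit(self):
        assert expit_mean([1.3], [0.0])[0] == pytest.approx(expit(1.3), abs=1e-12)
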