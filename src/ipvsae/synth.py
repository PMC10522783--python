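"""Synthetic geography, auxiliary covariates, truth, and survey sample.

Emulates the data structure of a district-level prevalence study: census-style
auxiliary proportions per district, a true prevalence surface following a
logit-linear model with Normal district effects, and a two-stage cluster
sample (PSUs within districts, one responding woman per household in a
Bernoulli-subsampled set of households) with unequal design weights.
Everything is deterministic given the config, including its seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .config import OUTCOME_OFFSETS, ConfigurationError, SynthConfig, stage_seed
from . import geometry

#: census-style auxiliary covariates and the range each occupies after the
#: Gaussian-copula transform.  Proportions stay inside [0, 1]; household size
#: and age at marriage are on their natural scales.
COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "sc_st_share": (0.05, 0.55),
    "hindu_share": (0.40, 0.95),
    "female_work_participation": (0.10, 0.50),
    "work_sex_gap": (0.20, 0.60),
    "female_literacy": (0.30, 0.90),
    "literacy_sex_gap": (0.05, 0.30),
    "female_head_share": (0.05, 0.25),
    "mean_household_size": (3.5, 6.5),
    "male_outmigration": (0.02, 0.30),
    "female_age_at_marriage": (17.0, 23.0),
    "male_birth_share": (0.05, 0.20),
    "sex_ratio_at_birth": (0.50, 0.56),
    "urban_share": (0.05, 0.80),
    "ses_index": (0.10, 0.90),
}


@dataclass(frozen=True)
class TrueParams:
    """True generative quantities, kept for recovery experiments."""

    district_id: tuple[str, ...]
    theta_true: np.ndarray  # prevalence of the primary outcome, in (0,1)
    u_true: np.ndarray  # district random effect, logit scale
    eta_true: np.ndarray  # x_d . beta + u_d
    beta_true: tuple[float, ...]
    sigma_u_true: float

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "district_id": list(self.district_id),
                "theta_true": self.theta_true,
                "u_true": self.u_true,
            }
        )
        for outcome, offset in OUTCOME_OFFSETS.items():
            df[f"theta_true_{outcome[2:]}"] = expit(self.eta_true + offset)
        return df


def _block_shape(k: int) -> tuple[int, int]:
    """Rows x cols of a state's district block: the most square divisor pair."""
    rows = max(d for d in range(1, int(np.sqrt(k)) + 1) if k % d == 0)
    return rows, k // rows


def generate_geography(
    n_states: int,
    districts_per_state: int | Sequence[int],
    seed: int = 0,
) -> dict:
    """Grid geography: one rectangular block of districts per state.

    Returns a GeoJSON feature collection of rectangular district polygons
    tiling a rectangle.  Each state occupies a contiguous block (rows x cols
    of district cells, chosen as square as the count allows) and blocks are
    stacked vertically, so the queen contiguity graph is connected,
    interstate borders are well defined, and the border proximity factor
    varies *within* states (districts deep inside a block sit further from
    the interstate border than districts on its rim).
    """
    if n_states < 1:
        raise ConfigurationError("n_states must be >= 1")
    if isinstance(districts_per_state, int):
        counts = [districts_per_state] * n_states
    else:
        counts = [int(c) for c in districts_per_state]
        if len(counts) != n_states:
            raise ConfigurationError("districts_per_state list must match n_states")
    if any(c < 1 for c in counts):
        raise ConfigurationError("district counts must be >= 1")
    if sum(counts) < 4:
        raise ConfigurationError("need at least 4 districts")

    shapes = [_block_shape(k) for k in counts]
    width = float(max(c for _, c in shapes))
    features = []
    d = 0
    y_base = 0.0
    for s, (count, (n_rows, n_cols)) in enumerate(zip(counts, shapes)):
        cell_w = width / n_cols
        for i in range(n_rows):
            y0, y1 = y_base + i, y_base + i + 1
            for j in range(n_cols):
                d += 1
                x0, x1 = j * cell_w, (j + 1) * cell_w
                features.append(
                    {
                        "type": "Feature",
                        "properties": {
                            "district_id": f"D{d:03d}",
                            "state_id": f"S{s + 1}",
                        },
                        "geometry": {
                            "type": "Polygon",
                            "coordinates": [
                                [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                            ],
                        },
                    }
                )
        y_base += n_rows
    return {"type": "FeatureCollection", "features": features}


def _exponential_field(
    centroids: np.ndarray, spatial_range: float, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Draw `size` Gaussian random fields with exp(-d/range) correlation."""
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    cov = np.exp(-d / spatial_range)
    cov[np.diag_indices_from(cov)] += 1e-8
    chol = np.linalg.cholesky(cov)
    return (chol @ rng.standard_normal((len(centroids), size))).T


def generate_auxiliary(
    geography: dict,
    spatial_range: float,
    seed: int = 0,
    max_attempts: int = 5,
) -> pd.DataFrame:
    """District auxiliary table with spatially autocorrelated covariates.

    Each covariate is a monotone transform (Gaussian copula to the range in
    ``COVARIATE_RANGES``) of a smooth Gaussian random field over district
    centroids with correlation exp(-d / spatial_range), so that spatially
    clustered prevalence surfaces — and hence LISA clusters — exist.  The
    border proximity factor (mean distance of the district boundary to its
    state's interstate border) is appended as column ``bpf``.
    """
    if spatial_range <= 0:
        raise ConfigurationError("spatial_range must be > 0")
    ids, states, polys = geometry.parse_geography(geography)
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    names = list(COVARIATE_RANGES)

    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed + attempt * 10_007) % (2**31 - 1))
        fields = _exponential_field(centroids, spatial_range, rng, len(names))
        data = {"district_id": ids, "state_id": states}
        for name, g in zip(names, fields):
            lo, hi = COVARIATE_RANGES[name]
            data[name] = lo + (hi - lo) * norm.cdf(g)
        aux = pd.DataFrame(data)
        X = np.column_stack([np.ones(len(aux)), aux[names].to_numpy()])
        # full column rank whenever the district count allows it
        if np.linalg.matrix_rank(X) == min(X.shape):
            break
    else:
        raise ConfigurationError(
            f"covariate matrix rank-deficient after {max_attempts} attempts"
        )

    bpf = geometry.compute_bpf(
        geography, include_outer_frame=(len(set(states)) == 1)
    )
    aux = aux.merge(bpf[["district_id", "bpf"]], on="district_id", validate="1:1")
    return aux


def generate_truth(
    aux_table: pd.DataFrame,
    beta_true: Sequence[float],
    sigma_u_true: float,
    seed: int = 0,
    covariates: Sequence[str] | None = None,
) -> TrueParams:
    """True prevalences from the logit-linear linking model.

    logit(theta_d) = x_d . beta + u_d with u_d ~ iid N(0, sigma_u^2); the
    identity holds exactly per district, by construction.
    """
    if sigma_u_true < 0:
        raise ConfigurationError("sigma_u_true must be >= 0")
    beta = np.asarray(beta_true, dtype=float)
    if covariates is None:
        candidates = [c for c in aux_table.columns if c not in ("district_id", "state_id")]
        covariates = candidates[: len(beta) - 1]
    covariates = list(covariates)
    if len(beta) != len(covariates) + 1:
        raise ConfigurationError(
            f"beta_true has {len(beta)} entries, expected {len(covariates) + 1}"
        )
    X = np.column_stack(
        [np.ones(len(aux_table)), aux_table[covariates].to_numpy(dtype=float)]
    )
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma_u_true, size=len(aux_table))
    eta = X @ beta + u
    return TrueParams(
        district_id=tuple(aux_table["district_id"]),
        theta_true=expit(eta),
        u_true=u,
        eta_true=eta,
        beta_true=tuple(beta),
        sigma_u_true=float(sigma_u_true),
    )


def sample_survey(true_params: TrueParams, config: SynthConfig) -> pd.DataFrame:
    """Two-stage weighted survey sample with known truth.

    Per district: ``psus_per_district`` PSUs of ``households_per_psu``
    households; each household independently enters the violence-module
    subsample with probability ``dv_subsample_fraction`` and then contributes
    exactly one respondent.  Outcomes are Bernoulli with a mild multiplicative
    PSU effect on the probability scale (clipped to (0,1)), which induces
    design effects above 1 without moving the district-level estimand.
    Design weights are log-normal with the configured coefficient of
    variation, renormalised to mean 1 within each district.
    """
    expected = (
        config.psus_per_district
        * config.households_per_psu
        * config.dv_subsample_fraction
    )
    if expected < 2:
        raise ConfigurationError("expected respondents per district < 2")

    rng = np.random.default_rng(stage_seed(config.seed, "survey"))
    cv = config.weight_dispersion
    sigma_w = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0

    rows: dict[str, list] = {
        "respondent_id": [],
        "district_id": [],
        "psu_id": [],
        "weight": [],
    }
    outcome_cols: dict[str, list] = {name: [] for name in OUTCOME_OFFSETS}
    rid = 0
    for d, district in enumerate(true_params.district_id):
        eta_d = true_params.eta_true[d]
        n_resp_district = 0
        weights_district: list[float] = []
        for p in range(config.psus_per_district):
            m_psu = (
                float(np.exp(rng.normal(0.0, config.psu_effect_sd)))
                if config.psu_effect_sd > 0
                else 1.0
            )
            selected = (
                rng.random(config.households_per_psu) < config.dv_subsample_fraction
            )
            n_resp = int(selected.sum())
            if n_resp == 0:
                continue
            for name, offset in OUTCOME_OFFSETS.items():
                prob = np.clip(expit(eta_d + offset) * m_psu, 1e-9, 1 - 1e-9)
                outcome_cols[name].extend(
                    (rng.random(n_resp) < prob).astype(int).tolist()
                )
            if sigma_w > 0:
                w = np.exp(rng.normal(-0.5 * sigma_w**2, sigma_w, size=n_resp))
            else:
                w = np.ones(n_resp)
            weights_district.extend(w.tolist())
            rows["district_id"].extend([district] * n_resp)
            rows["psu_id"].extend([f"{district}-P{p + 1:03d}"] * n_resp)
            rows["respondent_id"].extend(
                f"R{rid + k + 1:07d}" for k in range(n_resp)
            )
            rid += n_resp
            n_resp_district += n_resp
        if n_resp_district:
            w = np.asarray(weights_district)
            rows["weight"].extend((w / w.mean()).tolist())

    df = pd.DataFrame(rows)
    for name in OUTCOME_OFFSETS:
        df[name] = np.asarray(outcome_cols[name], dtype=int)
    return df


def generate_all(config: SynthConfig) -> dict:
    """Run geography → auxiliary → truth → survey from one config.

    Returns a dict with keys ``geography`` (GeoJSON dict), ``aux``
    (DataFrame), ``truth`` (TrueParams), ``survey`` (DataFrame).
    """
    geo = generate_geography(
        config.n_states, config.districts_per_state, stage_seed(config.seed, "geography")
    )
    aux = generate_auxiliary(
        geo, config.spatial_range, stage_seed(config.seed, "auxiliary")
    )
    truth = generate_truth(
        aux,
        config.beta_true,
        config.sigma_u_true,
        stage_seed(config.seed, "truth"),
        covariates=config.covariates,
    )
    survey = sample_survey(truth, config)
    return {"geography": geo, "aux": aux, "truth": truth, "survey": survey}
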