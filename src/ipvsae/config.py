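"""Configuration for the synthetic study generator and pipeline runs.

The generator emulates the statistical structure the analysis assumes: a
two-stage cluster sample (PSUs within districts, one responding woman per
selected household) drawn from districts whose true prevalence follows a
logit-linear model in census-style auxiliary covariates plus a Normal
district random effect.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence


class ConfigurationError(ValueError):
    """Raised when generator or pipeline configuration is invalid."""


#: outcome columns emitted by the survey generator, with the logit offset
#: applied to the linear predictor for each.  The primary outcome (physical
#: IPV) carries offset 0 so that ``theta_true`` is its exact prevalence;
#: emotional and sexual IPV share the same spatial pattern at lower levels,
#: mirroring the ordering of 12-month prevalences seen in national surveys.
OUTCOME_OFFSETS: dict[str, float] = {
    "y_physical": 0.0,
    "y_emotional": -0.85,
    "y_sexual": -1.7,
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic geography, truth, and survey sample.

    Attributes
    ----------
    n_states : number of states; each state is a contiguous block of districts.
    districts_per_state : districts in every state (int) or one entry per state.
    psus_per_district : primary sampling units (clusters) sampled per district.
    households_per_psu : households listed per PSU.
    dv_subsample_fraction : probability a household enters the violence module
        subsample; one woman responds per selected household (default 0.15).
    beta_true : logit-scale coefficients (intercept first) of the linking
        model for the primary outcome.
    covariates : auxiliary columns entering the linking model, aligned with
        ``beta_true[1:]``.
    sigma_u_true : SD of the district random effect on the logit scale.
    spatial_range : correlation length (map units) of the Gaussian fields
        behind the covariates; larger values give smoother, more clustered maps.
    weight_dispersion : coefficient of variation of design weights within a
        district (0 gives self-weighting, all weights 1).
    psu_effect_sd : SD of the log multiplicative PSU effect on outcome
        probabilities; induces design effects > 1.
    seed : master seed; identical configs reproduce byte-identical outputs.
    """

    n_states: int = 6
    districts_per_state: int | Sequence[int] = 6
    psus_per_district: int = 10
    households_per_psu: int = 100
    dv_subsample_fraction: float = 0.15
    beta_true: tuple[float, ...] = (0.5, -4.0, 2.0)
    covariates: tuple[str, ...] = ("female_literacy", "sc_st_share")
    sigma_u_true: float = 0.15
    spatial_range: float = 3.0
    weight_dispersion: float = 0.3
    psu_effect_sd: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ConfigurationError("n_states must be >= 1")
        counts = self.district_counts()
        if any(c < 1 for c in counts):
            raise ConfigurationError("districts_per_state entries must be >= 1")
        if sum(counts) < 4:
            raise ConfigurationError("need at least 4 districts in total")
        if self.psus_per_district < 1 or self.households_per_psu < 1:
            raise ConfigurationError("PSU and household counts must be >= 1")
        if not (0.0 < self.dv_subsample_fraction <= 1.0):
            raise ConfigurationError("dv_subsample_fraction must be in (0, 1]")
        if self.sigma_u_true < 0:
            raise ConfigurationError("sigma_u_true must be >= 0")
        if self.spatial_range <= 0:
            raise ConfigurationError("spatial_range must be > 0")
        if self.weight_dispersion < 0:
            raise ConfigurationError("weight_dispersion must be >= 0")
        if len(self.beta_true) != len(self.covariates) + 1:
            raise ConfigurationError(
                f"beta_true has {len(self.beta_true)} entries but needs "
                f"{len(self.covariates) + 1} (intercept + covariates)"
            )
        expected = (
            self.psus_per_district
            * self.households_per_psu
            * self.dv_subsample_fraction
        )
        if expected < 2:
            raise ConfigurationError(
                "expected respondents per district < 2; design variance "
                "estimation is impossible"
            )
        # normalise sequence fields to tuples so the config hashes stably
        object.__setattr__(self, "beta_true", tuple(float(b) for b in self.beta_true))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if not isinstance(self.districts_per_state, int):
            object.__setattr__(
                self, "districts_per_state", tuple(int(c) for c in self.districts_per_state)
            )

    def district_counts(self) -> list[int]:
        """Districts per state as a list of length ``n_states``."""
        if isinstance(self.districts_per_state, int):
            return [self.districts_per_state] * self.n_states
        counts = list(self.districts_per_state)
        if len(counts) != self.n_states:
            raise ConfigurationError(
                "districts_per_state list length must equal n_states"
            )
        return counts

    @property
    def n_districts(self) -> int:
        return sum(self.district_counts())

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("beta_true", "covariates"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("districts_per_state"), list):
            d["districts_per_state"] = tuple(d["districts_per_state"])
        return cls(**d)

    @classmethod
    def from_json(cls, path_or_text: str) -> "SynthConfig":
        text = path_or_text
        if not text.lstrip().startswith("{"):
            with open(path_or_text) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed by a fixed offset.

    Keeps stages isolated (re-running one stage from saved intermediates
    reproduces the pipeline's output) while the whole run stays reproducible
    from a single integer.
    """
    offsets = {
        "geography": 1,
        "auxiliary": 2,
        "truth": 3,
        "survey": 4,
        "bootstrap": 5,
        "lisa": 6,
    }
    if stage not in offsets:
        raise KeyError(f"unknown stage {stage!r}")
    return (int(master_seed) * 7 + offsets[stage]) % (2**31 - 1)
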