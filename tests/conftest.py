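"""Shared fixtures: synthetic study data and the heavier Monte-Carlo runs.

The expensive experiments (parameter recovery, diagnostic calibration) are
session-scoped so every test file shares one computation.
"""
from __future__ import annotations

import pytest

from ipvsae import SynthConfig, synth
from ipvsae.pipeline import diagnostic_calibration, recovery_experiment

#: generator defaults = the default study conditions (36 districts, 6 states,
#: ~150 expected respondents per district)
DEMO_CONFIG = SynthConfig()

#: 100-district configuration used by the Monte-Carlo recovery experiment:
#: 5 states x 20 districts, ~150 expected respondents per district, moderate
#: covariate effects and area-effect SD 0.3
RECOVERY_CONFIG = SynthConfig(
    n_states=5,
    districts_per_state=20,
    beta_true=(-1.2, 0.8, -0.5),
    sigma_u_true=0.3,
    seed=7,
)

#: default study conditions at the 100-district scale (for calibration runs)
CALIBRATION_CONFIG = SynthConfig(n_states=5, districts_per_state=20, seed=11)


def grid_geojson(n_rows: int, n_cols: int, state_of=None) -> dict:
    """Unit-square grid geography for hand-checkable fixtures.

    ``state_of(row, col)`` maps a cell to its state id (default: all "S1").
    District ids are D001.. in row-major order.
    """
    features = []
    d = 0
    for i in range(n_rows):
        for j in range(n_cols):
            d += 1
            state = state_of(i, j) if state_of else "S1"
            features.append(
                {
                    "type": "Feature",
                    "properties": {"district_id": f"D{d:03d}", "state_id": state},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [
                                [j, i],
                                [j + 1, i],
                                [j + 1, i + 1],
                                [j, i + 1],
                                [j, i],
                            ]
                        ],
                    },
                }
            )
    return {"type": "FeatureCollection", "features": features}


@pytest.fixture(scope="session")
def demo_data():
    """One default synthetic study: geography, aux, truth, survey."""
    return synth.generate_all(DEMO_CONFIG)


@pytest.fixture(scope="session")
def recovery_run():
    """50-replicate recovery experiment at the 100-district scale."""
    return recovery_experiment(RECOVERY_CONFIG, n_replicates=50, bootstrap_B=200)


@pytest.fixture(scope="session")
def calibration_run():
    """50 correctly-specified replicates for diagnostic null calibration."""
    return diagnostic_calibration(CALIBRATION_CONFIG, n_replicates=50, seed=3)
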