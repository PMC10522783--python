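"""Generator tests: geography tiling, covariate autocorrelation, truth
identities, and the two-stage sampling design."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ipvsae import ConfigurationError, SynthConfig, global_moran, queen_weights, synth
from ipvsae.lisa import global_moran_test


def total_area(geo):
    from shapely.geometry import shape

    return sum(shape(f["geometry"]).area for f in geo["features"])


class TestGeography:
    def test_single_state_tiling(self):
        geo = synth.generate_geography(1, 4, seed=1)
        assert len(geo["features"]) == 4
        assert {f["properties"]["state_id"] for f in geo["features"]} == {"S1"}
        from shapely.geometry import shape

        polys = [shape(f["geometry"]) for f in geo["features"]]
        for i in range(4):
            for j in range(i + 1, 4):
                assert polys[i].intersection(polys[j]).area == 0

    def test_tiling_conserves_area(self):
        geo = synth.generate_geography(2, 2, seed=7)
        from shapely.ops import unary_union
        from shapely.geometry import shape

        union = unary_union([shape(f["geometry"]) for f in geo["features"]])
        minx, miny, maxx, maxy = union.bounds
        assert abs(union.area - (maxx - minx) * (maxy - miny)) < 1e-9

    def test_contiguity_graph_connected(self):
        geo = synth.generate_geography(3, 4, seed=11)
        w = queen_weights(geo)
        assert not w.neighbourless_ids
        seen = {w.ids[0]}
        frontier = [w.ids[0]]
        while frontier:
            nxt = []
            for i in frontier:
                for j in w.neighbours[i]:
                    if j not in seen:
                        seen.add(j)
                        nxt.append(j)
            frontier = nxt
        assert seen == set(w.ids)

    def test_rejects_bad_counts(self):
        with pytest.raises(ConfigurationError):
            synth.generate_geography(0, 4)
        with pytest.raises(ConfigurationError):
            synth.generate_geography(1, 3)  # fewer than 4 districts


class TestAuxiliary:
    def test_independence_limit(self):
        """Near-zero range: covariates show no spatial autocorrelation."""
        geo = synth.generate_geography(3, 12, seed=2)
        aux = synth.generate_auxiliary(geo, spatial_range=0.01, seed=5)
        w = queen_weights(geo)
        covs = [c for c in aux.columns if c not in ("district_id", "state_id", "bpf")]
        inside = 0
        for k, c in enumerate(covs):
            res = global_moran_test(
                aux.set_index("district_id")[c], w, n_perm=199, seed=k
            )
            lo, hi = np.percentile(res["null"], [2.5, 97.5])
            inside += lo <= res["I"] <= hi
        # individual 95% bands: allow the expected few false positives
        assert inside >= len(covs) - 2

    def test_large_range_gives_autocorrelation(self):
        """Range beyond the map diameter: strong positive Moran's I."""
        successes = 0
        for seed in range(5):
            geo = synth.generate_geography(3, 12, seed=seed)
            aux = synth.generate_auxiliary(geo, spatial_range=50.0, seed=seed)
            w = queen_weights(geo)
            covs = [
                c for c in aux.columns if c not in ("district_id", "state_id", "bpf")
            ]
            exceed = 0
            for k, c in enumerate(covs):
                res = global_moran_test(
                    aux.set_index("district_id")[c], w, n_perm=199, seed=k
                )
                exceed += res["I"] > np.percentile(res["null"], 97.5)
            successes += exceed >= len(covs) - 2
        assert successes >= 4

    def test_full_column_rank(self):
        geo = synth.generate_geography(2, 8, seed=3)
        aux = synth.generate_auxiliary(geo, spatial_range=2.0, seed=9)
        covs = [c for c in aux.columns if c not in ("district_id", "state_id")]
        X = np.column_stack([np.ones(len(aux)), aux[covs].to_numpy()])
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_proportions_in_unit_interval(self):
        geo = synth.generate_geography(2, 4, seed=3)
        aux = synth.generate_auxiliary(geo, spatial_range=2.0, seed=9)
        for c in ("sc_st_share", "female_literacy", "urban_share", "ses_index"):
            assert aux[c].between(0, 1).all()

    def test_bad_range_rejected(self):
        geo = synth.generate_geography(2, 4, seed=3)
        with pytest.raises(ConfigurationError):
            synth.generate_auxiliary(geo, spatial_range=0.0)


class TestTruth:
    @staticmethod
    def _aux(n=8):
        geo = synth.generate_geography(2, n // 2, seed=1)
        return synth.generate_auxiliary(geo, spatial_range=2.0, seed=4)

    def test_null_model_gives_half(self):
        aux = self._aux()
        tp = synth.generate_truth(aux, (0.0, 0.0), 0.0, seed=1, covariates=["bpf"])
        assert np.allclose(tp.theta_true, 0.5)

    def test_unit_coefficient_closed_form(self):
        aux = self._aux().copy()
        aux["one"] = 1.0
        tp = synth.generate_truth(aux, (0.0, 1.0), 0.0, seed=1, covariates=["one"])
        assert np.allclose(tp.theta_true, expit(1.0))
        assert np.allclose(tp.theta_true, 0.7310586, atol=1e-6)

    def test_linking_model_holds_exactly(self, demo_data):
        tp, aux = demo_data["truth"], demo_data["aux"]
        X = np.column_stack(
            [np.ones(len(aux)), aux[list(SynthConfig().covariates)].to_numpy()]
        )
        assert np.allclose(
            logit(tp.theta_true), X @ np.array(tp.beta_true) + tp.u_true, atol=1e-12
        )

    def test_area_effect_scale(self):
        """sigma_u=0.5 with null slopes: SD of logit(theta) tracks sigma_u."""
        geo = synth.generate_geography(5, 40, seed=1)
        aux = synth.generate_auxiliary(geo, spatial_range=2.0, seed=4)
        ok = 0
        for seed in range(10):
            tp = synth.generate_truth(
                aux, (-1.0, 0.0), 0.5, seed=seed, covariates=["bpf"]
            )
            ok += 0.35 <= np.std(logit(tp.theta_true), ddof=1) <= 0.65
        assert ok >= 9

    def test_dimension_mismatch(self):
        with pytest.raises(ConfigurationError):
            synth.generate_truth(self._aux(), (0.0, 1.0, 2.0), 0.1, covariates=["bpf"])


class TestSurvey:
    def test_unbiased_outcome_mean(self):
        """Census sampling, no weights/PSU effects, theta=0.5: pooled mean ~ 0.5."""
        ok = 0
        for seed in range(10):
            cfg = SynthConfig(
                n_states=4,
                districts_per_state=25,
                psus_per_district=10,
                households_per_psu=10,
                dv_subsample_fraction=1.0,
                beta_true=(0.0, 0.0, 0.0),
                sigma_u_true=0.0,
                weight_dispersion=0.0,
                psu_effect_sd=0.0,
                seed=seed,
            )
            survey = synth.generate_all(cfg)["survey"]
            assert len(survey) == 10_000
            ok += 0.49 <= survey["y_physical"].mean() <= 0.51
        assert ok >= 9

    def test_subsample_size_binomial(self):
        """15% of 1000 households -> ~150 respondents per district."""
        band = 3 * np.sqrt(150 * 0.85)
        ok = 0
        for seed in range(10):
            cfg = SynthConfig(n_states=1, districts_per_state=4, seed=seed)
            survey = synth.generate_all(cfg)["survey"]
            counts = survey.groupby("district_id").size()
            ok += bool(((counts - 150).abs() <= band).all())
        assert ok >= 9

    def test_degenerate_dispersion_gives_unit_weights(self):
        cfg = SynthConfig(weight_dispersion=0.0)
        survey = synth.generate_all(cfg)["survey"]
        assert (survey["weight"] == 1.0).all()

    def test_weights_mean_one_within_district(self, demo_data):
        means = demo_data["survey"].groupby("district_id")["weight"].mean()
        assert np.allclose(means, 1.0, atol=1e-12)

    def test_at_most_one_respondent_per_household(self, demo_data):
        cfg = SynthConfig()
        by_psu = demo_data["survey"].groupby("psu_id").size()
        assert (by_psu <= cfg.households_per_psu).all()

    def test_too_small_design_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(psus_per_district=1, households_per_psu=5,
                        dv_subsample_fraction=0.1)


class TestDeterminism:
    def test_identical_config_identical_outputs(self):
        cfg = SynthConfig(seed=99)
        a, b = synth.generate_all(cfg), synth.generate_all(cfg)
        assert a["geography"] == b["geography"]
        pd.testing.assert_frame_equal(a["aux"], b["aux"])
        pd.testing.assert_frame_equal(a["survey"], b["survey"])
        assert np.array_equal(a["truth"].theta_true, b["truth"].theta_true)

    def test_different_seed_differs(self):
        a = synth.generate_all(SynthConfig(seed=1))["survey"]
        b = synth.generate_all(SynthConfig(seed=2))["survey"]
        assert not a["y_physical"].equals(b["y_physical"])
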