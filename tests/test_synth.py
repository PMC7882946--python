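"""The synthetic study generator: determinism, constructive guarantees, truth export."""

import numpy as np
import pytest

import mirounga as mg
from mirounga.habitats import Habitat
from mirounga.synth import latent_drift_rate


class TestBathymetry:
    def test_all_four_habitats_realizable(self, small_config, bathy):
        lon_g, lat_g = np.meshgrid(bathy.lon_axis, bathy.lat_axis)
        labels = set(mg.classify_locations(lat_g.ravel(), lon_g.ravel(), bathy.values.ravel()).tolist())
        for h in (Habitat.ANT_SHELF, Habitat.KERG_PLATEAU, Habitat.OCEANIC_EAST, Habitat.OCEANIC_WEST):
            assert h in labels

    def test_colony_cell_is_land(self, small_config, bathy):
        assert bathy.lookup(*small_config.colony) <= 0

    def test_deterministic(self, small_config):
        b1 = mg.make_bathymetry(small_config)
        b2 = mg.make_bathymetry(small_config)
        np.testing.assert_array_equal(b1.values, b2.values)


class TestIceSeason:
    def test_concentrations_in_unit_interval(self, small_config):
        ice = mg.make_ice_series(small_config)
        for doy in (1, 100, 200, 300):
            v = ice[doy].values
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_midsummer_colony_ice_free(self, small_config):
        ice = mg.make_ice_series(small_config)
        assert ice.concentration([small_config.colony[0]], [small_config.colony[1]], [15])[0] <= 0.15

    def test_midwinter_far_south_in_ice(self, small_config):
        ice = mg.make_ice_series(small_config)
        assert ice.concentration([80.0], [-67.0], [196])[0] > 0.15

    def test_edge_northernmost_in_winter(self, small_config):
        from mirounga.synth import ice_edge_latitude

        edges = ice_edge_latitude(small_config, np.arange(1, 366))
        assert int(np.argmax(edges)) + 1 == small_config.ice_peak_doy


class TestSimulateTrack:
    def test_same_seed_identical(self, small_config):
        from mirounga.synth import draw_population

        meta = draw_population(small_config, np.random.default_rng(0))[0]
        t1, _ = mg.simulate_track(meta, small_config, np.random.default_rng(7))
        t2, _ = mg.simulate_track(meta, small_config, np.random.default_rng(7))
        np.testing.assert_array_equal(t1.lon, t2.lon)
        np.testing.assert_array_equal(t1.lat, t2.lat)

    def test_high_persistence_travels_farther(self):
        # equal step variance, no steering: gamma 0.95 disperses far more than 0.1
        def net_displacement(gamma):
            d = mg.ar_displacement_series(np.full(100, gamma), np.random.default_rng(3))
            return float(np.linalg.norm(d.sum(axis=0)))

        assert net_displacement(0.95) > 3 * net_displacement(0.1)

    def test_certain_haulout_produces_coastal_run(self, small_config):
        cfg = mg.SimConfig(n_females=0, n_males=3, seed=5,
                           haulout_prob={"female": 0.0, "male": 1.0})
        study = mg.simulate_study(cfg, with_dives=False, with_ice=False)
        coast = mg.coast_distance_grid(study.bathy)
        for tr in study.tracks:
            dist = coast.lookup_many(tr.lon, tr.lat)
            runs = np.flatnonzero(dist <= 4.0)
            # at least 4 consecutive coastal days somewhere mid-trip
            pieces = np.split(runs, np.flatnonzero(np.diff(runs) != 1) + 1)
            assert max(len(p) for p in pieces) >= 4

    def test_truth_exported_with_modes(self, small_study):
        truth = small_study.truth
        assert {"gamma", "mode", "target_habitat", "drift_rate", "hauled"} <= set(truth.columns)
        assert set(truth["mode"].unique()) <= {"transit", "forage", "haulout"}
        valid = truth["gamma"].dropna()
        assert ((valid > 0) & (valid < 1)).all()


class TestSimulateDives:
    def _shelf_config(self, benthic_p):
        return mg.SimConfig(
            n_females=0, n_males=2, seed=9,
            habitat_preference={
                "male": {"ANT_SHELF": 0.0, "KERG_PLATEAU": 1.0, "OCEANIC_EAST": 0.0, "OCEANIC_WEST": 0.0},
                "female": {"ANT_SHELF": 0.0, "KERG_PLATEAU": 0.0, "OCEANIC_EAST": 1.0, "OCEANIC_WEST": 0.0},
            },
            benthic_prob={("male", "KERG_PLATEAU"): benthic_p},
            drift_dive_fraction=0.0,
            trip_length_days={"male": 120.0, "female": 120.0},
            trip_length_sd_days=0.0, min_trip_days=120,
            haulout_prob={"female": 0.0, "male": 0.0},
        )

    @pytest.mark.parametrize("p, expected", [(1.0, 100.0), (0.0, 0.0)])
    def test_generator_classifier_consistency(self, p, expected):
        study = mg.simulate_study(self._shelf_config(p), with_ice=False)
        cls = mg.classify_dives(study.dives, study.tracks, study.bathy)
        assert len(cls) > 100
        assert 100.0 * (cls["cls"] == "benthic").mean() == pytest.approx(expected)

    def test_drift_dives_carry_latent_rate(self, small_study):
        from mirounga.dives import drift_rates_by_day

        rates = drift_rates_by_day(small_study.dives)
        truth = small_study.truth.set_index(["seal_id", "t"])["drift_rate"]
        merged = rates.assign(
            truth=[truth.get((r.seal_id, float(r.day)), np.nan) for r in rates.itertuples()]
        ).dropna()
        err = merged["rate"] - merged["truth"]
        assert err.abs().mean() < 3 * small_study.config.drift_noise_sd

    def test_latent_trajectory_rises_then_plateaus(self, small_config):
        r = latent_drift_rate(small_config, np.arange(0, 200))
        assert r[0] == pytest.approx(small_config.drift_start_rate)
        assert np.all(np.diff(r) >= 0)
        assert r[-1] == pytest.approx(small_config.drift_ceiling_rate)
        assert (r <= small_config.drift_ceiling_rate + 1e-12).all()


class TestStudyDeterminismAndPreconditions:
    def test_same_seed_byte_identical(self, small_config):
        s1 = mg.simulate_study(small_config, with_ice=False)
        s2 = mg.simulate_study(small_config, with_ice=False)
        for t1, t2 in zip(s1.tracks, s2.tracks):
            np.testing.assert_array_equal(t1.lon, t2.lon)
        assert len(s1.dives) == len(s2.dives)
        assert s1.dives[0] == s2.dives[0]
        assert s1.truth.equals(s2.truth)

    def test_generated_data_satisfy_downstream_preconditions(self, small_study):
        # tracks are valid daily tracks inside the grid; dives have valid
        # profiles (enforced by the dataclasses); every seal has metadata
        ids = {m.seal_id for m in small_study.metas}
        for tr in small_study.tracks:
            assert tr.seal_id in ids
            assert len(tr) >= 4
            assert small_study.bathy.in_bounds(tr.lon, tr.lat).all()
        assert {d.seal_id for d in small_study.dives} <= ids

    def test_probability_vector_validation(self):
        cfg = mg.SimConfig(habitat_preference={
            "male": {"ANT_SHELF": 0.9, "KERG_PLATEAU": 0.3, "OCEANIC_EAST": 0.0, "OCEANIC_WEST": 0.0},
            "female": {"ANT_SHELF": 0.0, "KERG_PLATEAU": 0.0, "OCEANIC_EAST": 0.5, "OCEANIC_WEST": 0.5},
        })
        with pytest.raises(ValueError):
            cfg.validate()
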