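"""Synthetic-study generator: storm pulse, array geometry, latent dynamics,
detection law, and generator/model consistency."""

from __future__ import annotations

import numpy as np
import pytest

from stormssm.occupancy import OBS_COVARIATES, STATE_COVARIATES
from stormssm.simulate import (
    ScenarioConfig,
    StateTruth,
    StormTruth,
    expand_records,
    simulate_array,
    simulate_environment,
    simulate_latent_states,
    simulate_study,
)
from stormssm.sync_efficiency import sync_linear_predictor
from stormssm.occupancy import detection_prob, emigration_prob
from stormssm.telemetry_io import HourlyDetectionMatrix


class TestEnvironment:
    def test_seeded_runs_identical(self, small_config):
        a = simulate_environment(small_config)
        b = simulate_environment(small_config)
        assert a.raw.equals(b.raw)
        assert a.standardized.equals(b.standardized)

    def test_sst_drop_magnitude(self):
        cfg = ScenarioConfig(n_animals=0, seed=1)
        cov = simulate_environment(cfg)
        sst = cov.raw["sst"].to_numpy()
        assert sst.max() - sst.min() >= 6.0

    def test_zero_amplitude_storm_is_stationary(self):
        quiet = StormTruth(sst_drop_c=0, wind_peak_ms=0, baro_drop_hpa=0,
                           sal_crash_psu=0, turb_spike_fnu=0, noise_spike_mv=0,
                           tilt_spike_deg=0)
        cfg = ScenarioConfig(n_animals=0, storm=quiet, seed=1)
        cov = simulate_environment(cfg)
        raw = cov.raw
        # natural variability remains (synoptic SST spells have sd ~0.8 degC);
        # what vanishes is the storm-scale anomaly
        assert raw["sst"].max() - raw["sst"].min() < 5.5
        assert raw["sal"].min() > 30.0
        assert raw["wind"].max() < 16.0

    def test_storm_window_has_elevated_conditions(self, small_study):
        cov = small_study.covariates
        hours = cov.window.hours
        sw = small_study.config.storm_window
        ins = np.asarray((hours >= sw.start) & (hours < sw.end))
        assert cov.raw["wind"][ins].max() > cov.raw["wind"][~ins].mean() + 5
        assert cov.raw["sal"][ins].min() < 10.0


class TestArray:
    def test_2x2_exact_spacing(self):
        cfg = ScenarioConfig(n_receivers=4, n_sync_tags=2, spacing_m=(400.0, 400.0),
                             n_animals=0, seed=0)
        receivers, geometry = simulate_array(cfg)
        pos = np.array([[r.x, r.y] for r in receivers])
        d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        np.testing.assert_allclose(nn, 400.0)

    def test_default_array_geometry(self):
        cfg = ScenarioConfig(seed=2)
        receivers, geometry = simulate_array(cfg)
        assert len(receivers) == 40
        assert sum(r.has_sync_tag for r in receivers) == 20
        pos = np.array([[r.x, r.y] for r in receivers])
        d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert nn.min() >= 300.0 and nn.max() <= 500.0
        depths = np.array([r.depth_m for r in receivers])
        assert depths.min() >= 5.0 and depths.max() <= 15.0
        # convex-hull coverage within a factor 2 of ~10 km^2
        from scipy.spatial import ConvexHull

        area_km2 = ConvexHull(pos).volume / 1e6
        assert 5.0 <= area_km2 <= 20.0

    def test_distances_symmetric(self, small_study):
        pos = {r.receiver_id: (r.x, r.y) for r in small_study.receivers}

        def dist(a, b):
            (x1, y1), (x2, y2) = pos[a], pos[b]
            return np.hypot(x1 - x2, y1 - y2)

        ids = list(pos)
        for a, b in zip(ids[:-1], ids[1:]):
            assert dist(a, b) == pytest.approx(dist(b, a))


class TestLatentStates:
    def test_absorbing_presence_when_no_emigration(self):
        st = StateTruth(mu_a=-50.0, sigma_a=0.01, beta_sin=0, beta_cos=0,
                        beta_wind=0, beta_waves=0, beta_baro=0, beta_sst=0,
                        beta_sal=0, beta_turb=0, p_initial_present=0.999999999)
        cfg = ScenarioConfig(n_animals=8, window_hours=300, storm_start_hour=100,
                             state_truth=st, seed=3)
        cov = simulate_environment(cfg)
        z, _ = simulate_latent_states(cfg, cov)
        assert np.all(z == 1)

    def test_forced_evacuation_without_return(self):
        st = StateTruth(mu_a=50.0, sigma_a=0.01, beta_sin=0, beta_cos=0,
                        beta_wind=0, beta_waves=0, beta_baro=0, beta_sst=0,
                        beta_sal=0, beta_turb=0, phi_return=1e-12,
                        p_initial_present=0.999999999)
        cfg = ScenarioConfig(n_animals=8, window_hours=50, storm_start_hour=10,
                             state_truth=st, seed=3)
        cov = simulate_environment(cfg)
        z, _ = simulate_latent_states(cfg, cov)
        assert np.all(z[:, 0] == 1)
        assert np.all(z[:, 1:] == 0)

    def test_stationary_occupancy_fraction(self):
        """Constant rates: long-run presence ~ phi_ret / (phi_ret + phi_emig)."""
        quiet = StormTruth(sst_drop_c=0, wind_peak_ms=0, baro_drop_hpa=0,
                           sal_crash_psu=0, turb_spike_fnu=0, noise_spike_mv=0,
                           tilt_spike_deg=0)
        phi_emig = 0.02
        st = StateTruth(mu_a=float(np.log(phi_emig / (1 - phi_emig))), sigma_a=1e-6,
                        beta_sin=0, beta_cos=0, beta_wind=0, beta_waves=0,
                        beta_baro=0, beta_sst=0, beta_sal=0, beta_turb=0,
                        phi_return=0.05)
        T = 40_000
        cfg = ScenarioConfig(n_animals=2, window_hours=T, storm_start_hour=100,
                             storm_hours=24, storm=quiet, state_truth=st, seed=6)
        cov = simulate_environment(cfg)
        z, _ = simulate_latent_states(cfg, cov)
        target = 0.05 / (0.05 + phi_emig)
        se = np.sqrt(target * (1 - target) / (2 * T)) * 6  # correlated chain slack
        assert abs(z.mean() - target) < max(5 * se, 0.02)


class TestDetections:
    def test_detection_frequency_matches_probability(self):
        """Empirical per-cell frequency within 3 binomial sd of generating p."""
        quiet = StormTruth(sst_drop_c=0, wind_peak_ms=0, baro_drop_hpa=0,
                           sal_crash_psu=0, turb_spike_fnu=0, noise_spike_mv=0,
                           tilt_spike_deg=0)
        st = StateTruth(mu_a=-50.0, sigma_a=1e-6, beta_sin=0, beta_cos=0,
                        beta_wind=0, beta_waves=0, beta_baro=0, beta_sst=0,
                        beta_sal=0, beta_turb=0, p_initial_present=0.999999999)
        cfg = ScenarioConfig(n_receivers=4, n_sync_tags=2, n_animals=2,
                             window_hours=5000, storm_start_hour=100, storm=quiet,
                             state_truth=st, seed=8)
        study = simulate_study(cfg)
        assert np.all(study.z_true == 1)
        T = cfg.window_hours
        for i in range(2):
            for j in range(4):
                p = study.p_det[j]                     # (T,) varies mildly
                emp = study.animal_matrix.values[i, j].mean()
                mu = p.mean()
                sd = np.sqrt((p * (1 - p)).sum()) / T
                assert abs(emp - mu) < 3.5 * sd

    def test_absent_animals_produce_no_records(self):
        st = StateTruth(mu_a=50.0, sigma_a=0.01, beta_sin=0, beta_cos=0,
                        beta_wind=0, beta_waves=0, beta_baro=0, beta_sst=0,
                        beta_sal=0, beta_turb=0, phi_return=1e-12,
                        p_initial_present=1e-12)
        cfg = ScenarioConfig(n_receivers=4, n_sync_tags=2, n_animals=3,
                             window_hours=60, storm_start_hour=10,
                             state_truth=st, seed=4)
        study = simulate_study(cfg)
        assert np.all(study.z_true == 0)
        assert study.animal_matrix.values.sum() == 0
        assert study.animal_records() == []

    def test_certain_detection_yields_hourly_records(self, small_config):
        w = small_config.window
        ones = HourlyDetectionMatrix(
            ["S1"], ["R1"], w, np.ones((1, 1, w.n_hours), dtype=np.uint8)
        )
        rng = np.random.default_rng(0)
        records = expand_records(ones, (150.0, 250.0), rng,
                                 cell_prob=np.ones((1, 1, w.n_hours)))
        by_hour = {}
        for r in records:
            by_hour.setdefault(w.hour_index(r.timestamp), 0)
            by_hour[w.hour_index(r.timestamp)] += 1
        assert set(by_hour) == set(range(w.n_hours))  # >= 1 record every hour
        assert min(by_hour.values()) >= 1


class TestGeneratorModelConsistency:
    def test_cell_probabilities_match_model_evaluation(self, small_study):
        """Single source of truth: generator probabilities equal the model
        modules' probability operations to 1e-12."""
        cfg = small_study.config
        cov = small_study.covariates_latent   # generated the latent/animal layers
        rng = np.random.default_rng(0)
        hl = cov.hour_local
        # observation layer
        obs_beta = {x: cfg.obs_truth.slope(x) for x in OBS_COVARIATES}
        for _ in range(20):
            j = rng.integers(len(small_study.receivers))
            t = rng.integers(cfg.window_hours)
            covs_t = {x: cov.z(x)[t] for x in OBS_COVARIATES}
            p = detection_prob(float(small_study.theta_true[j]), obs_beta, covs_t, "full")
            assert p == pytest.approx(small_study.p_det[j, t], abs=1e-12)
        # state layer
        from stormssm.occupancy import EmigrationParams

        emig = EmigrationParams(
            alpha=small_study.alpha_true,
            mu_a=cfg.state_truth.mu_a, sigma_a=cfg.state_truth.sigma_a,
            beta_sin=cfg.state_truth.beta_sin, beta_cos=cfg.state_truth.beta_cos,
            beta={x: cfg.state_truth.slope(x) for x in STATE_COVARIATES},
        )
        from stormssm.occupancy import emigration_eta, state_design

        eta = emigration_eta(small_study.alpha_true, cfg.state_truth.slope_vector,
                             state_design(cov))
        for _ in range(20):
            i = rng.integers(cfg.n_animals)
            t = rng.integers(cfg.window_hours)
            covs_t = {x: cov.z(x)[t] for x in STATE_COVARIATES}
            phi = emigration_prob(float(small_study.alpha_true[i]), emig, covs_t,
                                  float(hl[t]))
            assert phi == pytest.approx(1 / (1 + np.exp(-eta[i, t])), abs=1e-12)
        # sync layer (generated against the fitter-visible table)
        cov = small_study.covariates
        g = small_study.geometry
        sync_beta = {
            "dist": cfg.sync_truth.beta_dist, "depth": cfg.sync_truth.beta_depth,
            **{x: cfg.sync_truth.slope(x) for x in
               ("wind", "waves", "noise", "tilt", "sharks")},
        }
        for _ in range(20):
            p_idx = rng.integers(g.n_pairs)
            t = rng.integers(cfg.window_hours)
            covs_t = {
                "logdist": g.log_distance_z[p_idx], "depth": g.depth_z[p_idx],
                **{x: cov.z(x)[t] for x in ("wind", "waves", "noise", "tilt", "sharks")},
            }
            p = sync_linear_predictor(float(small_study.sync_alpha_true[p_idx]),
                                      sync_beta, covs_t)
            assert p == pytest.approx(small_study.p_sync[p_idx, t], abs=1e-12)

    def test_end_to_end_seed_determinism(self, small_config):
        a = simulate_study(small_config)
        b = simulate_study(small_config)
        np.testing.assert_array_equal(a.animal_matrix.values, b.animal_matrix.values)
        np.testing.assert_array_equal(a.sync_matrix.values, b.sync_matrix.values)
        np.testing.assert_array_equal(a.z_true, b.z_true)
        assert a.covariates.standardized.equals(b.covariates.standardized)
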