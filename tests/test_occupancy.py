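"""Occupancy state-space model: probability layers, exact marginalization,
latent decoding and sampler cross-validation."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from stormssm.mcmc import McmcConfig, posterior_summary
from stormssm.occupancy import (
    OBS_COVARIATES,
    STATE_COVARIATES,
    EmigrationParams,
    ObservationParams,
    ReturnParams,
    TransferPrior,
    detection_prob,
    emigration_prob,
    emission_prob,
    fit_ssm,
    marginal_loglik,
    transition_prob,
)
from stormssm.telemetry_io import HourlyDetectionMatrix

from conftest import make_window, random_covariates


def _zero_covs():
    return {x: 0.0 for x in STATE_COVARIATES}


class TestTransitionProb:
    def test_complement_from_presence(self):
        assert transition_prob(1, 0.2, 0.05) == pytest.approx(0.8)

    def test_return_from_absence(self):
        assert transition_prob(0, 0.2, 0.05) == pytest.approx(0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        pe, pr = rng.uniform(0.01, 0.99, 2)
        for z in (0, 1):
            p1 = transition_prob(z, pe, pr)
            assert 0.0 < p1 < 1.0
            assert p1 + (1.0 - p1) == pytest.approx(1.0)

    def test_invalid_state(self):
        with pytest.raises(ValueError):
            transition_prob(2, 0.2, 0.05)


class TestEmigrationProb:
    def _params(self, **kw):
        beta = {x: kw.pop(x, 0.0) for x in STATE_COVARIATES}
        return EmigrationParams(
            alpha=np.array([0.0]), mu_a=0.0, sigma_a=1.0,
            beta_sin=kw.pop("beta_sin", 0.0), beta_cos=kw.pop("beta_cos", 0.0),
            beta=beta,
        )

    def test_all_slopes_zero(self):
        p = self._params()
        for h in (0, 5, 13, 23):
            assert emigration_prob(-1.5, p, _zero_covs(), h) == pytest.approx(
                1 / (1 + math.exp(1.5))
            )

    def test_diel_closed_form(self):
        p = self._params(beta_sin=1.0)
        # hour 6: sin(pi/2) = 1 -> logit phi = 1
        assert emigration_prob(0.0, p, _zero_covs(), 6.0) == pytest.approx(
            1 / (1 + math.exp(-1.0)), abs=1e-12
        )

    def test_exact_24h_periodicity(self):
        p = self._params(beta_sin=0.7, beta_cos=-0.4, sst=-1.0)
        covs = dict(_zero_covs(), sst=0.5)
        for h in (0.0, 3.0, 11.5, 17.25):
            assert emigration_prob(-2.0, p, covs, h) == pytest.approx(
                emigration_prob(-2.0, p, covs, h + 24.0), abs=1e-12
            )

    def test_missing_covariate(self):
        p = self._params()
        with pytest.raises(KeyError, match="sst"):
            emigration_prob(0.0, p, {"wind": 0.0}, 0)


class TestDetectionProb:
    def _covs(self, **kw):
        d = {x: 0.0 for x in OBS_COVARIATES}
        d.update(kw)
        return d

    def test_centering_identity_both_variants(self):
        betas = {x: -0.3 for x in OBS_COVARIATES}
        assert detection_prob(0.37, betas, self._covs(), "full") == pytest.approx(0.37)
        assert detection_prob(0.37, None, None, "reduced") == pytest.approx(0.37)

    def test_closed_form_shift(self):
        betas = {x: 0.0 for x in OBS_COVARIATES}
        betas["noise"] = -1.0
        p = detection_prob(0.5, betas, self._covs(noise=2.0), "full")
        assert p == pytest.approx(1 / (1 + math.exp(2.0)))

    def test_reduced_ignores_covariates(self):
        for noise in (-3.0, 0.0, 4.0):
            assert detection_prob(0.6, None, self._covs(noise=noise), "reduced") == 0.6

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            detection_prob(1.0, None, None, "reduced")


class TestEmissionProb:
    def test_forced_silence(self):
        assert emission_prob([0, 0, 0], 0, [0.3, 0.5, 0.9]) == 1.0

    def test_zero_forcing(self):
        assert emission_prob([0, 1, 0], 0, [0.3, 0.5, 0.9]) == 0.0

    def test_present_product(self):
        assert emission_prob([1, 0], 1, [0.5, 0.5]) == pytest.approx(0.25)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            emission_prob([1, 0], 1, [0.5])


def _random_instance(rng, t_len, n_recv):
    """Random parameters + observations on a small window."""
    window = make_window(hours=t_len)
    cov = random_covariates(window, rng)
    emig = EmigrationParams(
        alpha=np.array([rng.normal(-1.0, 1.0)]),
        mu_a=0.0, sigma_a=1.0,
        beta_sin=rng.normal(0, 0.5), beta_cos=rng.normal(0, 0.5),
        beta={x: rng.normal(0, 0.7) for x in STATE_COVARIATES},
    )
    ret = ReturnParams(alpha_return=rng.normal(-1.0, 1.0))
    obs = ObservationParams(
        theta=rng.uniform(0.2, 0.8, n_recv),
        beta_det={x: rng.normal(0, 0.4) for x in OBS_COVARIATES},
    )
    # simulate observations from an arbitrary latent path
    z = (rng.uniform(size=t_len) < 0.6).astype(int)
    p = np.array(
        [
            [
                detection_prob(
                    obs.theta[j], obs.beta_det,
                    {x: cov.z(x)[t] for x in OBS_COVARIATES}, "full",
                )
                for t in range(t_len)
            ]
            for j in range(n_recv)
        ]
    )
    y = ((rng.uniform(size=(n_recv, t_len)) < p) * z[None, :]).astype(np.uint8)
    return cov, emig, ret, obs, y, p


def _enumerate_loglik(cov, emig, ret, obs, y, pi1):
    """Independent oracle: sum over all 2^T latent paths with direct formulas."""
    n_recv, t_len = y.shape
    hl = cov.hour_local
    phi_e = np.array(
        [
            emigration_prob(
                float(emig.alpha[0]), emig,
                {x: cov.z(x)[t] for x in STATE_COVARIATES}, float(hl[t]),
            )
            for t in range(t_len)
        ]
    )
    phi_r = ret.phi_return
    p = np.array(
        [
            [
                detection_prob(
                    obs.theta[j], obs.beta_det,
                    {x: cov.z(x)[t] for x in OBS_COVARIATES}, "full",
                )
                for t in range(t_len)
            ]
            for j in range(n_recv)
        ]
    )
    total = 0.0
    for path in itertools.product((0, 1), repeat=t_len):
        pr = pi1 if path[0] == 1 else 1.0 - pi1
        for t in range(1, t_len):
            if path[t - 1] == 1:
                pr *= (1.0 - phi_e[t]) if path[t] == 1 else phi_e[t]
            else:
                pr *= phi_r if path[t] == 1 else 1.0 - phi_r
        for t in range(t_len):
            pr *= emission_prob(y[:, t], path[t], p[:, t])
            if pr == 0.0:
                break
        total += pr
    return math.log(total)


class TestMarginalLoglik:
    def test_one_step_closed_form(self):
        rng = np.random.default_rng(0)
        cov, emig, ret, obs, _, p = _random_instance(rng, 1, 3)
        y = np.zeros((3, 1), dtype=np.uint8)
        pi1 = 0.3
        ll = marginal_loglik(y, emig, ret, obs, cov, initial_p_present=pi1)
        expected = pi1 * np.prod(1.0 - p[:, 0]) + (1.0 - pi1)
        assert ll[0] == pytest.approx(math.log(expected), abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        t_len = int(rng.integers(2, 5))
        n_recv = int(rng.integers(2, 4))
        cov, emig, ret, obs, y, _ = _random_instance(rng, t_len, n_recv)
        ll = marginal_loglik(y[None], emig, ret, obs, cov, initial_p_present=0.5)
        oracle = _enumerate_loglik(cov, emig, ret, obs, y, 0.5)
        assert ll[0] == pytest.approx(oracle, abs=1e-10)

    def test_perfect_observation_limit(self):
        rng = np.random.default_rng(7)
        cov, emig, ret, obs, _, _ = _random_instance(rng, 6, 2)
        obs_perfect = ObservationParams(
            theta=np.full(2, 1.0 - 1e-12), beta_det={x: 0.0 for x in OBS_COVARIATES}
        )
        y = np.ones((2, 6), dtype=np.uint8)
        ll = marginal_loglik(
            y, emig, ret, obs_perfect, cov, initial_p_present=1.0 - 1e-12
        )
        # detected every hour with p ~ 1: only stay-present terms remain
        assert ll[0] <= 0.0
        phi = [
            emigration_prob(float(emig.alpha[0]), emig,
                            {x: cov.z(x)[t] for x in STATE_COVARIATES},
                            float(cov.hour_local[t]))
            for t in range(1, 6)
        ]
        assert ll[0] == pytest.approx(sum(math.log(1 - f) for f in phi), abs=1e-6)


class TestDecoding:
    def test_two_hour_forward_backward_by_hand(self):
        """Smoothing on a 2-hour instance vs direct 4-path computation."""
        from stormssm._forward import forward_backward
        from stormssm.occupancy import emission_log_terms

        p = np.array([[0.7, 0.4]])            # one receiver, two hours
        eta_det = np.log(p / (1 - p))
        y = np.zeros((1, 1, 2), dtype=np.uint8)
        y[0, 0, 1] = 1                        # detected in hour 1 only
        phi_e, phi_r, pi1 = 0.2, 0.1, 0.5
        eta_e = np.full((1, 2), math.log(phi_e / (1 - phi_e)))
        le1 = emission_log_terms(y, eta_det)
        has = y.any(axis=1).astype(np.uint8)
        gamma = forward_backward(
            eta_e, math.log(phi_r / (1 - phi_r)), np.ascontiguousarray(le1),
            np.ascontiguousarray(has), math.log(pi1), math.log(1 - pi1),
        )
        # direct path sums
        paths = {}
        for z0, z1 in itertools.product((0, 1), repeat=2):
            pr = pi1 if z0 else 1 - pi1
            pr *= (1 - phi_e if z1 else phi_e) if z0 else (phi_r if z1 else 1 - phi_r)
            pr *= (1 - p[0, 0]) if z0 else 1.0      # silent hour 0
            pr *= p[0, 1] if z1 else 0.0            # detection hour 1
            paths[(z0, z1)] = pr
        total = sum(paths.values())
        g0 = (paths[(1, 0)] + paths[(1, 1)]) / total
        g1 = (paths[(0, 1)] + paths[(1, 1)]) / total
        assert gamma[0, 0] == pytest.approx(g0, abs=1e-12)
        assert gamma[0, 1] == pytest.approx(g1, abs=1e-12)
        assert gamma[0, 1] == 1.0  # zero-forcing

    def test_fit_zero_forcing_exact(self, small_study, small_ssm_fit):
        detected = small_study.animal_matrix.values.any(axis=1)
        assert np.all(small_ssm_fit.occupancy[detected] == 1.0)
        assert np.all(
            (small_ssm_fit.occupancy >= 0.0) & (small_ssm_fit.occupancy <= 1.0)
        )

    def test_long_absence_decays_toward_absent(self, small_config):
        """An animal silent after hour 20 should decode to low presence late."""
        from stormssm.simulate import simulate_study

        study = simulate_study(small_config)
        m = study.animal_matrix
        values = m.values.copy()
        values[0, :, 20:] = 0
        m2 = HourlyDetectionMatrix(m.transmitters, m.receivers, m.window, values)
        tr = TransferPrior({x: (0.0, 0.3) for x in OBS_COVARIATES})
        cfg = McmcConfig(n_chains=1, n_iterations=600, burn_in=200, thin=2, seed=3)
        fit = fit_ssm(m2, study.covariates, tr, "full", cfg, decode_draws=20)
        assert fit.occupancy[0, -1] < 0.5
        last_det = int(np.nonzero(values[0].any(axis=0))[0].max())
        assert fit.occupancy[0, last_det] == 1.0  # detected hours stay pinned


class TestFitContracts:
    def test_always_detected_animal_pins_presence(self, small_study, quick_mcmc,
                                                  truth_transfer):
        m = small_study.animal_matrix
        values = m.values.copy()
        values[0, 0, :] = 1
        m2 = HourlyDetectionMatrix(m.transmitters, m.receivers, m.window, values)
        fit = fit_ssm(m2, small_study.covariates, truth_transfer, "full",
                      quick_mcmc, decode_draws=10)
        assert np.all(fit.occupancy[0] == 1.0)

    def test_reduced_variant_contract(self, small_reduced_fit):
        names = small_reduced_fit.samples.parameter_names()
        assert not any(n.startswith("beta_det_") for n in names)
        theta = small_reduced_fit.samples.pooled("theta")
        assert np.all((theta > 0) & (theta < 1))

    def test_degenerate_transfer_prior_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            TransferPrior({x: (0.0, 0.0) for x in OBS_COVARIATES})

    def test_samplers_target_same_posterior(self, small_study, truth_transfer):
        """Marginalized and data-augmentation routes agree within MC error."""
        m = small_study.animal_matrix
        sub = HourlyDetectionMatrix(
            m.transmitters[:4], m.receivers, m.window, m.values[:4]
        )
        cfg = McmcConfig(n_chains=2, n_iterations=2200, burn_in=900, thin=3, seed=11)
        fm = fit_ssm(sub, small_study.covariates, truth_transfer, "full", cfg,
                     method="marginal", decode_draws=5)
        fa = fit_ssm(sub, small_study.covariates, truth_transfer, "full", cfg,
                     method="augmented", decode_draws=5)
        for name in ("mu_a", "alpha_return", "beta_sst", "beta_baro"):
            a = posterior_summary(fm.samples, name)
            b = posterior_summary(fa.samples, name)
            # Monte-Carlo error bound: ~half a posterior sd comfortably exceeds
            # the standard error of the mean difference at the retained ESS
            assert abs(a["mean"] - b["mean"]) < 0.5 * max(a["sd"], b["sd"], 0.1)
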