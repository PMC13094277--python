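"""Sync-tag detection-efficiency regression: predictor, likelihood, fitting,
prior export and counterfactual curves."""

from __future__ import annotations

import math

import numpy as np
import pytest

from stormssm.mcmc import McmcConfig, PosteriorSamples
from stormssm.sync_efficiency import (
    ALL_SYNC_SLOPES,
    SYNC_TIME_COVARIATES,
    condition_covariates,
    covariate_diagnostics,
    export_transfer_priors,
    fit_sync_model,
    predict_detection_curve,
    sync_linear_predictor,
    sync_loglik,
)
from stormssm.telemetry_io import HourlyDetectionMatrix


def _covs(**kw):
    d = {x: 0.0 for x in ("logdist", "depth") + SYNC_TIME_COVARIATES}
    d.update(kw)
    return d


def _betas(**kw):
    d = {x: 0.0 for x in ALL_SYNC_SLOPES}
    d.update(kw)
    return d


class TestLinearPredictor:
    def test_neutral_covariates_give_half(self):
        assert sync_linear_predictor(0.0, _betas(), _covs()) == pytest.approx(0.5)

    def test_intercept_only_closed_form(self):
        assert sync_linear_predictor(2.0, _betas(), _covs()) == pytest.approx(
            1.0 / (1.0 + math.exp(-2.0)), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_logistic(self, seed):
        rng = np.random.default_rng(seed)
        betas = {k: rng.normal() for k in ALL_SYNC_SLOPES}
        covs = {k: rng.normal() for k in ("logdist", "depth") + SYNC_TIME_COVARIATES}
        alpha = rng.normal()
        eta = (
            alpha
            + betas["dist"] * covs["logdist"]
            + betas["depth"] * covs["depth"]
            + sum(betas[x] * covs[x] for x in SYNC_TIME_COVARIATES)
        )
        assert sync_linear_predictor(alpha, betas, covs) == pytest.approx(
            1.0 / (1.0 + math.exp(-eta)), abs=1e-12
        )

    def test_missing_terms_listed(self):
        with pytest.raises(KeyError, match="noise"):
            sync_linear_predictor(0.0, _betas(), {"logdist": 0.0, "depth": 0.0})

    def test_logit_logistic_roundtrip(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1 - 1e-6, 100)
        back = 1.0 / (1.0 + np.exp(-(np.log(p) - np.log1p(-p))))
        np.testing.assert_allclose(back, p, atol=1e-12)


class TestLoglik:
    def test_matches_cellwise_summation(self):
        rng = np.random.default_rng(2)
        P, T = 6, 30
        alpha = rng.uniform(-2, 2, P)
        bp = rng.normal(0, 0.5, 2)
        bt = rng.normal(0, 0.5, 5)
        xp = rng.normal(size=(P, 2))
        xt = rng.normal(size=(T, 5))
        y = rng.integers(0, 2, size=(P, T)).astype(np.uint8)
        direct = 0.0
        for p in range(P):
            for t in range(T):
                eta = alpha[p] + xp[p] @ bp + xt[t] @ bt
                prob = 1.0 / (1.0 + math.exp(-eta))
                direct += math.log(prob if y[p, t] else 1.0 - prob)
        assert sync_loglik(alpha, bp, bt, y, xp, xt) == pytest.approx(direct, abs=1e-10)


def _manual_posterior(values: dict[str, np.ndarray]) -> PosteriorSamples:
    cfg = McmcConfig(n_chains=1, n_iterations=len(next(iter(values.values()))),
                     burn_in=0, thin=1, seed=0)
    draws = {k: np.asarray(v, dtype=float)[None, :] for k, v in values.items()}
    return PosteriorSamples(draws=draws, config=cfg)


class TestTransferPriors:
    def _fit_like(self, beta_values, small_study):
        from stormssm.sync_efficiency import SyncFit, SyncModelSpec
        from stormssm.mcmc import ConvergenceReport

        n = len(next(iter(beta_values.values())))
        values = {f"beta_{k}": np.asarray(v, dtype=float)
                  for k, v in beta_values.items()}
        values.setdefault("alpha", np.zeros(n))
        samples = _manual_posterior(values)
        return SyncFit(samples=samples, convergence=ConvergenceReport(rhat={}),
                       geometry=small_study.geometry, spec=SyncModelSpec(),
                       data_hash="x")

    def test_two_point_mean_sd(self, small_study):
        vals = {k: [-0.1, -0.3] for k in ALL_SYNC_SLOPES}
        fit = self._fit_like(vals, small_study)
        tr = export_transfer_priors(fit)
        for x in SYNC_TIME_COVARIATES:
            mu, sd = tr.priors[x]
            assert mu == pytest.approx(-0.2)
            assert sd == pytest.approx(0.1414, abs=1e-4)
        assert set(tr.priors) == set(SYNC_TIME_COVARIATES)  # dist/depth excluded

    def test_degenerate_posterior_rejected(self, small_study):
        vals = {k: [0.5, 0.5] for k in ALL_SYNC_SLOPES}
        fit = self._fit_like(vals, small_study)
        with pytest.raises(ValueError, match="sd = 0"):
            export_transfer_priors(fit)

    def test_exported_matches_recomputed_summary(self, small_sync_fit):
        tr = export_transfer_priors(small_sync_fit)
        for x in SYNC_TIME_COVARIATES:
            pooled = small_sync_fit.samples.pooled(f"beta_{x}")
            assert tr.priors[x][0] == pytest.approx(float(pooled.mean()))
            assert tr.priors[x][1] == pytest.approx(float(pooled.std(ddof=1)))


@pytest.fixture(scope="module")
def small_sync_fit(small_study):
    cfg = McmcConfig(n_chains=2, n_iterations=1500, burn_in=600, thin=3, seed=19)
    return fit_sync_model(
        small_study.sync_matrix, small_study.covariates, small_study.geometry,
        mcmc_config=cfg,
    )


class TestDetectionCurve:
    def test_counterfactual_null(self, small_sync_fit):
        cond = {x: 0.4 for x in SYNC_TIME_COVARIATES}
        grid = np.array([100.0, 250.0, 400.0])
        a = predict_detection_curve(small_sync_fit, grid, cond, "baseline")
        b = predict_detection_curve(small_sync_fit, grid, cond, "storm")
        np.testing.assert_allclose(a.median, b.median)
        np.testing.assert_allclose(a.lower95, b.lower95)

    def test_negative_slopes_order_curves(self, small_study):
        """With all slope draws negative, storm conditions (higher covariate
        values) can only lower the curve."""
        from stormssm.sync_efficiency import SyncFit, SyncModelSpec
        from stormssm.mcmc import ConvergenceReport

        rng = np.random.default_rng(5)
        n = 200
        values = {f"beta_{k}": -np.abs(rng.normal(0.3, 0.1, n))
                  for k in ALL_SYNC_SLOPES}
        values["alpha"] = rng.normal(1.5, 0.3, size=(n, 4))
        cfg = McmcConfig(n_chains=1, n_iterations=n, burn_in=0, thin=1, seed=0)
        samples = PosteriorSamples(
            draws={k: v[None] for k, v in values.items()}, config=cfg
        )
        fit = SyncFit(samples=samples, convergence=ConvergenceReport(rhat={}),
                      geometry=small_study.geometry, spec=SyncModelSpec(),
                      data_hash="x")
        grid = np.linspace(100, 600, 11)
        base = predict_detection_curve(fit, grid, {x: 0.0 for x in SYNC_TIME_COVARIATES})
        storm = predict_detection_curve(fit, grid, {x: 2.0 for x in SYNC_TIME_COVARIATES},
                                        "storm")
        assert np.all(storm.median <= base.median + 1e-12)
        # negative distance slope -> non-increasing median curve
        assert np.all(np.diff(base.median) <= 1e-12)

    def test_positive_distance_rejected(self, small_sync_fit):
        with pytest.raises(ValueError):
            predict_detection_curve(
                small_sync_fit, np.array([-10.0, 100.0]),
                {x: 0.0 for x in SYNC_TIME_COVARIATES},
            )


class TestFitBehaviour:
    def test_saturated_data_pushes_intercepts_to_bound(self, small_study):
        m = small_study.sync_matrix
        ones = HourlyDetectionMatrix(
            m.transmitters, m.receivers, m.window,
            np.ones_like(m.values),
        )
        cfg = McmcConfig(n_chains=1, n_iterations=800, burn_in=300, thin=2, seed=3)
        fit = fit_sync_model(ones, small_study.covariates, small_study.geometry,
                             mcmc_config=cfg)
        alpha = fit.samples.pooled("alpha")
        assert np.median(alpha) > 2.5          # piled near the +4 bound
        assert np.all(np.abs(alpha) < 4.0)     # uniform support respected

    def test_joint_hour_permutation_leaves_posterior_unchanged(self, small_study):
        """The Bernoulli likelihood is exchangeable over hours: permuting data
        and covariates together yields bit-identical draws at a fixed seed."""
        import pandas as pd
        from stormssm.telemetry_io import CovariateTable

        cfg = McmcConfig(n_chains=1, n_iterations=400, burn_in=100, thin=2, seed=23)
        fit1 = fit_sync_model(small_study.sync_matrix, small_study.covariates,
                              small_study.geometry, mcmc_config=cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_study.config.window_hours)
        cov = small_study.covariates
        cov_p = CovariateTable(
            window=cov.window,
            raw=pd.DataFrame(cov.raw.to_numpy()[perm], columns=cov.raw.columns,
                             index=cov.raw.index),
            standardized=pd.DataFrame(cov.standardized.to_numpy()[perm],
                                      columns=cov.standardized.columns,
                                      index=cov.standardized.index),
            records=cov.records,
        )
        m = small_study.sync_matrix
        m_p = HourlyDetectionMatrix(m.transmitters, m.receivers, m.window,
                                    m.values[:, :, perm])
        fit2 = fit_sync_model(m_p, cov_p, small_study.geometry, mcmc_config=cfg)
        for name in [f"beta_{n}" for n in ALL_SYNC_SLOPES]:
            np.testing.assert_array_equal(fit1.samples.get(name),
                                          fit2.samples.get(name))

    def test_posterior_predictive_pair_rates_covered(self, small_study, small_sync_fit):
        """95% posterior intervals of per-pair hourly detection rates should
        cover most empirical pair rates."""
        g = small_study.geometry
        y = np.stack([
            small_study.sync_matrix.values[
                small_study.sync_matrix.transmitters.index(tag),
                small_study.sync_matrix.receivers.index(recv),
            ]
            for tag, recv in g.pairs
        ])
        emp = y.mean(axis=1)
        alpha = small_sync_fit.samples.pooled("alpha")          # (D, P)
        bt = np.column_stack([small_sync_fit.samples.pooled(f"beta_{x}")
                              for x in SYNC_TIME_COVARIATES])   # (D, 5)
        bp = np.column_stack([small_sync_fit.samples.pooled("beta_dist"),
                              small_sync_fit.samples.pooled("beta_depth")])
        xt = small_study.covariates.z_matrix(SYNC_TIME_COVARIATES)
        xp = np.column_stack([g.log_distance_z, g.depth_z])
        covered = 0
        u = bt @ xt.T                                           # (D, T)
        for p in range(g.n_pairs):
            eta = alpha[:, p][:, None] + (bp @ xp[p])[:, None] + u
            rates = (1.0 / (1.0 + np.exp(-eta))).mean(axis=1)
            lo, hi = np.quantile(rates, [0.025, 0.975])
            margin = 3.0 * math.sqrt(emp[p] * (1 - emp[p]) / y.shape[1] + 1e-6)
            covered += (lo - margin) <= emp[p] <= (hi + margin)
        assert covered >= 0.9 * g.n_pairs


class TestDiagnostics:
    def test_self_correlation_and_duplicate_flagged(self, small_study):
        cov = small_study.covariates
        corr, flags = covariate_diagnostics(cov)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)
        cov.standardized["dup"] = cov.standardized["wind"]
        try:
            corr2, flags2 = covariate_diagnostics(cov)
            assert any({a, b} == {"wind", "dup"} and abs(r - 1.0) < 1e-12
                       for a, b, r in flags2)
        finally:
            cov.standardized.drop(columns="dup", inplace=True)

    def test_independent_series_weakly_correlated(self):
        from conftest import make_window, random_covariates

        cov = random_covariates(make_window(hours=2000), np.random.default_rng(9))
        corr, flags = covariate_diagnostics(cov)
        assert not flags
        off = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
        assert np.abs(off).max() < 0.12

    def test_condition_covariates_sharks_held_at_mean(self, small_study):
        conds = condition_covariates(small_study.covariates,
                                     small_study.config.storm_window)
        assert conds["baseline"]["sharks"] == 0.0
        assert conds["storm"]["sharks"] == 0.0
        assert conds["storm"]["noise"] > conds["baseline"]["noise"]
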