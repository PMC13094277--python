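"""Bayesian logistic regression for hourly sync-tag detection efficiency.

Stationary synchronization transmitters housed inside receivers provide a
continuous probe of array performance: whether sync tag i was logged by
receiver j in hour t is modelled as

    y[i,j,t] ~ Bernoulli(p[i,j,t])
    logit(p[i,j,t]) = alpha_{i,j} + b_dist * logDIST_{i,j} + b_depth * DEPTH_j
                      + b_wind WIND_t + b_waves WAVES_t + b_noise NOISE_t
                      + b_tilt TILT_t + b_sharks SHARKS_t

with a free intercept per admissible tag-receiver pair,
alpha_{i,j} ~ Uniform(-4, 4) on the logit scale, and every slope
~ Normal(0, sd=1).  Covariates are standardized (log-distance after the log
transform).  The posterior means and sds of the five time-varying slopes are
exported as informative normal priors for the occupancy model's observation
layer.

Note on identifiability: because each pair carries a free intercept, the
pair-constant slopes (log-distance, depth) are informed only through the
intercepts' bounded support and their own priors; they are reported but are
weakly identified by construction.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .mcmc import (
    AdaptiveScale,
    ConvergenceReport,
    McmcConfig,
    PosteriorSamples,
    effective_sample_size,
    gelman_rubin,
    posterior_summary,
    run_chains,
)
from .occupancy import OBS_COVARIATES, TransferPrior
from .telemetry_io import CovariateTable, HourlyDetectionMatrix, PairGeometry

__all__ = [
    "SYNC_TIME_COVARIATES",
    "SYNC_PAIR_COVARIATES",
    "SyncModelSpec",
    "SyncFit",
    "DetectionCurve",
    "sync_linear_predictor",
    "sync_loglik",
    "fit_sync_model",
    "export_transfer_priors",
    "predict_detection_curve",
    "condition_covariates",
    "covariate_diagnostics",
]

SYNC_TIME_COVARIATES = ("wind", "waves", "noise", "tilt", "sharks")
SYNC_PAIR_COVARIATES = ("dist", "depth")
ALL_SYNC_SLOPES = SYNC_PAIR_COVARIATES + SYNC_TIME_COVARIATES


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class SyncModelSpec:
    """Priors and pair admissibility for the detection-efficiency model."""

    alpha_bound: float = 4.0          # alpha ~ Uniform(-bound, bound), logit scale
    slope_prior_sd: float = 1.0       # beta ~ Normal(0, sd)
    max_distance_m: float = 800.0     # admissible pair cutoff


def sync_linear_predictor(
    alpha_pair: float,
    betas: Mapping[str, float],
    covariates_at_t: Mapping[str, float],
) -> float:
    """Detection probability for one pair-hour from standardized covariates.

    ``betas`` keys: dist, depth, wind, waves, noise, tilt, sharks;
    ``covariates_at_t`` must supply logdist/depth (pair statics) and the five
    time-varying values, all on the standardized scale.
    """
    names = ("logdist", "depth") + SYNC_TIME_COVARIATES
    missing = [n for n in names if n not in covariates_at_t]
    if missing:
        raise KeyError(f"missing covariate terms: {missing}")
    missing_b = [b for b in ALL_SYNC_SLOPES if b not in betas]
    if missing_b:
        raise KeyError(f"missing slope coefficients: {missing_b}")
    eta = (
        alpha_pair
        + betas["dist"] * covariates_at_t["logdist"]
        + betas["depth"] * covariates_at_t["depth"]
        + sum(betas[x] * covariates_at_t[x] for x in SYNC_TIME_COVARIATES)
    )
    return float(_logistic(eta))


def sync_loglik(
    alpha: np.ndarray,
    beta_pair: np.ndarray,
    beta_time: np.ndarray,
    y: np.ndarray,
    x_pair: np.ndarray,
    x_time: np.ndarray,
) -> float:
    """Total Bernoulli log-likelihood over all pair-hour cells (reference form)."""
    eta = (alpha + x_pair @ beta_pair)[:, None] + (x_time @ beta_time)[None, :]
    return float((y * eta).sum() - np.logaddexp(0.0, eta).sum())


class _SyncKernel:
    """Adaptive Metropolis-within-Gibbs over {pair intercepts}, {time slopes},
    {pair-static slopes}."""

    def __init__(self, y, x_pair, x_time, spec: SyncModelSpec, cfg: McmcConfig,
                 rng: np.random.Generator):
        self.rng = rng
        self.y = y                      # (P, T) uint8 -> float for einsums
        self.p, self.t = y.shape
        self.x_pair = x_pair            # (P, 2) standardized [logdist, depth]
        self.x_time = x_time            # (T, 5)
        self.spec = spec
        self.k_pair = y.sum(axis=1).astype(float)    # (P,)
        self.m_time = y.sum(axis=0).astype(float)    # (T,)

        bound = spec.alpha_bound
        rate = np.clip(y.mean(axis=1), 1e-3, 1 - 1e-3)
        self.alpha = np.clip(np.log(rate / (1 - rate)), -bound + 0.1, bound - 0.1)
        self.alpha += rng.normal(0.0, 0.05, size=self.p)
        self.alpha = np.clip(self.alpha, -bound + 0.05, bound - 0.05)
        self.beta_time = np.zeros(len(SYNC_TIME_COVARIATES))
        self.beta_pair = np.zeros(len(SYNC_PAIR_COVARIATES))

        self.u = self.x_time @ self.beta_time        # (T,)
        self.pc = self.x_pair @ self.beta_pair       # (P,)
        self.sp = self._softplus_sums(self.alpha + self.pc, self.u)

        self.sc_alpha = AdaptiveScale(self.p, 0.5, target=0.44, rate=cfg.adapt_rate)
        self.sc_time = AdaptiveScale(len(SYNC_TIME_COVARIATES), 0.05,
                                     target=cfg.adapt_target, rate=cfg.adapt_rate)
        self.sc_pair = AdaptiveScale(len(SYNC_PAIR_COVARIATES), 0.1,
                                     target=cfg.adapt_target, rate=cfg.adapt_rate)
        self.sc_ridge = AdaptiveScale(len(SYNC_PAIR_COVARIATES), 0.3,
                                      target=0.44, rate=cfg.adapt_rate)

    def _softplus_sums(self, a, u):
        """(P,) row sums of softplus(a_p + u_t)."""
        return np.logaddexp(0.0, a[:, None] + u[None, :]).sum(axis=1)

    def step(self, iteration: int, adapting: bool) -> None:
        rng = self.rng
        bound = self.spec.alpha_bound
        sd_b = self.spec.slope_prior_sd

        # pair intercepts: independent likelihoods given slopes
        prop = self.alpha + rng.normal(0.0, self.sc_alpha.scale, size=self.p)
        inb = np.abs(prop) < bound
        sp_prop = self._softplus_sums(prop + self.pc, self.u)
        delta = (prop - self.alpha) * self.k_pair - (sp_prop - self.sp)
        acc = inb & (np.log(rng.uniform(size=self.p)) < delta)
        self.alpha[acc] = prop[acc]
        self.sp[acc] = sp_prop[acc]
        if adapting:
            self.sc_alpha.update(acc.astype(float))

        # time-varying slopes: joint random-walk block
        prop_bt = self.beta_time + rng.normal(0.0, self.sc_time.scale)
        u_prop = self.x_time @ prop_bt
        sp_prop = self._softplus_sums(self.alpha + self.pc, u_prop)
        dll = ((u_prop - self.u) * self.m_time).sum() - (sp_prop - self.sp).sum()
        dlp = -0.5 * ((prop_bt**2).sum() - (self.beta_time**2).sum()) / sd_b**2
        if math.log(rng.uniform()) < dll + dlp:
            self.beta_time = prop_bt
            self.u = u_prop
            self.sp = sp_prop
            acc_t = 1.0
        else:
            acc_t = 0.0
        if adapting:
            self.sc_time.update(np.full(len(SYNC_TIME_COVARIATES), acc_t))

        # pair-static slopes (weakly identified; mixing dominated by prior)
        prop_bp = self.beta_pair + rng.normal(0.0, self.sc_pair.scale)
        pc_prop = self.x_pair @ prop_bp
        sp_prop = self._softplus_sums(self.alpha + pc_prop, self.u)
        dll = ((pc_prop - self.pc) * self.k_pair).sum() - (sp_prop - self.sp).sum()
        dlp = -0.5 * ((prop_bp**2).sum() - (self.beta_pair**2).sum()) / sd_b**2
        if math.log(rng.uniform()) < dll + dlp:
            self.beta_pair = prop_bp
            self.pc = pc_prop
            self.sp = sp_prop
            acc_p = 1.0
        else:
            acc_p = 0.0
        if adapting:
            self.sc_pair.update(np.full(len(SYNC_PAIR_COVARIATES), acc_p))

        # ridge translation: a pair-constant slope and the intercepts trade off
        # one-for-one (eta is invariant under beta_k += d, alpha -= d * x_k),
        # so move along that ridge directly; the likelihood cancels exactly and
        # acceptance depends only on the priors (linear map, unit Jacobian).
        acc_r = np.zeros(len(SYNC_PAIR_COVARIATES))
        for k in range(len(SYNC_PAIR_COVARIATES)):
            d = rng.normal(0.0, self.sc_ridge.scale[k])
            alpha_prop = self.alpha - d * self.x_pair[:, k]
            if np.all(np.abs(alpha_prop) < bound):
                new_b = self.beta_pair[k] + d
                dlp = -0.5 * (new_b**2 - self.beta_pair[k] ** 2) / sd_b**2
                if math.log(rng.uniform()) < dlp:
                    self.beta_pair[k] = new_b
                    self.alpha = alpha_prop
                    self.pc = self.x_pair @ self.beta_pair
                    acc_r[k] = 1.0
        if adapting:
            self.sc_ridge.update(acc_r)

    def snapshot(self) -> dict:
        snap = {"alpha": self.alpha.copy()}
        for k, name in enumerate(SYNC_PAIR_COVARIATES):
            snap[f"beta_{name}"] = self.beta_pair[k]
        for k, name in enumerate(SYNC_TIME_COVARIATES):
            snap[f"beta_{name}"] = self.beta_time[k]
        return snap


@dataclass
class SyncFit:
    """Posterior of the detection-efficiency regression."""

    samples: PosteriorSamples
    convergence: ConvergenceReport
    geometry: PairGeometry
    spec: SyncModelSpec
    data_hash: str

    def summary(self, parameter: str) -> dict[str, float]:
        return posterior_summary(self.samples, parameter)

    def slope_names(self) -> list[str]:
        return [f"beta_{n}" for n in ALL_SYNC_SLOPES]


def _pair_matrix(matrix: HourlyDetectionMatrix, geometry: PairGeometry,
                 receivers_meta=None) -> np.ndarray:
    """(P, T) binary outcomes aligned with the geometry's pair list.

    Pairs reference (sync_tag_id, receiver_id); the detection matrix's
    transmitter axis must contain the sync-tag ids.
    """
    t_idx = {t: i for i, t in enumerate(matrix.transmitters)}
    r_idx = {r: i for i, r in enumerate(matrix.receivers)}
    rows = []
    for tag, recv in geometry.pairs:
        if tag not in t_idx:
            raise KeyError(f"sync tag {tag!r} not in detection matrix")
        if recv not in r_idx:
            raise KeyError(f"receiver {recv!r} not in detection matrix")
        rows.append(matrix.values[t_idx[tag], r_idx[recv]])
    return np.ascontiguousarray(np.stack(rows))


def fit_sync_model(
    matrix: HourlyDetectionMatrix,
    covariates: CovariateTable,
    geometry: PairGeometry,
    spec: SyncModelSpec | None = None,
    mcmc_config: McmcConfig | None = None,
) -> SyncFit:
    """Fit the Bernoulli-logit detection-efficiency model by MCMC.

    ``matrix`` must be restricted to sync-tag transmitters.  Raises no error
    on poor mixing: convergence (R-hat < 1.05 on all slopes) is reported in
    the returned fit and must be checked by the caller.
    """
    spec = spec or SyncModelSpec()
    cfg = mcmc_config or McmcConfig()
    if geometry.n_pairs < 2:
        raise ValueError("need at least 2 sync tag-receiver pairs")
    y = _pair_matrix(matrix, geometry)
    x_pair = np.column_stack([geometry.log_distance_z, geometry.depth_z])
    x_time = covariates.z_matrix(SYNC_TIME_COVARIATES)
    if y.shape[1] != x_time.shape[0]:
        raise ValueError("detection matrix and covariates cover different windows")

    samples = run_chains(
        lambda rng, c: _SyncKernel(y, x_pair, x_time, spec, cfg, rng), cfg
    )
    monitored = [f"beta_{n}" for n in ALL_SYNC_SLOPES]
    rhat, ess = {}, {}
    if cfg.n_chains >= 2:
        for n in monitored:
            rhat[n] = gelman_rubin(samples, n)
            ess[n] = effective_sample_size(samples.scalar(n))
    report = ConvergenceReport(rhat=rhat, ess=ess)

    h = hashlib.sha256()
    h.update(y.tobytes())
    h.update(x_time.tobytes())
    return SyncFit(samples=samples, convergence=report, geometry=geometry,
                   spec=spec, data_hash=h.hexdigest()[:16])


def export_transfer_priors(fit: SyncFit, require_converged: bool = False) -> TransferPrior:
    """Posterior mean/sd of the five time-varying slopes as normal priors.

    Distance, depth and the pair intercepts are deliberately excluded: only
    effects that also act on animal-tag detections transfer to the occupancy
    observation layer.
    """
    if require_converged and not fit.convergence.passed:
        raise RuntimeError("sync model did not satisfy the convergence threshold")
    priors: dict[str, tuple[float, float]] = {}
    for name in OBS_COVARIATES:
        key = f"beta_{name}"
        if key not in fit.samples.parameter_names():
            raise KeyError(f"coefficient {key!r} absent from posterior")
        pooled = fit.samples.pooled(key)
        mu = float(pooled.mean())
        sd = float(pooled.std(ddof=1))
        if sd <= 0.0:
            raise ValueError(f"degenerate posterior for {key!r}: sd = 0")
        priors[name] = (mu, sd)
    return TransferPrior(priors)


def condition_covariates(
    covariates: CovariateTable, storm_window
) -> dict[str, dict[str, float]]:
    """Baseline vs storm condition values for counterfactual prediction.

    Baseline = per-covariate mean (standardized scale) over non-storm hours;
    storm = mean over the storm window; the animal-density covariate is held
    at its overall mean (0) in both conditions.
    """
    hours = covariates.window.hours
    in_storm = (hours >= storm_window.start) & (hours < storm_window.end)
    if not in_storm.any():
        raise ValueError("storm window does not intersect the study window")
    out: dict[str, dict[str, float]] = {}
    for name, mask in (("baseline", ~in_storm), ("storm", in_storm)):
        vals = {x: float(covariates.z(x)[mask].mean()) for x in SYNC_TIME_COVARIATES}
        vals["sharks"] = 0.0
        out[name] = vals
    return out


@dataclass
class DetectionCurve:
    """Counterfactual detection probability vs distance for one condition."""

    distances_m: np.ndarray
    condition: str
    median: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray

    def __post_init__(self):
        for a in (self.median, self.lower95, self.upper95):
            if np.any((a < 0) | (a > 1)):
                raise ValueError("curve values must lie in [0, 1]")
        if np.any(self.lower95 > self.median) or np.any(self.median > self.upper95):
            raise ValueError("interval must bracket the median")

    def at(self, distance_m: float) -> float:
        return float(np.interp(distance_m, self.distances_m, self.median))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_m": self.distances_m,
                "condition": self.condition,
                "median": self.median,
                "lower95": self.lower95,
                "upper95": self.upper95,
            }
        )


def predict_detection_curve(
    fit: SyncFit,
    distance_grid: np.ndarray,
    condition_values: Mapping[str, float],
    condition: str = "baseline",
    depth_z: float | None = None,
) -> DetectionCurve:
    """Population-level detection-probability curve over distance.

    Per posterior draw d and distance r the curve evaluates
    logistic(mean_p alpha_p^(d) + b_dist^(d) z(ln r) + b_depth^(d) z_depth
    + sum_x b_x^(d) x_cond): pair intercepts enter through their across-pair
    mean (they absorb pair-level baseline), depth defaults to the array mean
    (z = 0).
    """
    distance_grid = np.asarray(distance_grid, dtype=float)
    if np.any(distance_grid <= 0):
        raise ValueError("distances must be strictly positive")
    missing = [x for x in SYNC_TIME_COVARIATES if x not in condition_values]
    if missing:
        raise KeyError(f"condition covariates missing: {missing}")
    logd_z = fit.geometry.log_distance_record.apply(np.log(distance_grid))
    if depth_z is None:
        depth_z = 0.0

    alpha_bar = fit.samples.pooled("alpha").mean(axis=1)        # (draws,)
    b = {n: fit.samples.pooled(f"beta_{n}") for n in ALL_SYNC_SLOPES}
    shift = sum(b[x] * condition_values[x] for x in SYNC_TIME_COVARIATES)
    eta = (
        alpha_bar[None, :]
        + b["dist"][None, :] * logd_z[:, None]
        + b["depth"][None, :] * depth_z
        + shift[None, :]
    )                                                            # (R, draws)
    p = _logistic(eta)
    lo, med, hi = np.quantile(p, [0.025, 0.5, 0.975], axis=1)
    return DetectionCurve(distance_grid, condition, med, lo, hi)


def covariate_diagnostics(
    covariates: CovariateTable, threshold: float = 0.7
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations of the standardized predictors.

    Returns the full correlation matrix and the list of pairs whose absolute
    correlation exceeds ``threshold`` (collinearity flags).
    """
    corr = covariates.standardized.corr()
    flags = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for bname in cols[i + 1:]:
            r = float(corr.loc[a, bname])
            if abs(r) > threshold:
                flags.append((a, bname, r))
    return corr, flags
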