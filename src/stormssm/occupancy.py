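"""Latent two-state occupancy state-space model with covariate-driven emigration.

Each tagged animal is either present (Z=1) in the receiver array or absent
(Z=0) in each study hour.  Presence evolves as a first-order Markov chain:

    Z[i,t] | Z[i,t-1] ~ Bernoulli(psi[i,t])
    psi[i,t] = 1 - phi_emig[i,t]   if Z[i,t-1] = 1
             = phi_return          if Z[i,t-1] = 0

    logit(phi_emig[i,t]) = alpha_i + b_sin sin(2 pi h_t / 24)
                           + b_cos cos(2 pi h_t / 24)
                           + b_wind WIND_t + b_waves WAVES_t + b_baro BARO_t
                           + b_sst SST_t + b_sal SAL_t + b_turb TURB_t
    logit(phi_return) = alpha_return        (no covariates)

with a shark-level random intercept alpha_i ~ Normal(mu_a, sigma_a^2),
mu_a ~ Normal(0, 2^2), tau_a = sigma_a^-2 ~ Gamma(1, 1), all slopes
~ Normal(0, 2^2), alpha_return ~ Normal(0, 2^2).

Detections are conditional on presence (an absent animal cannot be detected):

    y[i,j,t] | Z[i,t] ~ Bernoulli(Z[i,t] * p_det[j,t])
    logit(p_det[j,t]) = logit(theta_j) + b^det . x_t      (full variant)
    p_det[j,t] = theta_j                                  (reduced variant)

with theta_j ~ Beta(1,1) and informative transfer priors
b^det_x ~ Normal(mu^sync_x, (sigma^sync_x)^2) taken from the sync-tag
detection-efficiency model (x in {wind, waves, noise, tilt, sharks}).

Inference marginalizes the latent chain exactly by the forward algorithm
(default) or samples it by forward-filter/backward-sampling (data
augmentation); both samplers target the same posterior and are cross-checked
in the test suite.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from ._forward import forward_backward, forward_loglik, ffbs_sample
from .mcmc import (
    AdaptiveScale,
    ConvergenceReport,
    McmcConfig,
    PosteriorSamples,
    posterior_summary,
    run_chains,
)
from .telemetry_io import CovariateTable, HourlyDetectionMatrix

__all__ = [
    "STATE_COVARIATES",
    "OBS_COVARIATES",
    "EmigrationParams",
    "ReturnParams",
    "ObservationParams",
    "TransferPrior",
    "SsmFit",
    "transition_prob",
    "emigration_prob",
    "detection_prob",
    "emission_prob",
    "marginal_loglik",
    "fit_ssm",
    "decode_occupancy",
]

STATE_COVARIATES = ("wind", "waves", "baro", "sst", "sal", "turb")
OBS_COVARIATES = ("wind", "waves", "noise", "tilt", "sharks")

#: order of the state-process slope vector
STATE_SLOPES = ("sin", "cos") + STATE_COVARIATES


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


@dataclass
class TransferPrior:
    """Normal priors for the observation slopes, transferred from the
    sync-tag model posterior (mean, sd per covariate)."""

    priors: dict[str, tuple[float, float]]  # name -> (mu, sd)

    def __post_init__(self):
        missing = [x for x in OBS_COVARIATES if x not in self.priors]
        if missing:
            raise ValueError(f"transfer prior missing coefficients: {missing}")
        for name, (_, sd) in self.priors.items():
            if not sd > 0:
                raise ValueError(f"transfer prior for {name!r} has sd {sd} (must be > 0)")

    @property
    def mu(self) -> np.ndarray:
        return np.array([self.priors[x][0] for x in OBS_COVARIATES])

    @property
    def sd(self) -> np.ndarray:
        return np.array([self.priors[x][1] for x in OBS_COVARIATES])

    def to_dict(self) -> dict:
        return {k: {"mu": v[0], "sd": v[1]} for k, v in self.priors.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransferPrior":
        return cls({k: (float(v["mu"]), float(v["sd"])) for k, v in d.items()})


@dataclass
class EmigrationParams:
    alpha: np.ndarray          # per-animal intercepts, logit scale
    mu_a: float
    sigma_a: float
    beta_sin: float
    beta_cos: float
    beta: dict[str, float]     # wind, waves, baro, sst, sal, turb

    def __post_init__(self):
        if self.sigma_a <= 0:
            raise ValueError("sigma_a must be > 0")
        missing = [x for x in STATE_COVARIATES if x not in self.beta]
        if missing:
            raise ValueError(f"missing emigration slopes: {missing}")

    @property
    def slope_vector(self) -> np.ndarray:
        return np.array(
            [self.beta_sin, self.beta_cos] + [self.beta[x] for x in STATE_COVARIATES]
        )


@dataclass
class ReturnParams:
    alpha_return: float

    @property
    def phi_return(self) -> float:
        return float(_logistic(self.alpha_return))


@dataclass
class ObservationParams:
    theta: np.ndarray                    # per-receiver baseline probabilities
    beta_det: dict[str, float] | None    # None in the reduced variant

    def __post_init__(self):
        th = np.asarray(self.theta, dtype=float)
        if np.any(th <= 0) or np.any(th >= 1):
            raise ValueError("theta_j must lie strictly in (0, 1)")
        self.theta = th


def diel_terms(hour) -> tuple[np.ndarray, np.ndarray]:
    """sin/cos of the 24-h cycle at (possibly fractional) hour of day."""
    h = np.asarray(hour, dtype=float)
    ang = 2.0 * np.pi * h / 24.0
    return np.sin(ang), np.cos(ang)


def transition_prob(z_prev: int, phi_emig: float, phi_return: float) -> float:
    """P(Z_t = 1 | Z_{t-1} = z_prev)."""
    if z_prev not in (0, 1):
        raise ValueError("z_prev must be 0 or 1")
    for name, p in (("phi_emig", phi_emig), ("phi_return", phi_return)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    return 1.0 - phi_emig if z_prev == 1 else phi_return


def emigration_prob(
    alpha_i: float,
    params: "EmigrationParams | None" = None,
    covariates_at_t: Mapping[str, float] | None = None,
    hour_t: float = 0.0,
    slopes: np.ndarray | None = None,
) -> float:
    """Hourly emigration probability for one animal.

    phi = logistic(alpha_i + b_sin sin + b_cos cos + sum_x b_x x_t); exactly
    periodic in ``hour_t`` with period 24.
    """
    if slopes is None:
        slopes = params.slope_vector
    covariates_at_t = covariates_at_t or {}
    missing = [x for x in STATE_COVARIATES if x not in covariates_at_t]
    if missing:
        raise KeyError(f"missing emigration covariates: {missing}")
    s, c = diel_terms(hour_t)
    x = np.array([s, c] + [covariates_at_t[k] for k in STATE_COVARIATES])
    return float(_logistic(alpha_i + x @ slopes))


def detection_prob(
    theta_j: float,
    beta_det: Mapping[str, float] | None,
    covariates_at_t: Mapping[str, float] | None,
    variant: Literal["full", "reduced"] = "full",
) -> float:
    """Receiver-hour detection probability under either model variant."""
    if not 0.0 < theta_j < 1.0:
        raise ValueError("theta_j must lie in (0, 1)")
    if variant == "reduced":
        return float(theta_j)
    covariates_at_t = covariates_at_t or {}
    missing = [x for x in OBS_COVARIATES if x not in covariates_at_t]
    if missing:
        raise KeyError(f"missing observation covariates: {missing}")
    eta = float(_logit(theta_j)) + sum(
        beta_det[x] * covariates_at_t[x] for x in OBS_COVARIATES
    )
    return float(_logistic(eta))


def emission_prob(y_vec, z: int, p_det_vec) -> float:
    """P(y over receivers | Z = z); zero-forcing when absent."""
    y = np.asarray(y_vec)
    p = np.asarray(p_det_vec, dtype=float)
    if y.shape != p.shape:
        raise ValueError("detection vector and probability vector length mismatch")
    if z == 0:
        return 0.0 if y.any() else 1.0
    return float(np.prod(np.where(y == 1, p, 1.0 - p)))


# ---------------------------------------------------------------------------
# Vectorized model machinery
# ---------------------------------------------------------------------------

def state_design(covariates: CovariateTable) -> np.ndarray:
    """(T, 8) design: [sin, cos, wind, waves, baro, sst, sal, turb]."""
    s, c = diel_terms(covariates.hour_local)
    return np.column_stack([s, c, covariates.z_matrix(STATE_COVARIATES)])


def obs_design(covariates: CovariateTable) -> np.ndarray:
    """(T, 5) design: [wind, waves, noise, tilt, sharks] (standardized)."""
    return covariates.z_matrix(OBS_COVARIATES)


def emigration_eta(alpha: np.ndarray, slopes: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """(N, T) emigration logits from intercepts, slope vector and design."""
    return np.asarray(alpha, dtype=float)[:, None] + (xs @ np.asarray(slopes))[None, :]


def detection_eta(
    logit_theta: np.ndarray, beta_det: np.ndarray | None, xo: np.ndarray
) -> np.ndarray:
    """(J, T) detection logits (reduced variant: constant rows)."""
    lt = np.asarray(logit_theta, dtype=float)[:, None]
    if beta_det is None:
        return np.broadcast_to(lt, (lt.shape[0], xo.shape[0])).copy()
    return lt + (xo @ np.asarray(beta_det))[None, :]


def _log1m_sigmoid(eta):
    # log(1 - logistic(eta)) = -softplus(eta)
    return -np.logaddexp(0.0, eta)


def emission_log_terms(y: np.ndarray, eta_det: np.ndarray) -> np.ndarray:
    """(N, T) log emission probability given presence.

    log P(y[i,:,t] | Z=1) = sum_j log(1-p[j,t]) + sum_j y[i,j,t] * eta_det[j,t]
    (the second term uses logit p = log p - log(1-p)).
    """
    base = _log1m_sigmoid(eta_det).sum(axis=0)  # (T,)
    return base[None, :] + np.einsum("ijt,jt->it", y, eta_det, optimize=True)


def marginal_loglik(
    y: np.ndarray,
    emig: EmigrationParams,
    ret: ReturnParams,
    obs: ObservationParams,
    covariates: CovariateTable,
    variant: Literal["full", "reduced"] = "full",
    initial_p_present: float = 0.5,
) -> np.ndarray:
    """Exact per-animal log P(y) by forward marginalization over the latent chain.

    ``y`` has shape (n_animals, n_receivers, T) (a single animal may pass
    (n_receivers, T)).
    """
    y = np.asarray(y, dtype=np.uint8)
    if y.ndim == 2:
        y = y[None]
    xs = state_design(covariates)
    xo = obs_design(covariates)
    eta_e = emigration_eta(emig.alpha, emig.slope_vector, xs)
    bdet = None if variant == "reduced" else np.array(
        [obs.beta_det[x] for x in OBS_COVARIATES]
    )
    eta_d = detection_eta(_logit(obs.theta), bdet, xo)
    le1 = emission_log_terms(y, eta_d)
    has = np.ascontiguousarray(y.any(axis=1).astype(np.uint8))
    return forward_loglik(
        np.ascontiguousarray(eta_e),
        float(ret.alpha_return),
        np.ascontiguousarray(le1),
        has,
        math.log(initial_p_present),
        math.log1p(-initial_p_present),
    )


def _data_hash(y: np.ndarray, covariates: CovariateTable) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(y).tobytes())
    h.update(covariates.standardized.to_numpy().tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

_PRIOR_SD = 2.0          # slopes, mu_a, alpha_return
_TAU_SHAPE = 1.0         # Gamma(1, 1) on tau_a
_TAU_RATE = 1.0


def _norm_lp(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2


class _SsmKernelBase:
    """Shared state and caches for both SSM samplers."""

    def __init__(self, data, config: McmcConfig, rng: np.random.Generator):
        (y, xs, xo, transfer, variant, pi1) = data
        self.rng = rng
        self.y = y                     # (N, J, T) uint8
        self.n, self.j, self.t = y.shape
        self.xs = xs
        self.xo = xo
        self.variant = variant
        self.transfer = transfer
        self.log_pi1 = math.log(pi1)
        self.log_pi0 = math.log1p(-pi1)
        self.has = np.ascontiguousarray(y.any(axis=1).astype(np.uint8))
        self.ndet = np.ascontiguousarray(y.sum(axis=1).astype(np.float64))  # (N, T)
        cfg = config

        # --- initial values -------------------------------------------------
        self.mu_a = -3.0 + rng.normal(0.0, 0.3)
        self.tau_a = 1.0 + rng.uniform(0.0, 1.0)
        self.alpha = self.mu_a + rng.normal(0.0, 0.2, size=self.n)
        self.beta_state = np.zeros(len(STATE_SLOPES))
        self.alpha_return = _logit(0.1) + rng.normal(0.0, 0.2)
        if self.n > 0:
            present = self.has.astype(bool)
            rate = np.array(
                [
                    self.y[:, jj, :][present].mean() if present.any() else 0.3
                    for jj in range(self.j)
                ]
            )
        else:
            rate = np.full(self.j, 0.3)
        self.logit_theta = np.asarray(_logit(np.clip(rate, 0.02, 0.98)))
        if variant == "full":
            self.beta_det = transfer.mu.copy()
        else:
            self.beta_det = None

        # --- caches ---------------------------------------------------------
        self._refresh_state_cache()
        self._refresh_obs_cache()

        # --- adaptation -----------------------------------------------------
        tgt = cfg.adapt_target
        self.sc_alpha = AdaptiveScale(self.n, 0.5, target=0.44, rate=cfg.adapt_rate)
        self.sc_bstate = AdaptiveScale(len(STATE_SLOPES), 0.3, target=0.44, rate=cfg.adapt_rate)
        self.sc_aret = AdaptiveScale((), 0.3, target=0.44, rate=cfg.adapt_rate)
        self.theta_groups = [
            np.arange(g, min(g + 4, self.j)) for g in range(0, self.j, 4)
        ]
        self.sc_theta = AdaptiveScale(len(self.theta_groups), 0.4, target=tgt, rate=cfg.adapt_rate)
        self.sc_bdet = AdaptiveScale(len(OBS_COVARIATES), 0.3, target=0.44, rate=cfg.adapt_rate)

    # -- caches -------------------------------------------------------------
    def _refresh_state_cache(self):
        self.drift = self.xs @ self.beta_state          # (T,)
        self.eta_emig = np.ascontiguousarray(self.alpha[:, None] + self.drift[None, :])

    def _refresh_obs_cache(self):
        self.u_obs = (
            self.xo @ self.beta_det if self.beta_det is not None else np.zeros(self.t)
        )
        self.eta_det = self.logit_theta[:, None] + self.u_obs[None, :]   # (J, T)
        self.base = _log1m_sigmoid(self.eta_det).sum(axis=0)             # (T,)
        self.le1 = np.ascontiguousarray(
            self.base[None, :] + np.einsum("ijt,jt->it", self.y, self.eta_det, optimize=True)
        )

    # -- conjugate random-intercept hyperpriors ------------------------------
    def _gibbs_hyper(self):
        prior_prec = 1.0 / _PRIOR_SD**2
        prec = prior_prec + self.n * self.tau_a
        mean = (self.tau_a * self.alpha.sum()) / prec
        self.mu_a = self.rng.normal(mean, 1.0 / math.sqrt(prec))
        shape = _TAU_SHAPE + 0.5 * self.n
        rate = _TAU_RATE + 0.5 * np.sum((self.alpha - self.mu_a) ** 2)
        self.tau_a = self.rng.gamma(shape, 1.0 / rate)

    @property
    def sigma_a(self) -> float:
        return 1.0 / math.sqrt(self.tau_a)

    def snapshot(self) -> dict:
        snap = {
            "mu_a": self.mu_a,
            "sigma_a": self.sigma_a,
            "alpha_return": self.alpha_return,
            "alpha": self.alpha.copy(),
            "theta": _logistic(self.logit_theta),
        }
        for k, name in enumerate(STATE_SLOPES):
            snap[f"beta_{name}"] = self.beta_state[k]
        if self.beta_det is not None:
            for k, name in enumerate(OBS_COVARIATES):
                snap[f"beta_det_{name}"] = self.beta_det[k]
        return snap


class MarginalSsmKernel(_SsmKernelBase):
    """Metropolis-within-Gibbs on the exactly marginalized likelihood."""

    def __init__(self, data, config, rng):
        super().__init__(data, config, rng)
        self.ll = self._forward()       # (N,) per-animal loglik

    def _forward(self, eta_emig=None, alpha_return=None, le1=None):
        return forward_loglik(
            eta_emig if eta_emig is not None else self.eta_emig,
            float(alpha_return if alpha_return is not None else self.alpha_return),
            le1 if le1 is not None else self.le1,
            self.has,
            self.log_pi1,
            self.log_pi0,
        )

    def step(self, iteration: int, adapting: bool) -> None:
        rng = self.rng
        # 1. animal intercepts (independent accept/reject per animal)
        if self.n > 0:
            prop = self.alpha + rng.normal(0.0, self.sc_alpha.scale, size=self.n)
            eta_prop = np.ascontiguousarray(self.eta_emig + (prop - self.alpha)[:, None])
            ll_prop = self._forward(eta_emig=eta_prop)
            sd_a = self.sigma_a
            delta = (
                ll_prop - self.ll
                + _norm_lp(prop, self.mu_a, sd_a)
                - _norm_lp(self.alpha, self.mu_a, sd_a)
            )
            acc = np.log(rng.uniform(size=self.n)) < delta
            self.alpha[acc] = prop[acc]
            self.eta_emig[acc] = eta_prop[acc]
            self.ll[acc] = ll_prop[acc]
            if adapting:
                self.sc_alpha.update(acc.astype(float))

        # 2. random-intercept hyperparameters (conjugate)
        self._gibbs_hyper()

        # 3. state slopes, coordinate-wise
        acc_b = np.zeros(len(STATE_SLOPES))
        for k in range(len(STATE_SLOPES)):
            delta_k = rng.normal(0.0, self.sc_bstate.scale[k])
            shift = self.xs[:, k] * delta_k
            eta_prop = np.ascontiguousarray(self.eta_emig + shift[None, :])
            ll_prop = self._forward(eta_emig=eta_prop)
            new = self.beta_state[k] + delta_k
            dlp = _norm_lp(new, 0.0, _PRIOR_SD) - _norm_lp(self.beta_state[k], 0.0, _PRIOR_SD)
            if math.log(rng.uniform()) < ll_prop.sum() - self.ll.sum() + dlp:
                self.beta_state[k] = new
                self.eta_emig = eta_prop
                self.ll = ll_prop
                acc_b[k] = 1.0
        if adapting:
            self.sc_bstate.update(acc_b)

        # 4. return intercept
        prop_ar = self.alpha_return + rng.normal(0.0, float(self.sc_aret.scale))
        ll_prop = self._forward(alpha_return=prop_ar)
        dlp = _norm_lp(prop_ar, 0.0, _PRIOR_SD) - _norm_lp(self.alpha_return, 0.0, _PRIOR_SD)
        acc_r = math.log(rng.uniform()) < ll_prop.sum() - self.ll.sum() + dlp
        if acc_r:
            self.alpha_return = prop_ar
            self.ll = ll_prop
        if adapting:
            self.sc_aret.update(float(acc_r))

        # 5. receiver baselines, in small groups (joint accept per group)
        acc_t = np.zeros(len(self.theta_groups))
        for g, idx in enumerate(self.theta_groups):
            delta_g = rng.normal(0.0, self.sc_theta.scale[g], size=len(idx))
            lt_prop = self.logit_theta.copy()
            lt_prop[idx] += delta_g
            eta_rows_new = lt_prop[idx][:, None] + self.u_obs[None, :]
            eta_rows_old = self.eta_det[idx]
            d_base = (
                _log1m_sigmoid(eta_rows_new).sum(axis=0)
                - _log1m_sigmoid(eta_rows_old).sum(axis=0)
            )
            d_y = np.einsum("ijt,j->it", self.y[:, idx, :], delta_g, optimize=True)
            le1_prop = np.ascontiguousarray(self.le1 + d_base[None, :] + d_y)
            ll_prop = self._forward(le1=le1_prop)
            # Beta(1,1) on theta => logistic-density jacobian on the logit scale
            jac = (
                _log1m_sigmoid(lt_prop[idx]) + _log1m_sigmoid(-lt_prop[idx])
                - _log1m_sigmoid(self.logit_theta[idx])
                - _log1m_sigmoid(-self.logit_theta[idx])
            ).sum()
            if math.log(rng.uniform()) < ll_prop.sum() - self.ll.sum() + jac:
                self.logit_theta = lt_prop
                self.eta_det[idx] = eta_rows_new
                self.base += d_base
                self.le1 = le1_prop
                self.ll = ll_prop
                acc_t[g] = 1.0
        if adapting:
            self.sc_theta.update(acc_t)

        # 6. observation slopes (full variant), coordinate-wise
        if self.beta_det is not None:
            acc_d = np.zeros(len(OBS_COVARIATES))
            mu_p, sd_p = self.transfer.mu, self.transfer.sd
            for k in range(len(OBS_COVARIATES)):
                delta_k = rng.normal(0.0, self.sc_bdet.scale[k])
                du = self.xo[:, k] * delta_k                     # (T,)
                eta_prop = self.eta_det + du[None, :]
                base_prop = _log1m_sigmoid(eta_prop).sum(axis=0)
                le1_prop = np.ascontiguousarray(
                    self.le1 + (base_prop - self.base)[None, :] + self.ndet * du[None, :]
                )
                ll_prop = self._forward(le1=le1_prop)
                new = self.beta_det[k] + delta_k
                dlp = _norm_lp(new, mu_p[k], sd_p[k]) - _norm_lp(
                    self.beta_det[k], mu_p[k], sd_p[k]
                )
                if math.log(rng.uniform()) < ll_prop.sum() - self.ll.sum() + dlp:
                    self.beta_det[k] = new
                    self.u_obs += du
                    self.eta_det = eta_prop
                    self.base = base_prop
                    self.le1 = le1_prop
                    self.ll = ll_prop
                    acc_d[k] = 1.0
            if adapting:
                self.sc_bdet.update(acc_d)


class AugmentedSsmKernel(_SsmKernelBase):
    """Data-augmentation sampler: draw Z by FFBS, then conditional updates.

    Targets the same posterior as :class:`MarginalSsmKernel`; retained for
    cross-validation of the two inference routes (their posterior means must
    agree within Monte-Carlo error).
    """

    def __init__(self, data, config, rng):
        super().__init__(data, config, rng)
        self.z = np.zeros((self.n, self.t), dtype=np.uint8)
        self._sample_z()

    def _sample_z(self):
        if self.n == 0:
            return
        u = self.rng.uniform(size=(self.n, self.t))
        self.z = ffbs_sample(
            self.eta_emig, float(self.alpha_return), self.le1, self.has,
            self.log_pi1, self.log_pi0, u,
        )

    def _trans_loglik(self, eta_emig=None, alpha_return=None, per_animal=False):
        """Transition log-likelihood of the sampled latent paths."""
        eta = self.eta_emig if eta_emig is None else eta_emig
        ar = self.alpha_return if alpha_return is None else alpha_return
        prev1 = self.z[:, :-1] == 1
        stay = self.z[:, 1:] == 1
        e = eta[:, 1:]
        # from presence: log(1-phi) if stayed, log(phi) if left
        lp1 = np.where(stay, _log1m_sigmoid(e), _log1m_sigmoid(-e))
        contrib1 = np.where(prev1, lp1, 0.0)
        # from absence: log(phi_ret) if returned, log(1-phi_ret) if stayed out
        l_ret = float(_log1m_sigmoid(-np.asarray(ar)))
        l_out = float(_log1m_sigmoid(np.asarray(ar)))
        contrib0 = np.where(~prev1, np.where(stay, l_ret, l_out), 0.0)
        per = (contrib1 + contrib0).sum(axis=1)
        return per if per_animal else per.sum()

    def _obs_loglik_per_receiver(self, eta_det=None):
        """(J,) Bernoulli log-likelihood over present animal-hours."""
        eta = self.eta_det if eta_det is None else eta_det
        zmask = self.z.astype(bool)                       # (N, T)
        n_present = zmask.sum(axis=0).astype(float)       # (T,)
        y_present = np.einsum("ijt,it->jt", self.y, zmask.astype(float), optimize=True)
        # sum over t of [ y+ * log p + (n_present - y+) * log(1-p) ]
        l1mp = _log1m_sigmoid(eta)
        return (y_present * (eta + l1mp) + (n_present[None, :] - y_present) * l1mp).sum(axis=1)

    def step(self, iteration: int, adapting: bool) -> None:
        rng = self.rng
        self._sample_z()

        if self.n > 0:
            # animal intercepts against the transition likelihood
            prop = self.alpha + rng.normal(0.0, self.sc_alpha.scale, size=self.n)
            eta_prop = self.eta_emig + (prop - self.alpha)[:, None]
            cur = self._trans_loglik(per_animal=True)
            new = self._trans_loglik(eta_emig=eta_prop, per_animal=True)
            sd_a = self.sigma_a
            delta = new - cur + _norm_lp(prop, self.mu_a, sd_a) - _norm_lp(
                self.alpha, self.mu_a, sd_a
            )
            acc = np.log(rng.uniform(size=self.n)) < delta
            self.alpha[acc] = prop[acc]
            self.eta_emig[acc] = eta_prop[acc]
            if adapting:
                self.sc_alpha.update(acc.astype(float))

        self._gibbs_hyper()

        # state slopes
        acc_b = np.zeros(len(STATE_SLOPES))
        cur_total = self._trans_loglik()
        for k in range(len(STATE_SLOPES)):
            delta_k = rng.normal(0.0, self.sc_bstate.scale[k])
            eta_prop = self.eta_emig + (self.xs[:, k] * delta_k)[None, :]
            new_total = self._trans_loglik(eta_emig=eta_prop)
            new = self.beta_state[k] + delta_k
            dlp = _norm_lp(new, 0.0, _PRIOR_SD) - _norm_lp(self.beta_state[k], 0.0, _PRIOR_SD)
            if math.log(rng.uniform()) < new_total - cur_total + dlp:
                self.beta_state[k] = new
                self.eta_emig = eta_prop
                cur_total = new_total
                acc_b[k] = 1.0
        if adapting:
            self.sc_bstate.update(acc_b)

        # return intercept: conjugate-free 1-D Metropolis on transition counts
        prop_ar = self.alpha_return + rng.normal(0.0, float(self.sc_aret.scale))
        cur = self._trans_loglik()
        new = self._trans_loglik(alpha_return=prop_ar)
        dlp = _norm_lp(prop_ar, 0.0, _PRIOR_SD) - _norm_lp(self.alpha_return, 0.0, _PRIOR_SD)
        acc_r = math.log(rng.uniform()) < new - cur + dlp
        if acc_r:
            self.alpha_return = prop_ar
        if adapting:
            self.sc_aret.update(float(acc_r))

        # receiver baselines: conditionally independent across receivers given Z
        if self.variant == "reduced" and self.n > 0:
            # conjugate Beta(1,1) update on present hours
            zmask = self.z.astype(bool)
            n_present = float(zmask.sum())
            for jj in range(self.j):
                det = float(self.y[:, jj, :][zmask].sum())
                theta = rng.beta(1.0 + det, 1.0 + n_present - det)
                self.logit_theta[jj] = float(_logit(np.clip(theta, 1e-9, 1 - 1e-9)))
        else:
            delta_g = rng.normal(0.0, 0.2, size=self.j)
            lt_prop = self.logit_theta + delta_g
            eta_prop = lt_prop[:, None] + self.u_obs[None, :]
            cur_j = self._obs_loglik_per_receiver()
            new_j = self._obs_loglik_per_receiver(eta_det=eta_prop)
            jac_new = _log1m_sigmoid(lt_prop) + _log1m_sigmoid(-lt_prop)
            jac_old = _log1m_sigmoid(self.logit_theta) + _log1m_sigmoid(-self.logit_theta)
            acc = np.log(rng.uniform(size=self.j)) < new_j - cur_j + jac_new - jac_old
            self.logit_theta[acc] = lt_prop[acc]

        self._refresh_obs_cache()

        # observation slopes
        if self.beta_det is not None:
            mu_p, sd_p = self.transfer.mu, self.transfer.sd
            acc_d = np.zeros(len(OBS_COVARIATES))
            cur_total = self._obs_loglik_per_receiver().sum()
            for k in range(len(OBS_COVARIATES)):
                delta_k = rng.normal(0.0, self.sc_bdet.scale[k])
                eta_prop = self.eta_det + (self.xo[:, k] * delta_k)[None, :]
                new_total = self._obs_loglik_per_receiver(eta_det=eta_prop).sum()
                new = self.beta_det[k] + delta_k
                dlp = _norm_lp(new, mu_p[k], sd_p[k]) - _norm_lp(
                    self.beta_det[k], mu_p[k], sd_p[k]
                )
                if math.log(rng.uniform()) < new_total - cur_total + dlp:
                    self.beta_det[k] = new
                    self.eta_det = eta_prop
                    cur_total = new_total
                    acc_d[k] = 1.0
            if adapting:
                self.sc_bdet.update(acc_d)
            self._refresh_obs_cache()


@dataclass
class SsmFit:
    """Fitted occupancy model: draws, convergence, decoded latent states."""

    samples: PosteriorSamples
    convergence: ConvergenceReport
    occupancy: np.ndarray              # (N, T) posterior P(Z=1)
    variant: str
    animals: list[str]
    receivers: list[str]
    data_hash: str
    initial_p_present: float = 0.5

    def summary(self, parameter: str) -> dict[str, float]:
        return posterior_summary(self.samples, parameter)

    def state_slope_names(self) -> list[str]:
        return [f"beta_{n}" for n in STATE_SLOPES]


def _prepare_data(matrix, covariates, transfer_prior, variant, initial_p_present):
    y = np.ascontiguousarray(matrix.values, dtype=np.uint8)
    if y.shape[2] != covariates.window.n_hours:
        raise ValueError("detection matrix and covariates cover different windows")
    if variant == "full":
        if transfer_prior is None:
            raise ValueError("full variant requires a transfer prior")
    xs = state_design(covariates)
    xo = obs_design(covariates)
    return (y, xs, xo, transfer_prior, variant, initial_p_present)


def fit_ssm(
    matrix: HourlyDetectionMatrix,
    covariates: CovariateTable,
    transfer_prior: TransferPrior | None,
    variant: Literal["full", "reduced"] = "full",
    mcmc_config: McmcConfig | None = None,
    method: Literal["marginal", "augmented"] = "marginal",
    initial_p_present: float = 0.5,
    decode_draws: int = 200,
) -> SsmFit:
    """Fit the occupancy SSM and decode latent presence probabilities.

    ``method='marginal'`` (default) integrates the latent chain out exactly
    each likelihood evaluation; ``method='augmented'`` alternates FFBS draws
    of the chain with conditional parameter updates.
    """
    cfg = mcmc_config or McmcConfig()
    data = _prepare_data(matrix, covariates, transfer_prior, variant, initial_p_present)
    kernel_cls = MarginalSsmKernel if method == "marginal" else AugmentedSsmKernel

    samples = run_chains(lambda rng, c: kernel_cls(data, cfg, rng), cfg)
    monitored = (
        ["mu_a", "sigma_a", "alpha_return"]
        + [f"beta_{n}" for n in STATE_SLOPES]
        + ([f"beta_det_{n}" for n in OBS_COVARIATES] if variant == "full" else [])
    )
    rhat = {n: float(np.nan) for n in monitored}
    ess = {}
    if cfg.n_chains >= 2:
        from .mcmc import effective_sample_size, gelman_rubin

        for n in monitored:
            rhat[n] = gelman_rubin(samples, n)
            ess[n] = effective_sample_size(samples.scalar(n))
    report = ConvergenceReport(rhat=rhat, ess=ess)

    occupancy = decode_occupancy(
        samples, matrix, covariates, variant,
        initial_p_present=initial_p_present, max_draws=decode_draws,
        seed=cfg.seed,
    )
    return SsmFit(
        samples=samples,
        convergence=report,
        occupancy=occupancy,
        variant=variant,
        animals=list(matrix.transmitters),
        receivers=list(matrix.receivers),
        data_hash=_data_hash(data[0], covariates),
        initial_p_present=initial_p_present,
    )


def decode_occupancy(
    samples: PosteriorSamples,
    matrix: HourlyDetectionMatrix,
    covariates: CovariateTable,
    variant: Literal["full", "reduced"] = "full",
    initial_p_present: float = 0.5,
    max_draws: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Posterior presence probabilities P(Z[i,t]=1 | y), averaged over draws.

    Exactly 1 at any animal-hour with a detection (zero-forcing).  Parameter
    uncertainty is propagated by averaging the forward-backward smoother over
    (at most ``max_draws``) retained posterior draws.
    """
    y = np.ascontiguousarray(matrix.values, dtype=np.uint8)
    n, j, t = y.shape
    if n == 0:
        return np.zeros((0, t))
    xs = state_design(covariates)
    xo = obs_design(covariates)
    has = np.ascontiguousarray(y.any(axis=1).astype(np.uint8))
    total = samples.n_total
    rng = np.random.default_rng(seed)
    if total > max_draws:
        pick = np.sort(rng.choice(total, size=max_draws, replace=False))
    else:
        pick = np.arange(total)

    alpha_d = samples.pooled("alpha")                  # (total, N)
    theta_d = samples.pooled("theta")                  # (total, J)
    aret_d = samples.pooled("alpha_return")
    bstate_d = np.column_stack(
        [samples.pooled(f"beta_{nm}") for nm in STATE_SLOPES]
    )
    if variant == "full":
        bdet_d = np.column_stack(
            [samples.pooled(f"beta_det_{nm}") for nm in OBS_COVARIATES]
        )
    gamma = np.zeros((n, t))
    lp1 = math.log(initial_p_present)
    lp0 = math.log1p(-initial_p_present)
    for d in pick:
        eta_e = np.ascontiguousarray(alpha_d[d][:, None] + (xs @ bstate_d[d])[None, :])
        bd = bdet_d[d] if variant == "full" else None
        eta_d = detection_eta(_logit(theta_d[d]), bd, xo)
        le1 = np.ascontiguousarray(emission_log_terms(y, eta_d))
        gamma += forward_backward(eta_e, float(aret_d[d]), le1, has, lp1, lp0)
    gamma /= len(pick)
    gamma[has.astype(bool)] = 1.0
    return gamma
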