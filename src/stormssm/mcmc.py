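"""Adaptive Metropolis MCMC engine with burn-in/thinning bookkeeping and
Gelman-Rubin convergence diagnostics.

The engine is deliberately model-agnostic: a model contributes a *kernel
factory* that, given a per-chain random generator, returns an object with a
``step`` method (one full sweep over its parameter blocks) and a ``snapshot``
method (the current parameter values to record).  The engine owns chain
scheduling, seed derivation, burn-in, thinning and retained-draw counts, so
that every model in the package shares one audited implementation of that
bookkeeping.

Defaults follow the study protocol: three chains of 10,000 iterations each,
1,000 discarded as burn-in, every 10th retained (900 draws per chain, 2,700
total), convergence declared at R-hat < 1.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "ConvergenceReport",
    "AdaptiveScale",
    "RandomWalkKernel",
    "run_chains",
    "gelman_rubin",
    "effective_sample_size",
    "posterior_summary",
]


class McmcConfig(BaseModel):
    """Chain-run configuration.

    ``retained_per_chain`` = floor((n_iterations - burn_in) / thin).
    """

    n_chains: int = Field(default=3, ge=1)
    n_iterations: int = Field(default=10_000, ge=1)
    burn_in: int = Field(default=1_000, ge=0)
    thin: int = Field(default=10, ge=1)
    seed: int = 0
    adapt_target: float = Field(default=0.30, gt=0.0, lt=1.0)
    adapt_rate: float = Field(default=0.66, gt=0.5, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "McmcConfig":
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if (self.n_iterations - self.burn_in) < self.thin:
            raise ValueError("thin exceeds the post-burn-in iteration count")
        return self

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @property
    def retained_total(self) -> int:
        return self.retained_per_chain * self.n_chains

    def chain_rng(self, chain: int) -> np.random.Generator:
        """Derive a per-chain generator deterministically from the master seed."""
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(chain,)))


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    threshold: float = 1.05
    ess: dict[str, float] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(np.isfinite(v) and v < self.threshold for v in self.rhat.values())

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "passed": self.passed,
            "max_rhat": self.max_rhat,
            "rhat": dict(self.rhat),
            "ess": dict(self.ess),
        }


@dataclass
class PosteriorSamples:
    """Thinned multi-chain draws.

    ``draws[name]`` has shape ``(n_chains, n_retained, *param_shape)``.
    """

    draws: dict[str, np.ndarray]
    config: McmcConfig

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_retained(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def n_total(self) -> int:
        return self.n_chains * self.n_retained

    def get(self, name: str) -> np.ndarray:
        return self.draws[name]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated: shape ``(n_total, *param_shape)``."""
        a = self.draws[name]
        return a.reshape(a.shape[0] * a.shape[1], *a.shape[2:])

    def parameter_names(self) -> list[str]:
        return list(self.draws)

    def scalar_names(self) -> list[str]:
        """Expand vector parameters into indexed scalar names."""
        out: list[str] = []
        for name, a in self.draws.items():
            if a.ndim == 2:
                out.append(name)
            else:
                for idx in np.ndindex(a.shape[2:]):
                    out.append(f"{name}[{','.join(map(str, idx))}]")
        return out

    def scalar(self, name: str) -> np.ndarray:
        """Return an ``(n_chains, n_retained)`` array for a scalar(-indexed) name."""
        if name in self.draws:
            a = self.draws[name]
            if a.ndim != 2:
                raise KeyError(f"{name!r} is not scalar; use an indexed name")
            return a
        if "[" in name and name.endswith("]"):
            base, _, idx = name[:-1].partition("[")
            indices = tuple(int(i) for i in idx.split(","))
            return self.draws[base][(slice(None), slice(None)) + indices]
        raise KeyError(name)

    def convergence(self, threshold: float = 1.05, split: bool = False) -> ConvergenceReport:
        rhat = {n: gelman_rubin(self, n, split=split) for n in self.scalar_names()}
        ess = {n: effective_sample_size(self.scalar(n)) for n in self.scalar_names()}
        return ConvergenceReport(rhat=rhat, threshold=threshold, ess=ess)

    def to_dataframe(self):
        """Long format: one row per (chain, draw, scalar parameter)."""
        import pandas as pd

        rows = []
        for name in self.scalar_names():
            a = self.scalar(name)
            for c in range(a.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "draw": np.arange(a.shape[1]),
                            "parameter": name,
                            "value": a[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df, config: "McmcConfig") -> "PosteriorSamples":
        """Rebuild draws from the long-format CSV layout written by
        :meth:`to_dataframe` (vector parameters carry ``name[i,...]`` labels)."""
        n_chains = int(df["chain"].max()) + 1
        n_draws = int(df["draw"].max()) + 1
        grouped: dict[str, dict[tuple, np.ndarray]] = {}
        for name, sub in df.groupby("parameter", sort=False):
            if "[" in name and name.endswith("]"):
                base, _, idx = name[:-1].partition("[")
                indices = tuple(int(i) for i in idx.split(","))
            else:
                base, indices = name, ()
            mat = np.full((n_chains, n_draws), np.nan)
            mat[sub["chain"].to_numpy(), sub["draw"].to_numpy()] = sub["value"].to_numpy()
            grouped.setdefault(base, {})[indices] = mat
        draws: dict[str, np.ndarray] = {}
        for base, comp in grouped.items():
            if list(comp) == [()]:
                draws[base] = comp[()]
            else:
                shape = tuple(max(ix[d] for ix in comp) + 1 for d in range(len(next(iter(comp)))))
                out = np.full((n_chains, n_draws) + shape, np.nan)
                for ix, mat in comp.items():
                    out[(slice(None), slice(None)) + ix] = mat
                draws[base] = out
        return cls(draws=draws, config=config)


class ChainKernel(Protocol):  # pragma: no cover - typing only
    def step(self, iteration: int, adapting: bool) -> None: ...

    def snapshot(self) -> Mapping[str, np.ndarray | float]: ...


class AdaptiveScale:
    """Robbins-Monro proposal-scale adaptation, frozen after burn-in.

    Scales are multiplied by ``exp(gain_k * (accept - target))`` with
    ``gain_k = (1 + k)^(-rate)``; ``rate`` in (0.5, 1] guarantees diminishing
    adaptation, and the engine stops calling ``update`` after burn-in so the
    retained phase uses a fixed proposal (preserving detailed balance).
    """

    def __init__(self, shape, initial: float = 0.5, target: float = 0.30, rate: float = 0.66):
        self.scale = np.full(shape, float(initial))
        self.target = target
        self.rate = rate
        self._k = 0

    def update(self, accepted: np.ndarray | float) -> None:
        self._k += 1
        gain = (1.0 + self._k) ** (-self.rate)
        self.scale *= np.exp(gain * (np.asarray(accepted, dtype=float) - self.target))
        np.clip(self.scale, 1e-8, 1e8, out=self.scale)


class RandomWalkKernel:
    """Generic coordinate-wise adaptive random-walk Metropolis kernel.

    Suitable for any target supplied as a joint log-density over a flat
    parameter vector; used directly for the conjugate validation targets and
    as the reference sampler in tests.
    """

    def __init__(
        self,
        log_density: Callable[[np.ndarray], float],
        x0: np.ndarray,
        rng: np.random.Generator,
        name: str = "x",
        initial_scale: float = 0.5,
        target_accept: float = 0.40,
    ):
        self.log_density = log_density
        self.x = np.array(x0, dtype=float, copy=True)
        self.rng = rng
        self.name = name
        self._lp = float(log_density(self.x))
        if not math.isfinite(self._lp):
            raise ValueError(f"non-finite log density at initial value {self.x!r}")
        self._scales = AdaptiveScale(self.x.shape, initial_scale, target=target_accept)

    def step(self, iteration: int, adapting: bool) -> None:
        accepted = np.zeros(self.x.shape)
        for i in range(self.x.size):
            prop = self.x.copy()
            prop.flat[i] += self.rng.normal(0.0, self._scales.scale.flat[i])
            lp_prop = float(self.log_density(prop))
            if math.isfinite(lp_prop) and math.log(self.rng.uniform()) < lp_prop - self._lp:
                self.x = prop
                self._lp = lp_prop
                accepted.flat[i] = 1.0
        if adapting:
            self._scales.update(accepted)

    def snapshot(self) -> dict[str, np.ndarray]:
        return {self.name: self.x.copy()}


def run_chains(
    kernel_factory: Callable[[np.random.Generator, int], ChainKernel],
    config: McmcConfig,
) -> PosteriorSamples:
    """Run ``config.n_chains`` independent chains and collect thinned draws.

    Deterministic for a fixed seed and config: chain ``c`` uses a generator
    spawned from ``SeedSequence(config.seed, spawn_key=(c,))``.
    """
    per_chain: list[dict[str, list[np.ndarray]]] = []
    for c in range(config.n_chains):
        rng = config.chain_rng(c)
        kernel = kernel_factory(rng, c)
        records: dict[str, list[np.ndarray]] = {}
        for i in range(config.n_iterations):
            kernel.step(i, adapting=i < config.burn_in)
            # retain every thin-th post-burn-in iteration (the last of each
            # group, so retained = floor((n - burn) / thin) exactly)
            if i >= config.burn_in and (i - config.burn_in + 1) % config.thin == 0:
                snap = kernel.snapshot()
                for k, v in snap.items():
                    records.setdefault(k, []).append(np.array(v, dtype=float, copy=True))
        per_chain.append(records)

    names = list(per_chain[0])
    draws = {
        name: np.stack([np.stack(rec[name]) for rec in per_chain]) for name in names
    }
    for name, a in draws.items():
        if not np.all(np.isfinite(a)):
            raise FloatingPointError(f"non-finite retained draws for parameter {name!r}")
    samples = PosteriorSamples(draws=draws, config=config)
    assert samples.n_retained == config.retained_per_chain
    return samples


def _as_chain_matrix(samples, parameter: str | None) -> np.ndarray:
    if isinstance(samples, PosteriorSamples):
        if parameter is None:
            raise ValueError("parameter name required")
        return samples.scalar(parameter)
    a = np.asarray(samples, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected an (n_chains, n_draws) array")
    return a


def gelman_rubin(samples, parameter: str | None = None, split: bool = False) -> float:
    """Classical Gelman-Rubin potential-scale-reduction statistic.

    With m chains of n draws, within-chain variance W = mean of per-chain
    sample variances, between-chain variance B = n * variance of chain means,
    pooled estimate V = (n-1)/n * W + B/n, and R-hat = sqrt(V / W).
    ``split=True`` halves each chain first (split-chain variant).
    """
    a = _as_chain_matrix(samples, parameter)
    if a.shape[0] < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if split:
        half = a.shape[1] // 2
        a = np.concatenate([a[:, :half], a[:, half : 2 * half]], axis=0)
    m, n = a.shape
    if n < 2:
        raise ValueError("Gelman-Rubin requires at least 2 draws per chain")
    chain_means = a.mean(axis=1)
    w = a.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0.0:
        return 1.0  # identical constant chains
    v = (n - 1) / n * w + b / n
    return float(np.sqrt(v / w))


def effective_sample_size(chains: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS (auxiliary diagnostic)."""
    a = np.asarray(chains, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    m, n = a.shape
    centered = a - a.mean(axis=1, keepdims=True)
    var = centered.var(axis=1).mean()
    if var == 0.0:
        return float(m * n)
    max_lag = min(n - 1, 1000)
    rho_sum = 0.0
    for lag in range(1, max_lag):
        acov = np.mean([np.dot(c[:-lag], c[lag:]) / n for c in centered])
        rho = acov / var
        if rho < 0.0:
            break
        rho_sum += rho
    return float(m * n / (1.0 + 2.0 * rho_sum))


def posterior_summary(samples, parameter: str | None = None) -> dict[str, float]:
    """Median, mean, sd, and central 95% credible interval.

    Quantiles use linear interpolation between order statistics.
    """
    if isinstance(samples, PosteriorSamples):
        pooled = samples.pooled(parameter)
    else:
        pooled = np.asarray(samples, dtype=float).ravel()
    lo, med, hi = np.quantile(pooled, [0.025, 0.5, 0.975])
    return {
        "mean": float(pooled.mean()),
        "median": float(med),
        "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        "lower95": float(lo),
        "upper95": float(hi),
    }
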