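"""Log-space forward/backward kernels for the two-state occupancy process.

The latent presence state Z[i,t] of each animal evolves as a first-order
Markov chain (stay probability 1 - phi_emigration, re-entry probability
phi_return); emissions are receiver-level Bernoulli detections whose joint
log-probability given presence is precomputed per animal-hour.  An absent
animal cannot be detected (zero-forcing), so the z=0 emission log-probability
is 0 for silent hours and -inf for hours with any detection.

All kernels work on logits and log-probabilities and are numerically stable
for arbitrarily extreme parameters.  They are compiled with numba when
available (pure-python fallback otherwise, same semantics).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

NEG_INF = -1.0e30  # additive log-space sentinel (safe to add twice)


@njit(cache=True)
def _softplus(x: float) -> float:
    # log(1 + e^x), stable
    if x > 35.0:
        return x
    if x < -35.0:
        return 0.0
    return np.log1p(np.exp(x))


@njit(cache=True)
def _lse2(a: float, b: float) -> float:
    if a >= b:
        return a + _softplus(b - a)
    return b + _softplus(a - b)


@njit(cache=True)
def forward_loglik(eta_emig, eta_return, le1, has_det, log_pi1, log_pi0):
    """Per-animal marginal log-likelihood by the forward recursion.

    eta_emig : (N, T) emigration logits (column t drives the t-1 -> t move)
    eta_return : scalar return logit
    le1 : (N, T) log emission probability given presence
    has_det : (N, T) uint8, 1 if any receiver detected the animal that hour
    """
    n, t_len = le1.shape
    ll = np.zeros(n)
    l_ret = -_softplus(-eta_return)       # log phi_return
    l_stay0 = -_softplus(eta_return)      # log (1 - phi_return)
    for i in range(n):
        la1 = log_pi1 + le1[i, 0]
        la0 = log_pi0 + (NEG_INF if has_det[i, 0] else 0.0)
        for t in range(1, t_len):
            e = eta_emig[i, t]
            l_stay1 = -_softplus(e)       # log (1 - phi_emig)
            l_emig = -_softplus(-e)       # log phi_emig
            na1 = _lse2(la1 + l_stay1, la0 + l_ret) + le1[i, t]
            na0 = _lse2(la1 + l_emig, la0 + l_stay0)
            if has_det[i, t]:
                na0 = na0 + NEG_INF
            la1, la0 = na1, na0
        ll[i] = _lse2(la1, la0)
    return ll


@njit(cache=True)
def forward_backward(eta_emig, eta_return, le1, has_det, log_pi1, log_pi0):
    """Posterior presence probabilities P(Z[i,t] = 1 | y, parameters)."""
    n, t_len = le1.shape
    gamma = np.zeros((n, t_len))
    l_ret = -_softplus(-eta_return)
    l_stay0 = -_softplus(eta_return)
    a1 = np.zeros(t_len)
    a0 = np.zeros(t_len)
    for i in range(n):
        a1[0] = log_pi1 + le1[i, 0]
        a0[0] = log_pi0 + (NEG_INF if has_det[i, 0] else 0.0)
        for t in range(1, t_len):
            e = eta_emig[i, t]
            l_stay1 = -_softplus(e)
            l_emig = -_softplus(-e)
            a1[t] = _lse2(a1[t - 1] + l_stay1, a0[t - 1] + l_ret) + le1[i, t]
            a0[t] = _lse2(a1[t - 1] + l_emig, a0[t - 1] + l_stay0)
            if has_det[i, t]:
                a0[t] = a0[t] + NEG_INF
        b1 = 0.0
        b0 = 0.0
        ll = _lse2(a1[t_len - 1], a0[t_len - 1])
        gamma[i, t_len - 1] = 1.0 if has_det[i, t_len - 1] else np.exp(a1[t_len - 1] - ll)
        for t in range(t_len - 2, -1, -1):
            e = eta_emig[i, t + 1]
            l_stay1 = -_softplus(e)
            l_emig = -_softplus(-e)
            le0_next = NEG_INF if has_det[i, t + 1] else 0.0
            nb1 = _lse2(l_stay1 + le1[i, t + 1] + b1, l_emig + le0_next + b0)
            nb0 = _lse2(l_ret + le1[i, t + 1] + b1, l_stay0 + le0_next + b0)
            b1, b0 = nb1, nb0
            if has_det[i, t]:
                gamma[i, t] = 1.0
            else:
                gamma[i, t] = np.exp(a1[t] + b1 - ll)
    return gamma


@njit(cache=True)
def ffbs_sample(eta_emig, eta_return, le1, has_det, log_pi1, log_pi0, uniforms):
    """Draw a latent path per animal by forward filtering, backward sampling.

    ``uniforms`` is an (N, T) array of U(0,1) variates supplied by the caller
    so that all randomness flows through one seeded generator.
    """
    n, t_len = le1.shape
    z = np.zeros((n, t_len), dtype=np.uint8)
    l_ret = -_softplus(-eta_return)
    l_stay0 = -_softplus(eta_return)
    a1 = np.zeros(t_len)
    a0 = np.zeros(t_len)
    for i in range(n):
        a1[0] = log_pi1 + le1[i, 0]
        a0[0] = log_pi0 + (NEG_INF if has_det[i, 0] else 0.0)
        for t in range(1, t_len):
            e = eta_emig[i, t]
            a1[t] = _lse2(a1[t - 1] - _softplus(e), a0[t - 1] + l_ret) + le1[i, t]
            a0[t] = _lse2(a1[t - 1] - _softplus(-e), a0[t - 1] + l_stay0)
            if has_det[i, t]:
                a0[t] = a0[t] + NEG_INF
        # terminal state
        p1 = 1.0 / (1.0 + np.exp(a0[t_len - 1] - a1[t_len - 1]))
        z[i, t_len - 1] = 1 if uniforms[i, t_len - 1] < p1 else 0
        for t in range(t_len - 2, -1, -1):
            e = eta_emig[i, t + 1]
            if z[i, t + 1] == 1:
                w1 = a1[t] - _softplus(e)      # stayed
                w0 = a0[t] + l_ret             # returned
            else:
                w1 = a1[t] - _softplus(-e)     # emigrated
                w0 = a0[t] + l_stay0           # stayed out
            p1 = 1.0 / (1.0 + np.exp(w0 - w1))
            z[i, t] = 1 if uniforms[i, t] < p1 else 0
    return z
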