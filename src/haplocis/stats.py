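"""Beta-binomial utilities shared by the simulator and the ASE caller.

The beta-binomial is parameterized by the mean marginal probability of
success ``pi`` and the intra-class overdispersion ``rho`` in [0, 1):

    a = pi (1 - rho) / rho,   b = (1 - pi)(1 - rho) / rho

so rho -> 0 recovers the binomial and Var(k) = n pi (1-pi) (1 + (n-1) rho).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats


def _ab(pi: float, rho: float) -> tuple[float, float]:
    a = pi * (1.0 - rho) / rho
    b = (1.0 - pi) * (1.0 - rho) / rho
    return a, b


def rbetabin(rng: np.random.Generator, n, pi: float, rho: float) -> np.ndarray:
    """Draw beta-binomial counts at totals ``n`` (vectorized)."""
    n = np.asarray(n)
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if rho == 0.0:
        return rng.binomial(n, pi)
    a, b = _ab(pi, rho)
    p = rng.beta(a, b, size=n.shape)
    return rng.binomial(n, p)


def betabin_logpmf(k, n, pi: float, rho: float):
    if rho < 1e-12:
        return stats.binom.logpmf(k, n, pi)
    a, b = _ab(pi, rho)
    return stats.betabinom.logpmf(k, n, a, b)


def betabin_cdf(k, n, pi: float, rho: float):
    if rho < 1e-12:
        return stats.binom.cdf(k, n, pi)
    a, b = _ab(pi, rho)
    return stats.betabinom.cdf(k, n, a, b)


def betabin_mom(k: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Method-of-moments estimate of (pi, rho) with varying totals.

    Uses the depth-weighted mean for pi and equates the average excess of
    (p_i - pi)^2 over the binomial variance to the overdispersion term:
    E[(p_i - pi)^2] = pi (1 - pi) (1/n_i + rho (1 - 1/n_i)).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if len(k) == 0:
        raise ValueError("no observations")
    p = k / n
    pi = float(np.sum(k) / np.sum(n))
    v = pi * (1.0 - pi)
    if v <= 0:
        return pi, 0.0
    num = np.sum((p - pi) ** 2 - v / n)
    den = v * np.sum(1.0 - 1.0 / n)
    rho = float(num / den) if den > 0 else 0.0
    return pi, float(np.clip(rho, 0.0, 1.0 - 1e-9))


@dataclass
class BetaBinNull:
    """A fitted mapping-bias-aware null for allelic counts.

    ``pi_hat`` absorbs reference-mapping bias (expected haplotype-1 read
    fraction with no true signal); ``rho_hat`` absorbs extra-binomial
    variation. Fitting on symmetric, binomially distributed data drives
    pi_hat -> 0.5 and rho_hat -> 0.
    """

    pi_hat: float
    rho_hat: float
    n_obs: int
    loglik: float
    converged: bool
    method: str          # "mle" or "mom" (fallback)
    pi_mom: float
    rho_mom: float


def fit_betabin(k, n, min_obs: int = 50) -> BetaBinNull:
    """Maximum-likelihood fit of the beta-binomial null to counts ``k`` of ``n``.

    Optimizes over (logit pi, logit rho); falls back to method-of-moments if
    the optimizer fails. Method-of-moments estimates are always reported as a
    cross-check.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if len(k) < min_obs:
        raise ValueError(f"need >= {min_obs} observations to fit the null, got {len(k)}")
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("counts must satisfy 0 <= k <= n")
    pi_mom, rho_mom = betabin_mom(k, n)

    def nll(theta):
        pi = special.expit(theta[0])
        rho = special.expit(theta[1])
        return -np.sum(betabin_logpmf(k, n, pi, min(rho, 1 - 1e-9)))

    x0 = np.array([
        special.logit(np.clip(pi_mom, 1e-4, 1 - 1e-4)),
        special.logit(np.clip(rho_mom, 1e-6, 0.5)),
    ])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000})
    if res.success:
        pi_hat = float(special.expit(res.x[0]))
        rho_hat = float(special.expit(res.x[1]))
        return BetaBinNull(pi_hat, rho_hat, len(k), float(-res.fun), True,
                           "mle", pi_mom, rho_mom)
    return BetaBinNull(pi_mom, rho_mom, len(k),
                       float(np.sum(betabin_logpmf(k, n, pi_mom, rho_mom))),
                       False, "mom", pi_mom, rho_mom)
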