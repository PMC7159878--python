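"""Ex-Gaussian distribution: convolution of a Gaussian (mu, sigma) with an
exponential (tau).

Finish times of both the go and the stop process in the race model are
ex-Gaussian; the mean is ``mu + tau`` and the variance ``sigma**2 + tau**2``.
All functions are vectorised over ``t`` and work in whatever time unit the
parameters are given in (the race model uses seconds internally).

For ``tau`` below ``_TAU_FLOOR * sigma`` the distribution is evaluated in its
Gaussian limit so that tau -> 0 is continuous to machine precision.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr

_TAU_FLOOR = 1e-7


def _check(sigma: float, tau: float) -> None:
    if not (np.isfinite(sigma) and sigma > 0):
        raise ValueError(f"sigma must be positive and finite, got {sigma}")
    if not (np.isfinite(tau) and tau >= 0):
        raise ValueError(f"tau must be non-negative and finite, got {tau}")


def exgauss_logpdf(t, mu: float, sigma: float, tau: float):
    """Log density of the ex-Gaussian at ``t``."""
    _check(sigma, tau)
    t = np.asarray(t, dtype=float)
    if tau <= _TAU_FLOOR * sigma:
        z = (t - mu) / sigma
        return -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    # log f = -log tau + (mu - t)/tau + sigma^2/(2 tau^2) + log Phi((t-mu)/sigma - sigma/tau)
    arg = (t - mu) / sigma - sigma / tau
    return -np.log(tau) + (mu - t) / tau + 0.5 * (sigma / tau) ** 2 + log_ndtr(arg)


def exgauss_pdf(t, mu: float, sigma: float, tau: float):
    return np.exp(exgauss_logpdf(t, mu, sigma, tau))


def exgauss_cdf(t, mu: float, sigma: float, tau: float):
    """P(T <= t) for an ex-Gaussian finish time."""
    _check(sigma, tau)
    t = np.asarray(t, dtype=float)
    u = (t - mu) / sigma
    if tau <= _TAU_FLOOR * sigma:
        return ndtr(u)
    # F = Phi(u) - exp(log Phi(u - sigma/tau) + (mu - t)/tau + sigma^2/(2 tau^2))
    corr = np.exp(log_ndtr(u - sigma / tau) + (mu - t) / tau + 0.5 * (sigma / tau) ** 2)
    return np.clip(ndtr(u) - corr, 0.0, 1.0)


def exgauss_sf(t, mu: float, sigma: float, tau: float):
    return 1.0 - exgauss_cdf(t, mu, sigma, tau)


def exgauss_rvs(n: int, mu: float, sigma: float, tau: float, rng: np.random.Generator):
    """Draw ``n`` ex-Gaussian variates (Gaussian + exponential construction)."""
    _check(sigma, tau)
    x = rng.normal(mu, sigma, size=n)
    if tau > 0:
        x = x + rng.exponential(tau, size=n)
    return x


def exgauss_mean(mu: float, sigma: float, tau: float) -> float:
    return mu + tau


def exgauss_var(mu: float, sigma: float, tau: float) -> float:
    return sigma**2 + tau**2
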