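"""Negative-binomial primitives shared across the package.

The NB distribution is parameterized throughout by its mean ``mu`` and size
(overdispersion) parameter ``theta``, so that ``var = mu + mu**2 / theta``;
``theta -> inf`` recovers the Poisson.  This is the (mu, size) convention of
``MASS::glm.nb`` and maps onto :func:`scipy.stats.nbinom` via ``n = theta``,
``p = theta / (theta + mu)``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln

#: theta above this value is treated as the (quasi-)Poisson limit.
THETA_CAP = 1e6


def nb_logpmf(k, mu, theta):
    """Log-pmf of NB(mean mu, size theta); handles mu == 0 degenerately."""
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = np.where(k == 0, 0.0, -np.inf)
    if np.all(mu == 0):
        return out if out.shape else float(out)
    p = theta / (theta + mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = stats.nbinom.logpmf(k, theta, p)
    out = np.where(mu > 0, ll, out)
    return out if out.shape else float(out)


def nb_pmf(k, mu, theta):
    return np.exp(nb_logpmf(k, mu, theta))


def nb_loglik(y, mu, theta):
    """Total NB log-likelihood of counts ``y`` with per-observation means."""
    return float(np.sum(nb_logpmf(y, mu, theta)))


def nb_rvs(mu, theta, rng: np.random.Generator):
    """Vectorized NB(mean mu, size theta) draws; mu == 0 yields 0."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if np.any(pos):
        p = theta / (theta + mu[pos])
        out[pos] = rng.negative_binomial(theta, p)
    return out


def nb_quantile(q, mu, theta):
    """Smallest k with CDF >= q."""
    if mu <= 0:
        return 0
    p = theta / (theta + mu)
    return int(stats.nbinom.ppf(q, theta, p))


def nb_sf(k, mu, theta):
    """P(X > k) for NB(mu, theta)."""
    if mu <= 0:
        return 0.0
    p = theta / (theta + mu)
    return float(stats.nbinom.sf(k, theta, p))


def nb_tail_mean(k, mu, theta):
    """E[X * 1{X > k}] for NB(mu, theta).

    Uses the size-biasing identity j * nb(j; theta, mu) =
    mu * nb(j - 1; theta + 1, mu * (theta + 1) / theta), i.e. the partial mean
    is ``mu`` times a survival probability of the size-incremented NB.
    """
    if mu <= 0:
        return 0.0
    p = theta / (theta + mu)  # same p for size theta + 1 shifts the mean
    return float(mu * stats.nbinom.sf(k - 1, theta + 1.0, p))


def nb_loglik_profile_mu(y, theta):
    """NB log-likelihood at the ML mean (the sample mean), as a function of theta."""
    y = np.asarray(y, dtype=float)
    mu = y.mean()
    n = y.size
    if mu == 0:
        return 0.0
    return float(
        np.sum(gammaln(y + theta)) - n * gammaln(theta) - np.sum(gammaln(y + 1.0))
        + n * theta * np.log(theta / (theta + mu))
        + np.sum(y) * np.log(mu / (theta + mu))
    )
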