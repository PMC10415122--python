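"""Negative-binomial GLM with log link and offset.

Fits ``y ~ X`` with linear predictor ``eta = X @ beta + offset`` and
``y ~ NB(mean exp(eta), size theta)`` by alternating

(i)  IRLS for ``beta`` at fixed ``theta`` (working weights
     ``w = mu * theta / (theta + mu)``), and
(ii) Newton maximization of the profile log-likelihood in ``log theta``,
     initialized by method of moments, with a bisection fallback.

Convergence when ``max |d beta| < 1e-8`` and ``|d log theta| < 1e-8``
(at most 100 outer iterations).  Standard errors are Wald SEs from the
observed information of the weighted least-squares step at the converged
``(beta, theta)`` — the convention of standard NB GLM software, conditional
on the fitted dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

from ._nb import THETA_CAP, nb_loglik

_THETA_MIN = 1e-4
_TOL = 1e-8
_MAX_OUTER = 100


@dataclass
class NBGLMFit:
    """Raw design-matrix-level fit result."""

    beta: np.ndarray
    cov: np.ndarray
    theta: float
    loglik: float
    converged: bool
    n_iter: int
    fitted: np.ndarray  # fitted means

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _irls(y, X, offset, theta, beta=None, tol=_TOL, max_iter=50):
    """IRLS for beta at fixed theta. Returns (beta, mu, converged)."""
    n, p = X.shape
    if beta is None:
        # start from the log of a damped observed rate
        rate = (y + 0.5) / np.exp(offset)
        eta = offset + np.log(rate)
        beta, *_ = np.linalg.lstsq(X, eta - offset, rcond=None)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -300.0, 300.0)
        mu = np.exp(eta)
        w = mu * theta / (theta + mu)
        z = (eta - offset) + (y - mu) / mu
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = np.clip(X @ beta + offset, -300.0, 300.0)
    return beta, np.exp(eta), converged


def _theta_score(theta, y, mu):
    return np.sum(
        digamma(y + theta) - digamma(theta)
        + np.log(theta) - np.log(theta + mu)
        + 1.0 - (y + theta) / (theta + mu)
    )


def _theta_score_deriv(theta, y, mu):
    return np.sum(
        polygamma(1, y + theta) - polygamma(1, theta)
        + 1.0 / theta - 1.0 / (theta + mu)
        + (y - mu) / (theta + mu) ** 2
    )


def _theta_mom(y, mu):
    """Method-of-moments start: 1/theta from excess variance."""
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    if num <= 0 or den <= 0:
        return THETA_CAP
    return float(np.clip(den / num, _THETA_MIN, THETA_CAP))


def _profile_theta(y, mu, theta0):
    """Maximize the NB log-likelihood in theta at fixed means.

    Newton in log theta; if the score has no sign change inside
    [_THETA_MIN, THETA_CAP] the optimum sits at the boundary (the cap is the
    quasi-Poisson limit).
    """
    if _theta_score(THETA_CAP, y, mu) >= 0:
        return THETA_CAP
    if _theta_score(_THETA_MIN, y, mu) <= 0:
        return _THETA_MIN
    theta = float(np.clip(theta0, _THETA_MIN, THETA_CAP))
    for _ in range(50):
        s = _theta_score(theta, y, mu)
        ds = _theta_score_deriv(theta, y, mu)
        # Newton step on u = log(theta): f(u) = theta*s, f'(u) = theta*s + theta^2*ds
        f = theta * s
        fp = theta * s + theta * theta * ds
        if fp == 0:
            break
        u_new = np.log(theta) - f / fp
        theta_new = float(np.clip(np.exp(u_new), _THETA_MIN, THETA_CAP))
        if abs(np.log(theta_new) - np.log(theta)) < _TOL:
            return theta_new
        theta = theta_new
    # fallback: the score is decreasing in theta near the optimum; bisect
    return float(brentq(_theta_score, _THETA_MIN, THETA_CAP, args=(y, mu), xtol=1e-12))


def fit_nb_glm_design(y, X, offset, theta: float | None = None) -> NBGLMFit:
    """Fit the NB GLM; ``theta=None`` profiles the dispersion jointly.

    Non-convergence (e.g. a separated design cell with all-zero counts) is
    reported through ``converged=False``, never raised.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    fixed_theta = theta is not None

    beta, mu, _ = _irls(y, X, offset, THETA_CAP if theta is None else theta)
    th = theta if fixed_theta else _profile_theta(y, mu, _theta_mom(y, mu))

    converged = False
    n_iter = 0
    for n_iter in range(1, _MAX_OUTER + 1):
        beta_new, mu, irls_ok = _irls(y, X, offset, th, beta=beta)
        dbeta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if fixed_theta:
            if irls_ok and dbeta < _TOL:
                converged = True
                break
            continue
        th_new = _profile_theta(y, mu, th)
        dlogth = abs(np.log(th_new) - np.log(th))
        th = th_new
        if irls_ok and dbeta < _TOL and dlogth < _TOL:
            converged = True
            break
    if np.any(np.abs(X @ beta) > 250.0):
        # a coefficient ran off to the linear-predictor clip: separation,
        # e.g. an all-zero (cell type, arm) group
        converged = False
    if not converged:
        warnings.warn("NB GLM did not converge (diverging coefficients or "
                      "iteration limit)")

    w = mu * th / (th + mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
    return NBGLMFit(
        beta=beta, cov=cov, theta=float(th), loglik=nb_loglik(y, mu, th),
        converged=converged, n_iter=n_iter, fitted=mu,
    )
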