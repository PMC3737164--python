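"""Observation-model log-likelihoods and their derivatives in eta.

Each family provides the per-record log density, its first derivative, and
its negated second derivative with respect to the linear predictor ``eta``.
This triple is the entire contract the Laplace core consumes.  All
normalizing constants (binomial coefficients, factorials, Gaussian 2*pi
terms) are included, so deviances are absolute and comparable across
software.

Families
--------
gaussian   y | eta ~ N(eta, sigma_e^2)                      (identity link)
binomial   y | eta ~ Bin(n, logistic(eta))                  (logit link)
poisson    y | eta ~ Pois(E * exp(eta))                     (log link)
zip        y = 0 with prob p, else Pois(E * exp(eta))       (log link)

The ZIP density at y = 0 is ``p + (1-p) exp(-mu)``, a genuine mixture; its
curvature in eta can be locally negative, which the Newton solver clamps
(the reported deviance never is).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit, gammaln

ETA_CAP = 35.0

__all__ = ["loglik", "deviance", "ETA_CAP"]


def _capped_mu(eta: np.ndarray, exposure: np.ndarray) -> np.ndarray:
    """mu = E * exp(eta), with |eta| capped for numerical safety."""
    if np.any(np.abs(eta) > ETA_CAP):
        warnings.warn(
            f"linear predictor exceeded |eta| = {ETA_CAP}; capped before exponentiation",
            RuntimeWarning,
            stacklevel=3,
        )
        eta = np.clip(eta, -ETA_CAP, ETA_CAP)
    return exposure * np.exp(eta)


def loglik(
    family: str,
    y: np.ndarray,
    eta: np.ndarray,
    *,
    n_trials: np.ndarray | None = None,
    exposure: np.ndarray | None = None,
    sigma_e2: float | None = None,
    p: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-record (log density, d/deta, -d^2/deta^2)."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)

    if family == "gaussian":
        resid = y - eta
        value = -0.5 * np.log(2.0 * np.pi * sigma_e2) - 0.5 * resid**2 / sigma_e2
        d1 = resid / sigma_e2
        nd2 = np.full_like(eta, 1.0 / sigma_e2)
        return value, d1, nd2

    if family == "binomial":
        n = np.asarray(n_trials, dtype=float)
        if np.any(y < 0) or np.any(y > n):
            raise ValueError("binomial responses must satisfy 0 <= y <= n")
        prob = expit(eta)
        # log C(n,y) + y*eta - n*log(1+e^eta); log1p(exp) via logaddexp for stability
        value = (
            gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
            + y * eta - n * np.logaddexp(0.0, eta)
        )
        d1 = y - n * prob
        nd2 = n * prob * (1.0 - prob)
        return value, d1, nd2

    if family == "poisson":
        E = np.asarray(exposure, dtype=float)
        if np.any(E <= 0):
            raise ValueError("exposure must be positive")
        if np.any(y < 0):
            raise ValueError("count responses must be nonnegative")
        mu = _capped_mu(eta, E)
        value = y * np.log(mu) - mu - gammaln(y + 1)
        d1 = y - mu
        nd2 = mu.copy()
        return value, d1, nd2

    if family == "zip":
        E = np.asarray(exposure, dtype=float)
        if np.any(E <= 0):
            raise ValueError("exposure must be positive")
        if np.any(y < 0):
            raise ValueError("count responses must be nonnegative")
        if not 0.0 <= p <= 1.0:
            raise ValueError("zero-inflation probability must be in [0, 1]")
        mu = _capped_mu(eta, E)
        value = np.empty_like(eta)
        d1 = np.empty_like(eta)
        nd2 = np.empty_like(eta)

        zero = y == 0
        # y = 0: L = p + (1-p) exp(-mu); derivatives via g = (1-p) exp(-mu) mu
        mz = mu[zero]
        L = p + (1.0 - p) * np.exp(-mz)
        g = (1.0 - p) * np.exp(-mz) * mz
        value[zero] = np.log(L)
        d1[zero] = -g / L
        nd2[zero] = (g * (1.0 - mz) * L + g**2) / L**2

        pos = ~zero
        mp_ = mu[pos]
        yp = y[pos]
        with np.errstate(divide="ignore"):
            log1mp = np.log1p(-p) if p < 1.0 else -np.inf
        value[pos] = log1mp + yp * np.log(mp_) - mp_ - gammaln(yp + 1)
        d1[pos] = yp - mp_
        nd2[pos] = mp_
        return value, d1, nd2

    raise ValueError(f"unknown family {family!r}")


def deviance(
    family: str,
    y: np.ndarray,
    eta: np.ndarray,
    **aux,
) -> float:
    """D = -2 * sum_i log f(y_i | eta_i, theta), constants included."""
    value, _, _ = loglik(family, y, eta, **aux)
    return float(-2.0 * np.sum(value))
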