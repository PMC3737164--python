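"""Heritability posteriors on the scale appropriate to each likelihood.

* Gaussian traits: ``h^2 = sigma_u^2 / (sigma_u^2 + sigma_e^2)``, the
  proportion of phenotypic variance due to additive genetics, evaluated at
  every retained point of the joint hyperparameter grid.
* Binomial (logit) traits: liability-scale
  ``h^2 = sigma_u^2 / (sigma_u^2 + pi^2/3)``, where pi^2/3 is the variance
  of a standard logistic variable; an exact change of variables of the
  sigma_u^2 marginal.
* Poisson/ZIP (log) traits: ``h^2 = sigma_u^2 / (sigma_u^2 + 1/lambda*)``
  with the plug-in mean intensity ``lambda* = sum(y_i) / sum(E_i)``.

For non-Gaussian traits the heritability lives on the latent (liability or
log-intensity) scale and is NOT the proportion of explained variance in the
observed phenotype; every such posterior carries that caveat.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .inference import FitResult, InferenceError, PosteriorMarginal
from .model import ObservationSet

LOGISTIC_VARIANCE = math.pi**2 / 3.0

LATENT_SCALE_CAVEAT = (
    "latent-scale heritability: this is NOT the proportion of explained "
    "variance in the observed phenotype"
)

__all__ = [
    "HeritabilityPosterior",
    "h2_gaussian",
    "h2_binomial",
    "h2_poisson",
    "LOGISTIC_VARIANCE",
    "LATENT_SCALE_CAVEAT",
]


@dataclass
class HeritabilityPosterior:
    """Posterior of h^2 on (0, 1) with a definition tag."""

    marginal: PosteriorMarginal
    definition: str                 # gaussian | liability_logit | poisson_log
    lambda_star: float | None = None

    @property
    def mean(self) -> float:
        return self.marginal.mean

    @property
    def sd(self) -> float:
        return self.marginal.sd

    @property
    def quantiles(self) -> dict[float, float]:
        return self.marginal.quantiles

    def to_dict(self) -> dict:
        out = {"definition": self.definition, **self.marginal.to_dict()}
        if self.lambda_star is not None:
            out["lambda_star"] = self.lambda_star
        if self.definition != "gaussian":
            out["caveat"] = LATENT_SCALE_CAVEAT
        return out


def h2_gaussian(fit: FitResult, *, include_individual_variance: bool = False,
                n_bins: int = 60) -> HeritabilityPosterior:
    """h^2 posterior from the joint (sigma_u^2, sigma_e^2) grid.

    Each retained grid point contributes its weight at
    ``h = sigma_u^2 / (sigma_u^2 + sigma_e^2)``; with
    ``include_individual_variance`` the repeated-measures variance joins the
    denominator.
    """
    names = fit.layout.hyper_names
    if "sigma_u2" not in names or "sigma_e2" not in names:
        raise InferenceError("gaussian h^2 requires a fitted model with sigma_u2 and sigma_e2")
    values = []
    weights = []
    for pt in fit.points:
        su = pt.theta["sigma_u2"]
        denom = su + pt.theta["sigma_e2"]
        if include_individual_variance and "sigma_ind2" in pt.theta:
            denom += pt.theta["sigma_ind2"]
        values.append(su / denom)
        weights.append(pt.weight)
    marg = PosteriorMarginal.from_weighted_values(
        np.asarray(values), np.asarray(weights), n_bins=n_bins, support=(0.0, 1.0)
    )
    return HeritabilityPosterior(marginal=marg, definition="gaussian")


def _transform_sigma_marginal(sigma_marg: PosteriorMarginal, c: float) -> PosteriorMarginal:
    """Change of variables h = s / (s + c) applied to a density in s."""
    s = sigma_marg.grid
    dens_s = sigma_marg.density
    h = s / (s + c)
    # ds/dh = c / (1-h)^2
    dens_h = dens_s * c / (1.0 - h) ** 2
    order = np.argsort(h)
    return PosteriorMarginal.from_grid(h[order], dens_h[order])


def h2_binomial(fit_or_marginal) -> HeritabilityPosterior:
    """Liability-scale h^2 for a logit-link binomial animal model."""
    sigma_marg = _sigma_u_marginal(fit_or_marginal)
    warnings.warn(LATENT_SCALE_CAVEAT, UserWarning, stacklevel=2)
    marg = _transform_sigma_marginal(sigma_marg, LOGISTIC_VARIANCE)
    return HeritabilityPosterior(marginal=marg, definition="liability_logit")


def h2_poisson(fit_or_marginal, obs: ObservationSet) -> HeritabilityPosterior:
    """Log-scale h^2 for Poisson/ZIP models with plug-in lambda*.

    ``lambda* = sum(y_i) / sum(E_i)`` is the data estimate of the mean
    intensity; the transform is h = s / (s + 1/lambda*).
    """
    if obs.exposure is None or np.sum(obs.exposure) <= 0:
        raise InferenceError("lambda* undefined: total exposure is zero")
    lam = float(np.sum(obs.y) / np.sum(obs.exposure))
    if lam <= 0:
        raise InferenceError("lambda* is zero: all counts are zero")
    sigma_marg = _sigma_u_marginal(fit_or_marginal)
    warnings.warn(LATENT_SCALE_CAVEAT, UserWarning, stacklevel=2)
    marg = _transform_sigma_marginal(sigma_marg, 1.0 / lam)
    return HeritabilityPosterior(marginal=marg, definition="poisson_log", lambda_star=lam)


def _sigma_u_marginal(fit_or_marginal) -> PosteriorMarginal:
    if isinstance(fit_or_marginal, PosteriorMarginal):
        return fit_or_marginal
    marg = fit_or_marginal.hyper_marginals.get("sigma_u2")
    if marg is None:
        raise InferenceError("fit has no sigma_u2 marginal (model without breeding values?)")
    return marg
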