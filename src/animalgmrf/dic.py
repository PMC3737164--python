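"""Simulation-based evaluation of DIC as a test for additive genetic effects.

Model choice between

    H0:  eta_i = beta_0 + z_i' beta              (no genetics)
    H1:  eta_i = beta_0 + z_i' beta + u_i        (animal model)

is treated as a hypothesis test with statistic ``dDIC = DIC(H0) − DIC(H1)``
and rejection rule ``dDIC > limit`` (limit 10 by convention).  Its null
sampling distribution is estimated by simulating S datasets under H0 with
the study's pedigree, priors and missing structure, fitting both models to
each, and recording dDIC; the rejection proportion at the limit estimates
the type-I error.  Power at a given sigma_u^2 repeats this with data drawn
under H1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .inference import FitSettings, dic as compute_dic, explore_hyperparameters
from .model import AnimalModelSpec, ObservationSet, build_layout, constraint_matrix
from .pedigree import Pedigree, RelationshipFactors, inbreeding_coefficients
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["DeltaDicStudy", "delta_dic", "null_distribution", "power_curve"]


@dataclass
class DeltaDicStudy:
    """Replicated dDIC draws at one generating sigma_u^2."""

    sigma_u2: float
    sigma_e2: float
    limit: float
    seed: int
    delta_dics: np.ndarray
    n_failed: int
    family: str = "gaussian"

    @property
    def n_replicates(self) -> int:
        return len(self.delta_dics)

    @property
    def rejection_proportion(self) -> float:
        return float(np.mean(self.delta_dics > self.limit))

    def rejection_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Normal-approximation binomial CI for the rejection proportion."""
        from scipy.stats import norm

        p = self.rejection_proportion
        n = self.n_replicates
        z = norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(max(p * (1.0 - p), 1.0 / (4 * n)) / n)
        return (max(0.0, p - half), min(1.0, p + half))

    def limit_for_alpha(self, alpha: float) -> float:
        """Empirical upper-alpha quantile of the null dDIC draws."""
        return float(np.quantile(self.delta_dics, 1.0 - alpha))

    def to_dict(self) -> dict:
        lo, hi = self.rejection_ci()
        return {
            "sigma_u2": self.sigma_u2,
            "sigma_e2": self.sigma_e2,
            "family": self.family,
            "limit": self.limit,
            "seed": self.seed,
            "n_replicates": self.n_replicates,
            "n_failed": self.n_failed,
            "rejection_proportion": self.rejection_proportion,
            "rejection_ci95": [lo, hi],
            "delta_dic": self.delta_dics.tolist(),
        }


def delta_dic(
    obs: ObservationSet,
    ped: Pedigree,
    spec_with_u: AnimalModelSpec,
    spec_without_u: AnimalModelSpec | None = None,
    settings: FitSettings | None = None,
) -> float:
    """DIC(model without u) − DIC(model with u) on the same data."""
    if spec_without_u is None:
        spec_without_u = spec_with_u.without_breeding_values()
    settings = settings or FitSettings()
    dics = []
    for spec in (spec_without_u, spec_with_u):
        layout = build_layout(spec, ped, obs)
        B, e = constraint_matrix(layout)
        points, approxes = explore_hyperparameters(
            layout, obs, B, e,
            delta=settings.delta, drop_threshold=settings.drop_threshold,
            max_points=settings.max_points, theta_init=settings.theta_init,
            fixed_theta=settings.fixed_theta,
            record_correction=settings.record_correction,
            newton_max_iter=settings.newton_max_iter,
            newton_tol=settings.newton_tol,
        )
        dics.append(compute_dic(layout, obs, points, approxes, B, e).dic)
    return dics[0] - dics[1]


def _run_study(
    ped: Pedigree,
    spec: AnimalModelSpec,
    sim: SimulationConfig,
    S: int,
    limit: float,
    seed: int,
    settings: FitSettings | None,
    factors: RelationshipFactors,
) -> DeltaDicStudy:
    values = []
    failed = 0
    for r in range(S):
        cfg = SimulationConfig(**{**sim.__dict__, "seed": seed, "replicate": r})
        try:
            obs, _ = simulate_dataset(cfg, ped, factors=factors)
            values.append(delta_dic(obs, ped, spec, settings=settings))
        except Exception as err:  # noqa: BLE001 - replicate-level isolation
            failed += 1
            logger.warning("replicate %d failed: %s", r, err)
    if failed > 0.1 * S:
        raise RuntimeError(f"{failed}/{S} replicates failed; study aborted")
    return DeltaDicStudy(
        sigma_u2=sim.sigma_u2, sigma_e2=sim.sigma_e2, limit=limit, seed=seed,
        delta_dics=np.asarray(values), n_failed=failed, family=sim.family,
    )


def null_distribution(
    ped: Pedigree,
    spec: AnimalModelSpec,
    sim: SimulationConfig,
    S: int = 100,
    limit: float = 10.0,
    seed: int = 0,
    settings: FitSettings | None = None,
) -> DeltaDicStudy:
    """Sampling distribution of dDIC under H0 (sigma_u^2 = 0).

    The rejection proportion at ``limit`` estimates the type-I error of the
    ``dDIC > limit`` rule for this pedigree/missing structure.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    sim_h0 = SimulationConfig(**{**sim.__dict__, "sigma_u2": 0.0})
    factors = inbreeding_coefficients(ped)
    return _run_study(ped, spec, sim_h0, S, limit, seed, settings, factors)


def power_curve(
    ped: Pedigree,
    spec: AnimalModelSpec,
    sim: SimulationConfig,
    sigma_u2_values,
    S: int = 100,
    limit: float = 10.0,
    seed: int = 0,
    settings: FitSettings | None = None,
    unit_total_variance: bool = True,
) -> list[DeltaDicStudy]:
    """Rejection proportion of dDIC > limit across generating sigma_u^2.

    With ``unit_total_variance`` the Gaussian design keeps
    sigma_u^2 + sigma_e^2 = 1.
    """
    factors = inbreeding_coefficients(ped)
    studies = []
    for j, su in enumerate(sigma_u2_values):
        if su < 0:
            raise ValueError("sigma_u2 must be nonnegative")
        overrides = {"sigma_u2": float(su)}
        if unit_total_variance and sim.family == "gaussian":
            overrides["sigma_e2"] = 1.0 - float(su)
        sim_j = SimulationConfig(**{**sim.__dict__, **overrides})
        studies.append(_run_study(ped, spec, sim_j, S, limit, seed + j, settings, factors))
    return studies
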