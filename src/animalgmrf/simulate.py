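"""Synthetic pedigrees, breeding values, and trait data.

Breeding values are drawn sequentially over the pedigree's topological
order: founders get ``N(0, sigma_u^2)`` and each non-founder the mean of its
known parents plus Mendelian-sampling noise ``N(0, sigma_u^2 d_i)``, with
``d_i`` the inbreeding-aware fraction from the pedigree module, so that the
joint law is exactly ``N(0, sigma_u^2 A)``.

The missing-data profiles mirror a wild-passerine study design: roughly 29%
of pedigree members phenotyped for a morphological (Gaussian) trait and 33%
for reproductive (binomial/count) traits with 1-9 seasons each and ~70% zero
outcomes for the count trait.

All randomness flows from one master seed; replicate ``r`` of a study uses
``numpy.random.default_rng([seed, r])`` so replicates are independent and
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import expit

from .model import ObservationSet
from .pedigree import MISSING, Pedigree, RelationshipFactors, inbreeding_coefficients, pedigree_from_parents

GAUSSIAN_OBSERVED_FRACTION = 1025 / 3574
COUNT_OBSERVED_FRACTION = 1182 / 3574

__all__ = [
    "SimulationConfig",
    "synthetic_pedigree",
    "simulate_breeding_values",
    "simulate_traits",
    "sparrow_like_missing_mask",
    "simulate_dataset",
    "GAUSSIAN_OBSERVED_FRACTION",
    "COUNT_OBSERVED_FRACTION",
]


def synthetic_pedigree(
    n_founders: int = 60,
    n_generations: int = 7,
    mean_offspring: float = 2.0,
    immigrants_per_generation: int = 0,
    seed: int | np.random.Generator = 0,
    target_size: int | None = None,
) -> Pedigree:
    """Multi-generation pedigree with random monogamous pairing.

    Discrete generations: adults of generation g pair randomly (one mate
    each), each pair produces Poisson(mean_offspring) offspring, and
    ``immigrants_per_generation`` unrelated founders join each new
    generation.  Raises if the population dies out before the last
    generation.

    ``target_size`` truncates the pedigree to exactly that many individuals
    (individuals are generated in generation order, so every retained
    individual's parents are retained); raises if fewer were generated.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 1:
        raise ValueError("need at least 1 generation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ids: list[str] = []
    sires: list[str | None] = []
    dams: list[str | None] = []
    sexes: list[int] = []

    def new_individual(gen, sire, dam):
        name = f"g{gen}i{len(ids)}"
        sex = int(rng.integers(0, 2))
        ids.append(name)
        sires.append(sire)
        dams.append(dam)
        sexes.append(sex)
        return name, sex

    current = [new_individual(0, None, None) for _ in range(n_founders)]
    for gen in range(1, n_generations):
        males = [name for name, sex in current if sex == 0]
        females = [name for name, sex in current if sex == 1]
        rng.shuffle(males)
        rng.shuffle(females)
        offspring: list[tuple[str, int]] = []
        for m, f in zip(males, females):
            for _ in range(rng.poisson(mean_offspring)):
                offspring.append(new_individual(gen, m, f))
        for _ in range(immigrants_per_generation):
            offspring.append(new_individual(gen, None, None))
        if not offspring:
            raise RuntimeError(
                f"pedigree extinct at generation {gen}: no pairs produced offspring"
            )
        current = offspring
    if target_size is not None:
        if len(ids) < target_size:
            raise RuntimeError(
                f"generated only {len(ids)} individuals (< target_size={target_size}); "
                "increase founders or offspring"
            )
        ids, sires, dams = ids[:target_size], sires[:target_size], dams[:target_size]
    return pedigree_from_parents(ids, sires, dams)


def simulate_breeding_values(
    ped: Pedigree,
    sigma_u2: float,
    seed: int | np.random.Generator = 0,
    factors: RelationshipFactors | None = None,
    size: int | None = None,
) -> np.ndarray:
    """Draw u ~ N(0, sigma_u^2 A) by sequential Mendelian sampling.

    With ``size`` set, returns ``(size, n_p)`` independent replicates drawn
    with vectorized per-individual recursions (useful for checking the
    empirical covariance against sigma_u^2 A).
    """
    if sigma_u2 < 0:
        raise ValueError("sigma_u2 must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = ped.n_p
    reps = 1 if size is None else int(size)
    u = np.zeros((reps, n))
    if sigma_u2 == 0.0:
        return u[0] if size is None else u
    if factors is None:
        factors = inbreeding_coefficients(ped)
    z = rng.standard_normal((reps, n))
    for i in ped.generation_order:
        s, d = ped.sire_index[i], ped.dam_index[i]
        mean = 0.0
        if s != MISSING:
            mean = mean + 0.5 * u[:, s]
        if d != MISSING:
            mean = mean + 0.5 * u[:, d]
        u[:, i] = mean + z[:, i] * np.sqrt(sigma_u2 * factors.d[i])
    return u[0] if size is None else u


def sparrow_like_missing_mask(
    ped: Pedigree,
    trait_profile: str | float = "gaussian_like",
    seed: int | np.random.Generator = 0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean observed-mask over pedigree members.

    ``gaussian_like`` observes ~29% of individuals (morphological trait),
    ``count_like`` ~33% (reproductive traits); a float requests that exact
    observed fraction; an explicit mask is used verbatim.
    """
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != ped.n_p:
            raise ValueError("explicit mask length does not match pedigree size")
        return mask
    if trait_profile == "gaussian_like":
        fraction = GAUSSIAN_OBSERVED_FRACTION
    elif trait_profile == "count_like":
        fraction = COUNT_OBSERVED_FRACTION
    else:
        fraction = float(trait_profile)
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"observed fraction must be in (0, 1], got {fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_obs = int(round(fraction * ped.n_p))
    chosen = rng.choice(ped.n_p, size=n_obs, replace=False)
    out = np.zeros(ped.n_p, dtype=bool)
    out[chosen] = True
    return out


@dataclass
class SimulationConfig:
    """Generating model for one synthetic dataset.

    Defaults follow the synthetic study design: intercept-plus-genetics
    linear predictor (``eta_i = beta0 + u_i``), unit total variance split
    between ``sigma_u2`` and ``sigma_e2`` for Gaussian traits, binomial trial
    counts uniform on {1..9}, and ~70% structural-plus-sampling zeros for ZIP
    traits.
    """

    family: str = "gaussian"
    beta0: float = 0.0
    sigma_u2: float = 0.4
    sigma_e2: float = 0.6
    zip_p: float = 0.3
    trials: str | int | np.ndarray = "uniform1to9"   # binomial n_i source
    exposure: str | float | np.ndarray = "uniform1to9"
    observed: str | float | np.ndarray | None = None  # None -> all observed
    seed: int = 0
    replicate: int | None = None

    def rng(self) -> np.random.Generator:
        if self.replicate is None:
            return np.random.default_rng(self.seed)
        return np.random.default_rng([self.seed, self.replicate])


def _resolve_counts(source, n, rng) -> np.ndarray:
    if isinstance(source, str):
        if source == "uniform1to9":
            return rng.integers(1, 10, size=n).astype(float)
        raise ValueError(f"unknown trial/exposure source {source!r}")
    if np.isscalar(source):
        return np.full(n, float(source))
    arr = np.asarray(source, dtype=float)
    if len(arr) != n:
        raise ValueError("trials/exposure array length does not match pedigree size")
    return arr


def simulate_traits(
    config: SimulationConfig,
    ped: Pedigree,
    u: np.ndarray,
    rng: np.random.Generator | None = None,
) -> ObservationSet:
    """Draw trait records given breeding values, then apply the missing mask."""
    rng = rng if rng is not None else config.rng()
    n = ped.n_p
    if len(u) != n:
        raise ValueError("breeding-value vector length does not match pedigree size")
    eta = config.beta0 + u

    if config.observed is None:
        mask = np.ones(n, dtype=bool)
    elif isinstance(config.observed, (str, float)):
        mask = sparrow_like_missing_mask(ped, config.observed, rng)
    else:
        mask = sparrow_like_missing_mask(ped, mask=np.asarray(config.observed), seed=rng)

    ids = np.asarray(ped.ids, dtype=object)
    fam = config.family
    if fam == "gaussian":
        y = eta + rng.normal(0.0, np.sqrt(config.sigma_e2), size=n)
        return ObservationSet(ids=ids[mask], y=y[mask])
    if fam == "binomial":
        trials = _resolve_counts(config.trials, n, rng)
        y = rng.binomial(trials.astype(int), expit(eta))
        return ObservationSet(ids=ids[mask], y=y[mask], n_trials=trials[mask])
    if fam in ("poisson", "zip"):
        exposure = _resolve_counts(config.exposure, n, rng)
        lam = exposure * np.exp(eta)
        y = rng.poisson(lam).astype(float)
        if fam == "zip":
            inflated = rng.random(n) < config.zip_p
            y[inflated] = 0.0
        return ObservationSet(ids=ids[mask], y=y[mask], exposure=exposure[mask])
    raise ValueError(f"unknown family {fam!r}")


def simulate_dataset(
    config: SimulationConfig,
    ped: Pedigree,
    factors: RelationshipFactors | None = None,
) -> tuple[ObservationSet, np.ndarray]:
    """Breeding values plus traits under one config; returns (records, u)."""
    rng = config.rng()
    u = simulate_breeding_values(ped, config.sigma_u2, rng, factors=factors)
    obs = simulate_traits(config, ped, u, rng)
    return obs, u
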