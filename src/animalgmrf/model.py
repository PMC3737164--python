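"""Animal-model specification and latent-field assembly.

An animal model is a GLMM whose linear predictor for record ``r`` of
individual ``i`` is

    eta_r = beta_0 + z_r' beta + u_i (+ ind_i),

with breeding values ``u ~ N(0, sigma_u^2 A)`` correlated through the
pedigree, optional i.i.d. individual effects for repeated measures, and a
Gaussian residual that lives in the observation noise for Gaussian traits and
is omitted (confounded with the link) for binomial/Poisson/ZIP traits.

The latent field ``x = (beta_0, beta, u, ind)`` is a Gaussian Markov random
field with block-diagonal prior precision
``Q(theta) = blockdiag(I/sigma_beta^2, A^{-1}/sigma_u^2, I/sigma_ind^2)``;
identifiability is restored by sum-to-zero constraints on each factor's
levels and (optionally) on the breeding values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import Pedigree, a_inverse, inbreeding_coefficients

FAMILIES = ("gaussian", "binomial", "poisson", "zip")
LINKS = {"gaussian": "identity", "binomial": "logit", "poisson": "log", "zip": "log"}

__all__ = [
    "FAMILIES",
    "InvGammaPrior",
    "AnimalModelSpec",
    "ObservationSet",
    "LatentFieldLayout",
    "ModelSpecError",
    "build_layout",
    "constraint_matrix",
    "default_priors",
    "read_phenotypes",
]


class ModelSpecError(ValueError):
    pass


@dataclass(frozen=True)
class InvGammaPrior:
    """Inverse-gamma prior on a variance, mean b/(a-1) when a > 1."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ModelSpecError(f"inverse-gamma parameters must be positive, got ({self.a}, {self.b})")

    @property
    def mean(self) -> float | None:
        return self.b / (self.a - 1.0) if self.a > 1.0 else None

    @property
    def variance(self) -> float | None:
        if self.a <= 2.0:
            return None
        return self.b**2 / ((self.a - 1.0) ** 2 * (self.a - 2.0))

    def log_density_internal(self, theta: float) -> float:
        """Log prior density of log(sigma^2) = theta, Jacobian included."""
        return self.a * math.log(self.b) - math.lgamma(self.a) - self.a * theta - self.b * math.exp(-theta)

    def summary(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "mean": "undefined" if self.mean is None else self.mean,
            "variance": "undefined" if self.variance is None else self.variance,
        }


def default_priors(spec: "AnimalModelSpec") -> dict[str, InvGammaPrior]:
    """Default variance-component priors.

    ``sigma_u^2`` and ``sigma_e^2`` get InvGamma(0.5, 0.5); the
    repeated-measures individual variance gets InvGamma(1, 0.001).
    """
    priors = {}
    if spec.include_breeding_values:
        priors["sigma_u2"] = InvGammaPrior(0.5, 0.5)
    if spec.family == "gaussian":
        priors["sigma_e2"] = InvGammaPrior(0.5, 0.5)
    if spec.include_individual_effect:
        priors["sigma_ind2"] = InvGammaPrior(1.0, 0.001)
    return priors


@dataclass(frozen=True)
class AnimalModelSpec:
    """Declarative model: family, terms, priors, constraints.

    Parameters
    ----------
    family:
        One of ``gaussian``, ``binomial``, ``poisson``, ``zip``; the link is
        implied (identity / logit / log / log).
    fixed_factors:
        Mapping factor name -> declared level list (e.g. sex, hatch year,
        island).  Levels are sorted lexicographically for determinism.
    covariates:
        Names of linear covariates (e.g. age), sharing the fixed-effect
        prior variance.
    include_residual_effect:
        Gaussian only.  For non-Gaussian families the unstructured residual
        is confounded with the link and must be off.
    beta_variance:
        Fixed prior variance sigma_beta^2 of intercept, factor levels and
        covariate slopes.
    zip_p_prior_sd:
        SD of the Normal prior on logit(p) for the ZIP mixing probability.
    """

    family: str
    fixed_factors: dict[str, tuple[str, ...]] = dc_field(default_factory=dict)
    covariates: tuple[str, ...] = ()
    include_breeding_values: bool = True
    include_individual_effect: bool = False
    include_residual_effect: bool | None = None
    priors: dict[str, InvGammaPrior] | None = None
    beta_variance: float = 2.2e4
    constrain_breeding_values: bool = True
    zip_p_prior_sd: float = 1.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ModelSpecError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        residual = self.include_residual_effect
        if residual is None:
            residual = self.family == "gaussian"
        if residual and self.family != "gaussian":
            raise ModelSpecError(
                f"residual effect is confounded with the {LINKS[self.family]} link "
                f"for family {self.family!r} and must be omitted"
            )
        if not residual and self.family == "gaussian":
            raise ModelSpecError("gaussian likelihood requires the residual variance")
        object.__setattr__(self, "include_residual_effect", residual)
        if self.include_individual_effect and self.family != "gaussian":
            raise ModelSpecError("individual (repeated-measures) effect is supported for gaussian traits")
        canon = {
            name: tuple(sorted(set(str(l) for l in levels)))
            for name, levels in self.fixed_factors.items()
        }
        object.__setattr__(self, "fixed_factors", canon)
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.priors is None:
            object.__setattr__(self, "priors", default_priors(self))

    @property
    def link(self) -> str:
        return LINKS[self.family]

    @property
    def hyper_names(self) -> tuple[str, ...]:
        """Ordered non-Gaussian hyperparameters of the fitted model."""
        names = []
        if self.include_breeding_values:
            names.append("sigma_u2")
        if self.family == "gaussian":
            names.append("sigma_e2")
        if self.include_individual_effect:
            names.append("sigma_ind2")
        if self.family == "zip":
            names.append("p")
        return tuple(names)

    def without_breeding_values(self) -> "AnimalModelSpec":
        return AnimalModelSpec(
            family=self.family,
            fixed_factors=self.fixed_factors,
            covariates=self.covariates,
            include_breeding_values=False,
            include_individual_effect=self.include_individual_effect,
            include_residual_effect=self.include_residual_effect,
            priors={k: v for k, v in self.priors.items() if k != "sigma_u2"},
            beta_variance=self.beta_variance,
            constrain_breeding_values=self.constrain_breeding_values,
            zip_p_prior_sd=self.zip_p_prior_sd,
        )


@dataclass
class ObservationSet:
    """Phenotype records; pedigree members absent from it are missing data.

    ``n_trials`` is the binomial trial count; ``exposure`` the Poisson/ZIP
    exposure (e.g. number of breeding seasons).  Repeated rows per individual
    are allowed for Gaussian traits with an individual effect.
    """

    ids: np.ndarray
    y: np.ndarray
    n_trials: np.ndarray | None = None
    exposure: np.ndarray | None = None
    factors: dict[str, np.ndarray] = dc_field(default_factory=dict)
    covariate_values: dict[str, np.ndarray] = dc_field(default_factory=dict)

    def __post_init__(self):
        self.ids = np.asarray([str(i) for i in self.ids], dtype=object)
        self.y = np.asarray(self.y, dtype=float)
        if self.n_trials is not None:
            self.n_trials = np.asarray(self.n_trials, dtype=float)
        if self.exposure is not None:
            self.exposure = np.asarray(self.exposure, dtype=float)
        self.factors = {
            k: np.asarray([str(v) for v in vals], dtype=object)
            for k, vals in self.factors.items()
        }
        self.covariate_values = {k: np.asarray(v, dtype=float) for k, v in self.covariate_values.items()}

    @property
    def n_records(self) -> int:
        return len(self.ids)

    def validate(self, spec: AnimalModelSpec) -> None:
        if spec.family == "binomial":
            if self.n_trials is None:
                raise ModelSpecError("binomial data require per-record trial counts")
            if np.any(self.y < 0) or np.any(self.y > self.n_trials):
                raise ModelSpecError("binomial responses must satisfy 0 <= y <= n")
        if spec.family in ("poisson", "zip"):
            if self.exposure is None:
                raise ModelSpecError(f"{spec.family} data require per-record exposure")
            if np.any(self.exposure <= 0):
                raise ModelSpecError("exposure must be positive")
            if np.any(self.y < 0):
                raise ModelSpecError("count responses must be nonnegative")
        for name in spec.fixed_factors:
            if name not in self.factors:
                raise ModelSpecError(f"factor {name!r} missing from observations")
        for name in spec.covariates:
            if name not in self.covariate_values:
                raise ModelSpecError(f"covariate {name!r} missing from observations")
        if spec.family == "gaussian" and not spec.include_individual_effect:
            if len(np.unique(self.ids.astype(str))) != len(self.ids):
                raise ModelSpecError("repeated gaussian records require include_individual_effect")

    def standardized(self) -> tuple["ObservationSet", dict]:
        """Center/scale a gaussian response to mean 0, variance 1."""
        m = float(np.mean(self.y))
        s = float(np.std(self.y, ddof=1))
        out = ObservationSet(
            ids=self.ids, y=(self.y - m) / s, n_trials=self.n_trials,
            exposure=self.exposure, factors=self.factors,
            covariate_values=self.covariate_values,
        )
        return out, {"center": m, "scale": s}

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.ids, "y": self.y}
        if self.n_trials is not None:
            data["n"] = self.n_trials
        if self.exposure is not None:
            data["exposure"] = self.exposure
        for k, v in self.factors.items():
            data[k] = v
        for k, v in self.covariate_values.items():
            data[k] = v
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_phenotypes(path, factor_names=(), covariate_names=()) -> ObservationSet:
    """Read a phenotype CSV with header ``id,y[,n,exposure,<extras...>]``."""
    df = pd.read_csv(path)
    if "id" not in df.columns or "y" not in df.columns:
        raise ModelSpecError(f"phenotype file must have columns id,y; got {list(df.columns)}")
    return ObservationSet(
        ids=df["id"].astype(str).to_numpy(),
        y=df["y"].to_numpy(dtype=float),
        n_trials=df["n"].to_numpy(dtype=float) if "n" in df.columns else None,
        exposure=df["exposure"].to_numpy(dtype=float) if "exposure" in df.columns else None,
        factors={k: df[k].astype(str).to_numpy() for k in factor_names},
        covariate_values={k: df[k].to_numpy(dtype=float) for k in covariate_names},
    )


@dataclass
class LatentFieldLayout:
    """Block layout of the latent field and the record -> predictor map.

    Blocks appear in the order intercept, factor levels (each factor a
    contiguous block of its sorted levels), covariate slopes, breeding values
    ``u`` (pedigree order), individual effects (ids with records, sorted).
    ``ones_A_ones = 1'A1`` and ``logdet_Ainv`` are cached for the constraint
    normalizers of the marginal-likelihood computation.
    """

    spec: AnimalModelSpec
    ped: Pedigree
    blocks: dict[str, tuple[int, int]]
    dim: int
    Z: sp.csr_matrix
    record_individual: np.ndarray
    ind_ids: tuple[str, ...]
    Ainv: sp.csc_matrix | None
    logdet_Ainv: float
    ones_A_ones: float

    @property
    def n_records(self) -> int:
        return self.Z.shape[0]

    @property
    def hyper_names(self) -> tuple[str, ...]:
        return self.spec.hyper_names

    def block_slice(self, name: str) -> slice:
        off, size = self.blocks[name]
        return slice(off, off + size)

    def u_index(self, individual_id: str) -> int:
        off, _ = self.blocks["u"]
        return off + self.ped.index[individual_id]

    def prior_precision(self, theta: dict[str, float]) -> sp.csc_matrix:
        """Assemble Q(theta) = blockdiag(I/sigma_beta^2, A^{-1}/sigma_u^2, I/sigma_ind^2)."""
        parts = []
        n_fixed = self.blocks["fixed"][1]
        parts.append(sp.identity(n_fixed) / self.spec.beta_variance)
        if "u" in self.blocks:
            parts.append(self.Ainv / theta["sigma_u2"])
        if "ind" in self.blocks:
            parts.append(sp.identity(len(self.ind_ids)) / theta["sigma_ind2"])
        return sp.block_diag(parts, format="csc")

    def prior_logdet(self, theta: dict[str, float]) -> float:
        n_fixed = self.blocks["fixed"][1]
        val = -n_fixed * math.log(self.spec.beta_variance)
        if "u" in self.blocks:
            val += self.logdet_Ainv - self.ped.n_p * math.log(theta["sigma_u2"])
        if "ind" in self.blocks:
            val += -len(self.ind_ids) * math.log(theta["sigma_ind2"])
        return val


def build_layout(spec: AnimalModelSpec, ped: Pedigree, obs: ObservationSet) -> LatentFieldLayout:
    """Validate observations against the spec and assemble the layout."""
    obs.validate(spec)

    blocks: dict[str, tuple[int, int]] = {}
    offset = 0
    blocks["intercept"] = (offset, 1)
    offset += 1
    for name, levels in spec.fixed_factors.items():
        blocks[f"factor:{name}"] = (offset, len(levels))
        offset += len(levels)
    for name in spec.covariates:
        blocks[f"cov:{name}"] = (offset, 1)
        offset += 1
    blocks["fixed"] = (0, offset)

    if spec.include_breeding_values:
        blocks["u"] = (offset, ped.n_p)
        offset += ped.n_p
    ind_ids: tuple[str, ...] = ()
    if spec.include_individual_effect:
        ind_ids = tuple(sorted(set(obs.ids.astype(str))))
        blocks["ind"] = (offset, len(ind_ids))
        offset += len(ind_ids)
    dim = offset

    nrec = obs.n_records
    rec_ind = np.empty(nrec, dtype=int)
    for r, name in enumerate(obs.ids):
        if name not in ped.index:
            raise ModelSpecError(f"individual {name!r} has a record but is not in the pedigree")
        rec_ind[r] = ped.index[name]

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r, c, v=1.0):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    ind_pos = {name: i for i, name in enumerate(ind_ids)}
    for r in range(nrec):
        add(r, blocks["intercept"][0])
        for name, levels in spec.fixed_factors.items():
            level = obs.factors[name][r]
            try:
                j = levels.index(level)
            except ValueError:
                raise ModelSpecError(
                    f"record {r}: level {level!r} of factor {name!r} is not declared"
                ) from None
            add(r, blocks[f"factor:{name}"][0] + j)
        for name in spec.covariates:
            add(r, blocks[f"cov:{name}"][0], obs.covariate_values[name][r])
        if spec.include_breeding_values:
            add(r, blocks["u"][0] + rec_ind[r])
        if spec.include_individual_effect:
            add(r, blocks["ind"][0] + ind_pos[obs.ids[r]])
    Z = sp.coo_matrix((vals, (rows, cols)), shape=(nrec, dim)).tocsr()

    Ainv = None
    logdet_Ainv = 0.0
    ones_A_ones = 0.0
    if spec.include_breeding_values:
        Ainv = a_inverse(ped, inbreeding_coefficients(ped))
        lu = spla.splu(
            Ainv, permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
            options={"SymmetricMode": True},
        )
        logdet_Ainv = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        ones = np.ones(ped.n_p)
        ones_A_ones = float(ones @ lu.solve(ones))

    return LatentFieldLayout(
        spec=spec, ped=ped, blocks=blocks, dim=dim, Z=Z,
        record_individual=rec_ind, ind_ids=ind_ids,
        Ainv=Ainv, logdet_Ainv=logdet_Ainv, ones_A_ones=ones_A_ones,
    )


def constraint_matrix(layout: LatentFieldLayout) -> tuple[np.ndarray, np.ndarray]:
    """Sum-to-zero constraint system ``B x = e`` (e = 0).

    One row of ones per factor's level block, plus one row over the breeding
    values when the spec constrains them.  ``B`` may have zero rows.
    """
    rows = []
    spec = layout.spec
    for name in spec.fixed_factors:
        row = np.zeros(layout.dim)
        row[layout.block_slice(f"factor:{name}")] = 1.0
        rows.append(row)
    if spec.include_breeding_values and spec.constrain_breeding_values:
        row = np.zeros(layout.dim)
        row[layout.block_slice("u")] = 1.0
        rows.append(row)
    B = np.asarray(rows) if rows else np.zeros((0, layout.dim))
    return B, np.zeros(B.shape[0])
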