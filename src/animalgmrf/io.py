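"""Run configuration, manifests, and result serialization.

A run is described by one flat YAML file; command-line flags override file
values.  Every run writes a manifest echoing the fully resolved
configuration, the package version, and the master seed, so any stage can be
re-run in isolation.  Unknown configuration keys are errors, not warnings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .inference import FitResult, FitSettings
from .model import AnimalModelSpec, InvGammaPrior

__all__ = [
    "ConfigError",
    "load_config",
    "spec_from_config",
    "settings_from_config",
    "write_manifest",
    "serialize_fit",
    "write_json",
]


class ConfigError(ValueError):
    pass


_TOP_KEYS = {
    "seed", "output_dir", "pedigree", "phenotypes", "verbosity",
    "model", "simulation", "numerics", "dic_eval", "model_select",
}
_MODEL_KEYS = {
    "family", "factors", "covariates", "breeding_values", "individual_effect",
    "residual_effect", "priors", "beta_variance", "constrain_breeding_values",
    "zip_p_prior_sd", "standardize",
}
_SIM_KEYS = {
    "family", "n_founders", "n_generations", "mean_offspring",
    "immigrants_per_generation", "beta0", "sigma_u2", "sigma_e2", "zip_p",
    "trials", "exposure", "observed",
}
_NUM_KEYS = {"delta", "drop_threshold", "max_points", "max_iter", "tol",
             "record_correction", "compute_dic", "latent_sds"}
_DIC_KEYS = {"S", "limit", "sigma_u2_values", "alpha"}
_SELECT_KEYS = {"candidates", "stepwise"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path) -> dict:
    """Load and validate a run configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "top level")
    for key, allowed in (
        ("model", _MODEL_KEYS), ("simulation", _SIM_KEYS),
        ("numerics", _NUM_KEYS), ("dic_eval", _DIC_KEYS),
        ("model_select", _SELECT_KEYS),
    ):
        if key in cfg:
            if not isinstance(cfg[key], dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            _check_keys(cfg[key], allowed, f"section {key!r}")
    if "seed" not in cfg:
        raise ConfigError("configuration must set a seed")
    return cfg


def spec_from_config(model_cfg: dict, observed_levels: dict[str, list[str]] | None = None) -> AnimalModelSpec:
    """Build an AnimalModelSpec from the ``model`` config section.

    ``factors`` may be a mapping name -> level list, or a list of names whose
    levels are taken from the observed data.
    """
    if "family" not in model_cfg:
        raise ConfigError("model section must name a family")
    factors_cfg = model_cfg.get("factors", {})
    if isinstance(factors_cfg, list):
        if observed_levels is None:
            raise ConfigError("factor levels not declared and no data to infer them from")
        factors = {name: tuple(observed_levels[name]) for name in factors_cfg}
    else:
        factors = {name: tuple(levels) for name, levels in factors_cfg.items()}
    priors = None
    if "priors" in model_cfg:
        priors = {
            name: InvGammaPrior(float(ab[0]), float(ab[1]))
            for name, ab in model_cfg["priors"].items()
        }
    return AnimalModelSpec(
        family=model_cfg["family"],
        fixed_factors=factors,
        covariates=tuple(model_cfg.get("covariates", ())),
        include_breeding_values=bool(model_cfg.get("breeding_values", True)),
        include_individual_effect=bool(model_cfg.get("individual_effect", False)),
        include_residual_effect=model_cfg.get("residual_effect"),
        priors=priors,
        beta_variance=float(model_cfg.get("beta_variance", 2.2e4)),
        constrain_breeding_values=bool(model_cfg.get("constrain_breeding_values", True)),
        zip_p_prior_sd=float(model_cfg.get("zip_p_prior_sd", 1.0)),
    )


def settings_from_config(num_cfg: dict) -> FitSettings:
    return FitSettings(
        delta=float(num_cfg.get("delta", 0.5)),
        drop_threshold=float(num_cfg.get("drop_threshold", 2.5)),
        max_points=int(num_cfg.get("max_points", 400)),
        newton_max_iter=int(num_cfg.get("max_iter", 50)),
        newton_tol=float(num_cfg.get("tol", 1e-8)),
        record_correction=bool(num_cfg.get("record_correction", True)),
        compute_dic=bool(num_cfg.get("compute_dic", True)),
        latent_sds=str(num_cfg.get("latent_sds", "fixed")),
    )


def write_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_manifest(output_dir, command: str, cfg: dict, derived_seeds: dict | None = None) -> Path:
    path = Path(output_dir) / "manifest.json"
    write_json(path, {
        "command": command,
        "package_version": __version__,
        "seed": cfg.get("seed"),
        "derived_seeds": derived_seeds or {},
        "config": cfg,
    })
    return path


def serialize_fit(fit: FitResult) -> dict:
    """JSON-ready summary of a fit: hyper marginals, DIC, convergence."""
    out: dict = {
        "family": fit.layout.spec.family,
        "latent_dimension": fit.layout.dim,
        "n_records": fit.layout.n_records,
        "n_grid_points": len(fit.points),
        "hyper_marginals": {k: m.to_dict() for k, m in fit.hyper_marginals.items()},
        "theta_map": fit.theta_map,
        "priors": {k: p.summary() for k, p in fit.layout.spec.priors.items()},
        "convergence": {
            "max_newton_iterations": max(a.n_iter for a in fit.approxes),
            "max_grad_norm": max(a.grad_norm for a in fit.approxes),
        },
    }
    if fit.dic is not None:
        out["dic"] = fit.dic.to_dict()
    if fit.lincombs:
        out["lincombs"] = {k: m.to_dict() for k, m in fit.lincombs.items()}
    if "u" in fit.layout.blocks:
        u = fit.posterior_mean_u()
        out["breeding_values"] = {"sum_posterior_mean": float(u.sum())}
    return out
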