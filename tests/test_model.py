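"""Model specification, latent-field layout, and constraints."""

import numpy as np
import pytest

from animalgmrf.model import (
    AnimalModelSpec,
    InvGammaPrior,
    ModelSpecError,
    ObservationSet,
    build_layout,
    constraint_matrix,
    default_priors,
    read_phenotypes,
)
from animalgmrf.inference import explore_hyperparameters, latent_marginals

from conftest import random_pedigree


class TestSpecValidation:
    def test_residual_forced_off_for_binomial(self):
        with pytest.raises(ModelSpecError, match="confounded"):
            AnimalModelSpec(family="binomial", include_residual_effect=True)

    @pytest.mark.parametrize("family", ["binomial", "poisson", "zip"])
    def test_non_gaussian_defaults_omit_residual(self, family):
        spec = AnimalModelSpec(family=family)
        assert spec.include_residual_effect is False

    def test_unknown_family(self):
        with pytest.raises(ModelSpecError, match="unknown family"):
            AnimalModelSpec(family="lognormal")

    def test_hyper_names_by_family(self):
        assert AnimalModelSpec(family="gaussian").hyper_names == ("sigma_u2", "sigma_e2")
        assert AnimalModelSpec(family="binomial").hyper_names == ("sigma_u2",)
        assert AnimalModelSpec(family="zip").hyper_names == ("sigma_u2", "p")
        assert AnimalModelSpec(
            family="gaussian", include_individual_effect=True
        ).hyper_names == ("sigma_u2", "sigma_e2", "sigma_ind2")


class TestDefaultPriors:
    def test_gaussian_defaults(self):
        spec = AnimalModelSpec(family="gaussian")
        assert spec.priors["sigma_u2"] == InvGammaPrior(0.5, 0.5)
        assert spec.priors["sigma_e2"] == InvGammaPrior(0.5, 0.5)
        assert spec.beta_variance == 2.2e4

    def test_repeated_measures_adds_individual_prior(self):
        spec = AnimalModelSpec(family="gaussian", include_individual_effect=True)
        assert spec.priors["sigma_ind2"] == InvGammaPrior(1.0, 0.001)

    def test_undefined_prior_mean_reported_not_crashed(self):
        prior = InvGammaPrior(0.5, 0.5)
        assert prior.mean is None
        assert prior.summary()["mean"] == "undefined"
        assert InvGammaPrior(3.0, 1.0).mean == pytest.approx(0.5)


class TestLayout:
    def test_intercept_plus_u_dimension(self, trio):
        spec = AnimalModelSpec(family="gaussian")
        obs = ObservationSet(ids=["1", "2", "3"], y=[0.1, 0.2, 0.3])
        layout = build_layout(spec, trio, obs)
        assert layout.dim == 4  # beta0 + 3 breeding values

    def test_morphometric_style_dimension(self, founders_factory):
        # intercept + sex(2) + year(10) + island(6) + u over the full pedigree
        ped = founders_factory(3574)
        spec = AnimalModelSpec(
            family="gaussian",
            fixed_factors={
                "sex": ("f", "m"),
                "year": tuple(str(1993 + i) for i in range(10)),
                "island": tuple(f"i{k}" for k in range(6)),
            },
        )
        rng = np.random.default_rng(0)
        ids = [f"f{i}" for i in range(100)]
        obs = ObservationSet(
            ids=ids,
            y=rng.normal(size=100),
            factors={
                "sex": rng.choice(["f", "m"], 100),
                "year": rng.choice([str(1993 + i) for i in range(10)], 100),
                "island": rng.choice([f"i{k}" for k in range(6)], 100),
            },
        )
        layout = build_layout(spec, ped, obs)
        assert layout.dim == 1 + 2 + 10 + 6 + 3574

    def test_unknown_factor_level_rejected(self, trio):
        spec = AnimalModelSpec(family="gaussian", fixed_factors={"sex": ("f", "m")})
        obs = ObservationSet(ids=["1"], y=[0.0], factors={"sex": ["x"]})
        with pytest.raises(ModelSpecError, match="not declared"):
            build_layout(spec, trio, obs)

    def test_record_for_unknown_individual_rejected(self, trio):
        spec = AnimalModelSpec(family="gaussian")
        obs = ObservationSet(ids=["99"], y=[0.0])
        with pytest.raises(ModelSpecError, match="not in the pedigree"):
            build_layout(spec, trio, obs)

    def test_repeated_gaussian_records_need_individual_effect(self, trio):
        spec = AnimalModelSpec(family="gaussian")
        obs = ObservationSet(ids=["1", "1"], y=[0.0, 0.1])
        with pytest.raises(ModelSpecError, match="individual_effect"):
            build_layout(spec, trio, obs)
        spec_ok = AnimalModelSpec(family="gaussian", include_individual_effect=True)
        layout = build_layout(spec_ok, trio, obs)
        assert layout.blocks["ind"][1] == 1

    def test_binomial_response_bounds(self, trio):
        spec = AnimalModelSpec(family="binomial")
        obs = ObservationSet(ids=["1"], y=[3], n_trials=[2])
        with pytest.raises(ModelSpecError, match="0 <= y <= n"):
            build_layout(spec, trio, obs)

    def test_nonpositive_exposure_rejected(self, trio):
        spec = AnimalModelSpec(family="poisson")
        obs = ObservationSet(ids=["1"], y=[1], exposure=[0.0])
        with pytest.raises(ModelSpecError, match="exposure"):
            build_layout(spec, trio, obs)


class TestConstraints:
    def test_u_constraint_row(self, trio):
        spec = AnimalModelSpec(family="gaussian")
        obs = ObservationSet(ids=["1", "2", "3"], y=[0.1, 0.2, 0.3])
        layout = build_layout(spec, trio, obs)
        B, e = constraint_matrix(layout)
        np.testing.assert_array_equal(B, [[0.0, 1.0, 1.0, 1.0]])
        np.testing.assert_array_equal(e, [0.0])

    def test_factor_rows(self, trio):
        spec = AnimalModelSpec(
            family="gaussian", fixed_factors={"sex": ("f", "m")},
            constrain_breeding_values=False,
        )
        obs = ObservationSet(ids=["1"], y=[0.0], factors={"sex": ["f"]})
        layout = build_layout(spec, trio, obs)
        B, _ = constraint_matrix(layout)
        assert B.shape == (1, layout.dim)
        np.testing.assert_array_equal(B[0, layout.block_slice("factor:sex")], 1.0)

    def test_empty_constraint_system_accepted(self, trio):
        spec = AnimalModelSpec(family="gaussian", constrain_breeding_values=False)
        obs = ObservationSet(ids=["1"], y=[0.0])
        layout = build_layout(spec, trio, obs)
        B, e = constraint_matrix(layout)
        assert B.shape == (0, layout.dim)

    @pytest.mark.parametrize("scale", [1e-4, 1.0, 1e4])
    def test_prior_precision_spd_on_constraint_null_space(self, trio, scale):
        spec = AnimalModelSpec(family="gaussian", fixed_factors={"sex": ("f", "m")})
        obs = ObservationSet(
            ids=["1", "2", "3"], y=[0.1, 0.2, 0.3], factors={"sex": ["f", "m", "f"]}
        )
        layout = build_layout(spec, trio, obs)
        Q = layout.prior_precision({"sigma_u2": scale, "sigma_e2": 1.0}).toarray()
        np.testing.assert_allclose(Q, Q.T)
        B, _ = constraint_matrix(layout)
        # orthonormal basis of null(B)
        _, _, vt = np.linalg.svd(B)
        N = vt[B.shape[0]:].T
        eig = np.linalg.eigvalsh(N.T @ Q @ N)
        assert eig.min() > 0

    def test_eta_posterior_invariant_under_constraints(self, founders_factory):
        """With a diffuse intercept, sum-to-zero on u only reshuffles mass.

        Exact for exchangeable breeding values (founders: A = I), where the
        constraint direction coincides with the intercept direction; for
        structured pedigrees the constrained prior differs by a rank-one term
        along A*1 and eta is only approximately invariant.
        """
        ped = founders_factory(25)
        rng = np.random.default_rng(5)
        ids = [f"f{i}" for i in range(25)]
        obs = ObservationSet(ids=ids, y=rng.normal(0.5, 1.0, 25))
        theta = {"sigma_u2": 0.5, "sigma_e2": 0.5}
        etas = []
        for constrained in (True, False):
            spec = AnimalModelSpec(family="gaussian", constrain_breeding_values=constrained)
            layout = build_layout(spec, ped, obs)
            pts, apps = explore_hyperparameters(layout, obs, fixed_theta=theta)
            etas.append(layout.Z @ apps[0].x_star)
        np.testing.assert_allclose(etas[0], etas[1], atol=1e-6)


class TestPhenotypeIO:
    def test_roundtrip(self, tmp_path):
        obs = ObservationSet(
            ids=["a", "b"], y=[1.0, 2.0], n_trials=[2, 3],
            factors={"sex": ["f", "m"]}, covariate_values={"age": [1.0, 4.0]},
        )
        path = tmp_path / "pheno.csv"
        obs.write_csv(path)
        back = read_phenotypes(path, factor_names=["sex"], covariate_names=["age"])
        np.testing.assert_array_equal(back.ids, obs.ids)
        np.testing.assert_allclose(back.y, obs.y)
        np.testing.assert_allclose(back.n_trials, obs.n_trials)
        np.testing.assert_array_equal(back.factors["sex"], obs.factors["sex"])

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,value\na,1\n")
        with pytest.raises(ModelSpecError, match="id,y"):
            read_phenotypes(path)

    def test_standardization(self):
        obs = ObservationSet(ids=["a", "b", "c"], y=[1.0, 2.0, 3.0])
        std, transform = obs.standardized()
        assert np.mean(std.y) == pytest.approx(0.0)
        assert np.std(std.y, ddof=1) == pytest.approx(1.0)
        assert transform == {"center": 2.0, "scale": 1.0}
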