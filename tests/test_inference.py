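"""Laplace-grid inference against conjugate and dense-optimization oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import digamma
from scipy.stats import multivariate_normal

from animalgmrf.inference import (
    FitSettings,
    InferenceError,
    dic,
    explore_hyperparameters,
    fit_model,
    gaussian_approximation,
    hyper_marginal,
    latent_marginals,
    lincomb_posterior,
    log_evidence,
)
from animalgmrf.likelihoods import loglik
from animalgmrf.model import (
    AnimalModelSpec,
    ObservationSet,
    build_layout,
    constraint_matrix,
)
from animalgmrf.pedigree import pedigree_from_parents, relationship_matrix

from conftest import random_pedigree


def _founders(n):
    ids = [f"f{i}" for i in range(n)]
    return pedigree_from_parents(ids, [None] * n, [None] * n), ids


class TestGaussianApproximation:
    def test_single_datum_conjugate(self):
        # y = 1.2, latent effect prior N(0,1), sigma_e2 = 1 -> posterior N(0.6, 0.5)
        ped, ids = _founders(1)
        spec = AnimalModelSpec(family="gaussian", include_breeding_values=False, beta_variance=1.0)
        obs = ObservationSet(ids=ids, y=[1.2])
        layout = build_layout(spec, ped, obs)
        ga = gaussian_approximation(layout, obs, {"sigma_e2": 1.0})
        assert ga.x_star[0] == pytest.approx(0.6, abs=1e-12)
        assert ga.marginal_variances([0])[0] == pytest.approx(0.5, abs=1e-12)

    def test_binomial_symmetric_mode(self):
        ped, ids = _founders(1)
        spec = AnimalModelSpec(family="binomial", include_breeding_values=False, beta_variance=1.0)
        obs = ObservationSet(ids=ids, y=[1], n_trials=[2])
        layout = build_layout(spec, ped, obs)
        ga = gaussian_approximation(layout, obs, {})
        assert ga.x_star[0] == pytest.approx(0.0, abs=1e-10)
        assert ga.marginal_variances([0])[0] == pytest.approx(1.0 / 1.5, abs=1e-10)

    def test_binomial_mode_matches_dense_optimizer(self):
        """Newton mode equals a generic dense optimizer on a pedigreed model."""
        ped = random_pedigree(np.random.default_rng(11), 30)
        rng = np.random.default_rng(12)
        ids = [str(i) for i in range(30)]
        n = rng.integers(1, 8, 30).astype(float)
        y = rng.binomial(n.astype(int), 0.5).astype(float)
        obs = ObservationSet(ids=ids, y=y, n_trials=n)
        spec = AnimalModelSpec(family="binomial", constrain_breeding_values=False)
        layout = build_layout(spec, ped, obs)
        theta = {"sigma_u2": 0.8}
        ga = gaussian_approximation(layout, obs, theta)

        Q = layout.prior_precision(theta).toarray()
        Z = np.asarray(layout.Z.todense())

        def negobj(x):
            v, _, _ = loglik("binomial", y, Z @ x, n_trials=n)
            return -(np.sum(v) - 0.5 * x @ Q @ x)

        res = minimize(negobj, np.zeros(layout.dim), method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 2000})
        np.testing.assert_allclose(ga.x_star, res.x, atol=1e-6)

    def test_constrained_mode_matches_dense_oracle(self, trio):
        spec = AnimalModelSpec(family="gaussian", beta_variance=4.0)
        y = np.array([0.61, -0.34, 1.02])
        obs = ObservationSet(ids=["1", "2", "3"], y=y)
        layout = build_layout(spec, trio, obs)
        B, _ = constraint_matrix(layout)
        su2, se2 = 0.7, 0.9
        ga = gaussian_approximation(layout, obs, {"sigma_u2": su2, "sigma_e2": se2})
        A = relationship_matrix(trio)
        Z = np.asarray(layout.Z.todense())
        Sig = np.zeros((4, 4))
        Sig[0, 0] = 4.0
        Sig[1:, 1:] = su2 * A
        BS = B @ Sig
        Sigc = Sig - BS.T @ np.linalg.solve(B @ Sig @ B.T, BS)
        K = Sigc @ Z.T @ np.linalg.inv(Z @ Sigc @ Z.T + se2 * np.eye(3))
        np.testing.assert_allclose(ga.x_star, K @ y, atol=1e-10)
        np.testing.assert_allclose(
            ga.marginal_variances(np.arange(4)), np.diag(Sigc - K @ Z @ Sigc), atol=1e-10
        )
        assert abs(ga.x_star[1:].sum()) < 1e-10


class TestLogEvidence:
    def _conjugate_setup(self):
        ped, ids = _founders(5)
        rng = np.random.default_rng(1)
        y = rng.normal(0.3, 1.0, 5)
        spec = AnimalModelSpec(family="gaussian", include_breeding_values=False, beta_variance=2.0)
        obs = ObservationSet(ids=ids, y=y)
        layout = build_layout(spec, ped, obs)

        def analytic(se2):
            cov = 2.0 * np.ones((5, 5)) + se2 * np.eye(5)
            prior = spec.priors["sigma_e2"].log_density_internal(np.log(se2))
            return multivariate_normal.logpdf(y, np.zeros(5), cov) + prior

        return layout, obs, analytic

    def test_matches_conjugate_marginal_likelihood(self):
        layout, obs, analytic = self._conjugate_setup()
        offsets = []
        for se2 in (0.25, 0.5, 1.0, 2.0, 4.0):
            val, _ = log_evidence(layout, obs, {"sigma_e2": se2})
            offsets.append(val - analytic(se2))
        offsets = np.asarray(offsets)
        np.testing.assert_allclose(offsets - offsets[0], 0.0, atol=1e-8)

    def test_translation_invariance_of_theta_posterior(self):
        """A diffuse intercept absorbs a constant shift of all responses."""
        ped, ids = _founders(5)
        rng = np.random.default_rng(1)
        y = rng.normal(0.3, 1.0, 5)
        spec = AnimalModelSpec(family="gaussian", include_breeding_values=False)
        grid = (0.25, 1.0, 4.0)
        weights = []
        for shift in (0.0, 7.5):
            obs = ObservationSet(ids=ids, y=y + shift)
            layout = build_layout(spec, ped, obs)
            lev = np.array([log_evidence(layout, obs, {"sigma_e2": s})[0] for s in grid])
            w = np.exp(lev - lev.max())
            weights.append(w / w.sum())
        np.testing.assert_allclose(weights[0], weights[1], atol=1e-6)

    def test_binomial_toy_matches_brute_force_quadrature(self):
        """Laplace evidence vs direct quadrature of the latent integral."""
        ped, ids = _founders(10)
        rng = np.random.default_rng(3)
        n = np.full(10, 30.0)
        y = rng.binomial(30, 0.45, 10).astype(float)
        spec = AnimalModelSpec(family="binomial", include_breeding_values=False, beta_variance=1.5)
        obs = ObservationSet(ids=ids, y=y, n_trials=n)
        layout = build_layout(spec, ped, obs)
        val, _ = log_evidence(layout, obs, {})

        g = np.linspace(-5, 5, 801)
        v, _, _ = loglik("binomial", y[None, :], np.repeat(g[:, None], 10, axis=1), n_trials=n)
        ll = v.sum(axis=1) - 0.5 * g**2 / 1.5 - 0.5 * np.log(2 * np.pi * 1.5)
        mx = ll.max()
        oracle = mx + np.log(np.trapezoid(np.exp(ll - mx), g))
        assert val == pytest.approx(oracle, abs=1e-3)


class TestHyperExploration:
    def test_weights_sum_to_one(self, trio):
        spec = AnimalModelSpec(family="gaussian")
        obs = ObservationSet(ids=["1", "2", "3"], y=[0.4, -0.1, 0.9])
        layout = build_layout(spec, trio, obs)
        points, _ = explore_hyperparameters(layout, obs)
        assert sum(p.weight for p in points) == pytest.approx(1.0)

    def test_grid_mean_matches_conjugate_posterior(self):
        """Pinned-mean Gaussian model: log sigma_e2 grid mean vs closed form."""
        m = 12
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1.0, m)
        ped, ids = _founders(m)
        spec = AnimalModelSpec(family="gaussian", include_breeding_values=False, beta_variance=1e-12)
        obs = ObservationSet(ids=ids, y=y)
        layout = build_layout(spec, ped, obs)
        points, _ = explore_hyperparameters(layout, obs, delta=0.15, drop_threshold=8.0)
        w = np.array([p.weight for p in points])
        th = np.array([p.internal[0] for p in points])
        a = 0.5 + m / 2
        b = 0.5 + 0.5 * np.sum(y**2)
        assert (w * th).sum() == pytest.approx(np.log(b) - digamma(a), abs=1e-3)

        marg = hyper_marginal(layout, points, "sigma_e2")
        assert np.trapezoid(marg.density, marg.grid) == pytest.approx(1.0, abs=1e-6)
        assert marg.mean == pytest.approx(b / (a - 1), rel=0.01)
        assert marg.quantiles[0.025] < marg.quantiles[0.5] < marg.quantiles[0.975]

    def test_fixed_theta_is_plug_in(self, trio):
        spec = AnimalModelSpec(family="gaussian")
        obs = ObservationSet(ids=["1", "2", "3"], y=[0.4, -0.1, 0.9])
        layout = build_layout(spec, trio, obs)
        points, approxes = explore_hyperparameters(
            layout, obs, fixed_theta={"sigma_u2": 0.4, "sigma_e2": 0.6}
        )
        assert len(points) == 1
        assert points[0].weight == 1.0
        assert points[0].theta["sigma_u2"] == pytest.approx(0.4)

    def test_zero_hyper_model(self):
        ped, ids = _founders(4)
        spec = AnimalModelSpec(family="binomial", include_breeding_values=False)
        obs = ObservationSet(ids=ids, y=[1, 0, 2, 1], n_trials=[2, 2, 2, 2])
        layout = build_layout(spec, ped, obs)
        points, approxes = explore_hyperparameters(layout, obs)
        assert len(points) == 1 and points[0].weight == 1.0


class TestLatentMarginalsAndLincombs:
    def _fitted_trio(self, trio):
        spec = AnimalModelSpec(family="gaussian")
        obs = ObservationSet(ids=["1", "2", "3"], y=[0.4, -0.1, 0.9])
        layout = build_layout(spec, trio, obs)
        points, approxes = explore_hyperparameters(layout, obs)
        return layout, points, approxes

    def test_constrained_u_means_sum_to_zero(self, trio):
        layout, points, approxes = self._fitted_trio(trio)
        sl = layout.block_slice("u")
        margs = latent_marginals(points, approxes, np.arange(sl.start, sl.stop))
        assert abs(sum(m.mean for m in margs)) < 1e-6

    def test_indicator_lincomb_equals_latent_marginal(self, trio):
        layout, points, approxes = self._fitted_trio(trio)
        idx = layout.u_index("3")
        w = np.zeros(layout.dim)
        w[idx] = 1.0
        lc = lincomb_posterior(points, approxes, w)
        lm = latent_marginals(points, approxes, [idx])[0]
        assert lc.mean == pytest.approx(lm.mean, abs=1e-10)
        assert lc.sd == pytest.approx(lm.sd, abs=1e-10)

    def test_sum_over_constrained_u_is_point_mass_at_zero(self, trio):
        layout, points, approxes = self._fitted_trio(trio)
        w = np.zeros(layout.dim)
        w[layout.block_slice("u")] = 1.0
        lc = lincomb_posterior(points, approxes, w)
        assert abs(lc.mean) < 1e-8
        assert lc.sd < 1e-6

    def test_empty_lincomb_rejected(self, trio):
        layout, points, approxes = self._fitted_trio(trio)
        with pytest.raises(InferenceError, match="empty"):
            lincomb_posterior(points, approxes, np.zeros(layout.dim))

    def test_gaussian_latent_marginal_matches_conjugate(self):
        """At fixed theta the mixture collapses to the exact posterior."""
        ped, ids = _founders(3)
        spec = AnimalModelSpec(family="gaussian", include_breeding_values=False, beta_variance=1.0)
        obs = ObservationSet(ids=ids, y=[0.8, 1.1, 0.5])
        layout = build_layout(spec, ped, obs)
        points, approxes = explore_hyperparameters(layout, obs, fixed_theta={"sigma_e2": 0.5})
        marg = latent_marginals(points, approxes, [0])[0]
        # beta0 | y ~ N(sum(y)/(m + se2/sb2) ... conjugate with prior N(0,1)
        prec = 1.0 / 1.0 + 3 / 0.5
        mean = (np.sum([0.8, 1.1, 0.5]) / 0.5) / prec
        assert marg.mean == pytest.approx(mean, abs=1e-8)
        assert marg.sd == pytest.approx(np.sqrt(1 / prec), abs=1e-8)


class TestDIC:
    def test_intercept_only_effective_parameters_near_one(self):
        ped, ids = _founders(20)
        rng = np.random.default_rng(3)
        obs = ObservationSet(ids=ids, y=rng.normal(2.0, 1.0, 20))
        spec = AnimalModelSpec(family="gaussian", include_breeding_values=False)
        layout = build_layout(spec, ped, obs)
        B, e = constraint_matrix(layout)
        points, approxes = explore_hyperparameters(layout, obs, B, e, fixed_theta={"sigma_e2": 1.0})
        res = dic(layout, obs, points, approxes, B, e)
        assert res.p_d == pytest.approx(1.0, abs=0.05)

    def test_true_model_beats_no_genetics_model(self):
        from animalgmrf.simulate import SimulationConfig, simulate_dataset, synthetic_pedigree

        ped = synthetic_pedigree(n_founders=60, n_generations=6, seed=21)
        cfg = SimulationConfig(family="gaussian", sigma_u2=0.4, sigma_e2=0.6, seed=4)
        obs, _ = simulate_dataset(cfg, ped)
        dics = {}
        for with_u in (True, False):
            spec = AnimalModelSpec(family="gaussian", include_breeding_values=with_u)
            fit = fit_model(spec, ped, obs, FitSettings(latent_sds="none"))
            dics[with_u] = fit.dic.dic
        assert dics[True] < dics[False]

    def test_empty_observations_rejected(self, trio):
        spec = AnimalModelSpec(family="gaussian")
        obs = ObservationSet(ids=[], y=[])
        layout = build_layout(spec, trio, obs)
        B, e = constraint_matrix(layout)
        with pytest.raises(InferenceError, match="without observations"):
            dic(layout, obs, [], [], B, e)


class TestFitModel:
    def test_binary_data_triggers_warning(self):
        ped, ids = _founders(12)
        rng = np.random.default_rng(5)
        obs = ObservationSet(ids=ids, y=rng.integers(0, 2, 12).astype(float), n_trials=np.ones(12))
        spec = AnimalModelSpec(family="binomial")
        with pytest.warns(UserWarning, match="binary"):
            fit_model(spec, ped, obs, FitSettings(compute_dic=False, latent_sds="none"))

    def test_fit_result_summaries(self, trio):
        spec = AnimalModelSpec(family="gaussian")
        obs = ObservationSet(ids=["1", "2", "3"], y=[0.4, -0.1, 0.9])
        fit = fit_model(spec, trio, obs)
        assert set(fit.hyper_marginals) == {"sigma_u2", "sigma_e2"}
        assert np.isfinite(fit.dic.dic)
        assert abs(fit.posterior_mean_u().sum()) < 1e-8
        frame = fit.fixed_effects_frame()
        assert list(frame["term"]) == ["(intercept)"]
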