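"""Sum-product inference against the enumeration oracle, and EM learning."""

import numpy as np
import pytest

from conftest import random_params, random_submodel
from xshadow.errors import EnumerationSizeError, XshadowError
from xshadow.inference import em_fit, enumerate_posteriors, infer_posteriors
from xshadow.model import GeneSubmodel, ModelParameters
from xshadow.simulate import SimulationHyperparams, simulate_dataset, submodels_with_true_emissions


def _flat_emission_submodel(rng, M=3, N=2):
    """Every G state equally likely at every observed y."""
    sub = random_submodel(rng, max_m=M, max_n=N, allow_missing=False)
    sub.log_emission = np.zeros((sub.M, sub.N, 3))
    return sub


class TestInferPosteriors:
    def test_d_separation_when_f_cpds_coincide(self, rng):
        sub = random_submodel(rng)
        params = ModelParameters(theta_d=0.37, theta_f_d0=0.4, theta_f_d1=0.4)
        post = infer_posteriors(sub, params)
        assert post.p_d == pytest.approx(0.37, abs=1e-12)

    def test_flat_emissions_propagate_the_prior(self, rng):
        sub = _flat_emission_submodel(rng)
        params = random_params(rng)
        post = infer_posteriors(sub, params)
        expected = params.theta_d * params.theta_f_d1 + (1 - params.theta_d) * params.theta_f_d0
        np.testing.assert_allclose(post.p_f, expected, atol=1e-12)

    def test_matches_enumeration_on_100_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            sub = random_submodel(rng)
            params = random_params(rng)
            bp = infer_posteriors(sub, params)
            oracle = enumerate_posteriors(sub, params)
            assert abs(bp.p_d - oracle.p_d) < 1e-8
            np.testing.assert_allclose(bp.p_f, oracle.p_f, atol=1e-8)
            np.testing.assert_allclose(bp.p_g, oracle.p_g, atol=1e-8)
            assert bp.log_marginal == pytest.approx(oracle.log_marginal, abs=1e-8)

    def test_probabilities_are_normalised(self, rng):
        for _ in range(25):
            sub = random_submodel(rng)
            post = infer_posteriors(sub, random_params(rng))
            assert 0.0 <= post.p_d <= 1.0
            assert np.all((post.p_f >= 0) & (post.p_f <= 1))
            np.testing.assert_allclose(post.p_g.sum(axis=2), 1.0, atol=1e-9)

    def test_hand_computed_single_leaf_p_f(self):
        # one patient, one neighbour, H=up, w=1: P(F|y) from a 2x3 table by hand
        phi = np.array([0.1, 0.6, 0.3])  # emission densities at the observed y
        params = ModelParameters(
            theta_d=0.5,
            theta_f_d0=0.2,
            theta_f_d1=0.8,
            theta_g_f0=np.array([0.1, 0.8, 0.1]),
            theta_g_f1_up=np.array([0.05, 0.45, 0.5]),
        )
        lik_f0 = float(params.theta_g_f0 @ phi)
        lik_f1 = float(params.theta_g_f1_up @ phi)
        num = 0.0
        den = 0.0
        for d, pd in ((0, 0.5), (1, 0.5)):
            pf1 = params.theta_f_d1 if d else params.theta_f_d0
            num += pd * pf1 * lik_f1
            den += pd * (pf1 * lik_f1 + (1 - pf1) * lik_f0)
        expected = num / den
        sub = GeneSubmodel(
            gene="g",
            patients=["p"],
            neighbours=["n"],
            weights=np.array([1.0]),
            y=np.array([[0.0]]),
            log_emission=np.log(phi)[None, None, :],
            offline_posterior=np.full((1, 1, 3), 1 / 3),
            h=np.array([1]),
        )
        assert infer_posteriors(sub, params).p_f[0] == pytest.approx(expected, abs=1e-12)
        assert enumerate_posteriors(sub, params).p_f[0] == pytest.approx(expected, abs=1e-12)

    def test_dominant_emission_pins_the_regulation_state(self, rng):
        sub = random_submodel(rng, max_m=2, max_n=2, allow_missing=False)
        sub.log_emission = np.full((sub.M, sub.N, 3), -40.0)
        sub.log_emission[..., 2] = 0.0  # 'up' density overwhelms the others
        post = enumerate_posteriors(sub, random_params(rng))
        assert np.all(post.p_g[..., 2] > 0.999)

    def test_enumeration_guard(self, rng):
        sub = random_submodel(rng, max_m=3, max_n=3, allow_missing=False)
        big = GeneSubmodel(
            gene="g",
            patients=[f"p{i}" for i in range(5)],
            neighbours=[f"n{j}" for j in range(5)],
            weights=np.ones(5),
            y=np.zeros((5, 5)),
            log_emission=np.zeros((5, 5, 3)),
            offline_posterior=np.full((5, 5, 3), 1 / 3),
            h=np.ones(5, dtype=int),
        )
        with pytest.raises(EnumerationSizeError):
            enumerate_posteriors(big, ModelParameters())


def _simulated_submodels(seed, n_genes=20, m=8, n=4, delta=2.5):
    hyper = SimulationHyperparams(
        n_genes=n_genes,
        m_patients=m,
        n_neighbours=n,
        delta=delta,
        cohort_size=max(4 * m, 40),
        rng_seed=seed,
    )
    _, expr, _, truth = simulate_dataset(hyper)
    return submodels_with_true_emissions(expr, truth, hyper), truth, hyper


class TestEMFit:
    def test_objective_is_monotone_on_random_datasets(self):
        # the MAP objective (loglik + smoothing prior) is the quantity EM
        # ascends; the raw loglik must track it closely
        for seed in range(20):
            subs, _, _ = _simulated_submodels(seed, n_genes=8, m=5, n=3)
            trace = em_fit(subs, max_iter=25)
            assert np.all(np.diff(trace.objective) >= -1e-8)
            assert np.all(np.diff(trace.loglik) >= -0.05)

    def test_recovers_mutation_impact_rate(self):
        hyper = SimulationHyperparams(n_genes=200, delta=3.0, rng_seed=11)
        _, expr, _, truth = simulate_dataset(hyper)
        subs = submodels_with_true_emissions(expr, truth, hyper)
        trace = em_fit(subs)
        assert trace.params.theta_f_d1 == pytest.approx(hyper.theta.theta_f_d1, abs=0.05)
        assert trace.params.theta_f_d0 == pytest.approx(hyper.theta.theta_f_d0, abs=0.05)

    def test_single_iteration_from_truth_tracks_empirical_rates(self):
        # one E/M sweep started at the generative parameters should land on
        # the dataset's own empirical rates (MLE consistency)
        hyper = SimulationHyperparams(n_genes=200, delta=3.0, rng_seed=13)
        _, expr, _, truth = simulate_dataset(hyper)
        subs = submodels_with_true_emissions(expr, truth, hyper)
        trace = em_fit(subs, init=hyper.theta, max_iter=1)
        fitted = trace.params
        f_all = np.stack([truth.f[g] for g in truth.genes])
        emp_d = truth.d.mean()
        emp_f1 = f_all[truth.d == 1].mean()
        emp_f0 = f_all[truth.d == 0].mean()
        assert abs(fitted.theta_d - emp_d) < 0.02
        assert abs(fitted.theta_f_d1 - emp_f1) < 0.02
        assert abs(fitted.theta_f_d0 - emp_f0) < 0.02
        np.testing.assert_allclose(fitted.theta_g_f1_up, hyper.theta.theta_g_f1_up, atol=0.03)

    def test_submodel_order_does_not_matter(self):
        subs, _, _ = _simulated_submodels(3, n_genes=12, m=6, n=3)
        a = em_fit(subs, max_iter=10).params
        b = em_fit(subs[::-1], max_iter=10).params
        assert a.theta_d == pytest.approx(b.theta_d, abs=1e-10)
        assert a.theta_f_d1 == pytest.approx(b.theta_f_d1, abs=1e-10)
        np.testing.assert_allclose(a.theta_g_f1_up, b.theta_g_f1_up, atol=1e-10)

    def test_posterior_calibration_in_the_top_bin(self):
        hyper = SimulationHyperparams(n_genes=100, delta=2.0, rng_seed=17)
        _, expr, _, truth = simulate_dataset(hyper)
        subs = submodels_with_true_emissions(expr, truth, hyper)
        trace = em_fit(subs)
        pf, true_f = [], []
        for sub in subs:
            post = infer_posteriors(sub, trace.params)
            pf.append(post.p_f)
            true_f.append(truth.f[sub.gene])
        pf = np.concatenate(pf)
        true_f = np.concatenate(true_f)
        assert pf.size >= 2000
        top = (pf >= 0.8) & (pf <= 1.0)
        assert top.sum() > 50
        assert true_f[top].mean() >= 0.7

    def test_empty_collection_rejected(self):
        with pytest.raises(XshadowError):
            em_fit([])

    def test_single_mutation_genes_are_excluded_from_fitting(self):
        subs, _, _ = _simulated_submodels(9, n_genes=6, m=3, n=2)
        lone = GeneSubmodel(
            gene="solo",
            patients=["p"],
            neighbours=["n"],
            weights=np.array([1.0]),
            y=np.array([[0.0]]),
            log_emission=np.zeros((1, 1, 3)),
            offline_posterior=np.full((1, 1, 3), 1 / 3),
            h=np.array([1]),
        )
        trace = em_fit(subs + [lone], max_iter=5)
        assert "solo" not in trace.scored_genes
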