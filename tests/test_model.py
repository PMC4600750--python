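"""Model structure: parameters, weighted leaf CPDs, joint, H estimation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_params, random_submodel
from xshadow.model import (
    H_DOWN,
    H_UP,
    GeneSubmodel,
    ModelParameters,
    effective_g_cpd,
    estimate_h,
    joint_log_prob,
)
from xshadow.simulate import SimulationHyperparams, simulate_dataset, submodels_with_true_emissions


class TestParameters:
    def test_identifiability_constraint_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(theta_f_d0=0.8, theta_f_d1=0.2)

    def test_simplex_validation(self):
        with pytest.raises(ValueError):
            ModelParameters(theta_g_f0=np.array([0.5, 0.4, 0.2]))

    def test_tsv_round_trip(self, tmp_path, rng):
        p = random_params(rng)
        path = tmp_path / "params.tsv"
        p.write_tsv(path)
        q = ModelParameters.read_tsv(path)
        assert q.theta_d == pytest.approx(p.theta_d, abs=1e-15)
        np.testing.assert_allclose(q.theta_g_f1_up, p.theta_g_f1_up, atol=1e-15)


class TestEffectiveGCpd:
    def test_full_weight_returns_dysregulated_table(self):
        p = ModelParameters()
        _, f1 = effective_g_cpd(p, 1.0, H_UP)
        np.testing.assert_allclose(f1, p.theta_g_f1_up)

    def test_zero_weight_neutralises_the_neighbour(self):
        p = ModelParameters()
        _, f1 = effective_g_cpd(p, 0.0, H_UP)
        np.testing.assert_allclose(f1, p.theta_g_f0)

    def test_hand_computed_half_weight(self):
        p = ModelParameters(
            theta_g_f0=np.array([0.05, 0.9, 0.05]),
            theta_g_f1_up=np.array([0.05, 0.45, 0.5]),
        )
        _, f1 = effective_g_cpd(p, 0.5, H_UP)
        np.testing.assert_allclose(f1, [0.05, 0.675, 0.275], atol=1e-15)

    def test_outputs_are_simplexes_over_weight_grid(self, rng):
        p = random_params(rng)
        for w in np.linspace(0.0, 1.0, 101):
            for h in (H_DOWN, H_UP):
                f0, f1 = effective_g_cpd(p, w, h)
                for table in (f0, f1):
                    assert abs(table.sum() - 1.0) < 1e-12
                    assert np.all(table >= 0)

    def test_weight_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            effective_g_cpd(ModelParameters(), 1.5, H_UP)


class TestJointLogProb:
    def test_near_deterministic_cpds_leave_only_emissions(self, rng):
        eps = 1e-12
        sub = random_submodel(rng, allow_missing=False)
        params = ModelParameters(
            theta_d=1 - eps,
            theta_f_d0=eps,
            theta_f_d1=1 - eps,
            theta_g_f0=np.array([eps, 1 - 2 * eps, eps]),
            theta_g_f1_up=np.array([eps, eps, 1 - 2 * eps]),
            theta_g_f1_down=np.array([1 - 2 * eps, eps, eps]),
        )
        sub.weights = np.ones(sub.N)
        f = np.ones(sub.M, dtype=int)
        g = np.where(sub.h[None, :] == H_UP, 2, 0) * np.ones((sub.M, 1), dtype=int)
        expected = sum(
            sub.log_emission[m, n, g[m, n]] for m in range(sub.M) for n in range(sub.N)
        )
        assert joint_log_prob(sub, params, 1, f, g) == pytest.approx(expected, abs=1e-6)

    def test_exp_joint_sums_to_marginal_likelihood(self, rng):
        from xshadow.inference import enumerate_posteriors

        sub = random_submodel(rng, max_m=2, max_n=2, allow_missing=False)
        params = random_params(rng)
        logps = []
        for d in (0, 1):
            for f in itertools.product((0, 1), repeat=sub.M):
                for g_flat in itertools.product((0, 1, 2), repeat=sub.M * sub.N):
                    g = np.array(g_flat).reshape(sub.M, sub.N)
                    logps.append(joint_log_prob(sub, params, d, np.array(f), g))
        total = np.logaddexp.reduce(logps)
        oracle = enumerate_posteriors(sub, params)
        assert total == pytest.approx(oracle.log_marginal, abs=1e-10)

    def test_joint_is_nonpositive_for_subunit_emission_densities(self, rng):
        sub = random_submodel(rng, allow_missing=False)
        sub.log_emission = -np.abs(sub.log_emission)  # densities <= 1
        params = random_params(rng)
        f = np.zeros(sub.M, dtype=int)
        g = np.ones((sub.M, sub.N), dtype=int)
        assert joint_log_prob(sub, params, 0, f, g) <= 0.0

    def test_invalid_state_codes_rejected(self, rng):
        sub = random_submodel(rng)
        with pytest.raises(ValueError):
            joint_log_prob(
                sub,
                ModelParameters(),
                0,
                np.zeros(sub.M, dtype=int),
                np.full((sub.M, sub.N), 5),
            )

    def test_additive_over_independent_patients(self, rng):
        sub = random_submodel(rng, max_m=1, max_n=2, allow_missing=False)
        params = random_params(rng)
        # duplicate the single patient: joint given fixed d splits into a
        # shared prior term plus per-patient contributions
        double = GeneSubmodel(
            gene=sub.gene,
            patients=["p0", "p1"],
            neighbours=sub.neighbours,
            weights=sub.weights,
            y=np.vstack([sub.y, sub.y]),
            log_emission=np.concatenate([sub.log_emission] * 2, axis=0),
            offline_posterior=np.concatenate([sub.offline_posterior] * 2, axis=0),
            h=sub.h,
        )
        f = np.array([1])
        g = np.full((1, sub.N), 2)
        single = joint_log_prob(sub, params, 1, f, g)
        both = joint_log_prob(double, params, 1, np.array([1, 1]), np.vstack([g, g]))
        prior = np.log(params.theta_d)
        assert both - prior == pytest.approx(2 * (single - prior), rel=1e-10)


class TestEstimateH:
    def _sub_with_offline(self, offline):
        M, N = offline.shape[:2]
        return GeneSubmodel(
            gene="g",
            patients=[f"p{i}" for i in range(M)],
            neighbours=[f"n{j}" for j in range(N)],
            weights=np.ones(N),
            y=np.zeros((M, N)),
            log_emission=np.zeros((M, N, 3)),
            offline_posterior=offline,
        )

    def test_dominant_up_responsibilities_give_up(self):
        off = np.tile([0.05, 0.05, 0.9], (4, 1, 1))
        assert estimate_h(self._sub_with_offline(off))[0] == H_UP

    def test_exact_tie_breaks_to_up(self):
        off = np.tile([0.3, 0.4, 0.3], (4, 1, 1))
        assert estimate_h(self._sub_with_offline(off))[0] == H_UP

    def test_recovers_directions_in_strong_simulation(self):
        hyper = SimulationHyperparams(
            n_genes=10, m_patients=30, n_neighbours=10, delta=3.0, fraction_d1=1.0, rng_seed=5
        )
        _, expr, _, truth = simulate_dataset(hyper)
        subs = submodels_with_true_emissions(expr, truth, hyper, fix_h=False)
        correct = total = 0
        for sub in subs:
            correct += int(np.sum(sub.h == truth.h[sub.gene]))
            total += sub.N
        assert correct / total >= 0.9
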