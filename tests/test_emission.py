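"""Student's-t emission mixtures: density, fitting, responsibilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from xshadow.emission import (
    TMixture,
    _em_t_mixture,
    fit_t_mixture,
    fit_t_mixtures,
    posterior_G,
    t_log_density,
)
from xshadow.errors import DegenerateDataError


class TestTLogDensity:
    def test_large_df_limit_matches_gaussian_at_centre(self):
        assert t_log_density(0.0, 0.0, 1.0, 1e6) == pytest.approx(
            stats.norm.logpdf(0.0), abs=1e-4
        )

    def test_gaussian_limit_over_wide_range(self):
        y = np.linspace(-10, 10, 201)
        # absolute agreement near the bulk, relative agreement in the far
        # tails where the residual t-vs-normal gap scales like z^4 / (4 nu)
        np.testing.assert_allclose(
            t_log_density(y, 1.0, 2.0, 1e6),
            stats.norm.logpdf(y, 1.0, 2.0),
            atol=1e-4,
            rtol=1e-4,
        )

    def test_symmetry_about_location(self, rng):
        delta = rng.uniform(0.1, 5.0, size=20)
        loc, scale, df = 0.7, 1.3, 4.0
        np.testing.assert_allclose(
            t_log_density(loc + delta, loc, scale, df),
            t_log_density(loc - delta, loc, scale, df),
            rtol=1e-12,
        )

    def test_density_is_normalised_and_matches_reference(self):
        total, _ = integrate.quad(lambda y: np.exp(t_log_density(y, 0.0, 1.0, 3.0)), -np.inf, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)
        # independent oracle: scipy's own Student's t
        assert t_log_density(2.0, 0.0, 1.0, 3.0) == pytest.approx(
            stats.t.logpdf(2.0, 3.0), rel=1e-12
        )

    def test_invalid_scale_and_df_rejected(self):
        with pytest.raises(ValueError):
            t_log_density(0.0, 0.0, -1.0, 3.0)
        with pytest.raises(ValueError):
            t_log_density(0.0, 0.0, 1.0, 0.0)


class TestFit:
    def test_single_gaussian_is_dominated_by_the_neutral_component(self):
        passed = 0
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=1000)
            if fit_t_mixture(x).weights[1] >= 0.9:
                passed += 1
        assert passed >= 3

    def test_recovers_well_separated_components(self):
        rng = np.random.default_rng(0)
        comp = rng.choice(3, p=[0.2, 0.6, 0.2], size=5000)
        x = np.array([-3.0, 0.0, 3.0])[comp] + rng.standard_t(5, size=5000)
        mix = fit_t_mixture(x)
        np.testing.assert_allclose(mix.locations, [-3.0, 0.0, 3.0], atol=0.2)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_t_mixture(np.full(100, 3.5))

    def test_small_samples_fall_back_to_neutral(self):
        with pytest.warns(UserWarning, match="single neutral"):
            mix = fit_t_mixture(np.random.default_rng(0).normal(size=10))
        np.testing.assert_allclose(mix.weights, [0.0, 1.0, 0.0])

    def test_loglik_trace_is_monotone(self, rng):
        for _ in range(3):
            x = rng.normal(size=300) + np.where(rng.random(300) < 0.2, 4.0, 0.0)
            mix = fit_t_mixture(x)
            assert np.all(np.diff(mix.loglik_trace) >= -1e-8)

    def test_fit_is_stable_to_initialisation_details(self):
        # perturbed starting points land on the same ordered mixture
        rng = np.random.default_rng(3)
        comp = rng.choice(3, p=[0.25, 0.5, 0.25], size=2000)
        x = np.array([-4.0, 0.0, 4.0])[comp] + rng.normal(size=2000)
        w = np.array([0.15, 0.7, 0.15])
        sig = np.ones(3)
        nu = np.full(3, 10.0)
        a = _em_t_mixture(x, w, np.array([-3.0, 0.2, 3.0]), sig.copy(), nu.copy(), 500, 1e-9)
        b = _em_t_mixture(x, w[::-1].copy(), np.array([-2.5, -0.1, 2.8]), sig, nu, 500, 1e-9)
        np.testing.assert_allclose(a.locations, b.locations, atol=1e-4)
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-4)

    def test_batched_fit_agrees_with_scalar_fit(self):
        rng = np.random.default_rng(1)
        comp = rng.choice(3, p=[0.15, 0.7, 0.15], size=400)
        signal = np.array([-4.0, 0.0, 4.0])[comp] + rng.normal(size=400)
        noise = rng.normal(size=400)
        mats = np.column_stack([signal, noise])
        batch = fit_t_mixtures(mats)
        scalar = [fit_t_mixture(mats[:, j]) for j in range(2)]
        assert batch[0].collapsed == scalar[0].collapsed is False
        assert batch[1].collapsed == scalar[1].collapsed is True
        # nu comes from a grid in the batched route, so locations can wobble
        np.testing.assert_allclose(batch[0].locations, scalar[0].locations, atol=0.2)


class TestPosteriorG:
    def _mix(self):
        return TMixture(
            weights=np.array([0.25, 0.5, 0.25]),
            locations=np.array([-5.0, 0.0, 5.0]),
            scales=np.ones(3),
            dfs=np.full(3, 100.0),
        )

    def test_centre_point_is_neutral(self):
        assert np.argmax(posterior_G(self._mix(), 0.0)) == 1

    def test_far_tail_is_upregulated(self):
        mix = self._mix()
        y = mix.locations[2] + 20 * mix.scales[2]
        assert posterior_G(mix, y)[2] > 0.999

    def test_matches_brute_force_weighted_densities(self, rng):
        for _ in range(20):
            w = rng.dirichlet(np.ones(3))
            mix = TMixture(
                weights=w,
                locations=np.sort(rng.normal(scale=3, size=3)),
                scales=rng.uniform(0.5, 2.0, size=3),
                dfs=rng.uniform(2.5, 50.0, size=3),
            )
            y = float(rng.normal(scale=4))
            dens = w * np.exp([t_log_density(y, mix.locations[k], mix.scales[k], mix.dfs[k]) for k in range(3)])
            np.testing.assert_allclose(posterior_G(mix, y), dens / dens.sum(), rtol=1e-10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        y=st.floats(-50, 50),
        seed=st.integers(0, 10_000),
    )
    def test_responsibilities_sum_to_one(self, y, seed):
        rng = np.random.default_rng(seed)
        mix = TMixture(
            weights=rng.dirichlet(np.ones(3)),
            locations=np.sort(rng.normal(scale=3, size=3)),
            scales=rng.uniform(0.1, 3.0, size=3),
            dfs=rng.uniform(2.0, 100.0, size=3),
        )
        assert abs(posterior_G(mix, y).sum() - 1.0) < 1e-12


class TestTMixtureInvariants:
    def test_weight_simplex_enforced(self):
        with pytest.raises(ValueError):
            TMixture(np.array([0.5, 0.4, 0.2]), np.zeros(3), np.ones(3), np.full(3, 5.0))

    def test_location_ordering_enforced(self):
        with pytest.raises(ValueError):
            TMixture(
                np.array([0.2, 0.6, 0.2]), np.array([1.0, 0.0, 2.0]), np.ones(3), np.full(3, 5.0)
            )
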