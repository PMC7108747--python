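"""Bernoulli mixture EM: initialization, densities, EM steps, assignment."""

import math

import numpy as np
import pytest

from conftest import brute_force_mixture
from pangem.bmm import (
    EPS_CEIL,
    EPS_FLOOR,
    BernoulliMixturePartitioner,
    BMMParams,
    e_step,
    family_log_density,
    m_step,
    run_binem,
    triangular_init,
)
from pangem.partition import CLOUD, PERSISTENT, SHELL, assign_partitions
from pangem.synthetic import generate_pa, three_pattern_params


class TestTriangularInit:
    def test_k3_centroids_and_dispersion(self):
        p = triangular_init(3, 4)
        assert p.pi.tolist() == [1 / 3] * 3
        assert p.mu.tolist() == [[1] * 4, [0] * 4, [0] * 4]
        # s = 1/2; dispersion ramp (0.25, 0.5, 0.25) with the strict ceiling
        assert p.epsilon[0, 0] == pytest.approx(0.25)
        assert p.epsilon[1, 0] == pytest.approx(EPS_CEIL)
        assert p.epsilon[2, 0] == pytest.approx(0.25)

    def test_k4_symmetric_shape(self):
        p = triangular_init(4, 3)
        assert p.mu[:, 0].tolist() == [1, 1, 0, 0]
        assert np.allclose(p.epsilon[0], p.epsilon[3])
        assert np.allclose(p.epsilon[1], p.epsilon[2])
        assert (p.epsilon[1] >= p.epsilon[0]).all()

    @pytest.mark.parametrize("K", range(2, 21))
    def test_dispersion_always_in_valid_range(self, K):
        p = triangular_init(K, 5)
        assert (p.epsilon > 0).all() and (p.epsilon <= 0.5).all()

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            triangular_init(1, 3)


class TestLogDensity:
    def _params(self, mu, eps):
        mu = np.atleast_2d(mu)
        eps = np.atleast_2d(eps)
        pi = np.full(mu.shape[0], 1.0 / mu.shape[0])
        return BMMParams(pi, mu, eps)

    def test_single_match(self):
        p = self._params([[1]], [[0.25]])
        assert family_log_density([1], 0, p) == pytest.approx(math.log(0.75))

    def test_single_mismatch(self):
        p = self._params([[1]], [[0.25]])
        assert family_log_density([0], 0, p) == pytest.approx(math.log(0.25))

    def test_product_over_genomes(self):
        p = self._params([[1, 0]], [[0.1, 0.2]])
        assert family_log_density([1, 0], 0, p) == pytest.approx(math.log(0.9 * 0.8))


class TestEStep:
    def test_identical_components_give_uniform_posteriors(self):
        p = BMMParams([0.5, 0.5], [[1, 0], [1, 0]], [[0.2, 0.2], [0.2, 0.2]])
        T, _ = e_step(np.array([[1, 1], [0, 0], [1, 0]]), p)
        assert np.allclose(T, 0.5)

    def test_degenerate_mixture_concentrates(self):
        p = BMMParams([1.0, 0.0], [[1, 1], [0, 0]], [[0.1, 0.1], [0.1, 0.1]])
        T, _ = e_step(np.array([[0, 0]]), p)
        assert T[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("K", [2, 3])
    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, K, trial, rng):
        """Posteriors and log-likelihood equal a term-by-term evaluation
        of the mixture density on small random instances."""
        F, N = int(rng.integers(2, 9)), int(rng.integers(1, 5))
        X = rng.integers(0, 2, size=(F, N))
        pi = rng.dirichlet(np.ones(K))
        mu = rng.integers(0, 2, size=(K, N))
        eps = rng.uniform(0.05, 0.45, size=(K, N))
        params = BMMParams(pi, mu, eps)
        T, ll = e_step(X, params)
        T_ref, ll_ref = brute_force_mixture(X.tolist(), pi.tolist(), mu.tolist(), eps.tolist())
        np.testing.assert_allclose(T, T_ref, atol=1e-12)
        assert ll == pytest.approx(ll_ref, rel=1e-12)

    def test_exhaustive_tiny_instances(self):
        """Every binary 2×2 matrix agrees with the oracle exactly."""
        pi = [0.6, 0.4]
        mu = [[1, 0], [0, 1]]
        eps = [[0.1, 0.3], [0.2, 0.25]]
        params = BMMParams(pi, mu, eps)
        rows = [(a, b) for a in (0, 1) for b in (0, 1)]
        for r1 in rows:
            for r2 in rows:
                X = np.array([r1, r2])
                T, ll = e_step(X, params)
                T_ref, ll_ref = brute_force_mixture(X.tolist(), pi, mu, eps)
                np.testing.assert_allclose(T, T_ref, atol=1e-12)
                assert ll == pytest.approx(ll_ref, rel=1e-12)


class TestMStep:
    def test_hard_single_component_weighted_mean(self):
        X = np.array([[1], [1], [0]])
        T = np.ones((3, 1))
        p = m_step(X, T, constrained_dispersion=False)
        assert p.mu[0, 0] == 1
        assert p.epsilon[0, 0] == pytest.approx(1 / 3)

    def test_uniform_responsibilities_symmetric_components(self):
        X = np.array([[1, 0], [0, 1], [1, 1]])
        T = np.full((3, 2), 0.5)
        p = m_step(X, T)
        assert np.array_equal(p.mu[0], p.mu[1])
        assert np.allclose(p.epsilon[0], p.epsilon[1])

    def test_constrained_dispersion_averages_over_genomes(self):
        # component mismatch rates 0.1 and 0.3 across the two genomes
        X = np.array([[1, 1]] * 6 + [[0, 1]] * 1 + [[1, 0]] * 3)
        T = np.ones((10, 1))
        p = m_step(X, T, constrained_dispersion=True)
        assert np.allclose(p.epsilon[0], 0.2)

    def test_mu_tie_goes_to_zero(self):
        X = np.array([[1], [0]])
        T = np.ones((2, 1))
        p = m_step(X, T)
        assert p.mu[0, 0] == 0

    def test_empty_component_reseeded_with_warning(self):
        X = np.array([[1, 1], [1, 0], [0, 0]])
        T = np.zeros((3, 2))
        T[:, 0] = 1.0
        with pytest.warns(RuntimeWarning, match="re-seeded"):
            p = m_step(X, T)
        assert p.pi[1] > 0


class TestRunBinEM:
    def test_loglik_trace_monotone(self):
        pa, _ = generate_pa(150, 12, three_pattern_params(12), seed=0)
        _, _, trace = run_binem(pa, 3)
        assert (np.diff(trace) >= -1e-9).all()

    def test_hard_clusters_are_an_em_fixed_point(self):
        """With hard clusters and dispersion at the clamp, one E/M cycle
        reproduces the parameters and the posteriors are hard."""
        X = np.array([[1, 1]] * 5 + [[0, 0]] * 5)
        params = BMMParams([0.5, 0.5], [[1, 1], [0, 0]], np.full((2, 2), EPS_FLOOR))
        T, _ = e_step(X, params)
        np.testing.assert_allclose(T, np.repeat(np.eye(2), 5, axis=0), atol=1e-6)
        new = m_step(X, T)
        assert np.array_equal(new.mu, params.mu)
        np.testing.assert_allclose(new.pi, params.pi)
        np.testing.assert_allclose(new.epsilon, params.epsilon)

    def test_k_exceeding_f_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            run_binem(np.array([[1], [0]]), 3)

    def test_component_order_matches_presence_frequency(self):
        """After convergence component 1 is the most-present pattern and
        component K the least, across seeds."""
        for seed in range(20):
            pa, _ = generate_pa(300, 20, three_pattern_params(20), seed=seed)
            params, _, _ = run_binem(pa, 3)
            freq = params.mean_presence()
            assert freq[0] == max(freq) and freq[2] == min(freq)

    def test_parameter_recovery_well_separated(self):
        truth_params = three_pattern_params(50)
        pa, truth = generate_pa(1000, 50, truth_params, seed=42)
        params, T, _ = run_binem(pa, 3)
        assert np.abs(params.pi - truth_params.pi).max() < 0.05
        assert np.abs(params.epsilon[:, 0] - truth_params.epsilon[:, 0]).max() < 0.05
        labels = assign_partitions(T, 3, pa.family_ids).labels
        assert (labels == truth.labels_true).mean() >= 0.95


class TestEstimatorAPI:
    def test_sklearn_params_round_trip(self):
        est = BernoulliMixturePartitioner(n_partitions=4, tol=1e-5)
        assert est.get_params()["n_partitions"] == 4
        est.set_params(n_partitions=3)
        pa, _ = generate_pa(100, 10, three_pattern_params(10), seed=1)
        est.fit(pa.X)
        assert est.posteriors_.shape == (100, 3)
        assert est.labels_.shape == (100,)
        assert est.predict(pa.X[:5]).shape == (5,)
        assert np.isfinite(est.score(pa.X))

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            BernoulliMixturePartitioner().fit(np.array([[2, 0], [1, 1], [0, 1]]))


class TestAssignPartitions:
    def test_confident_persistent(self):
        part = assign_partitions(np.array([[0.9, 0.05, 0.05]]), 3)
        assert part.labels[0] == PERSISTENT and part.decided[0]

    def test_no_majority_falls_to_shell(self):
        part = assign_partitions(np.array([[0.45, 0.35, 0.20]]), 3)
        assert part.labels[0] == SHELL and not part.decided[0]
        assert part.components[0] == 2

    def test_exact_half_is_not_above_half(self):
        part = assign_partitions(np.array([[0.5, 0.5, 0.0]]), 3)
        assert part.labels[0] == SHELL and not part.decided[0]

    def test_cloud_is_last_component(self):
        part = assign_partitions(np.array([[0.1, 0.2, 0.7]]), 3)
        assert part.labels[0] == CLOUD
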