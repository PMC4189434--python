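"""Unit and property tests for the prior, likelihood and forward model."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import gammaln

from bacon import (
    Hyperparameters,
    dirichlet_concentrations,
    edge_count,
    enumerate_graphs,
    expected_nonedge_mass,
    forward_simulate,
    log_likelihood,
    log_likelihood_ratio,
    log_likelihood_row,
    log_prior,
    log_prior_ratio,
    n_pairs,
    sample_graph_from_prior,
    simulate_nonedge_mass,
    validate_adjacency,
    validate_counts,
)
from conftest import random_graph


class TestHyperparameters:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(alpha=0), dict(beta=-1), dict(d0=0), dict(d1=-2),
         dict(d0=2.0, d1=1.0)],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Hyperparameters(**kwargs)

    def test_d0_equal_d1_is_tolerated(self):
        Hyperparameters(d0=1.0, d1=1.0)

    def test_prior_density_mode(self):
        assert Hyperparameters(14, 53, 0.01, 1).prior_density_mode() == pytest.approx(
            13 / 65
        )
        # mode undefined at alpha <= 1: falls back to the prior mean
        assert Hyperparameters(1, 3, 0.01, 1).prior_density_mode() == pytest.approx(
            0.25
        )


class TestValidation:
    def test_asymmetric_graph_rejected(self):
        A = np.array([[0, 1], [0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            validate_adjacency(A)

    def test_self_loop_rejected(self):
        A = np.eye(3, dtype=int)
        with pytest.raises(ValueError, match="diagonal"):
            validate_adjacency(A)

    def test_negative_count_names_cell(self):
        N = np.zeros((3, 3), dtype=int)
        N[1, 2] = -4
        with pytest.raises(ValueError, match="row 1, column 2"):
            validate_counts(N)

    def test_nonzero_diagonal_rejected(self):
        N = np.diag([0, 5, 0])
        with pytest.raises(ValueError, match="diagonal"):
            validate_counts(N)


class TestPrior:
    def test_two_region_single_edge_probability_half(self):
        hyper = Hyperparameters(1, 1, 0.01, 1)
        one_edge = np.array([[0, 1], [1, 0]])
        assert log_prior(one_edge, hyper) == pytest.approx(np.log(0.5))

    @pytest.mark.parametrize("K", [2, 3, 4])
    @pytest.mark.parametrize("ab", [(1, 1), (14, 53), (0.5, 2.5)])
    def test_normalizes_over_all_graphs(self, K, ab):
        hyper = Hyperparameters(ab[0], ab[1], 0.01, 1)
        total = sum(np.exp(log_prior(A, hyper)) for A in enumerate_graphs(K))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_quadrature_over_edge_probability(self):
        # P(A) = E_p[p^e1 (1-p)^e0] under Beta(14, 53), K=4, e1=2
        hyper = Hyperparameters(14, 53, 0.01, 1)
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        expected, err = integrate.quad(
            lambda p: stats.beta.pdf(p, 14, 53) * p**2 * (1 - p) ** 4, 0, 1
        )
        assert np.exp(log_prior(A, hyper)) == pytest.approx(expected, rel=1e-8)

    def test_ratio_matches_full_recompute(self, rng):
        hyper = Hyperparameters(14, 53, 0.01, 1)
        for _ in range(20):
            A = random_graph(6, rng)
            i, j = sorted(rng.choice(6, size=2, replace=False))
            Astar = A.copy()
            Astar[i, j] = Astar[j, i] = 1 - Astar[i, j]
            assert log_prior_ratio(A, (i, j), hyper) == pytest.approx(
                log_prior(Astar, hyper) - log_prior(A, hyper), abs=1e-12
            )

    def test_ratio_uniform_prior_is_zero(self):
        hyper = Hyperparameters(1, 1, 0.01, 1)
        empty = np.zeros((2, 2), dtype=int)
        assert log_prior_ratio(empty, (0, 1), hyper) == pytest.approx(0.0)

    def test_ratio_toggle_twice_cancels(self, rng):
        hyper = Hyperparameters(3, 7, 0.01, 1)
        A = random_graph(5, rng)
        fwd = log_prior_ratio(A, (1, 3), hyper)
        Astar = A.copy()
        Astar[1, 3] = Astar[3, 1] = 1 - Astar[1, 3]
        assert fwd + log_prior_ratio(Astar, (1, 3), hyper) == pytest.approx(0.0)

    def test_ratio_rejects_self_pair(self):
        with pytest.raises(ValueError):
            log_prior_ratio(np.zeros((3, 3), dtype=int), (1, 1), Hyperparameters())


class TestPriorSampling:
    def test_mean_density_matches_beta_mean(self, rng):
        hyper = Hyperparameters(14, 53, 0.01, 1)
        n_draws, K = 2000, 90
        dens = [
            edge_count(sample_graph_from_prior(K, hyper, rng)) / n_pairs(K)
            for _ in range(n_draws)
        ]
        mean = 14 / 67
        # density variance under the Beta-Binomial (Beta variance dominates)
        se = np.std(dens, ddof=1) / np.sqrt(n_draws)
        assert abs(np.mean(dens) - mean) < 3 * se

    def test_degenerate_prior_gives_complete_graph(self, rng):
        hyper = Hyperparameters(1e6, 1e-6, 0.01, 1)
        A = sample_graph_from_prior(10, hyper, rng)
        assert edge_count(A) == n_pairs(10)

    def test_reproducible_under_seed(self, default_hyper):
        a = sample_graph_from_prior(8, default_hyper, np.random.default_rng(3))
        b = sample_graph_from_prior(8, default_hyper, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_requires_two_regions(self, rng, default_hyper):
        with pytest.raises(ValueError):
            sample_graph_from_prior(1, default_hyper, rng)


class TestLikelihood:
    def test_concentration_substitution(self):
        hyper = Hyperparameters(d0=0.01, d1=1.0)
        np.testing.assert_allclose(
            dirichlet_concentrations(np.array([1, 0, 1]), hyper), [1, 0.01, 1]
        )
        np.testing.assert_allclose(
            dirichlet_concentrations(np.zeros(4), hyper), np.full(4, 0.01)
        )
        np.testing.assert_allclose(
            dirichlet_concentrations(np.ones(4), hyper), np.ones(4)
        )

    def test_zero_budget_row_has_probability_one(self, default_hyper):
        assert log_likelihood_row(np.zeros(5), np.ones(5), default_hyper) == 0.0

    def test_single_target_row_is_deterministic(self, default_hyper):
        # K=2: the one-category multinomial puts all mass on its outcome
        for a in (0, 1):
            assert log_likelihood_row(
                np.array([17]), np.array([a]), default_hyper
            ) == pytest.approx(0.0, abs=1e-12)

    def test_row_matches_monte_carlo_integration(self):
        # E_x[Multinomial((2,1) | 3, x)] over x ~ Dirichlet(1, 0.01)
        hyper = Hyperparameters(d0=0.01, d1=1.0)
        exact = np.exp(
            log_likelihood_row(np.array([2, 1]), np.array([1, 0]), hyper)
        )
        rng = np.random.default_rng(11)
        x = rng.dirichlet([1.0, 0.01], size=1_000_000)
        vals = 3.0 * x[:, 0] ** 2 * x[:, 1]
        mc, se = vals.mean(), vals.std(ddof=1) / 1000.0
        assert abs(mc - exact) < 3 * se

    def test_total_is_sum_of_rows(self, tiny_problem):
        truth, counts, hyper = tiny_problem
        N = counts.counts
        K = N.shape[0]
        total = 0.0
        for i in range(K):
            targets = np.r_[0:i, i + 1 : K]
            total += log_likelihood_row(N[i, targets], truth[i, targets], hyper)
        assert log_likelihood(counts, truth, hyper) == pytest.approx(total)

    def test_all_zero_counts_log_likelihood_zero(self, default_hyper):
        N = np.zeros((4, 4), dtype=int)
        A = random_graph(4, np.random.default_rng(0))
        assert log_likelihood(N, A, default_hyper) == 0.0

    @pytest.mark.parametrize("graph_seed", [0, 1])
    def test_normalizes_over_count_matrices(self, graph_seed):
        # K=3, S=(2,2,2): sum over all 27 count matrices equals 1
        hyper = Hyperparameters(14, 53, 0.01, 1)
        A = random_graph(3, np.random.default_rng(graph_seed), p=0.6)
        total = 0.0
        rows = [(2, 0), (1, 1), (0, 2)]
        for r0 in rows:
            for r1 in rows:
                for r2 in rows:
                    N = np.zeros((3, 3), dtype=int)
                    N[0, [1, 2]] = r0
                    N[1, [0, 2]] = r1
                    N[2, [0, 1]] = r2
                    total += np.exp(log_likelihood(N, A, hyper))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_dimension_mismatch_raises(self, default_hyper):
        with pytest.raises(ValueError):
            log_likelihood(np.zeros((3, 3), int), np.zeros((4, 4), int), default_hyper)


class TestLikelihoodRatio:
    def test_matches_full_recompute(self, rng, default_hyper):
        for _ in range(20):
            A = random_graph(8, rng)
            _, _, counts = forward_simulate(8, default_hyper, 100, rng, graph=A)
            i, j = sorted(rng.choice(8, size=2, replace=False))
            Astar = A.copy()
            Astar[i, j] = Astar[j, i] = 1 - Astar[i, j]
            assert log_likelihood_ratio(counts, A, (i, j), default_hyper) == pytest.approx(
                log_likelihood(counts, Astar, default_hyper)
                - log_likelihood(counts, A, default_hyper),
                abs=1e-9,
            )

    def test_equal_concentrations_make_graph_irrelevant(self, rng):
        hyper = Hyperparameters(d0=1.0, d1=1.0)
        A = random_graph(5, rng)
        _, _, counts = forward_simulate(5, hyper, 50, rng, graph=A)
        for i, j in [(0, 1), (2, 4), (1, 3)]:
            assert log_likelihood_ratio(counts, A, (i, j), hyper) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_toggle_twice_cancels(self, rng, default_hyper):
        A = random_graph(6, rng)
        _, _, counts = forward_simulate(6, default_hyper, 80, rng, graph=A)
        fwd = log_likelihood_ratio(counts, A, (2, 5), default_hyper)
        Astar = A.copy()
        Astar[2, 5] = Astar[5, 2] = 1 - Astar[2, 5]
        assert fwd + log_likelihood_ratio(
            counts, Astar, (2, 5), default_hyper
        ) == pytest.approx(0.0, abs=1e-12)


class TestNonEdgeMass:
    def test_fully_connected_region_has_no_leak(self, default_hyper):
        assert expected_nonedge_mass(10, 10, default_hyper) == 0.0

    def test_reference_operating_point(self):
        # degree 18 of 89 targets at d0=0.01, d1=1
        hyper = Hyperparameters(d0=0.01, d1=1.0)
        assert expected_nonedge_mass(18, 89, hyper) == pytest.approx(
            0.71 / 18.71, rel=1e-12
        )

    def test_monotone_in_d0_and_degree(self):
        masses_d0 = [
            expected_nonedge_mass(18, 89, Hyperparameters(d0=d0, d1=1.0))
            for d0 in (0.001, 0.01, 0.1, 1.0)
        ]
        assert np.all(np.diff(masses_d0) > 0)
        hyper = Hyperparameters(d0=0.01, d1=1.0)
        masses_deg = [expected_nonedge_mass(e, 89, hyper) for e in (1, 10, 30, 89)]
        assert np.all(np.diff(masses_deg) < 0)

    def test_simulation_matches_closed_form(self, rng):
        hyper = Hyperparameters(d0=0.01, d1=1.0)
        mean, se = simulate_nonedge_mass(18, 89, hyper, 100_000, rng)
        assert abs(mean - expected_nonedge_mass(18, 89, hyper)) < 3 * se

    def test_degree_out_of_range(self, default_hyper):
        with pytest.raises(ValueError):
            expected_nonedge_mass(12, 10, default_hyper)


class TestForwardSimulate:
    def test_row_sums_equal_budgets(self, rng, default_hyper):
        budgets = np.array([10, 0, 500, 42, 7])
        _, _, counts = forward_simulate(5, default_hyper, budgets, rng)
        np.testing.assert_array_equal(counts.row_totals, budgets)

    def test_probability_rows_sum_to_one(self, rng, default_hyper):
        _, X, _ = forward_simulate(6, default_hyper, 100, rng)
        np.testing.assert_allclose(X.sum(axis=1), 1.0, atol=1e-10)

    def test_tiny_d0_starves_nonedges(self, rng):
        # every node needs an edge: a degree-0 row necessarily puts all of
        # its (normalized) mass on non-edges whatever d0 is
        hyper = Hyperparameters(d0=1e-8, d1=1.0)
        ring = np.zeros((10, 10), dtype=np.int8)
        for i in range(10):
            ring[i, (i + 1) % 10] = ring[(i + 1) % 10, i] = 1
        A, _, counts = forward_simulate(10, hyper, 10_000, rng, graph=ring)
        nonedge = (1 - A - np.eye(10, dtype=int)).astype(bool)
        assert counts.counts[nonedge].sum() / counts.counts.sum() < 1e-3

    def test_nonedge_mass_consistent_with_calibration(self, rng, default_hyper):
        # streamline fraction on non-edges tracks the per-degree expectation
        from bacon import random_density_matched_graph

        K = 30
        A = random_density_matched_graph(K, 87, rng)  # density 0.2
        _, _, counts = forward_simulate(K, default_hyper, 5000, rng, graph=A)
        N = counts.counts
        observed, expected = [], []
        for i in range(K):
            deg = int(A[i].sum())
            nonedge = (A[i] == 0) & (np.arange(K) != i)
            observed.append(N[i, nonedge].sum() / 5000)
            expected.append(expected_nonedge_mass(deg, K - 1, default_hyper))
        assert np.mean(observed) == pytest.approx(np.mean(expected), abs=0.02)

    def test_bit_identical_under_same_seed(self, default_hyper):
        out1 = forward_simulate(8, default_hyper, 200, np.random.default_rng(9))
        out2 = forward_simulate(8, default_hyper, 200, np.random.default_rng(9))
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])
        assert np.array_equal(out1[2].counts, out2[2].counts)
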