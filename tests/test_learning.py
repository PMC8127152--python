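import itertools

import numpy as np
import pytest

from multigft.graphs import SignalSet
from multigft.learning import (
    LearningConfig,
    MultiParadigmSet,
    SolverStatus,
    assemble_qp,
    laplacian_from_edge_vector,
    learn_multigraph,
    learn_single_laplacian,
    objective_value,
    smoothness_coefficients,
)


def two_paradigm_set(rng, n=5, p=(12, 15)):
    return MultiParadigmSet(
        tuple(SignalSet(rng.standard_normal((n, pk))) for pk in p)
    )


class TestAssembleQP:
    def test_dimensions_and_constraint_d1_n3(self, rng):
        data = MultiParadigmSet((SignalSet(rng.standard_normal((3, 4))),))
        qp = assemble_qp(data, LearningConfig(beta=1.0))
        assert qp.n_blocks == 1 and qp.block_size == 3
        assert qp.block_sum == pytest.approx(1.5)

    def test_quadratic_term_psd(self, rng):
        qp = assemble_qp(two_paradigm_set(rng), LearningConfig(beta=0.5, alpha=3.0))
        assert np.allclose(qp.H, qp.H.T)
        assert np.linalg.eigvalsh(qp.H)[0] >= -1e-9

    def test_linear_term_is_pairwise_squared_distances(self, rng):
        X = SignalSet(rng.standard_normal((4, 7)))
        z = smoothness_coefficients(X)
        # brute-force oracle: explicit sum over observations
        expected = []
        for i in range(4):
            for j in range(i + 1, 4):
                expected.append(
                    sum((X.values[i, t] - X.values[j, t]) ** 2 for t in range(7))
                )
        assert np.allclose(z, expected, atol=1e-10)

    def test_nonzero_alpha_with_single_paradigm_rejected(self, rng):
        data = MultiParadigmSet((SignalSet(rng.standard_normal((3, 4))),))
        with pytest.raises(ValueError, match="alpha"):
            assemble_qp(data, LearningConfig(beta=1.0, alpha=2.0))

    def test_single_node_rejected(self, rng):
        data = MultiParadigmSet((SignalSet(rng.standard_normal((1, 4))),))
        with pytest.raises(ValueError, match="2 nodes"):
            assemble_qp(data, LearningConfig(beta=1.0))


class TestObjectiveValue:
    def test_identical_laplacians_zero_coupling_term(self, rng):
        data = two_paradigm_set(rng)
        res = learn_multigraph(data, LearningConfig(beta=2.0, alpha=1e5 * 2.0))
        coupled = objective_value(res.laplacians, data, LearningConfig(beta=2.0, alpha=5.0))
        uncoupled = objective_value(res.laplacians, data, LearningConfig(beta=2.0, alpha=0.0))
        assert coupled == pytest.approx(uncoupled, rel=1e-6)

    def test_hand_expanded_d1_value(self):
        # 3-node path Laplacian, X = I3, beta = 1:
        # tr(X^T L X) = tr(L) = 4; ||L||_F^2 = 1+1+4+1+1+1+1 = 10 -> 14
        from multigft.graphs import LaplacianMatrix

        L = LaplacianMatrix(np.array([[1.0, -1, 0], [-1, 2, -1], [0, -1, 1]]))
        data = MultiParadigmSet((SignalSet(np.eye(3)),))
        val = objective_value([L], data, LearningConfig(beta=1.0))
        assert val == pytest.approx(14.0, abs=1e-12)

    def test_beta_scales_frobenius_contribution_linearly(self, rng):
        data = two_paradigm_set(rng)
        res = learn_multigraph(data, LearningConfig(beta=1.0, alpha=0.0))
        v1 = objective_value(res.laplacians, data, LearningConfig(beta=1.0))
        v2 = objective_value(res.laplacians, data, LearningConfig(beta=2.0))
        frob = sum(np.sum(L.matrix**2) for L in res.laplacians) / data.d
        assert v2 - v1 == pytest.approx(frob, rel=1e-9)


class TestLearnSingle:
    def test_identical_node_pair_attracts_largest_weight(self, rng):
        base = rng.standard_normal(10)
        X = np.vstack([base, base, 10 * rng.standard_normal((3, 10))])
        res = learn_single_laplacian(SignalSet(X), beta=1.0)
        W = -res.laplacians[0].matrix
        np.fill_diagonal(W, 0.0)
        assert (0, 1) == tuple(sorted(np.unravel_index(np.argmax(W), W.shape)))

    def test_large_beta_approaches_uniform_weights(self, rng):
        n = 5
        X = SignalSet(rng.standard_normal((n, 20)))
        res = learn_single_laplacian(X, beta=1e7)
        w = -res.laplacians[0].matrix[np.triu_indices(n, 1)]
        assert np.allclose(w, (n / 2) / (n * (n - 1) / 2), atol=1e-4)

    def test_small_beta_gives_sparse_solution(self, rng):
        n = 8
        X = SignalSet(rng.standard_normal((n, 30)))
        res = learn_single_laplacian(X, beta=1e-4)
        w = -res.laplacians[0].matrix[np.triu_indices(n, 1)]
        assert np.sum(np.abs(w) > 1e-4) <= n  # clear majority of pairs are zero

    def test_result_is_valid_laplacian_with_trace_n(self, rng):
        X = SignalSet(rng.standard_normal((6, 15)))
        res = learn_single_laplacian(X, beta=2.0)
        L = res.laplacians[0]
        assert L.trace == pytest.approx(6.0, abs=1e-6 * 6)
        assert np.allclose(L.matrix @ np.ones(6), 0.0, atol=1e-8)

    def test_deterministic(self, rng):
        X = SignalSet(rng.standard_normal((6, 15)))
        r1 = learn_single_laplacian(X, beta=2.0)
        r2 = learn_single_laplacian(X, beta=2.0)
        assert np.array_equal(r1.laplacians[0].matrix, r2.laplacians[0].matrix)


class TestLearnMultigraph:
    def test_zero_alpha_matches_independent_solutions(self, rng):
        data = two_paradigm_set(rng)
        joint = learn_multigraph(data, LearningConfig(beta=3.0, alpha=0.0))
        for k, X in enumerate(data.paradigms):
            single = learn_single_laplacian(X, beta=3.0)
            diff = np.linalg.norm(
                joint.laplacians[k].matrix - single.laplacians[0].matrix
            )
            assert diff <= 1e-6

    def test_huge_alpha_forces_identical_laplacians(self, rng):
        data = two_paradigm_set(rng)
        beta = 3.0
        res = learn_multigraph(data, LearningConfig(beta=beta, alpha=1e6 * beta))
        diff = np.linalg.norm(res.laplacians[0].matrix - res.laplacians[1].matrix)
        assert diff <= 1e-3

    def test_optimum_beats_brute_force_feasible_grid(self, rng):
        """QP optimum must undercut every discrete feasible weight pattern."""
        n, d = 5, 2
        data = two_paradigm_set(rng, n=n)
        config = LearningConfig(beta=1.5, alpha=2.0)
        res = learn_multigraph(data, config)
        assert res.solver_status == SolverStatus.OPTIMAL
        m = n * (n - 1) // 2
        # grid: distribute total weight n/2 over 2 chosen support pairs per paradigm
        levels = [np.zeros(m)]
        for pair in itertools.combinations(range(m), 2):
            w = np.zeros(m)
            w[list(pair)] = n / 4.0
            levels.append(w)
        best_grid = np.inf
        for wa in levels[1:]:
            for wb in levels[1:]:
                from multigft.graphs import LaplacianMatrix

                laps = [
                    LaplacianMatrix(laplacian_from_edge_vector(w, n))
                    for w in (wa, wb)
                ]
                best_grid = min(best_grid, objective_value(laps, data, config))
        assert res.objective_value <= best_grid + 1e-9

    def test_objective_not_worse_than_uniform_graph(self, rng):
        from multigft.graphs import LaplacianMatrix

        n = 6
        data = two_paradigm_set(rng, n=n)
        config = LearningConfig(beta=2.0, alpha=1.0)
        res = learn_multigraph(data, config)
        m = n * (n - 1) // 2
        uniform = laplacian_from_edge_vector(np.full(m, (n / 2) / m), n)
        laps = [LaplacianMatrix(uniform)] * 2
        assert res.objective_value <= objective_value(laps, data, config) + 1e-9

    def test_coupling_discrepancy_monotone_in_alpha(self, rng):
        data = two_paradigm_set(rng, n=6, p=(10, 25))
        prev = np.inf
        for alpha in [0.0, 0.5, 2.0, 10.0, 100.0]:
            res = learn_multigraph(data, LearningConfig(beta=2.0, alpha=alpha))
            gap = np.linalg.norm(
                res.laplacians[0].matrix - res.laplacians[1].matrix
            ) ** 2
            assert gap <= prev + 1e-8
            prev = gap

    def test_signal_scaling_scales_trace_term_quadratically(self, rng):
        data = two_paradigm_set(rng)
        scaled = MultiParadigmSet(
            tuple(SignalSet(3.0 * X.values) for X in data.paradigms)
        )
        cfg = LearningConfig(beta=1.0, alpha=0.0)
        laps = learn_multigraph(data, cfg).laplacians
        v = objective_value(laps, data, cfg)
        v_scaled = objective_value(laps, scaled, cfg)
        frob = sum(np.sum(L.matrix**2) for L in laps) / data.d
        assert v_scaled - frob == pytest.approx(9.0 * (v - frob), rel=1e-9)
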