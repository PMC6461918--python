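"""Contribution frontiers: gains, co-ancestry, scalarized QPs, tracing."""

import numpy as np
import pytest

from moob.core import (
    BreedingValues,
    ContributionVector,
    GeneticCorrelationMatrix,
    RelationshipMatrix,
)
from moob.frontier import (
    coancestry,
    constrained_min_coancestry,
    gain,
    penalized_quadratic_matrix,
    solve_scalarized_qp,
    trace_frontier,
)
from moob.pareto import nondominated_mask


def random_instance(rng, m, k=2):
    M = rng.normal(size=(m, m + 3))
    A = RelationshipMatrix(M @ M.T / (m + 3))
    bv = BreedingValues(rng.normal(size=(m, k)), [f"t{i}" for i in range(k)])
    return bv, A


def grid_best_objective(V, Q, w, step):
    """Dense simplex-grid search oracle for the scalarized objective,
    m = 3 or 4 candidates, vectorized over the last coordinate."""
    m = V.shape[0]
    d = int(round(1 / step))
    best = -np.inf
    grid = np.arange(d + 1)
    if m == 3:
        for a in grid:
            b = np.arange(d - a + 1)
            C = np.column_stack([np.full(b.size, a), b, d - a - b]) / d
            vals = scalarized(C, V, Q, w)
            best = max(best, vals.max())
    elif m == 4:
        for a in grid:
            for b in range(d - a + 1):
                c = np.arange(d - a - b + 1)
                C = np.column_stack(
                    [np.full(c.size, a), np.full(c.size, b), c, d - a - b - c]
                ) / d
                vals = scalarized(C, V, Q, w)
                best = max(best, vals.max())
    else:
        raise ValueError("oracle supports m in {3, 4}")
    return best


def scalarized(C, V, Q, w):
    k = V.shape[1]
    lin = C @ (V @ w[:k])
    quad = 0.5 * np.einsum("ij,jk,ik->i", C, Q, C)
    return lin - w[k] * quad


class TestGainAndCoancestry:
    def test_point_mass_gain(self, frontier_instance):
        bv, A = frontier_instance
        c = np.zeros(8)
        c[3] = 1.0
        assert gain(ContributionVector(c), bv, 0) == pytest.approx(bv.values[3, 0])

    def test_uniform_gain_is_trait_mean(self, frontier_instance):
        bv, _ = frontier_instance
        c = ContributionVector(np.full(8, 1 / 8))
        assert gain(c, bv, 1) == pytest.approx(bv.values[:, 1].mean())

    def test_gain_matches_loop_oracle(self, frontier_instance, rng):
        bv, _ = frontier_instance
        c = rng.dirichlet(np.ones(8))
        expected = sum(c[i] * bv.values[i, 0] for i in range(8))
        assert gain(ContributionVector(c), bv, 0) == pytest.approx(expected)

    def test_point_mass_coancestry_is_half_diagonal(self, frontier_instance):
        _, A = frontier_instance
        c = np.zeros(8)
        c[2] = 1.0
        assert coancestry(ContributionVector(c), A) == pytest.approx(A.A[2, 2] / 2)

    def test_identity_uniform_closed_form(self):
        m = 6
        A = RelationshipMatrix(np.eye(m))
        c = ContributionVector(np.full(m, 1 / m))
        assert coancestry(c, A) == pytest.approx(1 / (2 * m))

    def test_coancestry_matches_double_loop(self, frontier_instance, rng):
        _, A = frontier_instance
        c = rng.dirichlet(np.ones(8))
        expected = 0.5 * sum(
            c[i] * c[j] * A.A[i, j] for i in range(8) for j in range(8)
        )
        assert coancestry(ContributionVector(c), A) == pytest.approx(expected)

    def test_dimension_mismatch(self, frontier_instance):
        bv, A = frontier_instance
        with pytest.raises(ValueError):
            gain(ContributionVector(np.ones(3) / 3), bv, 0)
        with pytest.raises(ValueError):
            coancestry(ContributionVector(np.ones(3) / 3), A)


class TestPenalizedMatrix:
    def test_uncorrelated_pair_doubles(self):
        A = RelationshipMatrix(np.eye(3))
        psi = GeneticCorrelationMatrix(np.eye(2))
        np.testing.assert_allclose(
            penalized_quadratic_matrix(A, psi), 2 * np.eye(3)
        )

    def test_negative_pair_triples(self):
        A = RelationshipMatrix(np.eye(3))
        psi = GeneticCorrelationMatrix(np.array([[1, -0.5], [-0.5, 1]]))
        np.testing.assert_allclose(
            penalized_quadratic_matrix(A, psi), 3 * np.eye(3)
        )

    def test_three_trait_double_sum(self):
        A = RelationshipMatrix(np.eye(2))
        P = np.full((3, 3), -0.2)
        np.fill_diagonal(P, 1.0)
        psi = GeneticCorrelationMatrix(P)
        # factor = 3 - 2 * (3 pairs * -0.2) = 4.2
        np.testing.assert_allclose(
            penalized_quadratic_matrix(A, psi), 4.2 * np.eye(2)
        )

    def test_strongly_positive_correlations_raise(self):
        A = RelationshipMatrix(np.eye(2))
        psi = GeneticCorrelationMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="unpenalized"):
            penalized_quadratic_matrix(A, psi)


class TestScalarizedQP:
    def test_all_weight_on_quadratic_identity_gives_uniform(self):
        m = 7
        bv = BreedingValues(np.random.default_rng(1).normal(size=(m, 1)), ["t"])
        sol = solve_scalarized_qp(bv, np.eye(m), [0.0, 1.0])
        np.testing.assert_allclose(sol.decision.c, np.full(m, 1 / m), atol=1e-8)

    def test_pure_linear_weights_take_vertex(self, rng):
        bv = BreedingValues(rng.normal(size=(6, 1)), ["t"])
        sol = solve_scalarized_qp(bv, np.eye(6), [1.0, 0.0])
        c = sol.decision.c
        assert c[np.argmax(bv.values[:, 0])] == pytest.approx(1.0)
        assert sol.info["vertex_shortcut"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_simplex_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bv, A = random_instance(rng, 4)
        w = rng.dirichlet(np.ones(3))
        w[2] = max(w[2], 0.2)  # keep the problem strictly convex
        sol = solve_scalarized_qp(bv, A.A, w)
        own = scalarized(sol.decision.c[None, :], bv.values, A.A, w)[0]
        oracle = grid_best_objective(bv.values, A.A, w, step=0.01)
        assert own >= oracle - 1e-4

    def test_kkt_residual_reported_small(self, frontier_instance):
        bv, A = frontier_instance
        sol = solve_scalarized_qp(bv, A.A + 1e-6 * np.eye(8), [0.3, 0.3, 0.4])
        assert sol.info["kkt_residual"] < 1e-6

    def test_invalid_weights_raise(self, frontier_instance):
        bv, A = frontier_instance
        with pytest.raises(ValueError):
            solve_scalarized_qp(bv, A.A, [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            solve_scalarized_qp(bv, A.A, [-0.1, 0.5, 0.6])


class TestTraceFrontier:
    def test_single_trait_endpoints(self, rng):
        m = 6
        bv = BreedingValues(rng.normal(size=(m, 1)), ["t"])
        A = RelationshipMatrix(np.eye(m))
        front = trace_frontier(bv, A, resolution=11)
        X = front.objective_matrix()
        # min co-ancestry endpoint: uniform; max gain endpoint: best vertex
        assert X[:, 1].min() == pytest.approx(1 / (2 * m), abs=1e-6)
        assert X[:, 0].max() == pytest.approx(bv.values[:, 0].max(), abs=1e-6)

    def test_single_trait_joint_monotonicity(self, rng):
        bv = BreedingValues(rng.normal(size=(7, 1)), ["t"])
        A = RelationshipMatrix(np.eye(7))
        front = trace_frontier(bv, A, resolution=15)
        X = front.objective_matrix()
        order = np.argsort(X[:, 0])
        assert (np.diff(X[order, 1]) >= -1e-9).all()

    def test_no_mutually_dominating_pairs(self, frontier_instance):
        bv, A = frontier_instance
        front = trace_frontier(bv, A, resolution=9)
        X = front.objective_matrix()
        assert nondominated_mask(X, front.maximize).all()

    def test_monte_carlo_nondominance(self, frontier_instance):
        bv, A = frontier_instance
        front = trace_frontier(bv, A, resolution=9)
        rng = np.random.default_rng(5)
        C = rng.dirichlet(np.ones(8), size=2000)
        gains = C @ bv.values
        coan = 0.5 * np.einsum("ij,jk,ik->i", C, A.A, C)
        cloud = np.column_stack([gains, coan])
        sign = np.where(front.maximize, 1.0, -1.0)
        Xo = front.objective_matrix() * sign
        Co = cloud * sign
        for x in Xo:
            dominated = ((Co >= x + 1e-9).all(axis=1) & (Co > x + 1e-9).any(axis=1))
            assert not dominated.any()

    def test_eq2_uses_penalized_matrix(self, frontier_instance):
        bv, A = frontier_instance
        psi = GeneticCorrelationMatrix(np.array([[1, -0.5], [-0.5, 1]]))
        f1 = trace_frontier(bv, A, variant="eq1", resolution=7)
        f2 = trace_frontier(bv, A, variant="eq2", resolution=7, psi=psi)
        # co-ancestry axis of eq2 is scaled by the penalty factor 3
        assert f2.objective_matrix()[:, 2].max() == pytest.approx(
            3 * f1.objective_matrix()[:, 2].max(), rel=0.05
        )

    def test_deterministic(self, frontier_instance):
        bv, A = frontier_instance
        f1 = trace_frontier(bv, A, resolution=9)
        f2 = trace_frontier(bv, A, resolution=9)
        np.testing.assert_array_equal(
            f1.objective_matrix(), f2.objective_matrix()
        )

    def test_scale_equivariance_of_solution_set(self, frontier_instance):
        bv, A = frontier_instance
        scaled = BreedingValues(
            bv.values * np.array([3.0, 1.0]), list(bv.trait_names)
        )
        f1 = trace_frontier(bv, A, resolution=9)
        f2 = trace_frontier(scaled, A, resolution=9)
        # gain axis 0 rescales by 3; compare attainable gain ranges
        assert f2.objective_matrix()[:, 0].max() == pytest.approx(
            3 * f1.objective_matrix()[:, 0].max(), rel=1e-6
        )


class TestConstrainedMinCoancestry:
    def test_rho_at_max_returns_point_mass(self, rng):
        bv, A = random_instance(rng, 6, k=1)
        b = bv.values[:, 0]
        c = constrained_min_coancestry(bv, A, rho=float(b.max()))
        assert c.c[np.argmax(b)] == pytest.approx(1.0, abs=1e-6)

    def test_identity_mean_rho_gives_uniform(self):
        rng = np.random.default_rng(3)
        m = 5
        bv = BreedingValues(rng.normal(size=(m, 1)), ["t"])
        A = RelationshipMatrix(np.eye(m))
        c = constrained_min_coancestry(bv, A, rho=float(bv.values[:, 0].mean()))
        # KKT for min c'c subject to c'b = mean(b), sum c = 1: uniform
        np.testing.assert_allclose(c.c, np.full(m, 1 / m), atol=1e-6)

    @pytest.mark.parametrize("q", [0.2, 0.5, 0.8])
    def test_gain_constraint_satisfied(self, q, rng):
        bv, A = random_instance(rng, 8, k=1)
        b = bv.values[:, 0]
        rho = float(b.min() + q * (b.max() - b.min()))
        c = constrained_min_coancestry(bv, A, rho=rho)
        assert c.c @ b == pytest.approx(rho, abs=1e-6)

    def test_infeasible_rho_raises(self, rng):
        bv, A = random_instance(rng, 5, k=1)
        with pytest.raises(ValueError, match="infeasible"):
            constrained_min_coancestry(bv, A, rho=float(bv.values.max()) + 1)

    def test_equivalent_to_single_trait_frontier(self, rng):
        bv, A = random_instance(rng, 7, k=1)
        front = trace_frontier(bv, A, resolution=15)
        b = bv.values[:, 0]
        Xf0 = front.objective_matrix()
        # sweep the efficient range: from the gain of the minimum-co-ancestry
        # solution up to the best attainable gain
        rhos = np.linspace(Xf0[np.argmin(Xf0[:, 1]), 0], b.max(), 9)
        sweep = []
        for rho in rhos:
            c = constrained_min_coancestry(bv, A, rho=float(rho))
            sweep.append([c.c @ b, 0.5 * c.c @ A.A @ c.c])
        sweep = np.array(sweep)
        Xf = front.objective_matrix()
        # neither set may dominate the other (gain max, co-ancestry min)
        for g, r in sweep:
            dominated = (
                (Xf[:, 0] >= g + 1e-7) & (Xf[:, 1] <= r - 1e-7)
            ) & ((Xf[:, 0] > g + 1e-7) | (Xf[:, 1] < r - 1e-7))
            assert not dominated.any()
        for g, r in Xf:
            dominated = (
                (sweep[:, 0] >= g + 1e-7) & (sweep[:, 1] <= r - 1e-7)
            )
            assert not dominated.any()
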