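"""Pareto-optimal parental contributions balancing gains and co-ancestry.

For a candidate set with breeding-value vectors g_1 ... g_k and additive
relationship matrix A, a contribution vector c (non-negative, summing to
one) is scored on k + 1 objectives: the expected per-trait gains c'g_l
(maximized) and the group co-ancestry r(c) = 1/2 c'Ac (minimized) — the
expected average relationship of the next generation and a proxy for loss
of genetic diversity.  A correlation-penalized variant replaces A by
(k - 2 * sum_{i<j} Psi_ij) A, inflating the diversity penalty when traits
are negatively genetically correlated.

Because every objective is linear except the single concave quadratic, the
attainable objective set is convex and the full Pareto front is recovered
by weighted-sum scalarization: :func:`trace_frontier` sweeps a uniform
lattice of weight vectors over the (k + 1)-simplex, solves one simplex-
constrained QP per weight vector (warm-started along the sweep), and
prunes duplicates and any numerically dominated points.

:func:`constrained_min_coancestry` provides the classical single-trait
formulation — minimize co-ancestry subject to a fixed expected gain — used
as an independent cross-check of the k = 1 frontier.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterator, Sequence

import numpy as np

from .core import (
    BreedingValues,
    ContributionVector,
    GeneticCorrelationMatrix,
    RelationshipMatrix,
    estimate_genetic_correlations,
)
from .pareto import FrontierSolution, ObjectiveVector, ParetoFrontier
from .qp import solve_qp

__all__ = [
    "gain",
    "coancestry",
    "penalized_quadratic_matrix",
    "solve_scalarized_qp",
    "trace_frontier",
    "constrained_min_coancestry",
    "weight_lattice",
]


def gain(c: ContributionVector, g: BreedingValues, trait: int = 0) -> float:
    """Expected gain c'g for one trait."""
    if c.c.size != g.n_individuals:
        raise ValueError("contribution and breeding-value dimensions differ")
    return float(c.c @ g.values[:, trait])


def coancestry(c: ContributionVector, A: RelationshipMatrix) -> float:
    """Group co-ancestry r(c) = 1/2 c'Ac."""
    if c.c.size != A.n_individuals:
        raise ValueError("contribution and relationship dimensions differ")
    return float(0.5 * c.c @ A.A @ c.c)


def penalized_quadratic_matrix(
    A: RelationshipMatrix, psi: GeneticCorrelationMatrix, k: int | None = None
) -> np.ndarray:
    """Scaled relationship matrix for the correlation-penalized variant.

    Returns (k - 2 * sum_{i<j} Psi_ij) * A.  The scaling factor grows when
    trait pairs are negatively correlated, hardening the diversity
    objective; it can turn non-positive under strongly positive
    correlations, in which case the penalized formulation is undefined and
    the caller should fall back to the plain co-ancestry objective.
    """
    if k is None:
        k = psi.n_traits
    if k < 2:
        raise ValueError("penalized variant requires at least 2 traits")
    if psi.n_traits != k:
        raise ValueError("psi size does not match trait count")
    off = sum(psi.psi[i, j] for i, j in combinations(range(k), 2))
    factor = k - 2.0 * off
    if factor <= 0:
        raise ValueError(
            f"non-positive penalty factor {factor:.4g} "
            "(strongly positive genetic correlations); "
            "use the unpenalized co-ancestry objective instead"
        )
    return factor * A.A


def _ensure_pd(A: np.ndarray) -> np.ndarray:
    """Jitter A by +1e-8 I when its smallest eigenvalue is below 1e-10."""
    if np.linalg.eigvalsh(A).min() < 1e-10:
        A = A + 1e-8 * np.eye(A.shape[0])
    return A


def solve_scalarized_qp(
    g_all: BreedingValues,
    Q: np.ndarray,
    weights: Sequence[float],
    x0: np.ndarray | None = None,
    solver_opts: dict | None = None,
) -> FrontierSolution:
    """Maximizer of sum_l w_l c'g_l - w_{k+1} * 1/2 c'Qc over the simplex.

    Weights must be non-negative and not all zero.  A zero weight on the
    quadratic term makes the problem linear, which a QP cannot handle
    (no strict convexity); those weight vectors are answered by the vertex
    shortcut — a point mass on the candidate with the best weighted gain.
    The returned solution records the scalarization weights, the objective
    vector (per-trait gains, then the co-ancestry term 1/2 c'Qc) and the
    solver's KKT residual.
    """
    w = np.asarray(weights, dtype=float).ravel()
    k = g_all.n_traits
    if w.size != k + 1:
        raise ValueError(f"need {k + 1} weights, got {w.size}")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative and not all zero")
    m = g_all.n_individuals
    V = g_all.oriented()
    a = V @ w[:k]
    wq = w[k]
    if wq == 0.0:
        c = np.zeros(m)
        c[int(np.argmax(a))] = 1.0
        info = {"kkt_residual": 0.0, "iterations": 0, "vertex_shortcut": True}
    else:
        opts = solver_opts or {}
        ones = np.ones((1, m))
        start = np.full(m, 1.0 / m) if x0 is None else np.asarray(x0, float)
        c, qp_info = solve_qp(wq * Q, a, ones, np.ones(1), start, **opts)
        s = c.sum()
        if s > 0:
            c = c / s
        info = {
            "kkt_residual": qp_info["kkt_residual"],
            "iterations": qp_info["iterations"],
            "vertex_shortcut": False,
        }
    gains = g_all.values.T @ c
    r = 0.5 * c @ Q @ c
    objectives = ObjectiveVector(
        np.concatenate([gains, [r]]),
        np.concatenate([np.asarray(g_all.maximize, bool), [False]]),
    )
    return FrontierSolution(
        decision=ContributionVector(
            c,
            None if g_all.individual_ids is None else list(g_all.individual_ids),
        ),
        objectives=objectives,
        scalarization_weights=w,
        info=info,
    )


def weight_lattice(n_axes: int, resolution: int) -> Iterator[np.ndarray]:
    """Uniform lattice over the (n_axes - 1)-simplex with ``resolution``
    points per axis (compositions of resolution - 1, lexicographic)."""
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    d = resolution - 1

    def rec(prefix: list[int], remaining: int, slots: int):
        if slots == 1:
            yield prefix + [remaining]
            return
        for v in range(remaining + 1):
            yield from rec(prefix + [v], remaining - v, slots - 1)

    for comp in rec([], d, n_axes):
        yield np.asarray(comp, dtype=float) / d


def trace_frontier(
    g_all: BreedingValues,
    A: RelationshipMatrix,
    variant: str = "eq1",
    resolution: int = 21,
    psi: GeneticCorrelationMatrix | None = None,
    solver_opts: dict | None = None,
    prune_tol: float = 1e-6,
) -> ParetoFrontier:
    """Trace the contribution Pareto frontier by a scalarization sweep.

    ``variant="eq1"`` uses the plain group co-ancestry 1/2 c'Ac;
    ``variant="eq2"`` substitutes the correlation-penalized matrix (with
    ``psi`` estimated from ``g_all`` when not supplied).  One QP is solved
    per lattice weight vector, warm-started from the previous solution;
    solutions closer than ``prune_tol`` (sup-norm on objectives) collapse
    and numerically dominated points are dropped.  Deterministic: the same
    inputs always produce the same frontier.
    """
    if g_all.n_individuals != A.n_individuals:
        raise ValueError("breeding values and relationship matrix sizes differ")
    k = g_all.n_traits
    if variant == "eq1":
        Q = A.A
    elif variant == "eq2":
        if psi is None:
            psi = estimate_genetic_correlations(g_all)
        Q = penalized_quadratic_matrix(A, psi, k)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    Q = _ensure_pd(Q)
    solutions: list[FrontierSolution] = []
    x_prev: np.ndarray | None = None
    for w in weight_lattice(k + 1, resolution):
        sol = solve_scalarized_qp(g_all, Q, w, x0=x_prev, solver_opts=solver_opts)
        if not sol.info.get("vertex_shortcut"):
            x_prev = sol.decision.c
        solutions.append(sol)
    return ParetoFrontier(solutions).pruned(tol=prune_tol)


def constrained_min_coancestry(
    g: BreedingValues | np.ndarray,
    A: RelationshipMatrix,
    rho: float,
) -> ContributionVector:
    """Minimum co-ancestry at a fixed expected gain (single-trait legacy QP).

    minimize 1/2 c'Ac  subject to  c'b = rho, c'1 = 1, c >= 0.

    ``rho`` must lie between the smallest and largest breeding value.  As
    rho sweeps that range the solution set traces the same trade-off as
    the k = 1 scalarized frontier, which is how the two are cross-checked.
    """
    if isinstance(g, BreedingValues):
        b = g.oriented()[:, 0]
        ids = g.individual_ids
    else:
        b = np.asarray(g, dtype=float).ravel()
        ids = None
    m = b.size
    if m != A.n_individuals:
        raise ValueError("breeding values and relationship matrix sizes differ")
    bmin, bmax = float(b.min()), float(b.max())
    if not (bmin - 1e-9 <= rho <= bmax + 1e-9):
        raise ValueError(
            f"infeasible gain target rho={rho:.6g}; attainable range "
            f"[{bmin:.6g}, {bmax:.6g}]"
        )
    rho = float(np.clip(rho, bmin, bmax))
    x0 = np.zeros(m)
    imin, imax = int(np.argmin(b)), int(np.argmax(b))
    if bmax - bmin < 1e-12:
        x0[:] = 1.0 / m
    else:
        alpha = (rho - bmin) / (bmax - bmin)
        x0[imax] += alpha
        x0[imin] += 1.0 - alpha
    E = np.vstack([np.ones(m), b])
    e = np.array([1.0, rho])
    Q = _ensure_pd(A.A)
    c, _ = solve_qp(Q, np.zeros(m), E, e, x0)
    s = c.sum()
    if s > 0:
        c = c / s
    return ContributionVector(c, list(ids) if ids else None)
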