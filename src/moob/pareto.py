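"""Pareto dominance, non-dominated sorting and dominance-based selection.

Dominance here is the multi-objective-optimization concept (not allelic
dominance): solution ``a`` dominates ``b`` when it is at least as good in
every objective and strictly better in at least one, after accounting for
each objective's direction of improvement.  Non-dominated sorting peels a
set of objective vectors into frontiers: level 1 is the non-dominated set,
level 2 the non-dominated set once level 1 is removed, and so on.

:func:`dominance_weights` turns such a sorting into parental contributions
— the "non-dominated selection" breeding strategy, which fills a selection
quota frontier by frontier and gives individuals on better (lower)
frontiers proportionally larger weights.

The module also houses the generic frontier containers
(:class:`FrontierSolution`, :class:`ParetoFrontier`) used by the
contribution-frontier, mating and decision-support modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Sequence

import numpy as np

from .core import ContributionVector

__all__ = [
    "ObjectiveVector",
    "DominanceSort",
    "FrontierSolution",
    "ParetoFrontier",
    "dominates",
    "nondominated_sort",
    "nondominated_mask",
    "dominance_weights",
]


@dataclass
class ObjectiveVector:
    """A point in objective space with per-objective improvement directions."""

    values: np.ndarray
    maximize: np.ndarray | Sequence[bool]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(v).all():
            raise ValueError("objective values must be finite")
        self.values = v
        self.maximize = np.asarray(self.maximize, dtype=bool).ravel()
        if self.maximize.shape != v.shape:
            raise ValueError("maximize flags do not match objective length")

    def oriented(self) -> np.ndarray:
        """Values with minimized objectives negated (larger = better)."""
        return np.where(self.maximize, self.values, -self.values)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DominanceSort:
    """Per-individual frontier index (1 = non-dominated) from a sorting."""

    levels: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.size == 0 or self.levels.min() != 1:
            raise ValueError("level-1 set must be non-empty")
        if self.n_levels != self.levels.max():
            raise ValueError("n_levels inconsistent with levels")

    def level_members(self, level: int) -> np.ndarray:
        return np.flatnonzero(self.levels == level)


def _check_compatible(a: ObjectiveVector, b: ObjectiveVector) -> None:
    if len(a) != len(b):
        raise ValueError("objective vectors have different lengths")
    if not np.array_equal(a.maximize, b.maximize):
        raise ValueError("objective vectors have different improvement directions")


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """True iff ``a`` Pareto-dominates ``b`` (irreflexive)."""
    _check_compatible(a, b)
    av, bv = a.oriented(), b.oriented()
    return bool(np.all(av >= bv) and np.any(av > bv))


def _oriented_matrix(
    points: Sequence[ObjectiveVector] | np.ndarray,
    maximize: Sequence[bool] | None,
) -> np.ndarray:
    if isinstance(points, np.ndarray) and points.ndim == 2:
        X = np.asarray(points, dtype=float)
        if maximize is None:
            maximize = np.ones(X.shape[1], dtype=bool)
        sign = np.where(np.asarray(maximize, dtype=bool), 1.0, -1.0)
        return X * sign
    pts = list(points)
    if not pts:
        raise ValueError("empty input")
    ref = pts[0]
    for p in pts[1:]:
        _check_compatible(ref, p)
    return np.array([p.oriented() for p in pts])


def nondominated_sort(
    points: Sequence[ObjectiveVector] | np.ndarray,
    maximize: Sequence[bool] | None = None,
) -> DominanceSort:
    """Fast non-dominated sort into frontier levels (peeling semantics).

    Accepts either a list of :class:`ObjectiveVector` (with identical
    direction flags) or a raw (n, k) array plus ``maximize`` flags.
    Duplicated points never dominate each other and share a level.
    Implementation: pairwise dominance bookkeeping with domination counts
    propagated front by front (O(k n^2) time, O(n^2) bits).
    """
    X = _oriented_matrix(points, maximize)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty input")
    # dom[i, j] True iff point i dominates point j
    ge = (X[:, None, :] >= X[None, :, :]).all(axis=2)
    gt = (X[:, None, :] > X[None, :, :]).any(axis=2)
    dom = ge & gt
    n_dominators = dom.sum(axis=0)
    levels = np.zeros(n, dtype=int)
    current = np.flatnonzero(n_dominators == 0)
    level = 1
    remaining = n
    counts = n_dominators.astype(int)
    while remaining:
        if current.size == 0:  # pragma: no cover - impossible for finite inputs
            raise RuntimeError("non-dominated sort failed to make progress")
        levels[current] = level
        remaining -= current.size
        counts = counts - dom[current].sum(axis=0)
        counts[levels > 0] = -1
        current = np.flatnonzero(counts == 0)
        level += 1
    return DominanceSort(levels, int(levels.max()))


def nondominated_mask(
    points: np.ndarray, maximize: Sequence[bool] | None = None
) -> np.ndarray:
    """Boolean mask of the non-dominated rows of an (n, k) objective array."""
    X = _oriented_matrix(np.asarray(points, dtype=float), maximize)
    ge = (X[:, None, :] >= X[None, :, :]).all(axis=2)
    gt = (X[:, None, :] > X[None, :, :]).any(axis=2)
    return ~(ge & gt).any(axis=0)


def dominance_weights(
    sort: DominanceSort,
    selected_fraction: float,
    individual_ids: Sequence[str] | None = None,
    scheme: str = "linear",
) -> ContributionVector:
    """Parental contributions from a dominance sorting.

    The selection quota ``selected_fraction * m`` is filled frontier by
    frontier starting from level 1; the level at which the quota is reached
    is included in full, deeper levels get zero.  Included individuals at
    level ``l`` are weighted proportionally to ``L* - l + 1`` (``scheme=
    "linear"``, the default) or ``1 / l`` (``scheme="inverse"``), where
    ``L*`` is the deepest included level, then normalized to sum to one —
    so earlier frontiers always receive at least as much weight per
    individual as later ones, and members of one level share a common
    weight.
    """
    if not 0.0 < selected_fraction <= 1.0:
        raise ValueError("selected_fraction must be in (0, 1]")
    levels = sort.levels
    m = levels.size
    quota = selected_fraction * m
    if quota < 1.0:
        raise ValueError(
            f"selection quota {quota:.2f} is smaller than one individual"
        )
    order = np.arange(1, sort.n_levels + 1)
    sizes = np.array([(levels == l).sum() for l in order])
    cum = np.cumsum(sizes)
    last = int(order[np.searchsorted(cum, quota - 1e-12, side="left")])
    w = np.zeros(m, dtype=float)
    included = levels <= last
    if scheme == "linear":
        w[included] = last - levels[included] + 1
    elif scheme == "inverse":
        w[included] = 1.0 / levels[included]
    elif callable(scheme):
        w[included] = np.asarray([scheme(l) for l in levels[included]], dtype=float)
        if np.any(w[included] < 0):
            raise ValueError("weight scheme produced negative weights")
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    w /= w.sum()
    return ContributionVector(w, list(individual_ids) if individual_ids else None)


@dataclass
class FrontierSolution:
    """One Pareto-frontier member: decision variables plus objectives.

    ``decision`` is a :class:`~moob.core.ContributionVector` for
    parental-proportion frontiers or a mating plan for genomic-mating
    frontiers.  ``scalarization_weights`` records the weight vector that
    produced the solution, when one did.
    """

    decision: Any
    objectives: ObjectiveVector
    scalarization_weights: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    @property
    def contribution(self) -> ContributionVector:
        if not isinstance(self.decision, ContributionVector):
            raise TypeError("decision variables are not a contribution vector")
        return self.decision


@dataclass
class ParetoFrontier:
    """A set of frontier solutions with dominance/duplicate pruning."""

    solutions: list[FrontierSolution]
    deduplicated: bool = False

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self) -> Iterator[FrontierSolution]:
        return iter(self.solutions)

    def __getitem__(self, i: int) -> FrontierSolution:
        return self.solutions[i]

    @property
    def maximize(self) -> np.ndarray:
        if not self.solutions:
            raise ValueError("empty frontier")
        return self.solutions[0].objectives.maximize

    def objective_matrix(self) -> np.ndarray:
        return np.array([s.objectives.values for s in self.solutions])

    def pruned(self, tol: float = 1e-6) -> "ParetoFrontier":
        """Drop dominated solutions and collapse near-duplicates.

        Solutions whose objective vectors differ by less than ``tol`` in
        sup-norm collapse to the first occurrence.
        """
        if not self.solutions:
            raise ValueError("empty frontier")
        X = self.objective_matrix()
        keep_mask = nondominated_mask(X, self.maximize)
        kept_idx = np.flatnonzero(keep_mask)
        unique: list[int] = []
        for i in kept_idx:
            if all(np.max(np.abs(X[i] - X[j])) >= tol for j in unique):
                unique.append(int(i))
        return ParetoFrontier([self.solutions[i] for i in unique], deduplicated=True)
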