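"""Multi-objective genomic mating: scoring and searching mating plans.

Where contribution optimization only fixes *how much* each candidate
contributes, genomic mating fixes *who is crossed with whom*.  A mating
plan — a multiset of parent pairs — is scored on 2k + 1 objectives for k
traits: per-trait expected progeny mean (mid-parent value, maximized),
per-trait expected within-cross progeny variance (maximized: segregating
crosses keep future selection gain alive), and expected progeny inbreeding
(parental kinship, minimized).  Plan-level values are multiplicity-
weighted means over the crosses, so plan size does not inflate objectives.

Two cross-variance estimators are provided: a closed form for fully
inbred parents under unlinked loci (the variance among progeny lines at
fixation, e.g. doubled haploids — each locus where the parents differ
contributes its squared effect), and a seeded simulation-based estimator
that honors linkage through the genetic map.  The plan space is searched
with an elitist non-dominated-sorting evolutionary algorithm
(:func:`search_mating_frontier`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix, MarkerEffects, RelationshipMatrix, genetic_values
from .pareto import (
    FrontierSolution,
    ObjectiveVector,
    ParetoFrontier,
    nondominated_mask,
)

__all__ = [
    "MatingPlan",
    "MatingObjectives",
    "cross_gain",
    "cross_variance",
    "simulated_cross_variance",
    "cross_inbreeding",
    "evaluate_plan",
    "search_mating_frontier",
]


@dataclass
class MatingPlan:
    """A multiset of parent pairs; repeated pairs encode multiplicity."""

    crosses: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.crosses:
            raise ValueError("a mating plan needs at least one cross")
        norm = []
        for i, j in self.crosses:
            i, j = int(i), int(j)
            if i < 0 or j < 0:
                raise ValueError("parent indices must be non-negative")
            norm.append((min(i, j), max(i, j)))
        self.crosses = norm

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    def with_multiplicity(self) -> list[tuple[int, int, int]]:
        """Unique (parent_i, parent_j, multiplicity) triples, sorted."""
        counts = Counter(self.crosses)
        return [(i, j, n) for (i, j), n in sorted(counts.items())]


@dataclass
class MatingObjectives:
    """Plan-level objective summary: per-trait gain and cross-variance
    means plus the mean expected progeny inbreeding."""

    gain: np.ndarray
    cross_variance: np.ndarray
    inbreeding: float

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float).ravel()
        self.cross_variance = np.asarray(self.cross_variance, dtype=float).ravel()
        if np.any(self.cross_variance < -1e-10):
            raise ValueError("cross-variance must be non-negative")
        self.cross_variance = np.clip(self.cross_variance, 0.0, None)

    def to_objective_vector(self) -> ObjectiveVector:
        k = self.gain.size
        return ObjectiveVector(
            np.concatenate([self.gain, self.cross_variance, [self.inbreeding]]),
            np.concatenate([np.ones(2 * k, bool), [False]]),
        )


def _check_parent(G: GenotypeMatrix, i: int) -> None:
    if not 0 <= i < G.n_individuals:
        raise IndexError(f"parent index {i} out of range 0..{G.n_individuals - 1}")


def cross_gain(
    G: GenotypeMatrix, E: MarkerEffects, i: int, j: int, trait: int = 0
) -> float:
    """Expected progeny mean of a cross: the mid-parent genetic value."""
    _check_parent(G, i)
    _check_parent(G, j)
    vals = genetic_values(G, E).values[:, trait]
    return float(0.5 * (vals[i] + vals[j]))


def _dh_locus_variance(di: np.ndarray, dj: np.ndarray) -> np.ndarray:
    """Per-locus dosage variance among progeny lines at fixation.

    A derived line inherits, at each locus, a doubled allele drawn with
    probability q = (d_i + d_j) / 4 under unlinked loci, giving dosage
    variance 4 q (1 - q).  Reduces to the indicator "parents differ" for
    fully inbred parents."""
    q = (di + dj) / 4.0
    return 4.0 * q * (1.0 - q)


def cross_variance(
    G: GenotypeMatrix, E: MarkerEffects, i: int, j: int, trait: int = 0
) -> float:
    """Expected within-cross variance of progeny-line values (unlinked loci).

    Requires fully inbred parents (dosages in {0, 2}); each locus where
    the parents carry different alleles contributes its squared effect.
    For heterozygous parents use :func:`simulated_cross_variance`.
    """
    _check_parent(G, i)
    _check_parent(G, j)
    di = G.dosages[i].astype(float)
    dj = G.dosages[j].astype(float)
    if np.any(di == 1) or np.any(dj == 1):
        raise ValueError(
            "cross_variance requires fully inbred parents; "
            "use simulated_cross_variance for heterozygous parents"
        )
    seg = di != dj
    return float(np.sum(E.beta[seg, trait] ** 2))


def simulated_cross_variance(
    G: GenotypeMatrix,
    E: MarkerEffects,
    i: int,
    j: int,
    trait: int = 0,
    n_progeny: int = 500,
    seed: int = 0,
) -> float:
    """Monte-Carlo cross variance honoring linkage via the genetic map.

    Simulates derived (doubled-haploid) progeny of the cross: one gamete
    from each parent forms the F1, one recombinant F1 gamete is doubled
    per progeny.  Crossovers per chromosome are Poisson in map length with
    uniform positions (no interference), so linkage between nearby loci is
    respected.  Heterozygous parents are phased at random (seeded) — with
    no phase information this is an explicit assumption.  Returns the
    sample variance of the progeny genetic values.
    """
    from .sim import _gamete, _chromosome_blocks  # local import: sim uses mating too

    _check_parent(G, i)
    _check_parent(G, j)
    if n_progeny < 2:
        raise ValueError("need at least 2 progeny")
    rng = np.random.default_rng(seed)
    blocks = _chromosome_blocks(G.chromosomes, G.positions)

    def phased(d: np.ndarray) -> np.ndarray:
        h = np.zeros((2, d.size), dtype=np.int8)
        h[:, d == 2] = 1
        het = np.flatnonzero(d == 1)
        pick = rng.integers(0, 2, size=het.size)
        h[pick, het] = 1
        return h

    hi, hj = phased(G.dosages[i]), phased(G.dosages[j])
    beta = E.beta[:, trait]
    vals = np.empty(n_progeny)
    for p in range(n_progeny):
        f1 = np.stack([_gamete(hi, blocks, rng), _gamete(hj, blocks, rng)])
        dh = 2.0 * _gamete(f1, blocks, rng)
        vals[p] = dh @ beta
    return float(np.var(vals, ddof=1))


def cross_inbreeding(A: RelationshipMatrix, i: int, j: int) -> float:
    """Expected progeny inbreeding coefficient: parental kinship A_ij / 2."""
    n = A.n_individuals
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"parent index out of range 0..{n - 1}")
    return float(A.A[i, j] / 2.0)


def _plan_tables(
    G: GenotypeMatrix, E: MarkerEffects
) -> tuple[np.ndarray, np.ndarray]:
    """Per-candidate trait values and per-trait pairwise cross-variance
    matrices (unlinked-loci derived-line closed form), in matrix form."""
    D = G.dosages.astype(float)
    vals = D @ E.beta  # (m, k)
    k = E.n_traits
    m = D.shape[0]
    varmats = np.empty((k, m, m))
    for t in range(k):
        b2 = E.beta[:, t] ** 2
        u = D @ b2  # sum beta^2 d_i
        w = (D**2) @ b2
        cross = (D * b2) @ D.T
        S = u[:, None] + u[None, :]
        S2 = w[:, None] + w[None, :] + 2.0 * cross
        varmats[t] = S - 0.25 * S2  # sum beta^2 (S_l - S_l^2 / 4)
    return vals, np.clip(varmats, 0.0, None)


def evaluate_plan(
    P: MatingPlan,
    G: GenotypeMatrix,
    E: MarkerEffects,
    A: RelationshipMatrix,
    _tables: tuple[np.ndarray, np.ndarray] | None = None,
) -> MatingObjectives:
    """Score a plan: multiplicity-weighted means over its crosses.

    Cross variance uses the unlinked-loci derived-line closed form, which
    coincides with :func:`cross_variance` for fully inbred parents and
    generalizes it smoothly to heterozygous ones.
    """
    vals, varmats = _plan_tables(G, E) if _tables is None else _tables
    ii = np.array([c[0] for c in P.crosses])
    jj = np.array([c[1] for c in P.crosses])
    if ii.max(initial=0) >= G.n_individuals or jj.max(initial=0) >= G.n_individuals:
        raise IndexError("plan refers to a parent outside the candidate set")
    gains = 0.5 * (vals[ii] + vals[jj]).mean(axis=0)
    cvars = varmats[:, ii, jj].mean(axis=1)
    inb = float((A.A[ii, jj] / 2.0).mean())
    return MatingObjectives(gains, cvars, inb)


def _crowding_distance(X: np.ndarray) -> np.ndarray:
    n, k = X.shape
    d = np.zeros(n)
    for t in range(k):
        order = np.argsort(X[:, t], kind="stable")
        rng = X[order[-1], t] - X[order[0], t]
        d[order[0]] = d[order[-1]] = np.inf
        if rng > 1e-12 and n > 2:
            d[order[1:-1]] += (X[order[2:], t] - X[order[:-2], t]) / rng
    return d


def search_mating_frontier(
    candidates: GenotypeMatrix,
    E: MarkerEffects,
    A: RelationshipMatrix,
    n_crosses: int,
    search_opts: dict | None = None,
    seed: int = 0,
    allow_selfing: bool = True,
) -> ParetoFrontier:
    """Evolutionary search for the non-dominated set of mating plans.

    An elitist non-dominated-sorting genetic algorithm over fixed-size
    plans: binary tournament on (dominance level, crowding distance),
    plan crossover recombines the parents' cross lists slot by slot,
    mutation replaces one parent of a random cross.  An external archive
    keeps every non-dominated plan objective encountered, so the archive
    only improves across generations.  Deterministic for a given seed.

    ``search_opts`` keys (defaults): ``pop_size`` 100, ``generations``
    200, ``mutation_rate`` 0.1 per cross.
    """
    m = candidates.n_individuals
    if m < 2:
        raise ValueError("need at least 2 candidates")
    if n_crosses < 1:
        raise ValueError("n_crosses must be >= 1")
    opts = {"pop_size": 100, "generations": 200, "mutation_rate": 0.1}
    opts.update(search_opts or {})
    pop_size = int(opts["pop_size"])
    generations = int(opts["generations"])
    mut = float(opts["mutation_rate"])
    rng = np.random.default_rng(seed)
    tables = _plan_tables(candidates, E)

    def random_pair() -> tuple[int, int]:
        while True:
            i, j = int(rng.integers(m)), int(rng.integers(m))
            if allow_selfing or i != j:
                return (min(i, j), max(i, j))

    def evaluate(plan: list[tuple[int, int]]) -> np.ndarray:
        return (
            evaluate_plan(MatingPlan(list(plan)), candidates, E, A, _tables=tables)
            .to_objective_vector()
            .values
        )

    maximize = np.concatenate([np.ones(2 * E.n_traits, bool), [False]])
    pop = [[random_pair() for _ in range(n_crosses)] for _ in range(pop_size)]
    objs = np.array([evaluate(p) for p in pop])

    archive: list[tuple[tuple[tuple[int, int], ...], np.ndarray]] = []

    def update_archive(plans, values) -> None:
        nonlocal archive
        entries = archive + [
            (tuple(sorted(p)), v) for p, v in zip(plans, values)
        ]
        X = np.array([v for _, v in entries])
        keep = nondominated_mask(X, maximize)
        seen: list[np.ndarray] = []
        new: list = []
        for flag, entry in zip(keep, entries):
            if not flag:
                continue
            if any(np.max(np.abs(entry[1] - s)) < 1e-9 for s in seen):
                continue
            seen.append(entry[1])
            new.append(entry)
        archive = new

    update_archive(pop, objs)

    def rank_and_crowd(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        from .pareto import nondominated_sort

        sort = nondominated_sort(values, maximize)
        crowd = np.zeros(len(values))
        for level in range(1, sort.n_levels + 1):
            idx = sort.level_members(level)
            crowd[idx] = _crowding_distance(values[idx])
        return sort.levels, crowd

    for _ in range(generations):
        levels, crowd = rank_and_crowd(objs)

        def tournament() -> int:
            a, b = rng.integers(len(pop)), rng.integers(len(pop))
            if levels[a] != levels[b]:
                return int(a if levels[a] < levels[b] else b)
            return int(a if crowd[a] >= crowd[b] else b)

        children = []
        for _ in range(pop_size):
            pa, pb = pop[tournament()], pop[tournament()]
            child = [
                pa[s] if rng.random() < 0.5 else pb[s] for s in range(n_crosses)
            ]
            for s in range(n_crosses):
                if rng.random() < mut:
                    i, j = child[s]
                    repl = int(rng.integers(m))
                    keep = j if rng.random() < 0.5 else i
                    if not allow_selfing and repl == keep:
                        repl = (repl + 1) % m
                    child[s] = (min(keep, repl), max(keep, repl))
            children.append(child)
        child_objs = np.array([evaluate(p) for p in children])
        update_archive(children, child_objs)
        all_pop = pop + children
        all_objs = np.vstack([objs, child_objs])
        levels, crowd = rank_and_crowd(all_objs)
        order = np.lexsort((-crowd, levels))[:pop_size]
        pop = [all_pop[i] for i in order]
        objs = all_objs[order]

    solutions = [
        FrontierSolution(
            decision=MatingPlan(list(p)),
            objectives=ObjectiveVector(v, maximize.copy()),
        )
        for p, v in archive
    ]
    return ParetoFrontier(solutions, deduplicated=True)
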