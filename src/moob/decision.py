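"""Decision support for picking a preferred solution on a Pareto frontier.

A traced frontier is only half an answer: the breeder still has to commit
to one compromise.  This module implements the standard aids:

* :func:`ideal_point` — the (usually infeasible) objective vector
  combining the best attainable value of each objective separately;
* :func:`select_by_global_criterion` — the frontier member closest to the
  ideal point under a weighted p-norm on normalized axes, the rule used to
  automate frontier picks inside breeding simulations;
* :func:`find_knee` — the chord rule: the solution farthest from the line
  joining the two frontier endpoints, i.e. the region where a small gain
  in one objective starts costing a lot in the other;
* :func:`som_fit` — a batch-trained Kohonen self-organizing map giving a
  topology-preserving 2-d layout of high-dimensional frontiers.

All methods first orient objectives so smaller is better and (by default)
min-max normalize each axis over the frontier, making the choice invariant
to the scale of individual objectives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pareto import FrontierSolution, ObjectiveVector, ParetoFrontier

__all__ = [
    "DecisionConfig",
    "SomGrid",
    "ideal_point",
    "select_by_global_criterion",
    "find_knee",
    "som_fit",
]


@dataclass
class DecisionConfig:
    """Importance weights over the k + 1 objectives plus a normalization.

    Weights must be non-negative and sum to one (within 1e-8); they follow
    the frontier's own objective order.  ``normalization`` is one of
    ``minmax`` (default), ``zscore`` or ``none``; ``p_norm`` sets the
    exponent of the distance to the ideal point (2 = weighted Euclidean).
    """

    weights: np.ndarray
    normalization: str = "minmax"
    p_norm: float = 2.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError(f"weights sum to {w.sum():.10f}, expected 1")
        if self.normalization not in ("minmax", "zscore", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self.weights = w


@dataclass
class SomGrid:
    """Fitted self-organizing map: prototype grid plus assignments."""

    codebook: np.ndarray  # (u, v, k) prototypes in normalized objective space
    assignments: np.ndarray  # (n, 2) best-matching-unit grid coordinates
    quantization_error: float
    initial_quantization_error: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.codebook).all():
            raise ValueError("codebook contains non-finite entries")


def _cost_matrix(F: ParetoFrontier) -> np.ndarray:
    """Objectives oriented so smaller is better."""
    if len(F) == 0:
        raise ValueError("empty frontier")
    X = F.objective_matrix()
    sign = np.where(F.maximize, -1.0, 1.0)
    return X * sign


def _normalize(C: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "minmax":
        lo = C.min(axis=0)
        rng = C.max(axis=0) - lo
        Z = np.zeros_like(C)
        ok = rng > 1e-12
        Z[:, ok] = (C[:, ok] - lo[ok]) / rng[ok]
        # degenerate (zero-range) axes contribute zero distance
        return Z
    if normalization == "zscore":
        mu = C.mean(axis=0)
        sd = C.std(axis=0, ddof=0)
        Z = np.zeros_like(C)
        ok = sd > 1e-12
        Z[:, ok] = (C[:, ok] - mu[ok]) / sd[ok]
        return Z
    return C.copy()


def ideal_point(F: ParetoFrontier) -> ObjectiveVector:
    """Componentwise best (direction-aware) objective vector of a frontier."""
    C = _cost_matrix(F)
    best_cost = C.min(axis=0)
    sign = np.where(F.maximize, -1.0, 1.0)
    return ObjectiveVector(best_cost * sign, F.maximize.copy())


def _coancestry_axis(F: ParetoFrontier) -> int:
    """Index of the co-ancestry-like axis used for tie-breaking: the last
    minimized objective (frontier convention: gains first, co-ancestry
    last), falling back to the last axis."""
    minimized = np.flatnonzero(~F.maximize)
    return int(minimized[-1]) if minimized.size else len(F.maximize) - 1


def select_by_global_criterion(
    F: ParetoFrontier, cfg: DecisionConfig
) -> FrontierSolution:
    """Frontier member minimizing the weighted distance to the ideal point.

    Each axis is normalized per ``cfg.normalization`` (the ideal point maps
    to the componentwise minimum in cost space), then the weighted p-norm
    distance is minimized.  Ties (within 1e-12) break by lowest
    co-ancestry, then input order.
    """
    if len(F) == 0:
        raise ValueError("empty frontier")
    Z = _normalize(_cost_matrix(F), cfg.normalization)
    ideal = Z.min(axis=0)
    diff = np.abs(Z - ideal)
    dist = (cfg.weights * diff**cfg.p_norm).sum(axis=1) ** (1.0 / cfg.p_norm)
    best = dist.min()
    tied = np.flatnonzero(dist <= best + 1e-12)
    if tied.size > 1:
        ax = _coancestry_axis(F)
        C = _cost_matrix(F)
        tied = tied[np.argsort(C[tied, ax], kind="stable")]
    return F[int(tied[0])]


def find_knee(
    F: ParetoFrontier, axes: tuple[int, int] | None = None
) -> FrontierSolution:
    """Chord-rule knee of a (projected) two-objective frontier.

    Axes are min-max normalized; the knee is the solution with the largest
    perpendicular distance to the chord joining the two frontier endpoints
    (the extremes along the first chosen axis).  For frontiers with more
    than two objectives the caller picks the two axes (default: first
    objective vs last, typically gain vs co-ancestry).  If all points are
    collinear no knee is pronounced: the first solution by the tie rule is
    returned with ``info["no_pronounced_knee"] = True``.
    """
    if len(F) < 3:
        raise ValueError("need at least 3 solutions for knee detection; "
                         "use the global criterion instead")
    n_obj = len(F.maximize)
    if axes is None:
        axes = (0, n_obj - 1)
    i, j = axes
    Z = _normalize(_cost_matrix(F)[:, [i, j]], "minmax")
    order = np.lexsort((Z[:, 1], Z[:, 0]))
    p0, p1 = Z[order[0]], Z[order[-1]]
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm < 1e-12:
        dist = np.zeros(len(F))
    else:
        rel = Z - p0
        dist = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm
    best = dist.max()
    if best < 1e-9:
        sol = F[0]
        return replace(sol, info={**sol.info, "no_pronounced_knee": True})
    tied = np.flatnonzero(dist >= best - 1e-12)
    return F[int(tied[0])]


def som_fit(
    F: ParetoFrontier,
    grid: tuple[int, int] = (6, 6),
    epochs: int = 50,
    seed: int = 0,
) -> SomGrid:
    """Batch Kohonen training on the frontier's normalized objectives.

    The (u, v) codebook is initialized deterministically on the first two
    principal axes of the normalized objective cloud, then refined by
    batch updates with a Gaussian neighborhood whose radius decays
    linearly from max(u, v) / 2 to 0.5 over the epochs.  ``seed`` only
    matters when the principal axes are degenerate (tiny jitter).  Nearby
    frontier points map to nearby grid units, making the map a 2-d chart
    of high-dimensional trade-off surfaces.
    """
    u, v = grid
    if u * v < 2:
        raise ValueError("SOM grid must have at least 2 units")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if len(F) < 2:
        raise ValueError("need at least 2 solutions to fit a SOM")
    X = _normalize(_cost_matrix(F), "minmax")
    n, k = X.shape
    rng = np.random.default_rng(seed)
    mu = X.mean(axis=0)
    Xc = X - mu
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scale = S / max(np.sqrt(n), 1.0)
    pc = np.zeros((2, k))
    pc[: min(2, Vt.shape[0])] = Vt[:2] * scale[:2, None][: min(2, len(S))]
    if np.linalg.norm(pc) < 1e-12:
        pc = rng.normal(scale=1e-6, size=(2, k))
    gi = np.linspace(-2.0, 2.0, u) if u > 1 else np.zeros(1)
    gj = np.linspace(-2.0, 2.0, v) if v > 1 else np.zeros(1)
    codebook = (
        mu
        + gi[:, None, None] * pc[0][None, None, :]
        + gj[None, :, None] * pc[1][None, None, :]
    )
    coords = np.stack(np.meshgrid(np.arange(u), np.arange(v), indexing="ij"), -1)
    coords = coords.reshape(-1, 2).astype(float)  # (u*v, 2)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)

    def bmus(cb_flat: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - cb_flat[None, :, :]) ** 2).sum(-1)
        return d2.argmin(axis=1)

    cb = codebook.reshape(-1, k)
    qe0 = float(np.sqrt(((X - cb[bmus(cb)]) ** 2).sum(-1)).mean())
    r_start, r_end = max(u, v) / 2.0, 0.5
    for epoch in range(epochs):
        t = epoch / max(epochs - 1, 1)
        radius = r_start + (r_end - r_start) * t
        b = bmus(cb)
        H = np.exp(-grid_d2[:, b] / (2.0 * radius**2))  # (units, n)
        denom = H.sum(axis=1)
        num = H @ X
        ok = denom > 1e-12
        cb[ok] = num[ok] / denom[ok, None]
    b = bmus(cb)
    qe = float(np.sqrt(((X - cb[b]) ** 2).sum(-1)).mean())
    return SomGrid(
        codebook=cb.reshape(u, v, k),
        assignments=coords[b].astype(int),
        quantization_error=qe,
        initial_quantization_error=qe0,
    )
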