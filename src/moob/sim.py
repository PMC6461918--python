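"""Forward-in-time breeding simulation and strategy comparison.

The simulated system follows a classical two-trait quantitative-genetic
design: a population of N individuals genotyped at 1000 SNPs on each of
three 1-Morgan chromosomes, descended from two complementary fully inbred
founders through 100 generations of random mating.  Two traits are
controlled by 200 QTL per chromosome; at 100 of those the two traits carry
opposite-signed effects, which makes the traits negatively genetically
correlated — the hard case for multi-trait selection.  Environmental noise
is calibrated so each trait has heritability 0.5, and is re-calibrated
every cycle so heritability stays constant as genetic variance changes.

Meiosis draws a Poisson number of crossovers per chromosome (mean = map
length in Morgans) at uniform positions with no interference, so
recombination fractions follow the Haldane map function.

On top of this engine, :func:`run_breeding` executes one breeding program
under a configurable strategy — tandem, independent culling, index,
non-dominated selection, multi-objective optimized parental proportions
(plain or correlation-penalized co-ancestry), or genomic mating — and
:func:`run_experiment` replicates several strategies from identical base
populations, which is how the long-term comparisons are produced.
Genomic strategies refit a GBLUP prediction model on the phenotypes of
every odd-numbered cycle and reuse the stored marker effects in the next
even cycle.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import decision as decision_mod
from . import frontier as frontier_mod
from . import mating as mating_mod
from . import pareto as pareto_mod
from .core import (
    BreedingValues,
    GenotypeMatrix,
    MarkerEffects,
    compute_relationship,
    estimate_genetic_correlations,
)

__all__ = [
    "SimulationConfig",
    "TraitArchitecture",
    "BreedingState",
    "StrategyConfig",
    "GblupModel",
    "make_founders",
    "make_base_population",
    "meiosis",
    "predict_gebv",
    "apply_strategy",
    "run_breeding",
    "run_experiment",
    "SimulationResult",
    "ExperimentResult",
    "STRATEGIES",
]

STRATEGIES = (
    "tandem",
    "culling",
    "index",
    "nondominated",
    "moob_pp_eq1",
    "moob_pp_eq2",
    "genomic_mating",
)


@dataclass
class SimulationConfig:
    """Population and trait-architecture parameters of the simulated study."""

    pop_size: int = 100
    n_markers_per_chrom: int = 1000
    n_chrom: int = 3
    n_qtl_per_chrom: int = 200
    n_opposite_sign: int = 100
    h2: float = 0.5
    burnin_random_mating: int = 100
    base_tandem_rounds: int = 10
    base_selection_intensity: float = 0.5
    n_cycles_gs: int = 16
    n_cycles_ps: int = 10
    chrom_length_morgans: float = 1.0
    n_traits: int = 2

    def __post_init__(self) -> None:
        if self.pop_size < 20:
            raise ValueError("pop_size must be >= 20")
        if self.n_opposite_sign > self.n_qtl_per_chrom:
            raise ValueError("n_opposite_sign cannot exceed n_qtl_per_chrom")
        if not 0 < self.base_selection_intensity <= 1:
            raise ValueError("selection intensity must be in (0, 1]")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if self.n_traits != 2:
            raise ValueError("the two-trait architecture is fixed at 2 traits")


@dataclass
class TraitArchitecture:
    """QTL positions and effects of the two simulated traits."""

    qtl_indices: np.ndarray  # global marker indices of all QTL
    opposite_indices: np.ndarray  # subset with opposite-signed effects
    effects: MarkerEffects  # full-length (n_markers x 2), zero off-QTL
    environmental_sd: np.ndarray  # per trait, kept in sync with h2

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        self.opposite_indices = np.asarray(self.opposite_indices, dtype=int)
        if not np.isin(self.opposite_indices, self.qtl_indices).all():
            raise ValueError("opposite-sign QTL must be a subset of the QTL")
        self.environmental_sd = np.asarray(self.environmental_sd, dtype=float)


@dataclass
class BreedingState:
    """One population snapshot inside a breeding program."""

    generation: int
    haplotypes: np.ndarray  # (m, 2, n) 0/1 alleles
    chromosomes: np.ndarray
    positions: np.ndarray
    architecture: TraitArchitecture
    true_bv: BreedingValues
    phenotypes: np.ndarray
    gebv: BreedingValues | None = None
    marker_effects_hat: MarkerEffects | None = None
    trajectory: list[dict] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1)

    def genotypes(self) -> GenotypeMatrix:
        return GenotypeMatrix.from_dosages(
            self.dosages(), self.chromosomes, self.positions
        )

    def clone(self) -> "BreedingState":
        new = copy.copy(self)
        new.haplotypes = self.haplotypes.copy()
        new.phenotypes = self.phenotypes.copy()
        new.trajectory = [dict(r) for r in self.trajectory]
        return new


@dataclass
class StrategyConfig:
    """How parents are chosen each cycle.

    ``decision_weights`` follow the simulation protocol's ordering
    (co-ancestry/inbreeding first, then the trait gains); when ``None``
    they resolve by population size — (0.95, 0.025, 0.025) up to N = 200
    and (0.9, 0.05, 0.05) for larger populations, i.e. selection intensity
    is raised for big populations by shifting weight from the co-ancestry
    axis to the gains.
    """

    strategy: str
    selection_fraction: float = 0.5
    index_weights: Sequence[float] = (0.5, 0.5)
    culling_quantile: float = 0.4
    decision_weights: Sequence[float] | None = None
    frontier_resolution: int = 13
    n_crosses: int | None = None
    gm_search_opts: dict | None = None
    gm_variance_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}"
            )
        if not 0 < self.selection_fraction <= 1:
            raise ValueError("selection_fraction must be in (0, 1]")

    def resolved_decision_weights(self, pop_size: int, k: int) -> np.ndarray:
        if self.decision_weights is not None:
            w = np.asarray(self.decision_weights, dtype=float)
        elif pop_size <= 200:
            w = np.concatenate([[0.95], np.full(k, 0.05 / k)])
        else:
            w = np.concatenate([[0.9], np.full(k, 0.1 / k)])
        if w.size != k + 1:
            raise ValueError(f"need {k + 1} decision weights, got {w.size}")
        return w / w.sum()


# ---------------------------------------------------------------------------
# meiosis


def _chromosome_blocks(chromosomes: np.ndarray, positions: np.ndarray):
    """Contiguous (start, stop, positions, map length) runs per chromosome."""
    blocks = []
    n = len(chromosomes)
    start = 0
    for i in range(1, n + 1):
        if i == n or chromosomes[i] != chromosomes[start]:
            pos = positions[start:i]
            blocks.append((start, i, pos, float(pos[-1] - pos[0])))
            start = i
    return blocks


def _gamete(hap: np.ndarray, blocks, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a (2, n) haplotype pair.

    Per chromosome: crossover count ~ Poisson(map length in Morgans),
    positions uniform, no interference; the starting haplotype is chosen
    at random per chromosome.
    """
    n = hap.shape[1]
    out = np.empty(n, dtype=hap.dtype)
    for s, e, pos, length in blocks:
        start = int(rng.integers(2))
        k = int(rng.poisson(length)) if length > 0 else 0
        if k == 0:
            out[s:e] = hap[start, s:e]
        else:
            cuts = np.sort(rng.uniform(pos[0], pos[0] + length, size=k))
            idx = (start + np.searchsorted(cuts, pos, side="right")) % 2
            out[s:e] = hap[:, s:e][idx, np.arange(e - s)]
    return out


def meiosis(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    chromosomes: np.ndarray,
    positions: np.ndarray,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Offspring genome (2, n): one recombinant gamete from each parent."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    blocks = _chromosome_blocks(np.asarray(chromosomes), np.asarray(positions, float))
    return np.stack(
        [_gamete(np.asarray(parent_a), blocks, rng),
         _gamete(np.asarray(parent_b), blocks, rng)]
    )


def _next_generation(
    haplotypes: np.ndarray,
    parent_pairs: np.ndarray,
    blocks,
    rng: np.random.Generator,
) -> np.ndarray:
    n_off = parent_pairs.shape[0]
    out = np.empty((n_off, 2, haplotypes.shape[2]), dtype=haplotypes.dtype)
    for i in range(n_off):
        pa, pb = parent_pairs[i]
        out[i, 0] = _gamete(haplotypes[pa], blocks, rng)
        out[i, 1] = _gamete(haplotypes[pb], blocks, rng)
    return out


# ---------------------------------------------------------------------------
# founders and phenotypes


def _true_values(haplotypes: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    return haplotypes.sum(axis=1).astype(float) @ arch.effects.beta


def _calibrate_environment(g: np.ndarray, h2: float) -> np.ndarray:
    """Environmental SD per trait so that var(g) / var(p) = h2."""
    var_g = g.var(axis=0, ddof=1)
    return np.sqrt(np.clip(var_g, 0.0, None) * (1.0 - h2) / h2)


def _phenotype(
    g: np.ndarray, arch: TraitArchitecture, h2: float, rng: np.random.Generator
) -> np.ndarray:
    arch.environmental_sd = _calibrate_environment(g, h2)
    return g + rng.standard_normal(g.shape) * arch.environmental_sd


def make_founders(
    cfg: SimulationConfig, seed: int | np.random.Generator = 0
) -> BreedingState:
    """Founder population: two complementary inbred lines, random mating.

    The two founders carry opposite alleles at every marker; N copies of
    their F1 are put through ``burnin_random_mating`` generations of
    random mating (parents drawn uniformly with replacement), yielding a
    population of recombinant mosaics.  The two-trait QTL architecture is
    attached, environmental noise is calibrated so each trait's
    heritability equals ``cfg.h2``, and phenotypes are drawn.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_per, n_chr = cfg.n_markers_per_chrom, cfg.n_chrom
    chromosomes = np.repeat(np.arange(1, n_chr + 1), n_per)
    positions = np.concatenate(
        [np.sort(rng.uniform(0.0, cfg.chrom_length_morgans, n_per)) for _ in range(n_chr)]
    )
    n = n_per * n_chr
    qtl, opposite = [], []
    beta = np.zeros((n, 2))
    for c in range(n_chr):
        base = c * n_per
        idx = base + np.sort(rng.choice(n_per, size=cfg.n_qtl_per_chrom, replace=False))
        opp = rng.choice(idx, size=cfg.n_opposite_sign, replace=False)
        b1 = rng.standard_normal(cfg.n_qtl_per_chrom)
        b2 = rng.standard_normal(cfg.n_qtl_per_chrom)
        beta[idx, 0] = b1
        beta[idx, 1] = b2
        # opposite-signed QTL: trait-2 effect forced opposite to trait 1,
        # the source of the negative genetic correlation between traits
        pos_in_idx = np.searchsorted(idx, np.sort(opp))
        beta[np.sort(opp), 1] = -np.sign(beta[np.sort(opp), 0]) * np.abs(
            b2[pos_in_idx]
        )
        qtl.append(idx)
        opposite.append(np.sort(opp))
    arch = TraitArchitecture(
        qtl_indices=np.concatenate(qtl),
        opposite_indices=np.concatenate(opposite),
        effects=MarkerEffects(beta, ["trait1", "trait2"]),
        environmental_sd=np.ones(2),
    )
    N = cfg.pop_size
    f1 = np.stack([np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)])
    haps = np.repeat(f1[None, :, :], N, axis=0)
    blocks = _chromosome_blocks(chromosomes, positions)
    for _ in range(cfg.burnin_random_mating):
        pairs = rng.integers(N, size=(N, 2))
        haps = _next_generation(haps, pairs, blocks, rng)
    g = _true_values(haps, arch)
    phen = _phenotype(g, arch, cfg.h2, rng)
    state = BreedingState(
        generation=0,
        haplotypes=haps,
        chromosomes=chromosomes,
        positions=positions,
        architecture=arch,
        true_bv=BreedingValues(g, ["trait1", "trait2"]),
        phenotypes=phen,
    )
    return state


def make_base_population(
    cfg: SimulationConfig, seed: int | np.random.Generator = 0
) -> BreedingState:
    """Base population for the strategy comparison: founders put through
    ``base_tandem_rounds`` rounds of phenotypic tandem selection at
    ``base_selection_intensity`` (traits alternating by round)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = make_founders(cfg, rng)
    blocks = _chromosome_blocks(state.chromosomes, state.positions)
    N = cfg.pop_size
    n_sel = max(2, int(round(N * cfg.base_selection_intensity)))
    for r in range(cfg.base_tandem_rounds):
        trait = r % 2
        order = np.argsort(-state.phenotypes[:, trait], kind="stable")
        selected = order[:n_sel]
        pairs = selected[rng.integers(n_sel, size=(N, 2))]
        state.haplotypes = _next_generation(state.haplotypes, pairs, blocks, rng)
        g = _true_values(state.haplotypes, state.architecture)
        state.true_bv = BreedingValues(g, ["trait1", "trait2"])
        state.phenotypes = _phenotype(g, state.architecture, cfg.h2, rng)
        state.generation += 1
    return state


# ---------------------------------------------------------------------------
# genomic prediction


@dataclass
class GblupModel:
    """Per-trait GBLUP fit, stored as backsolved marker effects.

    Ridge shrinkage on the genomic relationship matrix with ratio
    (1 - h2) / h2; the fitted model predicts centered GEBVs for any new
    genotypes via its marker effects.
    """

    beta: np.ndarray  # (n_markers, k)
    train_freqs: np.ndarray
    train_means: np.ndarray

    def predict(self, dosages: np.ndarray) -> np.ndarray:
        Z = dosages.astype(float) - 2.0 * self.train_freqs
        return Z @ self.beta


def fit_gblup(
    dosages: np.ndarray, phenotypes: np.ndarray, h2_assumed: float
) -> tuple[np.ndarray, GblupModel]:
    """Fit per-trait GBLUP; returns training GEBVs and the model.

    Solves (K + lambda I) alpha = y_centered with K the VanRaden
    relationship of the training set and lambda = (1 - h2) / h2, then
    backsolves marker effects beta = Z' alpha / denom so the model can be
    carried to new genotypes.  h2_assumed -> 1 reproduces the centered
    phenotypes; h2_assumed -> 0 shrinks all GEBVs to zero.
    """
    if not 0 < h2_assumed < 1:
        raise ValueError("h2_assumed must be in (0, 1)")
    D = np.asarray(dosages, dtype=float)
    Y = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    if Y.shape[0] != D.shape[0]:
        raise ValueError("phenotype rows do not match genotype rows")
    m, n = D.shape
    p = D.mean(axis=0) / 2.0
    Z = D - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    k = Y.shape[1]
    beta = np.zeros((n, k))
    gebv = np.zeros((m, k))
    means = Y.mean(axis=0)
    if denom > 0:
        K = Z @ Z.T / denom
        lam = (1.0 - h2_assumed) / h2_assumed
        M = K + lam * np.eye(m) + 1e-10 * np.eye(m)
        for t in range(k):
            yc = Y[:, t] - means[t]
            if yc.std() < 1e-12:
                continue
            try:
                alpha = np.linalg.solve(M, yc)
            except np.linalg.LinAlgError:
                alpha = np.linalg.solve(M + 1e-6 * np.eye(m), yc)
            gebv[:, t] = K @ alpha
            beta[:, t] = Z.T @ alpha / denom
    model = GblupModel(beta=beta, train_freqs=p, train_means=means)
    return gebv, model


def predict_gebv(
    training: BreedingState, h2_assumed: float
) -> tuple[BreedingValues, GblupModel]:
    """GBLUP GEBVs for a population from its own phenotypes."""
    gebv, model = fit_gblup(training.dosages(), training.phenotypes, h2_assumed)
    names = list(training.architecture.effects.trait_names)
    return BreedingValues(gebv, names), model


# ---------------------------------------------------------------------------
# strategies


def _top_fraction(scores: np.ndarray, fraction: float) -> np.ndarray:
    m = scores.size
    n_sel = max(2, int(round(m * fraction)))
    order = np.argsort(-scores, kind="stable")
    return order[:n_sel]


def _uniform_contribution(m: int, selected: np.ndarray):
    from .core import ContributionVector

    c = np.zeros(m)
    c[selected] = 1.0 / selected.size
    return ContributionVector(c)


def _safe_zscores(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    Z = np.zeros_like(values)
    ok = sd > 1e-9
    Z[:, ok] = (values[:, ok] - mu[ok]) / sd[ok]
    return Z


def apply_strategy(
    state: BreedingState,
    scfg: StrategyConfig,
    cycle: int,
    rng: np.random.Generator | None = None,
):
    """Turn the current population's scores into next-cycle parents.

    Returns a :class:`~moob.core.ContributionVector` for
    contribution-based strategies or a :class:`~moob.mating.MatingPlan`
    for genomic mating.  Scores are the stored GEBVs when present,
    otherwise the raw phenotypes (phenotypic selection).
    """
    scores = state.gebv.values if state.gebv is not None else state.phenotypes
    m, k = scores.shape
    strat = scfg.strategy
    if strat == "tandem":
        trait = (cycle - 1) % k
        return _uniform_contribution(
            m, _top_fraction(scores[:, trait], scfg.selection_fraction)
        )
    if strat == "culling":
        q = scfg.culling_quantile
        while True:
            thresholds = np.quantile(scores, q, axis=0)
            survivors = np.flatnonzero((scores >= thresholds).all(axis=1))
            if survivors.size >= 2 or q <= 0:
                break
            q = max(0.0, q - 0.05)  # relax all thresholds jointly
        if survivors.size < 2:
            survivors = np.arange(m)
        return _uniform_contribution(m, survivors)
    if strat == "index":
        w = np.asarray(scfg.index_weights, dtype=float)
        idx_score = _safe_zscores(scores) @ w
        return _uniform_contribution(
            m, _top_fraction(idx_score, scfg.selection_fraction)
        )
    if strat == "nondominated":
        sort = pareto_mod.nondominated_sort(scores, maximize=np.ones(k, bool))
        return pareto_mod.dominance_weights(sort, scfg.selection_fraction)
    if strat in ("moob_pp_eq1", "moob_pp_eq2"):
        A = compute_relationship(state.genotypes())
        bv = BreedingValues(_safe_zscores(scores), [f"t{t + 1}" for t in range(k)])
        variant = "eq1" if strat == "moob_pp_eq1" else "eq2"
        psi = None
        if variant == "eq2":
            try:
                psi = estimate_genetic_correlations(bv)
            except ValueError:
                variant = "eq1"
        try:
            front = frontier_mod.trace_frontier(
                bv, A, variant=variant, resolution=scfg.frontier_resolution, psi=psi
            )
        except ValueError:
            # non-positive penalty factor: fall back to the plain objective
            front = frontier_mod.trace_frontier(
                bv, A, variant="eq1", resolution=scfg.frontier_resolution
            )
        dw = scfg.resolved_decision_weights(m, k)
        weights = np.concatenate([dw[1:], dw[:1]])  # gains first, co-ancestry last
        cfg = decision_mod.DecisionConfig(weights=weights)
        return decision_mod.select_by_global_criterion(front, cfg).contribution
    if strat == "genomic_mating":
        if state.marker_effects_hat is None:
            raise ValueError("genomic mating needs estimated marker effects")
        if rng is None:
            rng = np.random.default_rng(0)
        G = state.genotypes()
        A = compute_relationship(G)
        n_crosses = scfg.n_crosses or max(2, m // 5)
        front = mating_mod.search_mating_frontier(
            G,
            state.marker_effects_hat,
            A,
            n_crosses=n_crosses,
            search_opts=scfg.gm_search_opts or {"pop_size": 40, "generations": 40},
            seed=int(rng.integers(2**31 - 1)),
        )
        dw = scfg.resolved_decision_weights(m, k)
        wv = scfg.gm_variance_weight
        weights = np.concatenate([dw[1:], np.full(k, wv), dw[:1]])
        weights = weights / weights.sum()
        cfg = decision_mod.DecisionConfig(weights=weights)
        return decision_mod.select_by_global_criterion(front, cfg).decision
    raise ValueError(f"unknown strategy {strat!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# breeding loops


@dataclass
class SimulationResult:
    """Trajectory and summary gains of one breeding run."""

    strategy: str
    trajectory: pd.DataFrame
    base_mean: np.ndarray
    base_sd: np.ndarray
    final_state: BreedingState

    @property
    def per_trait_gain(self) -> np.ndarray:
        """Final-cycle gain per trait in base-population genetic SD units."""
        last = self.trajectory.iloc[-1]
        k = self.base_mean.size
        return np.array(
            [last[f"gain_trait{t + 1}"] for t in range(k)], dtype=float
        )

    @property
    def combined_gain(self) -> float:
        """Sum of standardized per-trait gains at the final cycle."""
        return float(self.per_trait_gain.sum())


def _inbreeding_metric(dosages: np.ndarray, p0: np.ndarray, denom0: float) -> float:
    """Mean kinship relative to the base population's allele frequencies."""
    Z = dosages.astype(float) - 2.0 * p0
    A = Z @ Z.T / denom0
    return float(A.mean() / 2.0)


def _record(
    state: BreedingState,
    cycle: int,
    base_mean: np.ndarray,
    base_sd: np.ndarray,
    p0: np.ndarray,
    denom0: float,
) -> dict:
    g = state.true_bv.values
    rec: dict = {
        "cycle": cycle,
        "inbreeding": _inbreeding_metric(state.dosages(), p0, denom0),
    }
    for t in range(g.shape[1]):
        name = f"trait{t + 1}"
        rec[f"mean_{name}"] = float(g[:, t].mean())
        rec[f"var_{name}"] = float(g[:, t].var(ddof=1))
        rec[f"gain_{name}"] = float((g[:, t].mean() - base_mean[t]) / base_sd[t])
    return rec


def run_breeding(
    base_state: BreedingState,
    cfg: SimulationConfig,
    scfg: StrategyConfig,
    seed: int | Sequence[int] | np.random.Generator = 0,
    mode: str = "gs",
    n_cycles: int | None = None,
) -> SimulationResult:
    """Run one breeding program from a base population.

    ``mode="gs"`` refits the GBLUP model on the current cycle's phenotypes
    at odd cycles and carries the stored marker effects into even cycles;
    ``mode="ps"`` uses phenotypes directly and never touches genotype
    data.  Each cycle the chosen strategy yields parental contributions
    (offspring parents drawn independently proportional to the
    contributions, with replacement) or a mating plan (offspring allocated
    evenly across its crosses); heritability is held constant by
    re-calibrating the environmental noise every cycle.
    """
    if mode not in ("gs", "ps"):
        raise ValueError("mode must be 'gs' or 'ps'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_cycles is None:
        n_cycles = cfg.n_cycles_gs if mode == "gs" else cfg.n_cycles_ps
    state = base_state.clone()
    state.trajectory = []
    blocks = _chromosome_blocks(state.chromosomes, state.positions)
    N = cfg.pop_size
    g0 = state.true_bv.values
    base_mean = g0.mean(axis=0)
    base_sd = g0.std(axis=0, ddof=1)
    base_sd = np.where(base_sd > 1e-12, base_sd, 1.0)
    p0 = state.dosages().mean(axis=0) / 2.0
    denom0 = 2.0 * np.sum(p0 * (1.0 - p0))
    if denom0 <= 0:
        raise ValueError("base population has no polymorphic markers")
    state.trajectory.append(_record(state, 0, base_mean, base_sd, p0, denom0))
    model: GblupModel | None = None
    for cycle in range(1, n_cycles + 1):
        if mode == "gs":
            if model is None or cycle % 2 == 1:
                gebv_bv, model = predict_gebv(state, cfg.h2)
                state.gebv = gebv_bv
            else:
                state.gebv = BreedingValues(
                    model.predict(state.dosages()),
                    list(state.architecture.effects.trait_names),
                )
            state.marker_effects_hat = MarkerEffects(
                model.beta, list(state.architecture.effects.trait_names)
            )
        else:
            state.gebv = None
        choice = apply_strategy(state, scfg, cycle, rng)
        if isinstance(choice, mating_mod.MatingPlan):
            crosses = np.asarray(choice.crosses)
            pairs = crosses[np.arange(N) % len(crosses)]
        else:
            prob = choice.c / choice.c.sum()
            pairs = rng.choice(state.n_individuals, size=(N, 2), p=prob)
        state.haplotypes = _next_generation(state.haplotypes, pairs, blocks, rng)
        g = _true_values(state.haplotypes, state.architecture)
        state.true_bv = BreedingValues(g, list(state.architecture.effects.trait_names))
        state.phenotypes = _phenotype(g, state.architecture, cfg.h2, rng)
        state.generation += 1
        state.gebv = None
        state.trajectory.append(_record(state, cycle, base_mean, base_sd, p0, denom0))
    return SimulationResult(
        strategy=scfg.strategy,
        trajectory=pd.DataFrame(state.trajectory),
        base_mean=base_mean,
        base_sd=base_sd,
        final_state=state,
    )


@dataclass
class ExperimentResult:
    """Replicated multi-strategy comparison from shared base populations."""

    runs: dict[str, list[SimulationResult]]
    summary: pd.DataFrame

    def final_combined_gains(self, strategy: str) -> np.ndarray:
        return np.array([r.combined_gain for r in self.runs[strategy]])

    def mean_final_gain(self, strategy: str) -> float:
        return float(self.final_combined_gains(strategy).mean())

    def advantage_percent(self, strategy: str, competitors: Sequence[str]) -> float:
        """Relative margin (%) of ``strategy`` over the best competitor in
        mean final-cycle combined standardized gain."""
        own = self.mean_final_gain(strategy)
        best = max(self.mean_final_gain(s) for s in competitors)
        return 100.0 * (own - best) / abs(best)


def run_experiment(
    cfg: SimulationConfig,
    strategies: Sequence[StrategyConfig | str],
    n_reps: int = 10,
    seed: int = 0,
    mode: str = "gs",
    n_cycles: int | None = None,
) -> ExperimentResult:
    """Replicate several strategies from identical base populations.

    Each replicate builds one base population (founders + tandem
    pre-selection) and runs every strategy from a clone of it, so
    strategies are compared on exactly the same starting material.  All
    randomness derives from ``seed``; results are deterministic.
    """
    scfgs = [
        s if isinstance(s, StrategyConfig) else StrategyConfig(strategy=s)
        for s in strategies
    ]
    names = [s.strategy for s in scfgs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategies in experiment")
    runs: dict[str, list[SimulationResult]] = {n: [] for n in names}
    for rep in range(n_reps):
        base = make_base_population(cfg, np.random.default_rng([seed, rep]))
        for s_idx, scfg in enumerate(scfgs):
            res = run_breeding(
                base,
                cfg,
                scfg,
                seed=np.random.default_rng([seed, rep, s_idx]),
                mode=mode,
                n_cycles=n_cycles,
            )
            runs[scfg.strategy].append(res)
    rows = []
    for name in names:
        trajs = [r.trajectory for r in runs[name]]
        cycles = trajs[0]["cycle"].to_numpy()
        for ci, cycle in enumerate(cycles):
            row = {"strategy": name, "cycle": int(cycle)}
            for col in trajs[0].columns:
                if col == "cycle":
                    continue
                vals = np.array([t.iloc[ci][col] for t in trajs])
                row[f"{col}_mean"] = float(vals.mean())
                row[f"{col}_var"] = float(vals.var(ddof=1)) if len(vals) > 1 else 0.0
            rows.append(row)
    return ExperimentResult(runs=runs, summary=pd.DataFrame(rows))
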