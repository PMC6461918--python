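"""Core quantitative-genetics containers and marker-based computations.

This module holds the data types shared by the rest of the package —
genotype matrices of SNP allele dosages, genomic relationship matrices,
(estimated) breeding values, marker effects, genetic-correlation matrices
and parental-contribution vectors — together with the elementary
computations connecting them:

* :func:`compute_relationship` — additive genomic relationship matrix
  (VanRaden-type) from marker dosages,
* :func:`genetic_values` — genetic values as dosage x effect sums,
* :func:`standardize` — per-trait z-scoring of breeding values so traits
  are on a common scale,
* :func:`estimate_genetic_correlations` — pairwise correlations of
  breeding-value columns.

All dosages are counts of the (arbitrarily designated) alternate allele in
{0, 1, 2}; fully inbred lines carry only {0, 2}.  Genetic map positions are
in Morgans.  Missing genotypes are rejected, not imputed: the methods here
assume complete high-density marker data on the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrix",
    "BreedingValues",
    "GeneticCorrelationMatrix",
    "MarkerEffects",
    "ContributionVector",
    "allele_frequencies",
    "compute_relationship",
    "genetic_values",
    "standardize",
    "estimate_genetic_correlations",
]


def _unique_or_raise(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for x in labels:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:5]}")
    return labels


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele-dosage matrix with a genetic map.

    Parameters
    ----------
    dosages:
        (m, n) array of allele counts in {0, 1, 2}.
    chromosomes:
        length-n per-marker chromosome labels.
    positions:
        length-n genetic positions in Morgans, non-decreasing within each
        chromosome (in order of appearance).
    individual_ids, marker_ids:
        unique labels.
    inbred_flag:
        whether every individual is fully homozygous; inferred from the
        data when ``None``.
    """

    dosages: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]
    inbred_flag: bool | None = None

    def __post_init__(self) -> None:
        D = np.asarray(self.dosages)
        if D.ndim != 2:
            raise ValueError("dosages must be a 2-d (individuals x markers) array")
        if not np.isin(D, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(D, (0, 1, 2)))[0]
            raise ValueError(
                f"dosage outside {{0,1,2}} at individual {bad[0]}, marker {bad[1]}"
            )
        self.dosages = D.astype(np.int8, copy=False)
        m, n = D.shape
        self.chromosomes = np.asarray(self.chromosomes)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.chromosomes.shape != (n,) or self.positions.shape != (n,):
            raise ValueError("marker map length does not match number of markers")
        for chrom in pd.unique(self.chromosomes):
            pos = self.positions[self.chromosomes == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValueError(
                    f"positions on chromosome {chrom!r} are not non-decreasing"
                )
        self.individual_ids = _unique_or_raise(self.individual_ids, "individual ids")
        self.marker_ids = _unique_or_raise(self.marker_ids, "marker ids")
        if len(self.individual_ids) != m or len(self.marker_ids) != n:
            raise ValueError("id lists do not match dosage matrix shape")
        has_het = bool((D == 1).any())
        if self.inbred_flag is None:
            self.inbred_flag = not has_het
        elif self.inbred_flag and has_het:
            raise ValueError("inbred_flag set but heterozygous dosages present")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "chromosome": self.chromosomes,
                "position": self.positions,
            }
        )

    @classmethod
    def from_dosages(
        cls,
        dosages: np.ndarray,
        chromosomes: np.ndarray | None = None,
        positions: np.ndarray | None = None,
        individual_ids: Sequence[str] | None = None,
        marker_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Build a genotype matrix, filling in a trivial single-chromosome
        map (markers 1 cM apart) and default labels where omitted."""
        D = np.asarray(dosages)
        m, n = D.shape
        if chromosomes is None:
            chromosomes = np.ones(n, dtype=int)
        if positions is None:
            positions = np.arange(n, dtype=float) * 0.01
        if individual_ids is None:
            individual_ids = [f"ind{i + 1}" for i in range(m)]
        if marker_ids is None:
            marker_ids = [f"m{j + 1}" for j in range(n)]
        return cls(D, np.asarray(chromosomes), np.asarray(positions, float),
                   list(individual_ids), list(marker_ids))

    def subset(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        return GenotypeMatrix(
            self.dosages[idx],
            self.chromosomes,
            self.positions,
            [self.individual_ids[i] for i in idx],
            self.marker_ids,
        )


@dataclass
class RelationshipMatrix:
    """Symmetric m x m additive genomic relationship matrix.

    Validated on construction: symmetry to 1e-8, eigenvalues >= -1e-8
    (positive semi-definite up to jitter) and non-negative diagonal.
    """

    A: np.ndarray
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("relationship matrix must be square")
        if np.max(np.abs(A - A.T), initial=0.0) > 1e-8:
            raise ValueError("relationship matrix is not symmetric")
        A = 0.5 * (A + A.T)
        if np.any(np.diag(A) < -1e-10):
            raise ValueError("relationship matrix has a negative diagonal entry")
        if np.linalg.eigvalsh(A).min() < -1e-8:
            raise ValueError("relationship matrix is not PSD (eigenvalue < -1e-8)")
        self.A = A
        if not self.individual_ids:
            self.individual_ids = [f"ind{i + 1}" for i in range(A.shape[0])]
        else:
            self.individual_ids = _unique_or_raise(self.individual_ids, "individual ids")
        if len(self.individual_ids) != A.shape[0]:
            raise ValueError("individual_ids do not match matrix order")

    @property
    def n_individuals(self) -> int:
        return self.A.shape[0]


@dataclass
class BreedingValues:
    """Individuals x traits matrix of (estimated) breeding values.

    ``maximize`` records, per trait, the direction of improvement;
    ``standardized`` marks per-trait z-scored columns.
    """

    values: np.ndarray
    trait_names: list[str]
    maximize: np.ndarray | Sequence[bool] | None = None
    standardized: bool = False
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim == 1:
            V = V[:, None]
        if not np.isfinite(V).all():
            raise ValueError("breeding values contain missing/non-finite entries")
        self.values = V
        m, k = V.shape
        self.trait_names = [str(t) for t in self.trait_names]
        if len(self.trait_names) != k:
            raise ValueError("trait_names length does not match value columns")
        if self.maximize is None:
            self.maximize = np.ones(k, dtype=bool)
        else:
            self.maximize = np.asarray(self.maximize, dtype=bool)
            if self.maximize.shape != (k,):
                raise ValueError("maximize flags do not match trait count")
        if self.individual_ids is not None:
            self.individual_ids = _unique_or_raise(self.individual_ids, "individual ids")
            if len(self.individual_ids) != m:
                raise ValueError("individual_ids do not match value rows")
        if self.standardized and m > 1:
            if np.max(np.abs(V.mean(axis=0))) > 1e-6 or np.max(
                np.abs(V.std(axis=0, ddof=1) - 1.0)
            ) > 1e-6:
                raise ValueError("standardized flag set but columns are not z-scores")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def oriented(self) -> np.ndarray:
        """Values with minimized traits negated, so larger is always better."""
        sign = np.where(np.asarray(self.maximize), 1.0, -1.0)
        return self.values * sign


@dataclass
class GeneticCorrelationMatrix:
    """k x k symmetric matrix of genetic correlations (unit diagonal)."""

    psi: np.ndarray
    trait_names: list[str] | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.psi, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("psi must be square")
        if np.max(np.abs(P - P.T), initial=0.0) > 1e-8:
            raise ValueError("psi is not symmetric")
        if np.max(np.abs(np.diag(P) - 1.0), initial=0.0) > 1e-8:
            raise ValueError("psi diagonal must be 1")
        if np.any(P < -1 - 1e-8) or np.any(P > 1 + 1e-8):
            raise ValueError("correlations must lie in [-1, 1]")
        self.psi = np.clip(0.5 * (P + P.T), -1.0, 1.0)
        np.fill_diagonal(self.psi, 1.0)

    @property
    def n_traits(self) -> int:
        return self.psi.shape[0]


@dataclass
class MarkerEffects:
    """Markers x traits matrix of additive allele-substitution effects."""

    beta: np.ndarray
    trait_names: list[str]
    marker_ids: list[str] | None = None

    def __post_init__(self) -> None:
        B = np.asarray(self.beta, dtype=float)
        if B.ndim == 1:
            B = B[:, None]
        if not np.isfinite(B).all():
            raise ValueError("marker effects contain non-finite entries")
        self.beta = B
        self.trait_names = [str(t) for t in self.trait_names]
        if len(self.trait_names) != B.shape[1]:
            raise ValueError("trait_names length does not match effect columns")
        if self.marker_ids is not None and len(self.marker_ids) != B.shape[0]:
            raise ValueError("marker_ids do not match effect rows")

    @property
    def n_markers(self) -> int:
        return self.beta.shape[0]

    @property
    def n_traits(self) -> int:
        return self.beta.shape[1]


@dataclass
class ContributionVector:
    """Non-negative parental proportions summing to one over the candidates.

    Entries down to -1e-9 are tolerated (solver round-off) and clipped to
    zero; anything more negative, or a sum off 1 by more than 1e-8, is an
    error.
    """

    c: np.ndarray
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float).ravel()
        if np.any(c < -1e-9):
            raise ValueError(
                f"negative contribution {c.min():.3g} at index {int(np.argmin(c))}"
            )
        c = np.clip(c, 0.0, None)
        if abs(c.sum() - 1.0) > 1e-8:
            raise ValueError(f"contributions sum to {c.sum():.10f}, expected 1")
        self.c = c
        if self.individual_ids is not None:
            self.individual_ids = _unique_or_raise(self.individual_ids, "individual ids")
            if len(self.individual_ids) != c.size:
                raise ValueError("individual_ids do not match contribution length")

    @property
    def support(self) -> np.ndarray:
        """Indices of candidates with non-negligible contribution."""
        return np.flatnonzero(self.c > 1e-10)


# ---------------------------------------------------------------------------
# computations


def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele frequencies computed from the candidate set itself."""
    return G.dosages.mean(axis=0) / 2.0


def compute_relationship(G: GenotypeMatrix, method: str = "vanraden1") -> RelationshipMatrix:
    """Additive genomic relationship matrix from marker dosages.

    ``vanraden1`` (default): A = ZZ' / (2 * sum_l p_l (1 - p_l)) with Z the
    column-centered dosages — the classical frequency-scaled cross-product.
    ``vanraden2``: each polymorphic marker standardized by its own
    sqrt(2 p (1 - p)) before the cross-product, averaged over polymorphic
    markers.  Monomorphic markers center to zero and contribute nothing
    either way.  Allele frequencies come from the candidate set (no
    external reference panel), so the result is invariant to swapping
    which allele is counted.
    """
    if G.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    D = G.dosages.astype(float)
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("zero scaling denominator: all markers are monomorphic")
    Z = D - 2.0 * p
    if method == "vanraden1":
        denom = 2.0 * np.sum(p * (1.0 - p))
        A = (Z @ Z.T) / denom
    elif method == "vanraden2":
        w = np.zeros_like(p)
        w[poly] = 1.0 / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
        Zs = Z * w
        A = (Zs @ Zs.T) / poly.sum()
    else:
        raise ValueError(f"unknown relationship method {method!r}")
    A = 0.5 * (A + A.T)
    return RelationshipMatrix(A, list(G.individual_ids))


def genetic_values(G: GenotypeMatrix, E: MarkerEffects) -> BreedingValues:
    """Genetic values as dosage-weighted sums of marker effects."""
    if G.n_markers != E.n_markers:
        raise ValueError(
            f"marker count mismatch: {G.n_markers} genotyped vs {E.n_markers} effects"
        )
    values = G.dosages.astype(float) @ E.beta
    return BreedingValues(
        values,
        list(E.trait_names),
        standardized=False,
        individual_ids=list(G.individual_ids),
    )


def standardize(BV: BreedingValues) -> BreedingValues:
    """Per-trait z-scores (mean 0, unit sample variance); directions kept."""
    V = BV.values
    mu = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s < 1e-12:
            raise ValueError(f"trait {BV.trait_names[j]!r} has zero variance")
    return BreedingValues(
        (V - mu) / sd,
        list(BV.trait_names),
        maximize=np.asarray(BV.maximize).copy(),
        standardized=True,
        individual_ids=None if BV.individual_ids is None else list(BV.individual_ids),
    )


def estimate_genetic_correlations(BV: BreedingValues) -> GeneticCorrelationMatrix:
    """Pairwise correlation of breeding-value columns."""
    if BV.n_individuals < 3:
        raise ValueError("need at least 3 individuals to estimate correlations")
    V = BV.values
    sd = V.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s < 1e-12:
            raise ValueError(f"trait {BV.trait_names[j]!r} is constant")
    psi = np.corrcoef(V, rowvar=False)
    psi = np.atleast_2d(psi)
    return GeneticCorrelationMatrix(np.clip(psi, -1.0, 1.0), list(BV.trait_names))
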