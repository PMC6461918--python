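# Methods

This note records the models, numerical choices and limitations behind
`moob`, in the order the package builds on them.

## Genomic relationships and breeding values

The default relationship estimator is the frequency-scaled centered
cross-product (VanRaden method 1): with dosage matrix **M** (m × n,
entries 0/1/2), allele frequencies p_l estimated from the candidate set
itself, and **Z** = **M** − 2**p**,

    A = Z Z′ / (2 Σ_l p_l (1 − p_l)).

Monomorphic markers center to zero and contribute nothing; if every
marker is monomorphic the scaling denominator is zero and the
computation refuses to proceed.  A second estimator (`vanraden2`,
per-marker standardization averaged over polymorphic markers) is exposed
behind the `method` argument because the choice of estimator is a
genuine degree of freedom — nothing downstream depends on which is used,
only on **A** being PSD.  Because frequencies come from the sample, **1**
is in the null space of **A**: group co-ancestry is measured *relative
to the current population*, and the uniform contribution vector has
co-ancestry ≈ 0.  Missing genotypes are rejected rather than imputed;
the methods assume complete high-density data on the candidates.

Breeding values are standardized per trait to z-scores (sample SD,
ddof = 1) before multi-trait optimization so traits compete on a common
scale; direction-of-improvement flags ride along and minimized traits
are negated internally.  Genetic correlations Ψ are the plain Pearson
correlations of the breeding-value columns.

## Contribution frontiers

The multi-objective program maximizes (c′g₁, …, c′g_k, −½c′Ac) over the
probability simplex.  The penalized variant multiplies **A** by
(k − 2 Σ_{i<j} Ψ_{i,j}); the inner sum is over unordered trait pairs.
This factor is positive whenever correlations are not strongly positive;
if it is ≤ 0 the variant is undefined and the code raises, directing the
caller to the plain objective — silently proceeding would flip the sign
of the diversity term.

Every objective is linear except one concave quadratic, so the
attainable set in objective space is convex and weighted-sum
scalarization recovers the complete Pareto front.  `trace_frontier`
scans a uniform lattice of weight vectors on the (k+1)-simplex
(default 21 points per axis → 231 QPs for k = 2; the simulator uses 13
points per axis, 91 QPs, which resolves the front amply for N ≤ 400
candidates while keeping replicated runs quick).  Each weight vector
yields the QP

    min_c  ½ w_q c′Ac − (Σ_l w_l g_l)′ c,    c ≥ 0, Σ c = 1,

solved by a primal active-set method that is exact up to linear-algebra
round-off: equality-constrained KKT solves on the free set, ratio tests
against the non-negativity bounds, dual-feasibility checks to free
variables (`moob/qp.py`).  QPs along the scan are warm-started from the
previous solution, which cuts typical solves to a handful of pivots.
Degenerate vertices (a freed variable immediately re-blocked at a
zero-length step) are banned from re-entry until a positive step occurs.
Weight vectors with zero weight on the quadratic make the problem
linear; they are answered by the vertex shortcut (point mass on the
best weighted-gain candidate) instead of a degenerate QP.  **A** is
jittered by +1e−8·I when its smallest eigenvalue is below 1e−10 so the
quadratic is strictly convex.  Solutions whose objective vectors differ
by < 1e−6 in sup-norm are collapsed, and numerically dominated points
are pruned.  The whole sweep is deterministic.

The classical single-trait formulation — minimize ½c′Ac subject to
c′b = ρ, Σc = 1, c ≥ 0 — is kept as an independent cross-check: sweeping
ρ over the *efficient* range (from the gain of the minimum-co-ancestry
solution up to max b) traces the same trade-off as the k = 1 frontier.
Below that range the gain *equality* forces gain down and co-ancestry
up, and the solutions are not Pareto-optimal; the equivalence tests
sweep only the efficient range.

## Decision support

Objectives are first oriented so smaller is better, then min-max
normalized over the frontier (zero-range axes contribute nothing —
documented behavior, not an error).  The global criterion returns the
solution minimizing the weighted p-norm distance (default p = 2) to the
ideal point, with ties broken by lowest co-ancestry, then input order.
The knee is the chord rule on a two-objective projection: the point
farthest from the segment joining the frontier endpoints; collinear
frontiers return the first solution flagged `no_pronounced_knee`.  The
self-organizing map is batch Kohonen training: codebook initialized
deterministically on the first two principal axes of the normalized
objectives, Gaussian neighborhood with radius decaying linearly from
max(u, v)/2 to 0.5 over the epochs (defaults 6 × 6, 50 epochs).  The
seed only matters for degenerate inputs (tiny jitter when the principal
axes vanish).

## Genomic mating

A mating plan (multiset of parent pairs) is scored on 2k + 1
objectives: per-trait mid-parent gain and expected within-cross variance
(both maximized) and expected progeny inbreeding A_ij/2 (minimized),
aggregated over crosses as multiplicity-weighted *means* so plan size
does not inflate objectives.  Because the relationship matrix is
centered on the current population, kinship — and hence the inbreeding
objective — can be negative for less-related-than-average pairs.

Cross variance assumes progeny carried to fixation (doubled haploids /
deep RILs) and unlinked loci.  For fully inbred parents each segregating
locus contributes β² (this is `cross_variance`, with an exhaustive
progeny-enumeration oracle in the tests defining its meaning); the plan
evaluator uses the smooth generalization Σ_l β_l²·4q_l(1−q_l) with
q_l = (d_i + d_j)/4, which coincides with the closed form for inbred
parents and extends it to heterozygous ones.  A simulation-based
estimator (`simulated_cross_variance`) honors linkage through the
genetic map by simulating doubled-haploid progeny of the cross;
heterozygous parents are phased at random (seeded), an explicit
assumption since phase is unobserved in dosage data.

The plan space is searched with an elitist non-dominated-sorting
evolutionary algorithm: binary tournament on (dominance level, crowding
distance), slot-wise plan crossover, parent-replacement mutation
(defaults: 100 plans, 200 generations, mutation 0.1/cross), plus an
external archive of every non-dominated objective vector encountered —
so the archive can only improve across generations.  On instances small
enough to enumerate, the archive attains the exact non-dominated set
(tested to 4 parents × 2 crosses and 3 parents × 1 cross).

## Breeding simulator

The simulated system: two fully inbred, complementary founders; N copies
of their F1 put through 100 generations of random mating (uniform parent
draws with replacement) produce the founder population.  Three
chromosomes of 1 Morgan each (length chosen as a conventional value;
positions of the 1000 markers per chromosome uniform).  Meiosis draws a
Poisson(L) number of crossovers per chromosome at uniform positions with
no interference, so recombination follows the Haldane map function —
verified against ½(1 − e^{−2d}) in the tests.

Two traits share 200 QTL per chromosome.  Effects are drawn standard
normal independently per trait; at 100 designated QTL per chromosome the
trait-2 effect is forced to the sign opposite trait 1's
(β₂ ← −sign(β₁)|β₂|).  This is what makes the traits reliably negatively
genetically correlated in the founders (≈ −0.3): merely flipping signs
of an independent symmetric draw would leave the joint distribution —
and hence the expected correlation — unchanged, so the forced-opposition
form is the construction that actually produces the intended antagonism.

Environmental noise is Gaussian with variance set to (1 − h²)/h² times
the current genetic variance per trait — equal to the genetic variance
at the default h² = 0.5 — and re-calibrated every cycle so heritability
stays constant as selection erodes variance.  The base population for
strategy comparisons applies 10 rounds of phenotypic tandem selection at
50% intensity (traits alternating by round) to the founders; each
replicate freezes one base population and runs every strategy from a
clone of it.

Genomic strategies refit prediction at odd cycles on that cycle's
phenotypes and reuse the stored model at even cycles.  Prediction is
per-trait GBLUP — ridge on the genomic relationship with shrinkage
(1 − h²)/h², marker effects backsolved as β = Z′α/denominator so the
model transfers to new genotypes — plus a moment estimate of the
genetic correlation from the GEBVs (it feeds the penalized frontier
variant and reporting).  This is a deliberate simplification of a full
multivariate REML mixed model; it shares the same shrinkage structure
per trait but estimates the between-trait covariance post hoc.

Strategies map scores (GEBVs, or phenotypes in phenotypic-selection
mode) to parental contributions:

* *tandem* — truncation on one trait, alternating by cycle parity;
* *culling* — survivors above every per-trait quantile threshold
  (default 40th percentile, a conventional choice; thresholds relax
  jointly in 5-point steps until at least two survive);
* *index* — truncation on the weighted sum of per-trait z-scores
  (default weights 0.5/0.5);
* *nondominated* — dominance-level weights, linear-in-level scheme
  (weight ∝ L* − ℓ + 1 over included levels; the level at which the
  quota is reached is included in full, its members sharing one weight);
* *moob_pp_eq1 / eq2* — trace the contribution frontier on standardized
  GEBVs and pick by global criterion.  Decision weights follow the
  simulation protocol's ordering (co-ancestry first): 0.95/0.025/0.025
  for N ≤ 200 and 0.9/0.05/0.05 for larger populations, i.e. selection
  intensity is raised for large populations by shifting weight off the
  co-ancestry axis.  If the penalized variant's factor is non-positive
  the cycle falls back to the plain objective rather than aborting a
  long simulation;
* *genomic_mating* — search the plan frontier using the fitted marker
  effects, pick by global criterion (cross-variance axes get zero
  decision weight by default), allocate offspring evenly across the
  chosen crosses.

Offspring are produced by drawing each of the N offspring's two parents
independently proportional to the contributions (random mating given
contributions); selfing is possible, as under random union of gametes.
Trajectories log, per cycle, mean true breeding value, genetic variance
and standardized gain per trait, plus mean kinship relative to the base
population's allele frequencies (the inbreeding column).  The combined
gain used for strategy comparison is the sum of per-trait gains in
base-population genetic-SD units; per-trait gains are reported alongside.

## What the generator does and does not emulate

The synthetic populations reproduce the statistical structure the
frontier and mating methods care about: biallelic SNP genomes with
realistic LD from a narrow founder base, antagonistic polygenic traits,
constant heritability, and GEBVs with honest prediction error.  They do
not model multi-environment trials, genotype-by-environment interaction,
non-additive gene action, genotyping error or missingness — so passing
tests demonstrate the optimization and simulation machinery, not
robustness to those real-data complications.  Empirical datasets enter
through the same delimited-text/VCF interfaces; the multivariate mixed
model used to produce GEBVs from raw multi-environment phenotypes is out
of scope (GEBV tables are an input).

## Problem sizes and determinism

The replicated strategy comparison in `scripts/acceptance.py` runs
N = 100 with 10 replicates of 16 genomic cycles (its margin over the
best competitor is seed-variable at this replication level, roughly
±5 percentage points); the founder-heritability check uses N = 200 and
20 seeds.  The unit-test suite uses smaller populations (20–100
individuals, 60–600 markers) chosen to exercise every code path with
oracle-verifiable sizes.  Everything that draws random numbers takes a
seed or Generator and is bit-reproducible per platform; CLI commands
write a manifest (resolved config, seed, input digests, wall time) next
to each output.

## Known limitations

* Weighted-sum scalarization is complete only because the objective set
  is convex; if a future objective breaks concavity (e.g. integer
  progeny counts) the scan would miss non-convex frontier regions —
  such formulations are explicitly out of scope.
* The active-set QP assumes a PD quadratic after jitter; relationship
  matrices read from files that are far from PSD are rejected at
  construction rather than repaired.
* The evolutionary mating search carries no optimality guarantee beyond
  the enumerable instances it is tested on; the archive is the best set
  found within the configured budget.
* Contribution vectors are continuous proportions; converting them to
  integer family sizes is left to the caller.
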