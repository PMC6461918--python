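"""Forward breeding simulation: MOOB vs classical multi-trait strategies.

Runs a scaled-down replicated comparison (small population, few cycles so
the example finishes in seconds): tandem, equal-weight index and the
multi-objective optimized parental-proportions strategy, all starting
from identical base populations, selecting on GBLUP GEBVs refit at odd
cycles.  Prints the final combined standardized gain (sum over the two
traits of the gain in base-population genetic SD units).
"""

from moob.sim import SimulationConfig, StrategyConfig, run_experiment

cfg = SimulationConfig(pop_size=40, n_markers_per_chrom=150,
                       n_qtl_per_chrom=30, n_opposite_sign=15,
                       burnin_random_mating=40)
strategies = [
    StrategyConfig("tandem"),
    StrategyConfig("index"),
    StrategyConfig("moob_pp_eq1", frontier_resolution=9),
]
result = run_experiment(cfg, strategies, n_reps=3, seed=0, mode="gs",
                        n_cycles=14)

print("final-cycle combined standardized gain (mean over 3 reps):")
for s in ("tandem", "index", "moob_pp_eq1"):
    gains = result.final_combined_gains(s)
    print(f"  {s:14s} {gains.mean():6.2f}  (reps: "
          + ", ".join(f"{g:.2f}" for g in gains) + ")")
margin = result.advantage_percent("moob_pp_eq1", ("tandem", "index"))
print(f"MOOB margin over best competitor: {margin:.1f}%")
# The co-ancestry objective slows early gains slightly but preserves the
# genetic variance that keeps later cycles productive; the margin grows
# with population size and cycle count (see the full-size comparison run
# by scripts/acceptance.py).
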