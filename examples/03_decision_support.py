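"""Choosing one compromise on a frontier: ideal point, global criterion,
knee, and a self-organizing-map layout.

The global criterion picks the frontier member closest (weighted,
normalized axes) to the ideal point — the simulation protocol uses
weights 0.95/0.025/0.025 on co-ancestry/gain1/gain2.  The knee is the
point where improving one objective starts costing a lot in another.
"""

import numpy as np

from moob import (
    DecisionConfig,
    compute_relationship,
    find_knee,
    ideal_point,
    select_by_global_criterion,
    som_fit,
    standardize,
    trace_frontier,
)
from moob.core import BreedingValues
from moob.sim import SimulationConfig, make_founders

cfg = SimulationConfig(pop_size=40, n_markers_per_chrom=80, n_qtl_per_chrom=16,
                       n_opposite_sign=8, burnin_random_mating=25)
state = make_founders(cfg, seed=3)
A = compute_relationship(state.genotypes())
bv = standardize(BreedingValues(state.true_bv.values, ["t1", "t2"]))
front = trace_frontier(bv, A, resolution=15)

print("ideal point (gain1, gain2, co-ancestry):",
      np.round(ideal_point(front).values, 3))

# weights in internal objective order: gains first, co-ancestry last
cfg_w = DecisionConfig(weights=np.array([0.025, 0.025, 0.95]))
pick = select_by_global_criterion(front, cfg_w)
print("global-criterion pick:", np.round(pick.objectives.values, 3),
      "| support size", pick.decision.support.size)

knee = find_knee(front, axes=(0, 2))  # gain1 vs co-ancestry projection
print("knee (gain1 vs co-ancestry):", np.round(knee.objectives.values, 3))

som = som_fit(front, grid=(4, 4), epochs=30, seed=0)
print(f"SOM quantization error {som.quantization_error:.4f} "
      f"(init {som.initial_quantization_error:.4f})")
# A heavy co-ancestry weight picks a conservative, diversity-preserving
# solution; the knee is the natural visual compromise on the curve.
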