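"""Run one small tissue patch for two simulated days and inspect the output.

Builds a 240 µm patch of confluent parenchymal epithelium seeded with three
cancer cells and a few resting immune cells, advances the full multiscale
loop (diffusion, mechanics/motility, stochastic interactions, lymph node)
and prints the population time series, the day-2 live cancer count P_M and
its outcome label.
"""

import numpy as np

from micromet import WorldConfig, initialize_world, run_simulation
from micromet.analysis import classify_outcome, compress_trajectory, thresholds_for_population

cfg = WorldConfig(seed=7)
cfg.domain_size = 240.0
cfg.dt_diffusion = cfg.dt_mechanics = 0.5
cfg.initial_cancer = 3
cfg.initial_macrophages = 4
cfg.initial_dcs = 2
cfg.duration = 2880.0  # 2 days
cfg.snapshot_interval = 480.0

world = initialize_world(cfg)
n_total = len(world.cells)
traj = run_simulation(world)

print(traj.populations[["t", "cancer", "parenchymal", "m0", "m1", "cd8", "corpses"]]
      .iloc[::8].to_string(index=False))

thr = thresholds_for_population(n_total)
pm = traj.final_cancer_count
print(f"\nP_M (live cancer on day 2) = {pm}")
print(f"thresholds for this {n_total}-cell patch: T_SC={thr.T_SC:.0f}, T_NC={thr.T_NC:.0f}")
print(f"outcome label: {classify_outcome(pm, thr)}  (SC=elimination, MC=partial, NC=escape)")

feats = compress_trajectory(traj)
print(f"\ncompressed trajectory: {traj.n_snapshots} snapshots x 5x5x3 "
      f"= {len(feats.vector)}-dimensional feature vector, "
      f"max channel intensity {feats.vector.max():.2f}")
print("(a default 10-day run has 31 snapshots and 2325 dimensions)")
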