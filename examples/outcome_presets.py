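"""The three immune-response regimes: escape, partial control, elimination.

Runs the shipped low/moderate/high presets on the reduced 380 µm patch for
ten simulated days each (a few minutes of wall time in total) and labels
the outcomes.  The low preset lets the colony escape toward carrying
capacity (NC), the moderate one prunes it without clearing it (MC), and
the high one eliminates it before day 10 (SC).
"""

from micromet import initialize_world, run_simulation
from micromet.analysis import classify_outcome, thresholds_for_population
from micromet.presets import PRESET_LEVELS, preset_config

for level in PRESET_LEVELS:
    cfg = preset_config(level, seed=1)
    world = initialize_world(cfg)
    n0 = len(world.cells)
    traj = run_simulation(world)
    thr = thresholds_for_population(n0)
    pm = traj.final_cancer_count
    pops = traj.populations
    print(f"{level:9s} immune response: P_M = {pm:4d} of {n0} initial cells "
          f"-> {classify_outcome(pm, thr)}   "
          f"(peak CD8 {pops['cd8'].max()}, "
          f"parenchymal loss {pops['parenchymal'].iloc[0] - pops['parenchymal'].iloc[-1]})")
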