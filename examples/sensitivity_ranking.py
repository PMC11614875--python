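"""Rank patient parameters by their association with the outcome label.

Uses a synthetic labeled cohort (labels are generated here from a known
rule, not from simulations) purely to demonstrate the Mann-Whitney
sensitivity machinery: patients whose macrophage recruitment rate is below
its range midpoint are labeled "no control" (NC), others "significant
control" (SC), with 15% label noise.  The test should rank r_recruit_M
first by a wide margin and leave the untouched parameters non-significant.
"""

import numpy as np

from micromet import default_ranges, lhs_sample, sensitivity_table

rng = np.random.default_rng(3)
ranges = default_ranges()
patients = lhs_sample(ranges, 400, seed=3)

lo, hi = ranges["r_recruit_M"]
labeled = []
for p in patients:
    label = "NC" if p["r_recruit_M"] < 0.5 * (lo + hi) else "SC"
    if rng.random() < 0.15:  # label noise
        label = "SC" if label == "NC" else "NC"
    labeled.append((p, label))

table = sensitivity_table(labeled)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\nrows are sorted by ascending p-value; 'significant' is the "
      "two-sided Mann-Whitney test at alpha = 0.05")
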