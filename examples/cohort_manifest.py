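"""Build a 10,000-patient virtual cohort and a personalized therapy grid.

Latin hypercube sampling draws the ten immune parameters (six recruitment
constants, three lymph-node T-cell-production parameters, and the
activated-DC egress rate) over ×0.1–×10 of their baselines; ten replicates
per patient give a 100,000-job manifest.  The 3×3 therapy grid re-runs one
patient at the {min, center, max} combinations of the two recruitment
rates — the model's most outcome-relevant parameters.
"""

import numpy as np

from micromet import build_manifest, default_ranges, lhs_sample, therapy_grid

ranges = default_ranges()
patients = lhs_sample(ranges, 10_000, seed=42)

# LHS stratification: exactly one patient per centile bin in every dimension
for name in ("r_recruit_M", "delta_C"):
    bins = np.floor([p.unit[name] * 10_000 for p in patients]).astype(int)
    print(f"{name:12s}: {len(np.unique(bins))} of 10000 strata occupied")

manifest = build_manifest(patients, n_replicates=10, base_seed=42)
print(f"\ncohort manifest: {len(manifest)} jobs "
      f"({len(patients)} patients x 10 replicates), "
      f"{len({j.seed for j in manifest.jobs})} distinct seeds")
job = manifest.jobs[0]
print(f"first job: patient {job.patient_id}, replicate {job.replicate}, seed {job.seed}")

grid = therapy_grid(patients[0], ranges, n_replicates=10)
print(f"\ntherapy grid for patient 0: {len(grid)} jobs over the 3x3 "
      f"(r_recruit_M x r_recruit_D) mesh")
levels = sorted({j.overrides["r_recruit_M"] for j in grid.jobs})
print("r_recruit_M mesh levels:", ", ".join(f"{v:.3g}" for v in levels))
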