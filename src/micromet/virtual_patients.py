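"""Virtual-patient cohorts: Latin hypercube sampling, manifests, therapy grids.

A virtual patient is one draw of the ten immune parameters that the cohort
varies: the six recruitment constants of macrophages and DCs
(r_recruit, ρ_min, ρ_sat for each), three lymph-node T-cell-production
parameters (π_T, κ_T, δ_C) and the activated-DC egress rate r_leave.
Replicated stochastic simulations of each patient make up an ensemble; the
manifest is a flat, deterministic job list (patient, replicate, seed,
parameter overrides) that any scheduler — or a local loop — can execute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .config import PATIENT_PARAMETERS
from .errors import ConfigurationError

__all__ = [
    "PatientParameterSet",
    "SimulationJob",
    "EnsembleManifest",
    "default_ranges",
    "lhs_sample",
    "build_manifest",
    "therapy_grid",
]

_SEED_MOD = 2**31


@dataclass
class PatientParameterSet:
    """One virtual patient: named values plus their normalized coordinates."""

    patient_id: int
    values: dict[str, float]
    unit: dict[str, float] = field(default_factory=dict)  # coordinates in [0,1]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class SimulationJob:
    patient_id: int
    replicate: int
    seed: int
    overrides: dict[str, float]


@dataclass
class EnsembleManifest:
    jobs: list[SimulationJob]

    def __len__(self) -> int:
        return len(self.jobs)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for j in self.jobs:
                fh.write(
                    json.dumps(
                        {
                            "patient_id": j.patient_id,
                            "replicate": j.replicate,
                            "seed": j.seed,
                            "overrides": j.overrides,
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path) -> "EnsembleManifest":
        jobs = []
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                jobs.append(SimulationJob(d["patient_id"], d["replicate"], d["seed"], d["overrides"]))
        return cls(jobs)


def default_ranges(config=None) -> dict[str, tuple[float, float]]:
    """Cohort ranges: ×0.1 – ×10 of each baseline, on a linear scale."""
    from .config import WorldConfig

    cfg = config or WorldConfig()
    out = {}
    for name, (block, attr) in PATIENT_PARAMETERS.items():
        base = getattr(getattr(cfg, block), attr)
        out[name] = (0.1 * base, 10.0 * base)
    return out


def lhs_sample(
    ranges: dict[str, tuple[float, float]], n: int, seed: int
) -> list[PatientParameterSet]:
    """Latin hypercube sample of n patients over the named ranges.

    For every dimension exactly one point falls in each of the n equal-width
    strata of [0, 1] (uniform jitter within the stratum, independent random
    permutations across dimensions); deterministic under the seed.
    """
    if n < 1:
        raise ConfigurationError("need n >= 1 patients")
    for name, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ConfigurationError(f"invalid range for {name}: [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    names = list(ranges)
    coords = np.empty((n, len(names)))
    for d in range(len(names)):
        coords[:, d] = (rng.permutation(n) + rng.random(n)) / n
    patients = []
    for k in range(n):
        values, unit = {}, {}
        for d, name in enumerate(names):
            lo, hi = ranges[name]
            unit[name] = float(coords[k, d])
            values[name] = float(lo + coords[k, d] * (hi - lo))
        patients.append(PatientParameterSet(patient_id=k, values=values, unit=unit))
    return patients


def _job_seed(base_seed: int, index: int) -> int:
    return (int(base_seed) + index) % _SEED_MOD


def build_manifest(
    patients: list[PatientParameterSet], n_replicates: int, base_seed: int
) -> EnsembleManifest:
    """|patients| × n_replicates jobs with deterministic, distinct seeds."""
    if n_replicates < 1:
        raise ConfigurationError("need n_replicates >= 1")
    jobs = []
    for p in patients:
        for r in range(n_replicates):
            jobs.append(
                SimulationJob(
                    patient_id=p.patient_id,
                    replicate=r,
                    seed=_job_seed(base_seed, len(jobs)),
                    overrides=dict(p.values),
                )
            )
    return EnsembleManifest(jobs)


def therapy_grid(
    patient: PatientParameterSet,
    ranges: dict[str, tuple[float, float]],
    dims: tuple[str, str] = ("r_recruit_M", "r_recruit_D"),
    n_replicates: int = 10,
    base_seed: int = 0,
) -> EnsembleManifest:
    """3×3 hypothetical-immunotherapy mesh around one patient.

    Each mesh node combines the {minimum, central, maximum} of the two
    chosen parameters' configured ranges, all other parameters held at the
    patient's own values; n_replicates jobs per node (9·n_replicates total).
    """
    for d in dims:
        if d not in PATIENT_PARAMETERS:
            raise ConfigurationError(f"unknown patient parameter {d!r}")
        if d not in ranges:
            raise ConfigurationError(f"no configured range for {d!r}")
    levels = {}
    for d in dims:
        lo, hi = ranges[d]
        levels[d] = (lo, 0.5 * (lo + hi), hi)
    jobs = []
    for v0 in levels[dims[0]]:
        for v1 in levels[dims[1]]:
            for r in range(n_replicates):
                overrides = dict(patient.values)
                overrides[dims[0]] = v0
                overrides[dims[1]] = v1
                jobs.append(
                    SimulationJob(
                        patient_id=patient.patient_id,
                        replicate=r,
                        seed=_job_seed(base_seed, len(jobs)),
                        overrides=overrides,
                    )
                )
    return EnsembleManifest(jobs)
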