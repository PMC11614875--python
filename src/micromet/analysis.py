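"""Outcome classification, trajectory compression and parameter sensitivity.

A run is labeled from its day-10 live cancer population P_M against two
thresholds derived from the domain's total cell population: significant
control (SC, elimination) when P_M < T_SC, no control (NC, escape) when
P_M > T_NC, and marginal control (MC, partial elimination) in between
(boundaries inclusive to MC).  Defaults T_SC = 100 and T_NC = 1500 cells
are 5% and 75% of the ~2000-cell tissue patch.

Spatial/temporal trajectories are compressed to a fixed-length feature
vector: each snapshot is rasterized to a 5×5×3 RGB thumbnail (R = cancer,
G = immune, B = parenchymal local density, each divided by the hexagonal
carrying density and clamped to [0, 1]) and the 31 snapshots of a 10-day
run concatenate to a 2325-dimensional vector.

Parameter sensitivity compares each patient parameter between the
consistently-NC and consistently-SC patients with a two-sided
Mann–Whitney U test at α = 0.05, reported in ascending order of p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "ClassifierThresholds",
    "TrajectoryFeatures",
    "SensitivityResult",
    "classify_outcome",
    "thresholds_for_population",
    "consensus_labels",
    "compress_trajectory",
    "mann_whitney_u",
    "sensitivity_table",
]

LABELS = ("SC", "MC", "NC")


@dataclass
class ClassifierThresholds:
    T_SC: float = 100.0  # elimination threshold (cells)
    T_NC: float = 1500.0  # escape threshold (cells)

    def __post_init__(self) -> None:
        if not 0 < self.T_SC < self.T_NC:
            raise ConfigurationError("need 0 < T_SC < T_NC")


def thresholds_for_population(n_total: int) -> ClassifierThresholds:
    """Thresholds at 5% / 75% of a domain's total cell population."""
    return ClassifierThresholds(T_SC=0.05 * n_total, T_NC=0.75 * n_total)


def classify_outcome(P_M: float, thr: ClassifierThresholds | None = None) -> str:
    """SC / MC / NC label of one run from its final live cancer count."""
    if P_M < 0:
        raise ConfigurationError("P_M must be nonnegative")
    thr = thr or ClassifierThresholds()
    if P_M < thr.T_SC:
        return "SC"
    if P_M > thr.T_NC:
        return "NC"
    return "MC"


def consensus_labels(labels) -> set[str]:
    """Distinct labels across replicates; a singleton means a consistent patient."""
    labels = list(labels)
    if not labels:
        raise ConfigurationError("need at least one replicate label")
    bad = set(labels) - set(LABELS)
    if bad:
        raise ConfigurationError(f"unknown labels {bad}")
    return set(labels)


@dataclass
class TrajectoryFeatures:
    thumbnails: np.ndarray  # (n_snapshots, nx, ny, 3) intensities in [0, 1]
    vector: np.ndarray  # flattened, time-ordered

    def __len__(self) -> int:
        return len(self.vector)


_IMMUNE = {"macrophage", "dc", "cd8", "cd4"}


def _carrying_count(bin_area: float, radius: float) -> float:
    """Cells per bin at confluent hexagonal packing (area 2√3·R² per cell)."""
    return bin_area / (2.0 * math.sqrt(3.0) * radius**2)


def compress_trajectory(
    trajectory,
    thumb: tuple[int, int] = (5, 5),
    cell_radius: float | None = None,
    carrying_density: float | None = None,
) -> TrajectoryFeatures:
    """Compress a trajectory to thumbnails and a concatenated feature vector.

    Channels: R = live cancer, G = live immune, B = live parenchymal local
    density, each normalized by the hexagonal carrying density of the bin
    and clamped to [0, 1]; snapshots are concatenated in time order, so a
    default 31-snapshot run yields 31 · 5 · 5 · 3 = 2325 dimensions.
    """
    if trajectory.n_snapshots < 1:
        raise ConfigurationError("trajectory needs at least one snapshot")
    nx, ny = thumb
    L = trajectory.config.domain_size
    R = cell_radius if cell_radius is not None else trajectory.config.cell_radius
    bin_area = (L / nx) * (L / ny)
    carrying = carrying_density if carrying_density is not None else _carrying_count(bin_area, R)
    edges_x = np.linspace(0.0, L, nx + 1)
    edges_y = np.linspace(0.0, L, ny + 1)
    thumbs = np.zeros((trajectory.n_snapshots, nx, ny, 3))
    for s, tab in enumerate(trajectory.cell_tables):
        live = tab[tab["alive"]]
        for ch, mask in enumerate(
            (
                live["type"] == "cancer",
                live["type"].isin(_IMMUNE),
                live["type"] == "parenchymal",
            )
        ):
            sub = live[mask]
            if len(sub) == 0:
                continue
            H, _, _ = np.histogram2d(sub["x"], sub["y"], bins=(edges_x, edges_y))
            thumbs[s, :, :, ch] = np.clip(H / carrying, 0.0, 1.0)
    return TrajectoryFeatures(thumbnails=thumbs, vector=thumbs.reshape(-1).copy())


@dataclass
class SensitivityResult:
    parameter: str
    U: float
    p_value: float
    significant: bool  # at α = 0.05


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test of identical distributions.

    Exact null by enumeration for |a|+|b| ≤ 12 without ties; tie-corrected
    normal approximation otherwise.  Returns (U of sample a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigurationError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) + len(b) <= 12 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(res.pvalue)


def sensitivity_table(patients_with_labels, parameters=None) -> pd.DataFrame:
    """Mann–Whitney sensitivity of every patient parameter, NC vs SC.

    patients_with_labels: iterable of (PatientParameterSet, consensus label);
    only consistently-labeled NC and SC patients enter the comparison.
    Rows are sorted by ascending p-value.
    """
    nc, sc = [], []
    for patient, label in patients_with_labels:
        if label == "NC":
            nc.append(patient)
        elif label == "SC":
            sc.append(patient)
    if not nc or not sc:
        raise ConfigurationError("need at least one NC and one SC patient")
    if parameters is None:
        parameters = list(nc[0].values)
    rows = []
    for name in parameters:
        u, p = mann_whitney_u([q[name] for q in nc], [q[name] for q in sc])
        rows.append(SensitivityResult(name, u, p, p < 0.05))
    rows.sort(key=lambda r: r.p_value)
    return pd.DataFrame(
        [(r.parameter, r.U, r.p_value, r.significant) for r in rows],
        columns=["parameter", "U", "p_value", "significant"],
    )
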