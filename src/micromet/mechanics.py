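"""Cell mechanics: adhesion/repulsion, elasto-plastic ECM tethering, pressure.

Cells are overdamped off-lattice spheres (velocity ∝ force, no inertia).
Parenchymal cells are tethered to an extracellular-matrix attachment point
x⃗_ECM; writing d⃗ = x⃗_ECM − x⃗ and d̂ = ‖d⃗‖ − R, the tether evolves as

    dx⃗/dt     =  r_E · d̂ · d⃗/‖d⃗‖        (elastic restoring force)
    dx⃗_ECM/dt = −r_P · d⃗                  (plastic matrix reorganization)

so the cell rests with the attachment point on its membrane (d̂ = 0).  A
parenchymal cell crushed by a cancer cell beyond a maximum tolerated
deformation d_max undergoes programmed death, freeing space for the colony.

The dimensionless "simple pressure" on a cell is Σ_j (1 − d_ij/(R_i+R_j))²
over overlapping neighbors; it gates the cancer cell cycle (see agents).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError

__all__ = [
    "EcmAnchor",
    "MechanicsParams",
    "elastoplastic_step",
    "ecm_step_arrays",
    "pair_candidates",
    "displacements_from_pairs",
    "pairwise_displacements",
    "simple_pressure",
    "deformation_death_check",
]


@dataclass
class EcmAnchor:
    """Elasto-plastic attachment of a parenchymal cell to the matrix."""

    x_ecm: np.ndarray  # attachment point (µm)
    r_E: float = 0.05  # elastic coefficient (1/min)
    r_P: float = 5e-4  # plastic relaxation rate (1/min)
    d_max: float = 1.5  # maximum tolerated deformation (µm)

    def __post_init__(self) -> None:
        if self.r_E < 0 or self.r_P < 0:
            raise ConfigurationError("r_E and r_P must be nonnegative")
        if self.d_max <= 0:
            raise ConfigurationError("d_max must be positive")
        self.x_ecm = np.asarray(self.x_ecm, dtype=float)


@dataclass
class MechanicsParams:
    """Pairwise adhesion-repulsion constants (overlapping-spheres potential)."""

    cca: float = 0.4  # cell-cell adhesion strength (µm/min at full reach)
    ccr: float = 10.0  # cell-cell repulsion strength (µm/min at full overlap)
    R_interact: float = 1.25  # max interaction distance / (R_i + R_j)
    mu: float = 1.0  # drag normalization (overdamped)

    def __post_init__(self) -> None:
        if self.cca < 0 or self.ccr < 0:
            raise ConfigurationError("cca and ccr must be nonnegative")
        if self.R_interact < 1.0:
            raise ConfigurationError("R_interact must be >= 1")


def ecm_step_arrays(
    positions: np.ndarray,
    anchors: np.ndarray,
    radii: np.ndarray,
    r_E: float,
    r_P: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized forward-Euler tether update for many cells.

    Returns (new_positions, new_anchors); rows with ‖d⃗‖ = 0 are equilibria
    and stay put.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    d = anchors - positions
    norm = np.linalg.norm(d, axis=1)
    ok = norm > 0.0
    d_hat = norm - radii
    newp = positions.copy()
    newa = anchors.copy()
    scale = np.zeros_like(norm)
    scale[ok] = r_E * d_hat[ok] / norm[ok]
    newp += dt * scale[:, None] * d
    newa[ok] -= dt * r_P * d[ok]
    return newp, newa


def elastoplastic_step(
    position: np.ndarray, anchor: EcmAnchor, radius: float, dt: float
) -> tuple[np.ndarray, EcmAnchor]:
    """One forward-Euler update of the elasto-plastic tether for one cell."""
    p = np.asarray(position, dtype=float)[None, :]
    a = anchor.x_ecm[None, :]
    newp, newa = ecm_step_arrays(p, a, np.array([radius]), anchor.r_E, anchor.r_P, dt)
    return newp[0], EcmAnchor(newa[0], anchor.r_E, anchor.r_P, anchor.d_max)


def pair_candidates(
    positions: np.ndarray, radii: np.ndarray, R_interact: float, skin: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate interacting pairs within R_interact·2·max(R) + skin.

    With a positive skin this is a Verlet neighbor list: it stays valid
    while no cell has moved more than skin/2 since it was built.
    """
    n = len(positions)
    if n < 2:
        return np.empty(0, int), np.empty(0, int)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(
        r=R_interact * 2.0 * float(radii.max()) + skin, output_type="ndarray"
    )
    if len(pairs) == 0:
        return np.empty(0, int), np.empty(0, int)
    return pairs[:, 0], pairs[:, 1]


def displacements_from_pairs(
    positions: np.ndarray,
    radii: np.ndarray,
    pair_i: np.ndarray,
    pair_j: np.ndarray,
    params: MechanicsParams,
    dt: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Overdamped pairwise displacements over dt, given a candidate pair list.

    Repulsion ∝ ccr·(1 − d/(R_i+R_j))² inside overlap, adhesion
    ∝ −cca·(1 − d/(R_interact·(R_i+R_j)))² inside reach; contributions on a
    pair are equal and opposite (no net momentum).  Coincident centers repel
    along a seeded random unit vector (documented tie-break; pass rng).
    """
    disp = np.zeros_like(positions)
    if len(pair_i) == 0:
        return disp
    diff = positions[pair_i] - positions[pair_j]
    dist = np.linalg.norm(diff, axis=1)
    rsum = radii[pair_i] + radii[pair_j]
    keep = dist < params.R_interact * rsum
    i, j, diff, dist, rsum = pair_i[keep], pair_j[keep], diff[keep], dist[keep], rsum[keep]
    if len(i) == 0:
        return disp

    coincident = dist == 0.0
    unit = np.zeros((len(i), 2))
    nz = ~coincident
    unit[nz] = diff[nz] / dist[nz, None]
    if coincident.any():
        if rng is None:
            rng = np.random.default_rng(0)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=int(coincident.sum()))
        unit[coincident] = np.column_stack((np.cos(theta), np.sin(theta)))

    mag = -params.cca * (1.0 - dist / (params.R_interact * rsum)) ** 2
    overlap = dist < rsum
    mag[overlap] += params.ccr * (1.0 - dist[overlap] / rsum[overlap]) ** 2
    force = (mag / params.mu)[:, None] * unit  # on cell i; −force on cell j
    np.add.at(disp, i, dt * force)
    np.add.at(disp, j, -dt * force)
    return disp


def pairwise_displacements(
    positions: np.ndarray,
    radii: np.ndarray,
    params: MechanicsParams,
    dt: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pairwise adhesion-repulsion displacements with a fresh neighbor search."""
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ConfigurationError("all radii must be positive")
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    i, j = pair_candidates(positions, radii, params.R_interact)
    return displacements_from_pairs(positions, radii, i, j, params, dt, rng)


def simple_pressure(cell: tuple[np.ndarray, float], neighbors) -> float:
    """Simple pressure on one cell given (position, radius) neighbors."""
    pos, radius = np.asarray(cell[0], float), float(cell[1])
    p = 0.0
    for npos, nrad in neighbors:
        d = float(np.linalg.norm(np.asarray(npos, float) - pos))
        rsum = radius + nrad
        if d < rsum:
            p += (1.0 - d / rsum) ** 2
    return p


def deformation_death_check(d_hat: float, d_max: float, cause_is_cancer: bool) -> bool:
    """Mechanical-death rule for a live parenchymal cell.

    True iff the deformation exceeds the tolerated maximum AND the dominant
    deforming neighbor (largest overlap) is a cancer cell; deformation by
    other parenchymal cells never triggers death.
    """
    return bool(d_hat > d_max and cause_is_cancer)
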