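"""The cell data model, the pressure-gated cancer cycle, death, and engulfment.

Six cell types share one agent class: cancer, parenchymal (resident
epithelial tissue), macrophage, dendritic cell (DC), CD8+ cytotoxic T cell,
and CD4+ helper T cell.  Volume and radius are tied by V = (4/3)πR³.

Cancer cells cycle between G0/G1 and a timed S-G2-M phase; the G0/G1 → S
transition probability per interval Δt falls linearly with the local simple
pressure p,

    Prob = r̄₀₁ · max{0, (p_max − p)/p_max} · Δt,

so crowded colonies stall while free edges proliferate.  Parenchymal cells
are in homeostasis and never divide.

Dying cells become corpses that shrink linearly over τ_clear while releasing
their volume into the debris field, unless a macrophage engulfs them first
(the macrophage then absorbs the corpse's entire remaining volume).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dfield
from enum import IntEnum

import numpy as np

from .errors import ConfigurationError, StaleReferenceError

__all__ = [
    "CellType",
    "Phase",
    "MacState",
    "DcState",
    "Cell",
    "CycleParams",
    "cycle_transition_probability",
    "divide",
    "start_death",
    "engulf",
    "radius_from_volume",
    "volume_from_radius",
]


class CellType(IntEnum):
    CANCER = 0
    PARENCHYMAL = 1
    MACROPHAGE = 2
    DC = 3
    CD8 = 4
    CD4 = 5



class Phase(IntEnum):
    G0G1 = 0
    SG2M = 1
    DEAD_APOPTOTIC = 2
    DEAD_DEBRIS = 3


class MacState(IntEnum):
    M0 = 0
    M1 = 1
    M2 = 2
    HYPERACTIVATED = 3
    EXHAUSTED = 4


class DcState(IntEnum):
    INACTIVE = 0
    ACTIVE = 1
    DEPARTED = 2


def volume_from_radius(radius: float) -> float:
    return (4.0 / 3.0) * math.pi * radius**3


def radius_from_volume(volume: float) -> float:
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


_fresh_id = itertools.count(1_000_000)


@dataclass
class Cell:
    """One off-lattice agent."""

    id: int
    type: CellType
    position: np.ndarray
    radius: float = 8.4
    phase: Phase = Phase.G0G1
    mac_state: MacState | None = None
    dc_state: DcState | None = None
    attached_to: set = dfield(default_factory=set)  # ids of attachment partners
    attach_clock: float = 0.0  # elapsed attachment time (min)
    ingested_volume: float = 0.0  # µm³ of engulfed material
    pressure: float = 0.0  # dimensionless simple pressure
    anchor: object | None = None  # EcmAnchor for parenchymal cells
    # engine bookkeeping
    volume: float = dfield(default=None)  # type: ignore[assignment]
    motil_dir: np.ndarray | None = None  # persisted random walk direction ξ
    phase_clock: float = 0.0  # time in current timed phase (min)
    digest_timer: float = 0.0  # remaining phagocytosis lockout (min)
    corpse_remaining: float = 0.0  # undegraded corpse volume (µm³)
    volume_at_death: float = 0.0  # µm³ at the moment of death
    kill_credit: float = 0.0  # accumulated CD8 attachment time (cancer)
    credit_by_attacker: dict = dfield(default_factory=dict)
    attach_target: object | None = None  # Cell a CD8/DC is bound to
    removed: bool = False
    secretes_tnf: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.volume is None:
            self.volume = volume_from_radius(self.radius)
        if self.type is CellType.MACROPHAGE and self.mac_state is None:
            self.mac_state = MacState.M0
        if self.type is CellType.DC and self.dc_state is None:
            self.dc_state = DcState.INACTIVE

    # -- state helpers ----------------------------------------------------

    @property
    def alive(self) -> bool:
        return self.phase in (Phase.G0G1, Phase.SG2M) and not self.removed

    @property
    def dead(self) -> bool:
        return self.phase in (Phase.DEAD_APOPTOTIC, Phase.DEAD_DEBRIS) and not self.removed

    def set_volume(self, volume: float) -> None:
        """Change volume; radius follows from V = (4/3)πR³."""
        self.volume = volume
        self.radius = radius_from_volume(volume)


@dataclass
class CycleParams:
    """Pressure-gated cancer cycle constants."""

    r01_bar: float = 7.2e-4  # base G0/G1→S rate (1/min), ~1 division/day unstressed
    p_max: float = 1.0  # simple-pressure threshold halting proliferation
    division_time: float = 480.0  # S-G2-M duration (min)
    tau_grow: float = 240.0  # volume-recovery time constant after division (min)

    def __post_init__(self) -> None:
        if self.r01_bar < 0:
            raise ConfigurationError("r01_bar must be nonnegative")
        if self.p_max <= 0:
            raise ConfigurationError("p_max must be positive")
        if self.tau_grow <= 0:
            raise ConfigurationError("tau_grow must be positive")


def grow_toward(cell: Cell, v_target: float, dt: float, tau_grow: float) -> Cell:
    """Exponential volume recovery toward the target live-cell volume.

    Daughters are born at half the mother's volume; V relaxes as
    dV/dt = (V_target − V)/τ_grow so a daughter regains ~95% of the target
    within three time constants (inside one cycle at defaults).
    """
    v = v_target + (cell.volume - v_target) * math.exp(-dt / tau_grow)
    cell.set_volume(v)
    return cell


def cycle_transition_probability(p: float, params: CycleParams, dt: float) -> float:
    """G0/G1 → S transition probability in an interval dt at pressure p."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if p < 0:
        raise ConfigurationError("pressure must be nonnegative")
    prob = params.r01_bar * max(0.0, (params.p_max - p) / params.p_max) * dt
    return min(1.0, prob)


def divide(cell: Cell, rng: np.random.Generator, id_alloc=None) -> tuple[Cell, Cell]:
    """Split a cell that finished S-G2-M into two half-volume daughters.

    Daughters are placed at ± R_mother/2 along a uniformly random axis (so
    their separation equals the mother's radius) and restart in G0/G1.
    """
    if id_alloc is None:
        id_alloc = lambda: next(_fresh_id)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    axis = np.array([np.cos(theta), np.sin(theta)])
    half_v = cell.volume / 2.0
    r_d = radius_from_volume(half_v)
    offset = (cell.radius / 2.0) * axis
    daughters = []
    for sign in (+1.0, -1.0):
        d = Cell(
            id=id_alloc(),
            type=cell.type,
            position=cell.position + sign * offset,
            radius=r_d,
            phase=Phase.G0G1,
        )
        daughters.append(d)
    return daughters[0], daughters[1]


def start_death(cell: Cell, mode: str = "apoptosis-mechanical") -> Cell:
    """Move a live cell onto the corpse pathway (idempotent).

    The corpse stops cycling, moving and secreting TNF, and will release its
    volume at death into the debris field at a constant rate over τ_clear.
    """
    if not cell.alive:
        return cell
    cell.phase = Phase.DEAD_APOPTOTIC
    cell.corpse_remaining = cell.volume
    cell.volume_at_death = cell.volume
    cell.secretes_tnf = False
    cell.phase_clock = 0.0
    cell.attached_to.clear()
    cell.attach_clock = 0.0
    return cell


def engulf(mac: Cell, target: Cell, tau_digest: float = 15.0) -> Cell:
    """A macrophage absorbs a target cell's entire (remaining) volume.

    The target is removed from the world; the macrophage's volume and
    ingested-material tally grow by the absorbed volume, an unpolarized (M0)
    macrophage activates to the pro-inflammatory M1 state, and a digestion
    lockout of τ_digest minutes starts during which it cannot engulf again.
    """
    if target.removed:
        raise StaleReferenceError(f"target cell {target.id} was already removed")
    absorbed = target.corpse_remaining if target.dead else target.volume
    mac.set_volume(mac.volume + absorbed)
    mac.ingested_volume += absorbed
    mac.digest_timer = tau_digest
    if mac.mac_state is MacState.M0:
        mac.mac_state = MacState.M1
        mac.secretes_tnf = True
    target.removed = True
    target.corpse_remaining = 0.0
    return mac
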