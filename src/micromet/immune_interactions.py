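"""Stochastic immune-cell interaction rules.

Every discrete interaction is a rate event: in an interval Δt it fires with
probability min(1, rate·Δt).  The rules implemented here:

* recruitment — macrophages and DCs enter through vascular voxels at a rate
  proportional to the TNF signal integrated over the tissue,
  N = r_recruit ∫_Ω min(1, max(0, (ρ−ρ_min)/(ρ_sat−ρ_min))) dV Δt,
  with unbiased stochastic rounding of the fractional part;
* phagocytosis — macrophages in contact with dead cells engulf them
  (rate r_phag) and polarize M0 → M1; hyperactivated macrophages may engulf
  live cancer cells; past an ingested-volume threshold they exhaust
  (absorbing: no further phagocytosis, elevated death rate); CD4 contact
  hyperactivates M1; CD8 contact converts M1 → M2 permanently (TNF off);
* dendritic cells — inactive DCs attach to cancer or dying parenchymal
  cells (rate r_attach) and activate; active DCs leave for the lymph node
  (rate r_leave), emitting a departure event for the delay queue;
* CD8 killing — unattached CD8s attach to live cancer neighbors (rate
  r_attach); several CD8s may bind one target and their attachment times
  add, killing the target once the pooled credit reaches T_attach; an
  attached CD8 detaches with probability Δt/T_attach per interval, taking
  its own contributed credit with it.

"Contact" means center distance ≤ R_i + R_j.  Candidate partners are tested
in randomized order, one success per cell per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .agents import Cell, CellType, DcState, MacState, engulf, start_death
from .errors import ConfigurationError
from .microenvironment import DiffusionField, VoxelGrid

__all__ = [
    "RecruitmentParams",
    "InteractionRates",
    "rate_event",
    "stochastic_round",
    "recruited_count",
    "place_recruited",
    "macrophage_update",
    "dc_update",
    "cd8_update",
]


@dataclass
class RecruitmentParams:
    """TNF-driven recruitment through the vasculature (one immune cell type)."""

    r_recruit: float  # cells per µm³ per min at saturating signal
    rho_min: float  # minimum TNF signal (substrate/µm³)
    rho_sat: float  # saturating TNF signal (substrate/µm³)

    def __post_init__(self) -> None:
        if self.r_recruit < 0:
            raise ConfigurationError("recruitment rate must be nonnegative")
        if not self.rho_sat > self.rho_min >= 0:
            raise ConfigurationError("need rho_sat > rho_min >= 0")


@dataclass
class InteractionRates:
    r_phag: float = 0.05  # macrophage phagocytosis rate (1/min)
    r_attach_dc: float = 0.05  # DC attachment rate (1/min)
    r_leave: float = 2e-3  # activated-DC lymph-node departure rate (1/min)
    r_attach_cd8: float = 0.05  # CD8 attachment rate (1/min)
    T_attach: float = 60.0  # pooled attachment time that kills (min)
    exhaustion_threshold: float = 2482.7  # ingested µm³ triggering exhaustion
    exhausted_death_rate: float = 8.7e-4  # elevated death rate (1/min)
    tau_digest: float = 15.0  # post-engulfment lockout (min)

    def __post_init__(self) -> None:
        for name in ("r_phag", "r_attach_dc", "r_leave", "r_attach_cd8",
                     "exhaustion_threshold", "exhausted_death_rate", "tau_digest"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.T_attach <= 0:
            raise ConfigurationError("T_attach must be positive")


def rate_event(rate: float, dt: float, rng: np.random.Generator) -> bool:
    """True with probability min(1, rate·dt)."""
    if rate < 0:
        raise ConfigurationError("rate must be nonnegative")
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    p = rate * dt
    if p >= 1.0:
        return True
    return bool(rng.random() < p)

def stochastic_round(x: float, rng: np.random.Generator) -> int:
    """Unbiased integerization: floor(x) plus Bernoulli(frac(x))."""
    base = int(np.floor(x))
    return base + int(rng.random() < (x - base))


def recruited_count(
    tnf_field: DiffusionField,
    grid: VoxelGrid,
    params: RecruitmentParams,
    dt: float,
    rng: np.random.Generator,
) -> int:
    """Number of immune cells recruited in dt from the tissue TNF signal."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    ramp = (tnf_field.conc - params.rho_min) / (params.rho_sat - params.rho_min)
    signal = np.clip(ramp, 0.0, 1.0).sum() * grid.voxel_volume
    return stochastic_round(params.r_recruit * signal * dt, rng)


def place_recruited(
    grid: VoxelGrid,
    n: int,
    cell_type: CellType,
    rng: np.random.Generator,
    radius: float = 8.4,
    id_alloc=None,
) -> list[Cell]:
    """n fresh cells of cell_type jittered around random vascular voxel centers."""
    if n == 0:
        return []
    centers = grid.vascular_positions()
    if len(centers) == 0:
        raise ConfigurationError("cannot place recruited cells: no vascular voxels")
    idx = rng.integers(0, len(centers), size=n)
    jitter = rng.uniform(-0.25, 0.25, size=(n, 2)) * grid.voxel_size
    cells = []
    for k in range(n):
        cid = id_alloc() if id_alloc is not None else None
        cell = Cell(
            id=cid if cid is not None else -(k + 1),
            type=cell_type,
            position=centers[idx[k]] + jitter[k],
            radius=radius,
        )
        cells.append(cell)
    return cells


def _in_contact(a: Cell, b: Cell) -> bool:
    pa, pb = a.position, b.position
    return math.hypot(pa[0] - pb[0], pa[1] - pb[1]) <= a.radius + b.radius


def _shuffled(seq, rng: np.random.Generator):
    seq = list(seq)
    if len(seq) > 1:
        order = rng.permutation(len(seq))
        seq = [seq[k] for k in order]
    return seq


def macrophage_update(
    mac: Cell,
    neighbors: list[Cell],
    rates: InteractionRates,
    dt: float,
    rng: np.random.Generator,
    events: list | None = None,
) -> Cell:
    """One phenotype-step update of the macrophage state machine.

    Transition DAG: M0 → M1 → {M2, hyperactivated, exhausted}; M2 and
    exhausted are absorbing.  Order per step: phagocytosis attempt (dead
    cells; live cancer too if hyperactivated), CD4-contact hyperactivation,
    CD8-contact M2 conversion, exhaustion check.
    """
    if not (mac.type is CellType.MACROPHAGE and mac.alive):
        return mac
    contacts = [nb for nb in neighbors if nb is not mac and not nb.removed and _in_contact(mac, nb)]

    # (1)-(2) phagocytosis: M2 and exhausted macrophages never engulf
    if mac.mac_state in (MacState.M0, MacState.M1, MacState.HYPERACTIVATED) and mac.digest_timer <= 0.0:
        targets = [nb for nb in contacts if nb.dead]
        if mac.mac_state is MacState.HYPERACTIVATED:
            targets += [nb for nb in contacts if nb.alive and nb.type is CellType.CANCER]
        for target in _shuffled(targets, rng):
            if rate_event(rates.r_phag, dt, rng):
                engulf(mac, target, rates.tau_digest)
                if events is not None:
                    events.append(("engulf", mac.id, target.id))
                break

    # (3) CD4 contact hyperactivates a pro-inflammatory macrophage
    if mac.mac_state is MacState.M1 and any(
        nb.type is CellType.CD4 and nb.alive for nb in contacts
    ):
        mac.mac_state = MacState.HYPERACTIVATED
        if events is not None:
            events.append(("hyperactivate", mac.id, None))

    # (4) CD8 contact converts M1 to anti-inflammatory M2; TNF off, permanent
    if mac.mac_state is MacState.M1 and any(
        nb.type is CellType.CD8 and nb.alive for nb in contacts
    ):
        mac.mac_state = MacState.M2
        mac.secretes_tnf = False
        if events is not None:
            events.append(("m2_convert", mac.id, None))

    # (5) exhaustion is absorbing; exhausted macrophages die at an elevated rate
    if (
        mac.mac_state not in (MacState.M2, MacState.EXHAUSTED)
        and mac.ingested_volume >= rates.exhaustion_threshold
    ):
        mac.mac_state = MacState.EXHAUSTED
        mac.secretes_tnf = False
        if events is not None:
            events.append(("exhaust", mac.id, None))
    if mac.mac_state is MacState.EXHAUSTED and rate_event(rates.exhausted_death_rate, dt, rng):
        start_death(mac, "exhaustion-death")
    return mac


def _dc_eligible(nb: Cell) -> bool:
    """DC activation targets: live-or-dying cancer cells, dying parenchyma."""
    if nb.removed:
        return False
    if nb.type is CellType.CANCER:
        return nb.alive or nb.dead
    if nb.type is CellType.PARENCHYMAL:
        return nb.dead
    return False


def dc_update(
    dc: Cell,
    neighbors: list[Cell],
    rates: InteractionRates,
    dt: float,
    rng: np.random.Generator,
    events: list | None = None,
) -> tuple[Cell, bool]:
    """One phenotype-step DC update; returns (dc, departed_this_step).

    Inactive DCs attach to an eligible contact (antigen capture) and
    activate; active DCs leave the tissue for the lymph node with
    probability r_leave·dt, at which point they are removed from the world
    and a departure event is handed to the lymph-node delay queue.
    """
    if not (dc.type is CellType.DC and dc.alive) or dc.dc_state is DcState.DEPARTED:
        return dc, False
    if dc.dc_state is DcState.INACTIVE:
        for nb in _shuffled(neighbors, rng):
            if nb is dc or not _dc_eligible(nb) or not _in_contact(dc, nb):
                continue
            if rate_event(rates.r_attach_dc, dt, rng):
                dc.dc_state = DcState.ACTIVE
                if events is not None:
                    events.append(("activate", dc.id, nb.id))
                break
        return dc, False
    if rate_event(rates.r_leave, dt, rng):
        dc.dc_state = DcState.DEPARTED
        dc.removed = True
        if events is not None:
            events.append(("dc_depart", dc.id, None))
        return dc, True
    return dc, False


def cd8_update(
    t: Cell,
    neighbors: list[Cell],
    rates: InteractionRates,
    dt: float,
    rng: np.random.Generator,
    events: list | None = None,
) -> Cell:
    """One phenotype-step CD8 update: attach, accrue kill credit, detach.

    Attached CD8s pool their attachment time on the target (additive
    credit); the cancer cell dies when the pool reaches T_attach, releasing
    every attached CD8.  Credit is accrued and the kill checked before the
    detachment draw, so T_attach = dt kills in a single step.
    """
    if not (t.type is CellType.CD8 and t.alive):
        return t
    target = t.attach_target
    if target is not None and (target.removed or not target.alive):
        # stale reference: target died or was engulfed elsewhere
        t.attach_target = None
        t.attached_to.discard(getattr(target, "id", None))
        t.attach_clock = 0.0
        target = None
    if target is None:
        for nb in _shuffled(neighbors, rng):
            if nb is t or nb.removed or not nb.alive or nb.type is not CellType.CANCER:
                continue
            if _in_contact(t, nb) and rate_event(rates.r_attach_cd8, dt, rng):
                t.attach_target = nb
                t.attached_to.add(nb.id)
                nb.attached_to.add(t.id)
                nb.credit_by_attacker.setdefault(t.id, 0.0)
                if events is not None:
                    events.append(("cd8_attach", t.id, nb.id))
                break
        return t

    # accrue this attacker's credit, then test for the kill
    t.attach_clock += dt
    target.credit_by_attacker[t.id] = target.credit_by_attacker.get(t.id, 0.0) + dt
    target.kill_credit += dt
    if target.kill_credit >= rates.T_attach - 1e-9:
        if events is not None:
            events.append(("kill", t.id, target.id))
        start_death(target, "killed-by-cd8")
        for aid in list(target.attached_to):
            target.attached_to.discard(aid)
        target.credit_by_attacker.clear()
        t.attach_target = None
        t.attached_to.discard(target.id)
        t.attach_clock = 0.0
        return t
    if rate_event(1.0 / rates.T_attach, dt, rng):
        # detach, withdrawing this attacker's contribution
        target.kill_credit -= target.credit_by_attacker.pop(t.id, 0.0)
        target.attached_to.discard(t.id)
        t.attach_target = None
        t.attached_to.discard(target.id)
        t.attach_clock = 0.0
        if events is not None:
            events.append(("cd8_detach", t.id, target.id))
    return t
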