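"""World assembly and the nested-timestep main loop.

Three clocks are nested: diffusion (dt_diffusion) inside mechanics/motility
(dt_mechanics) inside phenotype/interaction decisions, recruitment and the
lymph-node step (dt_phenotype).  A single seeded NumPy generator drives all
stochastic draws in a fixed order, so a (config, seed) pair reproduces a
trajectory bit-for-bit.

The tissue starts as a confluent hexagonal monolayer of parenchymal cells
tethered to the matrix at rest (d̂ = 0), with the configured numbers of
cancer cells, unpolarized macrophages and inactive DCs dropped at uniform
random non-overlapping positions; both substrate fields start at zero and
the lymph node at its antigen-free baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mechanics as mech
from . import _kernels
from .agents import (
    Cell,
    CellType,
    DcState,
    MacState,
    Phase,
    cycle_transition_probability,
    divide,
    grow_toward,
    start_death,
    volume_from_radius,
)
from .config import WorldConfig
from .errors import ConfigurationError
from .immune_interactions import (
    cd8_update,
    dc_update,
    macrophage_update,
    place_recruited,
    recruited_count,
)
from .lymph_node import LymphNodeState, dispatch_t_cells, ln_step
from .microenvironment import DiffusionField, VoxelGrid, assign_vascular_voxels
from .motility import motility_state, random_unit

__all__ = ["World", "Trajectory", "initialize_world", "run_simulation", "simulate"]

log = logging.getLogger("micromet")

_POP_COLUMNS = [
    "t", "cancer", "parenchymal", "m0", "m1", "m2", "hyperactivated",
    "exhausted", "dc_inactive", "dc_active", "cd8", "cd4", "corpses",
]


@dataclass
class Trajectory:
    """Everything one run records."""

    times: list = field(default_factory=list)  # snapshot times (min)
    cell_tables: list = field(default_factory=list)  # one DataFrame per snapshot
    field_tables: list = field(default_factory=list)  # per-snapshot voxel tables
    vascular_mask: pd.DataFrame | None = None  # voxel table, written once per run
    populations: pd.DataFrame | None = None
    lymph: pd.DataFrame | None = None
    events: pd.DataFrame | None = None
    config: WorldConfig | None = None

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    @property
    def final_cancer_count(self) -> int:
        """P_M: live cancer cells in the final snapshot."""
        tab = self.cell_tables[-1]
        return int(((tab["type"] == "cancer") & (tab["alive"])).sum())

    def save(self, outdir) -> None:
        import json
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for t, tab in zip(self.times, self.cell_tables):
            tab.to_csv(out / f"cells_t{int(round(t)):06d}.csv", index=False)
        for t, tab in zip(self.times, self.field_tables):
            tab.to_csv(out / f"fields_t{int(round(t)):06d}.csv", index=False)
        if self.vascular_mask is not None:
            self.vascular_mask.to_csv(out / "vascular_mask.csv", index=False)
        self.populations.to_csv(out / "populations.csv", index=False)
        self.lymph.to_csv(out / "lymphnode.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        with open(out / "run-manifest.json", "w") as fh:
            json.dump({"config": self.config.to_dict(), "P_M": self.final_cancer_count}, fh,
                      indent=2, default=float)


class World:
    """Mutable simulation state."""

    def __init__(self, config: WorldConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        n = int(round(config.domain_size / config.voxel_size))
        if abs(n * config.voxel_size - config.domain_size) > 1e-6:
            raise ConfigurationError("voxel_size must divide domain_size")
        self.grid = VoxelGrid(nx=n, ny=n, voxel_size=config.voxel_size)
        f = config.fields
        self.tnf = DiffusionField("TNF", self.grid, f.D_tnf, f.lambda_tnf)
        self.debris = DiffusionField("debris", self.grid, f.D_debris, f.lambda_debris)
        self.cells: list[Cell] = []
        self.lymph = LymphNodeState()
        self.t = 0.0
        self._next_id = 0
        self.events: list = []

    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id

    @property
    def live_cells(self) -> list[Cell]:
        return [c for c in self.cells if c.alive]

    def counts(self) -> dict:
        out = dict.fromkeys(_POP_COLUMNS[1:], 0)
        for c in self.cells:
            if c.removed:
                continue
            if c.dead:
                out["corpses"] += 1
            elif c.type is CellType.CANCER:
                out["cancer"] += 1
            elif c.type is CellType.PARENCHYMAL:
                out["parenchymal"] += 1
            elif c.type is CellType.MACROPHAGE:
                out[{MacState.M0: "m0", MacState.M1: "m1", MacState.M2: "m2",
                     MacState.HYPERACTIVATED: "hyperactivated",
                     MacState.EXHAUSTED: "exhausted"}[c.mac_state]] += 1
            elif c.type is CellType.DC:
                out["dc_inactive" if c.dc_state is DcState.INACTIVE else "dc_active"] += 1
            elif c.type is CellType.CD8:
                out["cd8"] += 1
            elif c.type is CellType.CD4:
                out["cd4"] += 1
        return out


def hex_lattice(domain: float, radius: float) -> np.ndarray:
    """Confluent hexagonal packing of circles of the given radius."""
    s = 2.0 * radius
    dy = s * np.sqrt(3.0) / 2.0
    pts = []
    y = radius
    row = 0
    while y <= domain - radius + 1e-9:
        x = radius + (s / 2.0 if row % 2 else 0.0)
        while x <= domain - radius + 1e-9:
            pts.append((x, y))
            x += s
        y += dy
        row += 1
    return np.array(pts)


def initialize_world(config: WorldConfig, rng: np.random.Generator | None = None) -> World:
    """Assemble the initial tissue patch."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    world = World(config, rng)
    assign_vascular_voxels(world.grid, config.vascular_fraction, rng)
    R = config.cell_radius
    L = config.domain_size

    for xy in hex_lattice(L, R):
        cell = Cell(id=world.new_id(), type=CellType.PARENCHYMAL, position=xy, radius=R)
        cell.anchor = mech.EcmAnchor(
            xy + R * random_unit(rng), config.ecm.r_E, config.ecm.r_P, config.ecm.d_max
        )
        world.cells.append(cell)

    # cancer seeds and resident immune cells at random non-overlapping spots
    placed: list[np.ndarray] = []
    specs = [
        (CellType.CANCER, config.initial_cancer),
        (CellType.MACROPHAGE, config.initial_macrophages),
        (CellType.DC, config.initial_dcs),
    ]
    for ctype, count in specs:
        for _ in range(count):
            for attempt in range(2000):
                pos = rng.uniform(R, L - R, size=2)
                if all(np.linalg.norm(pos - q) >= 2 * R for q in placed):
                    break
            else:
                raise ConfigurationError(
                    f"could not place {count} {ctype.name} cells in a {L} µm domain"
                )
            placed.append(pos)
            world.cells.append(Cell(id=world.new_id(), type=ctype, position=pos, radius=R))
    return world


# ---------------------------------------------------------------------------
# main loop internals
# ---------------------------------------------------------------------------


class _Block:
    """Per-phenotype-step cached arrays for the mechanics/motility substeps."""

    def __init__(self, world: World):
        cfg = world.config
        cells = [c for c in world.cells if not c.removed]
        self.cells = cells
        n = len(cells)
        self.pos = np.array([c.position for c in cells]) if n else np.zeros((0, 2))
        self.radius = np.array([c.radius for c in cells])
        # parenchymal tether block
        par_idx, anchors = [], []
        for k, c in enumerate(cells):
            if c.type is CellType.PARENCHYMAL and c.alive and c.anchor is not None:
                par_idx.append(k)
                anchors.append(c.anchor.x_ecm)
        self.par_idx = np.array(par_idx, dtype=int)
        self.anchors = np.array(anchors) if anchors else np.zeros((0, 2))
        # motility block (only immune types can move; cheap pre-filter)
        mot_idx, speed, sig_t, sig_d, xi = [], [], [], [], []
        for k, c in enumerate(cells):
            if c.type.value < CellType.MACROPHAGE.value:
                continue
            mp = motility_state(c, cfg.motility)
            if mp is None or mp.s_mot == 0.0:
                continue
            if c.motil_dir is None:
                c.motil_dir = random_unit(world.rng)
            mot_idx.append(k)
            speed.append(mp.s_mot)
            sig_t.append(mp.sigma_tnf)
            sig_d.append(mp.sigma_debris)
            xi.append(c.motil_dir)
        self.mot_idx = np.array(mot_idx, dtype=int)
        self.speed = np.array(speed)
        self.sig_t = np.array(sig_t)
        self.sig_d = np.array(sig_d)
        self.xi = np.array(xi) if xi else np.zeros((0, 2))
        # Verlet neighbor list, refreshed once any cell's travel eats the skin
        self.skin = 10.0
        self.travel = np.zeros(n)
        self._refresh_pairs(cfg)

    def _refresh_pairs(self, cfg) -> None:
        self.pair_i, self.pair_j = mech.pair_candidates(
            self.pos, self.radius, cfg.mechanics.R_interact, self.skin
        )
        self.travel[:] = 0.0

    def note_travel(self, max_travel: float, cfg) -> None:
        if max_travel > 0.45 * self.skin:
            self._refresh_pairs(cfg)

    def scatter(self) -> None:
        for k, c in enumerate(self.cells):
            c.position = self.pos[k]
        for k, j in enumerate(self.par_idx):
            self.cells[j].anchor.x_ecm = self.anchors[k]
        for k, j in enumerate(self.mot_idx):
            self.cells[j].motil_dir = self.xi[k]


def _grad_at(conc: np.ndarray, h: float, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    gx, gy = np.gradient(conc, h, edge_order=1)
    return np.column_stack((gx[ii, jj], gy[ii, jj]))


def _motility_displacements(world: World, blk: _Block, dt: float) -> np.ndarray:
    """dt·v⃗ for every motile cell in the block (rng draws happen here)."""
    cfg = world.config
    rng = world.rng
    if len(blk.mot_idx):
        h = cfg.voxel_size
        n = world.grid.nx
        mpos = blk.pos[blk.mot_idx]
        ii = np.clip((mpos[:, 0] / h).astype(int), 0, n - 1)
        jj = np.clip((mpos[:, 1] / h).astype(int), 0, world.grid.ny - 1)
        gt = _grad_at(world.tnf.conc, h, ii, jj)
        gd = _grad_at(world.debris.conc, h, ii, jj)
        bias = blk.sig_t[:, None] * gt + blk.sig_d[:, None] * gd
        nrm = np.linalg.norm(bias, axis=1)
        flat = nrm == 0.0
        m = len(blk.mot_idx)
        if flat.any():
            theta = rng.uniform(0.0, 2 * np.pi, size=int(flat.sum()))
            bias[flat] = np.column_stack((np.cos(theta), np.sin(theta)))
            nrm[flat] = 1.0
        bias /= nrm[:, None]
        repick = rng.random(m) < min(1.0, dt / cfg.motility.T_per)
        if repick.any():
            theta = rng.uniform(0.0, 2 * np.pi, size=int(repick.sum()))
            blk.xi[repick] = np.column_stack((np.cos(theta), np.sin(theta)))
        b = cfg.motility.b
        blend = (1.0 - b) * blk.xi + b * bias
        bnrm = np.linalg.norm(blend, axis=1)
        degenerate = bnrm < 1e-14
        if degenerate.any():
            theta = rng.uniform(0.0, 2 * np.pi, size=int(degenerate.sum()))
            blk.xi[degenerate] = np.column_stack((np.cos(theta), np.sin(theta)))
            blend = (1.0 - b) * blk.xi + b * bias
            bnrm = np.linalg.norm(blend, axis=1)
        v = blk.speed[:, None] * blend / bnrm[:, None]
        return dt * v
    return np.zeros((0, 2))


def _mech_substep(world: World, blk: _Block, dt: float) -> None:
    """One mechanics/motility substep over the block's state arrays."""
    cfg = world.config
    if len(blk.cells) == 0:
        return
    mot_disp = _motility_displacements(world, blk, dt)
    if _kernels.HAVE_NUMBA:
        max_travel = _kernels._substep(
            blk.pos, blk.radius, blk.pair_i, blk.pair_j,
            cfg.mechanics.cca, cfg.mechanics.ccr, cfg.mechanics.R_interact,
            cfg.mechanics.mu, dt,
            blk.par_idx, blk.anchors, cfg.ecm.r_E, cfg.ecm.r_P,
            blk.mot_idx, mot_disp, cfg.domain_size, blk.travel,
        )
    else:  # pragma: no cover - exercised only without numba
        disp = mech.displacements_from_pairs(
            blk.pos, blk.radius, blk.pair_i, blk.pair_j, cfg.mechanics, dt, world.rng
        )
        if len(blk.mot_idx):
            disp[blk.mot_idx] += mot_disp
        blk.pos += disp
        blk.travel += np.linalg.norm(disp, axis=1)
        if len(blk.par_idx):
            old = blk.pos[blk.par_idx].copy()
            newp, newa = mech.ecm_step_arrays(
                old, blk.anchors, blk.radius[blk.par_idx],
                cfg.ecm.r_E, cfg.ecm.r_P, dt,
            )
            blk.pos[blk.par_idx] = newp
            blk.anchors = newa
            blk.travel[blk.par_idx] += np.linalg.norm(newp - old, axis=1)
        L = cfg.domain_size
        p = blk.pos
        np.abs(p, out=p)
        over = p > L
        p[over] = 2.0 * L - p[over]
        np.clip(p, 0.0, np.nextafter(L, 0.0), out=p)
        max_travel = float(blk.travel.max()) if len(blk.travel) else 0.0
    blk.note_travel(max_travel, cfg)


def _contacts_and_pressure(
    cells: list[Cell], consumer_mask: np.ndarray
) -> tuple[np.ndarray, dict[int, list[Cell]]]:
    """Simple pressures and touching-neighbor lists from one pair pass.

    Contact means center distance ≤ R_i + R_j; the pressure sums
    (1 − d/(R_i+R_j))² over strictly overlapping pairs.  Neighbor lists are
    materialized only for the cells flagged in consumer_mask (the ones whose
    interaction rules read them).
    """
    from scipy.spatial import cKDTree

    out: dict[int, list[Cell]] = {}
    press = np.zeros(len(cells))
    if len(cells) < 2:
        return press, out
    pos = np.array([c.position for c in cells])
    rad = np.array([c.radius for c in cells])
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=2.0 * float(rad.max()), output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(pos[i] - pos[j], axis=1)
        rsum = rad[i] + rad[j]
        keep = d <= rsum
        i, j, d, rsum = i[keep], j[keep], d[keep], rsum[keep]
        term = np.zeros(len(d))
        overlap = d < rsum
        term[overlap] = (1.0 - d[overlap] / rsum[overlap]) ** 2
        np.add.at(press, i, term)
        np.add.at(press, j, term)
        either = consumer_mask[i] | consumer_mask[j]
        for a, b in zip(i[either], j[either]):
            a, b = int(a), int(b)
            if consumer_mask[a]:
                out.setdefault(a, []).append(cells[b])
            if consumer_mask[b]:
                out.setdefault(b, []).append(cells[a])
    return press, out


def _source_arrays(world: World, dt_phen: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel secretion-rate arrays (substrate/min) for the coming block."""
    cfg = world.config
    grid = world.grid
    s_tnf = np.zeros((grid.nx, grid.ny))
    s_debris = np.zeros((grid.nx, grid.ny))
    h = grid.voxel_size
    for c in world.cells:
        if c.removed or not (c.secretes_tnf or c.dead):
            continue
        i = min(int(c.position[0] / h), grid.nx - 1)
        j = min(int(c.position[1] / h), grid.ny - 1)
        if c.alive and c.secretes_tnf:
            s_tnf[i, j] += cfg.fields.tnf_secretion_rate
        elif c.dead and c.corpse_remaining > 0.0:
            rate = min(c.volume_at_death / cfg.tau_clear, c.corpse_remaining / dt_phen)
            s_debris[i, j] += rate
            c._release_rate = rate  # consumed by the corpse bookkeeping
    return s_tnf, s_debris


def _phenotype_step(world: World) -> None:
    cfg = world.config
    rng = world.rng
    dt = cfg.dt_phenotype
    cells = [c for c in world.cells if not c.removed]

    # who will read a neighbor list this step: immune effectors, plus any
    # parenchymal cell deformed beyond tolerance (for death attribution)
    consumer_mask = np.zeros(len(cells), dtype=bool)
    par: list[tuple[int, Cell]] = []
    for k, c in enumerate(cells):
        if c.type is CellType.PARENCHYMAL:
            if c.alive and c.anchor is not None:
                par.append((k, c))
        elif c.alive and c.type in (CellType.MACROPHAGE, CellType.DC, CellType.CD8):
            consumer_mask[k] = True
    flagged: list[tuple[int, Cell, float]] = []
    if par:
        ppos = np.array([c.position for _, c in par])
        panch = np.array([c.anchor.x_ecm for _, c in par])
        prad = np.array([c.radius for _, c in par])
        d_hat = np.linalg.norm(panch - ppos, axis=1) - prad
        for m in np.nonzero(d_hat > cfg.ecm.d_max)[0]:
            k, c = par[m]
            flagged.append((k, c, float(d_hat[m])))
            consumer_mask[k] = True

    pressures, neighbors = _contacts_and_pressure(cells, consumer_mask)
    for c, p in zip(cells, pressures):
        c.pressure = float(p)

    # corpse degradation first, mirroring the debris already released to the
    # field during the diffusion block (constant rate over tau_clear)
    for c in cells:
        rate = getattr(c, "_release_rate", None)
        if rate is None or not c.dead:
            continue
        del c._release_rate
        c.corpse_remaining = max(0.0, c.corpse_remaining - rate * dt)
        c.set_volume(max(c.corpse_remaining, 1e-9))
        if c.corpse_remaining <= 1e-9:
            c.phase = Phase.DEAD_DEBRIS
            c.removed = True

    # parenchymal deformation deaths (vectorized d̂ screen, then attribution)
    for k, c, d_hat in flagged:
        if mech.deformation_death_check(
            d_hat, cfg.ecm.d_max, _dominant_overlap_is_cancer(c, neighbors.get(k, []))
        ):
            start_death(c, "apoptosis-mechanical")
            world.events.append((world.t, "crush_death", c.id, None))

    born: list[Cell] = []
    order = rng.permutation(len(cells)) if cells else []
    for k in order:
        c = cells[k]
        if c.removed or c.type is CellType.PARENCHYMAL:
            continue
        if c.type is CellType.CANCER and c.alive:
            grow_toward(c, _target_volume(cfg), dt, cfg.cycle.tau_grow)
            if c.phase is Phase.G0G1:
                if rng.random() < cycle_transition_probability(c.pressure, cfg.cycle, dt):
                    c.phase = Phase.SG2M
                    c.phase_clock = 0.0
            elif c.phase is Phase.SG2M:
                c.phase_clock += dt
                if c.phase_clock >= cfg.cycle.division_time - 1e-9:
                    d1, d2 = divide(c, rng, id_alloc=world.new_id)
                    c.removed = True
                    born.extend([d1, d2])
        elif c.type is CellType.MACROPHAGE and c.alive:
            c.digest_timer = max(0.0, c.digest_timer - dt)
            ev: list = []
            macrophage_update(c, neighbors.get(k, []), cfg.rates, dt, rng, ev)
            world.events.extend((world.t, *e) for e in ev)
        elif c.type is CellType.DC and c.alive:
            ev = []
            _, departed = dc_update(c, neighbors.get(k, []), cfg.rates, dt, rng, ev)
            world.events.extend((world.t, *e) for e in ev)
            if departed:
                world.lymph.record_departure(world.t)
        elif c.type is CellType.CD8 and c.alive:
            ev = []
            cd8_update(c, neighbors.get(k, []), cfg.rates, dt, rng, ev)
            world.events.extend((world.t, *e) for e in ev)

    world.cells.extend(born)

    # TNF-driven recruitment through the vasculature
    n_mac = recruited_count(world.tnf, world.grid, cfg.recruit_m, dt, rng)
    n_dc = recruited_count(world.tnf, world.grid, cfg.recruit_d, dt, rng)
    for n, ctype in ((n_mac, CellType.MACROPHAGE), (n_dc, CellType.DC)):
        if n:
            world.cells.extend(
                place_recruited(world.grid, n, ctype, rng, cfg.cell_radius, world.new_id)
            )
            world.events.append((world.t, "recruit", ctype.name, n))

    # lymph node advance and delayed T-cell dispatch
    ln_step(world.lymph, cfg.ln, world.t, dt)
    n_cd8, n_cd4 = dispatch_t_cells(world.lymph, world.t + dt, cfg.ln, rng)
    for n, ctype in ((n_cd8, CellType.CD8), (n_cd4, CellType.CD4)):
        if n:
            world.cells.extend(
                place_recruited(world.grid, n, ctype, rng, cfg.cell_radius, world.new_id)
            )
            world.events.append((world.t, "recruit", ctype.name, n))

    world.cells = [c for c in world.cells if not c.removed]


def _target_volume(cfg: WorldConfig) -> float:
    return volume_from_radius(cfg.cell_radius)


def _dominant_overlap_is_cancer(cell: Cell, contacts: list[Cell]) -> bool:
    import math

    best, best_overlap = None, 0.0
    p = cell.position
    for nb in contacts:
        if nb.removed:
            continue
        q = nb.position
        overlap = cell.radius + nb.radius - math.hypot(p[0] - q[0], p[1] - q[1])
        if overlap > best_overlap:
            best, best_overlap = nb, overlap
    return best is not None and best.type is CellType.CANCER


def _field_table(world: World) -> pd.DataFrame:
    """Flat per-voxel table: indices, centers, and both concentrations."""
    grid = world.grid
    ii, jj = np.meshgrid(np.arange(grid.nx), np.arange(grid.ny), indexing="ij")
    xc, yc = grid.voxel_centers()
    return pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "x_center": xc[ii.ravel()],
            "y_center": yc[jj.ravel()],
            "tnf": world.tnf.conc.ravel(),
            "debris": world.debris.conc.ravel(),
        }
    )


def _snapshot_table(world: World) -> pd.DataFrame:
    rows = []
    for c in world.cells:
        if c.removed:
            continue
        state = ""
        if c.mac_state is not None:
            state = c.mac_state.name.lower()
        elif c.dc_state is not None:
            state = c.dc_state.name.lower()
        rows.append(
            (c.id, c.type.name.lower(), state, c.position[0], c.position[1], c.radius,
             c.volume, c.phase.name.lower(), c.alive, c.pressure, c.ingested_volume)
        )
    return pd.DataFrame(
        rows,
        columns=["id", "type", "state", "x", "y", "radius", "volume", "phase",
                 "alive", "pressure", "ingested_volume"],
    )


def run_simulation(world: World, config: WorldConfig | None = None) -> Trajectory:
    """Advance the world to config.duration, recording snapshots and series."""
    cfg = config or world.config
    n_mech = int(round(cfg.dt_phenotype / cfg.dt_mechanics))
    n_diff = max(1, int(round(cfg.dt_mechanics / cfg.dt_diffusion)))
    dt_diff = cfg.dt_mechanics / n_diff
    n_phen = int(round(cfg.duration / cfg.dt_phenotype))
    snap_every = int(round(cfg.snapshot_interval / cfg.dt_phenotype))
    pop_every = max(1, int(round(cfg.population_interval / cfg.dt_phenotype)))

    traj = Trajectory(config=cfg)
    ii, jj = np.nonzero(world.grid.vascular_mask)
    traj.vascular_mask = pd.DataFrame({"i": ii, "j": jj})
    pop_rows, ln_rows = [], []

    def record(step: int) -> None:
        if step % pop_every == 0:
            pop_rows.append({"t": world.t, **world.counts()})
            ln_rows.append((world.t, *world.lymph.pools))
        if step % snap_every == 0:
            traj.times.append(world.t)
            traj.cell_tables.append(_snapshot_table(world))
            traj.field_tables.append(_field_table(world))

    record(0)
    next_log = 60.0
    for step in range(1, n_phen + 1):
        s_tnf, s_debris = _source_arrays(world, cfg.dt_phenotype)
        blk = _Block(world)
        for _ in range(n_mech):
            for _ in range(n_diff):
                for fld, src in ((world.tnf, s_tnf), (world.debris, s_debris)):
                    fld.diffuse(dt_diff)
                    fld.decay(dt_diff)
                    if src.any():
                        fld.add_source_array(src, dt_diff)
            _mech_substep(world, blk, cfg.dt_mechanics)
        blk.scatter()
        _phenotype_step(world)
        world.t = step * cfg.dt_phenotype
        if not np.isfinite(world.tnf.conc).all() or not np.isfinite(world.debris.conc).all():
            raise RuntimeError(f"numerical blow-up in fields at t={world.t} min")
        record(step)
        if world.t >= next_log:
            log.info("t=%.0f min: %s", world.t, {k: v for k, v in world.counts().items() if v})
            next_log += 60.0

    traj.populations = pd.DataFrame(pop_rows, columns=_POP_COLUMNS)
    traj.lymph = pd.DataFrame(
        ln_rows, columns=["t", "D_M", "T_H1", "T_H2", "T_C", "T_Ct", "T_ht"]
    )
    traj.events = pd.DataFrame(world.events, columns=["t", "event", "subject", "object"])
    return traj


def simulate(config: WorldConfig, seed: int | None = None) -> Trajectory:
    """Initialize and run one simulation; seed overrides config.seed."""
    if seed is not None:
        config = WorldConfig.from_dict({**config.to_dict(), "seed": int(seed)})
    world = initialize_world(config)
    return run_simulation(world)
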