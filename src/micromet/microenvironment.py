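"""Cartesian voxel grid, diffusible cytokine/debris fields, and the vascular mask.

The tissue patch is a 2-D monolayer discretized into square voxels of side
``voxel_size`` (µm); each voxel carries a 3-D bookkeeping volume
``voxel_size**3`` (µm³) so that secretion/uptake rates expressed per unit
volume stay dimensionally consistent with the off-lattice agents.

Two substrates live on the grid: TNF (pro-inflammatory cytokine secreted by
activated macrophages) and cellular debris (released by dying cells).  Both
obey

    dρ/dt = D ∇²ρ − λ ρ + sources − sinks

with no-flux (Neumann) boundaries, advanced by operator splitting:
implicit (backward-Euler, per-axis) diffusion, analytic decay, then
cell–voxel exchange.  The per-axis implicit solves are unconditionally
stable, conserve mass exactly with λ = 0 and no sources, and preserve
positivity (the per-axis matrices are M-matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from .errors import ConfigurationError, OutOfDomainError

__all__ = [
    "VoxelGrid",
    "DiffusionField",
    "assign_vascular_voxels",
    "step_fields",
    "sample",
]


@dataclass
class VoxelGrid:
    """Uniform 2-D voxel grid; arrays are indexed ``[i, j]`` with x-index i."""

    nx: int
    ny: int
    voxel_size: float
    vascular_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ConfigurationError("grid needs nx, ny >= 1")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be positive")
        if self.vascular_mask is None:
            self.vascular_mask = np.zeros((self.nx, self.ny), dtype=bool)

    @property
    def voxel_volume(self) -> float:
        """Bookkeeping volume of one voxel (µm³): h² footprint × h thickness."""
        return float(self.voxel_size**3)

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny

    @property
    def extent(self) -> tuple[float, float]:
        return self.nx * self.voxel_size, self.ny * self.voxel_size

    def voxel_of(self, position) -> tuple[int, int]:
        """Containing voxel of a position (µm); raises outside the domain."""
        x, y = float(position[0]), float(position[1])
        lx, ly = self.extent
        if not (0.0 <= x < lx and 0.0 <= y < ly):
            raise OutOfDomainError(f"position ({x:g}, {y:g}) outside [0,{lx:g})x[0,{ly:g})")
        return int(x / self.voxel_size), int(y / self.voxel_size)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        h = self.voxel_size
        return (np.arange(self.nx) + 0.5) * h, (np.arange(self.ny) + 0.5) * h

    def vascular_positions(self) -> np.ndarray:
        """(n_vascular, 2) array of vascular voxel centers."""
        ii, jj = np.nonzero(self.vascular_mask)
        h = self.voxel_size
        return np.column_stack(((ii + 0.5) * h, (jj + 0.5) * h))


def assign_vascular_voxels(grid: VoxelGrid, fraction: float, rng: np.random.Generator) -> VoxelGrid:
    """Flag exactly ``round(fraction · n_voxels)`` voxels as vascularized.

    Voxels are sampled uniformly without replacement; immune cells recruited
    from the circulation enter the tissue through these voxels.  The count
    uses round-half-even so it is deterministic; the choice of voxels is
    deterministic under a fixed seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("vascular fraction must lie in [0, 1]")
    n = round(fraction * grid.n_voxels)
    flat = rng.choice(grid.n_voxels, size=n, replace=False)
    mask = np.zeros(grid.n_voxels, dtype=bool)
    mask[flat] = True
    grid.vascular_mask = mask.reshape(grid.nx, grid.ny)
    return grid


def _banded_neumann(n: int, r: float) -> np.ndarray:
    """Banded form of I − r·L with L the 1-D no-flux Laplacian stencil."""
    ab = np.zeros((3, n))
    ab[0, 1:] = -r
    ab[2, :-1] = -r
    ab[1, :] = 1.0 + 2.0 * r
    ab[1, 0] = 1.0 + r
    ab[1, -1] = 1.0 + r
    return ab


@dataclass
class DiffusionField:
    """One diffusible substrate on a :class:`VoxelGrid`.

    conc has units substrate/µm³, D µm²/min, lam 1/min.
    """

    name: str
    grid: VoxelGrid
    D: float
    lam: float
    conc: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.D < 0 or self.lam < 0:
            raise ConfigurationError("D and lambda must be nonnegative")
        if self.conc is None:
            self.conc = np.zeros((self.grid.nx, self.grid.ny))
        self._ab_cache: dict[tuple[int, float], np.ndarray] = {}

    # -- numerics ---------------------------------------------------------

    def _factorized(self, n: int, r: float):
        """LU factorization of the constant tridiagonal I − r·L (cached)."""
        key = (n, r)
        fac = self._ab_cache.get(key)
        if fac is None:
            from scipy.linalg import lapack

            ab = _banded_neumann(n, r)
            du = ab[0, 1:].copy()
            d = ab[1, :].copy()
            dl = ab[2, :-1].copy()
            dl_f, d_f, du_f, du2, ipiv, info = lapack.dgttrf(dl, d, du)
            if info != 0:  # pragma: no cover - matrix is strictly diag. dominant
                raise RuntimeError("tridiagonal factorization failed")
            gttrs = lapack.get_lapack_funcs(("gttrs",), (self.conc,))[0]
            fac = self._ab_cache[key] = (dl_f, d_f, du_f, du2, ipiv, gttrs)
        return fac

    def diffuse(self, dt: float) -> None:
        """One implicit diffusion sub-step (x sweep, then y sweep).

        The two per-axis operators commute on a tensor-product grid, so the
        split step preserves the grid's dihedral symmetry to round-off.
        """
        if dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.D == 0.0:
            return
        h = self.grid.voxel_size
        r = self.D * dt / h**2
        nx, ny = self.grid.nx, self.grid.ny
        if nx > 1:
            dl, d, du, du2, ipiv, gttrs = self._factorized(nx, r)
            x, info = gttrs(dl, d, du, du2, ipiv, self.conc)
            self.conc = x
        if ny > 1:
            dl, d, du, du2, ipiv, gttrs = self._factorized(ny, r)
            x, info = gttrs(dl, d, du, du2, ipiv, np.ascontiguousarray(self.conc.T))
            self.conc = x.T

    def decay(self, dt: float) -> None:
        """Analytic decay sub-step: ρ ← ρ·exp(−λ dt)."""
        if self.lam > 0.0:
            self.conc *= np.exp(-self.lam * dt)

    def add_source_array(self, rate: np.ndarray, dt: float) -> None:
        """Add a per-voxel secretion rate array (substrate/min) for dt minutes."""
        self.conc += rate * (dt / self.grid.voxel_volume)

    def total_mass(self) -> float:
        return float(self.conc.sum() * self.grid.voxel_volume)


def step_fields(field: DiffusionField, sources, sinks, dt: float) -> DiffusionField:
    """Advance a field by dt: implicit diffusion → analytic decay → exchange.

    sources: iterable of (position, secretion rate substrate/min, saturation
    concentration or None); sinks: iterable of (position, uptake rate).
    Concentrations never go negative.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    field.diffuse(dt)
    field.decay(dt)
    vol = field.grid.voxel_volume
    for pos, rate, sat in sources or ():
        if rate < 0:
            raise ConfigurationError("secretion rate must be nonnegative")
        i, j = field.grid.voxel_of(pos)
        dc = rate * dt / vol
        if sat is not None and np.isfinite(sat):
            dc = min(dc, max(0.0, sat - field.conc[i, j]))
        field.conc[i, j] += dc
    for pos, rate in sinks or ():
        if rate < 0:
            raise ConfigurationError("uptake rate must be nonnegative")
        i, j = field.grid.voxel_of(pos)
        field.conc[i, j] = max(0.0, field.conc[i, j] - rate * dt / vol)
    return field


def sample(field: DiffusionField, position) -> tuple[float, np.ndarray]:
    """Concentration and gradient at a position.

    Value by containing-voxel lookup; gradient by central differences between
    voxel centers (one-sided at boundary voxels).
    """
    i, j = field.grid.voxel_of(position)
    c = field.conc
    h = field.grid.voxel_size
    nx, ny = field.grid.nx, field.grid.ny

    def _diff(arr_lo, arr_hi, spacing):
        return (arr_hi - arr_lo) / spacing

    if nx == 1:
        gx = 0.0
    elif i == 0:
        gx = _diff(c[0, j], c[1, j], h)
    elif i == nx - 1:
        gx = _diff(c[nx - 2, j], c[nx - 1, j], h)
    else:
        gx = _diff(c[i - 1, j], c[i + 1, j], 2 * h)
    if ny == 1:
        gy = 0.0
    elif j == 0:
        gy = _diff(c[i, 0], c[i, 1], h)
    elif j == ny - 1:
        gy = _diff(c[i, ny - 2], c[i, ny - 1], h)
    else:
        gy = _diff(c[i, j - 1], c[i, j + 1], 2 * h)
    return float(c[i, j]), np.array([gx, gy])
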