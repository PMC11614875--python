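"""Biased-random-walk chemotaxis of immune cells.

Each motile cell carries a persisted random unit direction ξ⃗ that is
re-drawn as a Poisson process with rate 1/T_per.  Its velocity blends ξ⃗
with a chemotactic bias direction b⃗,

    v⃗ = s_mot · ((1−b) ξ⃗ + b b⃗) / ‖(1−b) ξ⃗ + b b⃗‖ ,

so every emitted velocity has magnitude s_mot.  The bias direction is the
normalized weighted sum of the TNF and debris gradients,

    b⃗ = (σ_TNF ∇ρ_TNF + σ_debris ∇ρ_debris) / ‖·‖ .

State-dependent sensitivities: unpolarized macrophages and inactive DCs
follow debris only (σ_TNF, σ_debris) = (0, 1); activated macrophages and
DCs follow both (> 0, > 0); CD8+/CD4+ T cells follow TNF only (1, 0).
Activation halves motility speed; attached cells do not move.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import Cell, CellType, DcState, MacState
from .errors import ConfigurationError

__all__ = [
    "MotilityParams",
    "bias_direction",
    "velocity",
    "maybe_repick_direction",
    "motility_state",
    "UndefinedBiasError",
]


class UndefinedBiasError(ValueError):
    """Both chemotactic sensitivities are zero; the walk is unbiased."""


@dataclass
class MotilityParams:
    s_mot: float = 1.0  # speed (µm/min)
    b: float = 0.5  # migration bias in [0, 1]
    T_per: float = 5.0  # persistence time (min)
    sigma_tnf: float = 1.0  # TNF-gradient sensitivity (≥ 0)
    sigma_debris: float = 0.0  # debris-gradient sensitivity (≥ 0)
    enabled: bool = True
    activated_speed_factor: float = 0.5  # speed reduction upon activation

    def __post_init__(self) -> None:
        if not 0.0 <= self.b <= 1.0:
            raise ConfigurationError("bias b must lie in [0, 1]")
        if self.T_per <= 0:
            raise ConfigurationError("persistence time must be positive")
        if self.s_mot < 0 or self.sigma_tnf < 0 or self.sigma_debris < 0:
            raise ConfigurationError("speed and sensitivities must be nonnegative")


def random_unit(rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.cos(theta), np.sin(theta)])


def bias_direction(
    grad_tnf: np.ndarray,
    grad_debris: np.ndarray,
    params: MotilityParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Unit chemotactic bias b⃗ from the weighted substrate gradients.

    A vanishing weighted sum (flat fields) yields a uniformly random unit
    vector — the degenerate-input rule, so callers always get a direction.
    """
    if params.sigma_tnf == 0.0 and params.sigma_debris == 0.0:
        raise UndefinedBiasError("both chemotactic sensitivities are zero")
    v = params.sigma_tnf * np.asarray(grad_tnf, float) + params.sigma_debris * np.asarray(
        grad_debris, float
    )
    norm = np.linalg.norm(v)
    if norm == 0.0:
        return random_unit(rng if rng is not None else np.random.default_rng())
    return v / norm


def velocity(
    params: MotilityParams,
    bias_dir: np.ndarray,
    current_random_dir: np.ndarray,
    rng: np.random.Generator | None = None,
    speed: float | None = None,
) -> np.ndarray:
    """Motile velocity with ‖v⃗‖ = s_mot exactly.

    If the blend (1−b)ξ⃗ + b·b⃗ vanishes (b = 1/2, ξ⃗ = −b⃗), ξ⃗ is re-drawn.
    """
    s = params.s_mot if speed is None else speed
    xi = np.asarray(current_random_dir, float)
    b = params.b
    for _ in range(16):
        blend = (1.0 - b) * xi + b * np.asarray(bias_dir, float)
        norm = np.linalg.norm(blend)
        if norm > 1e-14:
            return s * blend / norm
        xi = random_unit(rng if rng is not None else np.random.default_rng())
    return s * np.asarray(bias_dir, float)


def maybe_repick_direction(T_per: float, dt: float, rng: np.random.Generator) -> bool:
    """Poisson re-pick of ξ⃗: true with probability min(1, dt/T_per)."""
    if T_per <= 0:
        raise ConfigurationError("persistence time must be positive")
    return bool(rng.random() < min(1.0, dt / T_per))


def motility_state(cell: Cell, base: MotilityParams) -> MotilityParams | None:
    """Per-state motility parameters for a cell, or None if it does not move.

    Implements the state table: cancer/parenchymal cells are non-motile;
    attached cells are immobile; activation reduces speed.
    """
    if not base.enabled or not cell.alive:
        return None
    if cell.type not in (CellType.MACROPHAGE, CellType.DC, CellType.CD8, CellType.CD4):
        return None
    if cell.attached_to or cell.attach_target is not None:
        return None
    s = base.s_mot
    if cell.type is CellType.MACROPHAGE:
        if cell.mac_state is MacState.M0:
            sig_t, sig_d = 0.0, 1.0
        else:
            sig_t, sig_d = 1.0, 1.0
            s *= base.activated_speed_factor
    elif cell.type is CellType.DC:
        if cell.dc_state is DcState.INACTIVE:
            sig_t, sig_d = 0.0, 1.0
        else:
            sig_t, sig_d = 1.0, 1.0
            s *= base.activated_speed_factor
    else:  # CD8 / CD4
        sig_t, sig_d = 1.0, 0.0
    return MotilityParams(
        s_mot=s,
        b=base.b,
        T_per=base.T_per,
        sigma_tnf=sig_t,
        sigma_debris=sig_d,
        enabled=True,
        activated_speed_factor=base.activated_speed_factor,
    )
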