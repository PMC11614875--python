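"""Lymph-node submodel: a delayed ODE system coupling DC arrival to T cells.

Activated dendritic cells that leave the tissue arrive at the lymph node
after a trafficking delay τ_DC, feeding the migrated-DC pool D_M.  D_M
drives proliferation/activation of two helper T-cell pools (T_H1, T_H2) and
a cytotoxic pool (T_C); cumulative dispatch counters T_Ct and T_ht
integrate κ_T·T_C and κ_T·(T_H1+T_H2).  The tissue receives CD8+/CD4+
T cells after a second delay τ_T according to T_Ct(t−τ_T) and T_ht(t−τ_T):

    dD_M/dt  = k_D·D(t−τ_DC) − δ_DM·D_M
    dT_H1/dt = σ_TH1·T_H1/(1+T_H2)² + π_TH1·D_M·T_H1²/(1+T_H2)²
               − δ_TH1·D_M·T_H1³/(β+T_H2) − μ_TH·T_H1
    dT_H2/dt = σ_TH2·T_H2/(1+T_H2)
               + π_TH2·(ρ+T_H1)/(1+T_H2)·D_M·T_H2²/(1+T_H1+T_H2) − μ_TH·T_H2
    dT_C/dt  = π_T·(φ_T−T_C)/φ_T·D_M·T_C/(β_T1+D_M)
               − δ_T·D_M·T_C/(β_T2+D_M) − δ_C·(T_C−φ_C)
    dT_Ct/dt = κ_T·T_C
    dT_ht/dt = κ_T·(T_H1+T_H2)

D(t−τ_DC) is the rate of tissue DC departures at the delayed time,
reconstructed from an event queue of departure times, which keeps arrivals
finite and causal.  Integration is classical RK4 with the delay term held
piecewise-constant over a step; pools are clipped at zero.  Dispatch is a
pure counter: T_C is not drained when cells are sent to the tissue.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .immune_interactions import stochastic_round

__all__ = ["LymphNodeParams", "LymphNodeState", "ln_derivatives", "ln_step", "dispatch_t_cells"]


@dataclass
class LymphNodeParams:
    k_D: float = 1.0  # antigen presentation rate by migrated DCs (1/min)
    tau_DC: float = 180.0  # DC tissue → lymph-node trafficking delay (min)
    delta_DM: float = 2e-3  # decay of migrated DCs (1/min)
    sigma_TH1: float = 3e-4  # TH1 baseline proliferation (1/min)
    sigma_TH2: float = 1e-4  # TH2 baseline proliferation (1/min)
    pi_TH1: float = 2e-3  # DC-induced TH1 activation (1/min)
    pi_TH2: float = 1e-3  # DC-induced TH2 activation (1/min)
    delta_TH1: float = 2e-3  # DC-mediated TH1 deactivation (1/min)
    beta: float = 5.0  # half-max of TH1 deactivation (cells)
    mu_TH: float = 2e-3  # natural helper death rate (1/min)
    rho_w: float = 0.2  # TH1→TH2 weight conversion (cells)
    pi_T: float = 5e-3  # DC-mediated cytotoxic activation (1/min)
    delta_T: float = 5e-4  # DC-mediated cytotoxic deactivation (1/min)
    phi_T: float = 100.0  # lymph-node ↔ tissue scaling factor (cells)
    beta_T1: float = 1.0  # half-max of cytotoxic activation (cells)
    beta_T2: float = 1.0  # half-max of cytotoxic deactivation (cells)
    delta_C: float = 5e-4  # natural cytotoxic decay (1/min)
    phi_C: float = 1.0  # cytotoxic population threshold (cells)
    kappa_T: float = 5e-4  # T-cell recruitment (dispatch) rate (1/min)
    tau_T: float = 720.0  # lymph-node → tissue trafficking delay (min)

    def __post_init__(self) -> None:
        for name in ("phi_T", "beta", "beta_T1", "beta_T2"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("k_D", "tau_DC", "delta_DM", "sigma_TH1", "sigma_TH2", "pi_TH1",
                     "pi_TH2", "delta_TH1", "mu_TH", "rho_w", "pi_T", "delta_T",
                     "delta_C", "phi_C", "kappa_T", "tau_T"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")


@dataclass
class LymphNodeState:
    """Pools (D_M, T_H1, T_H2, T_C, T_Ct, T_ht), delay queues and counters."""

    pools: np.ndarray = field(default=None)  # type: ignore[assignment]
    dc_departure_queue: list = field(default_factory=list)  # sorted departure times
    dispatched_cd8: int = 0
    dispatched_cd4: int = 0
    history_t: list = field(default_factory=list)  # times of recorded (T_Ct, T_ht)
    history_tct: list = field(default_factory=list)
    history_tht: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pools is None:
            # helpers need a nonzero inoculum to escape the T_H = 0 invariant
            # set; T_C starts at its antigen-free baseline φ_C
            self.pools = np.array([0.0, 1.0, 1.0, 1.0, 0.0, 0.0])
        self.pools = np.asarray(self.pools, dtype=float)

    d_m = property(lambda s: s.pools[0])
    t_h1 = property(lambda s: s.pools[1])
    t_h2 = property(lambda s: s.pools[2])
    t_c = property(lambda s: s.pools[3])
    t_ct = property(lambda s: s.pools[4])
    t_ht = property(lambda s: s.pools[5])

    def record_departure(self, t: float) -> None:
        self.dc_departure_queue.append(t)

    def delayed_departure_rate(self, t: float, dt: float, tau: float) -> float:
        """Departures per minute in the window (t − τ − dt, t − τ]."""
        lo = bisect_right(self.dc_departure_queue, t - tau - dt)
        hi = bisect_right(self.dc_departure_queue, t - tau)
        return (hi - lo) / dt

    def delayed_counter(self, t_delayed: float) -> tuple[float, float]:
        """(T_Ct, T_ht) at a past time, from the recorded step history."""
        if t_delayed < 0 or not self.history_t:
            return 0.0, 0.0
        k = bisect_right(self.history_t, t_delayed) - 1
        if k < 0:
            return 0.0, 0.0
        return self.history_tct[k], self.history_tht[k]


def ln_derivatives(state, D_delayed: float, params: LymphNodeParams) -> np.ndarray:
    """Right-hand sides of the six-pool system; D_delayed is k_D's argument."""
    y = state.pools if isinstance(state, LymphNodeState) else np.asarray(state, float)
    d_m, th1, th2, tc = y[0], y[1], y[2], y[3]
    p = params
    d_dm = p.k_D * D_delayed - p.delta_DM * d_m
    d_th1 = (
        p.sigma_TH1 * th1 / (1.0 + th2) ** 2
        + p.pi_TH1 * d_m * th1**2 / (1.0 + th2) ** 2
        - p.delta_TH1 * d_m * th1**3 / (p.beta + th2)
        - p.mu_TH * th1
    )
    d_th2 = (
        p.sigma_TH2 * th2 / (1.0 + th2)
        + p.pi_TH2 * (p.rho_w + th1) / (1.0 + th2) * d_m * th2**2 / (1.0 + th1 + th2)
        - p.mu_TH * th2
    )
    d_tc = (
        p.pi_T * ((p.phi_T - tc) / p.phi_T) * d_m * tc / (p.beta_T1 + d_m)
        - p.delta_T * d_m * tc / (p.beta_T2 + d_m)
        - p.delta_C * (tc - p.phi_C)
    )
    d_tct = p.kappa_T * tc
    d_tht = p.kappa_T * (th1 + th2)
    return np.array([d_dm, d_th1, d_th2, d_tc, d_tct, d_tht])


def _rk4(y: np.ndarray, d_delayed: float, params: LymphNodeParams, dt: float) -> np.ndarray:
    k1 = ln_derivatives(y, d_delayed, params)
    k2 = ln_derivatives(y + 0.5 * dt * k1, d_delayed, params)
    k3 = ln_derivatives(y + 0.5 * dt * k2, d_delayed, params)
    k4 = ln_derivatives(y + dt * k3, d_delayed, params)
    return y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _advance(y, d_delayed, params, dt, depth=0) -> np.ndarray:
    """One RK4 step with adaptive halving.

    The helper pools are polynomially self-limited and become stiff at
    large D_M; when a step misbehaves (non-finite values, strong negativity
    or an explosive jump) it is retried as two half-steps, which preserves
    the fourth-order accuracy of the smooth regime.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        ynew = _rk4(y, d_delayed, params, dt)
    scale = np.abs(y).max() + 1.0
    bad = (
        not np.isfinite(ynew).all()
        or (ynew < -0.1 * scale).any()
        or np.abs(ynew).max() > 20.0 * scale
    )
    if bad and depth < 16:
        half = _advance(y, d_delayed, params, 0.5 * dt, depth + 1)
        return _advance(np.maximum(half, 0.0), d_delayed, params, 0.5 * dt, depth + 1)
    return np.nan_to_num(ynew, nan=0.0, posinf=0.0, neginf=0.0)


def ln_step(state: LymphNodeState, params: LymphNodeParams, t: float, dt: float) -> LymphNodeState:
    """Advance the pools from t to t+dt with classical RK4.

    The delay term is the departure-event rate in (t−τ_DC−dt, t−τ_DC],
    held constant over the step; pools are clipped at zero afterwards and
    the cumulative counters are appended to the dispatch history.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if dt > params.tau_DC:
        raise ConfigurationError("dt must not exceed tau_DC (delay under-resolved)")
    d_delayed = state.delayed_departure_rate(t, dt, params.tau_DC)
    state.pools = np.maximum(_advance(state.pools, d_delayed, params, dt), 0.0)
    state.history_t.append(t + dt)
    state.history_tct.append(float(state.pools[4]))
    state.history_tht.append(float(state.pools[5]))
    return state


def dispatch_t_cells(
    state: LymphNodeState, t: float, params: LymphNodeParams, rng: np.random.Generator
) -> tuple[int, int]:
    """T cells to deliver to the tissue now: (n_cd8, n_cd4).

    The cumulative arrival targets at time t are T_Ct(t−τ_T) and
    T_ht(t−τ_T); the increment over what was already dispatched is
    stochastically rounded (unbiased) and the counters updated.
    """
    target_ct, target_ht = state.delayed_counter(t - params.tau_T)
    n_cd8 = stochastic_round(max(0.0, target_ct - state.dispatched_cd8), rng)
    n_cd4 = stochastic_round(max(0.0, target_ht - state.dispatched_cd4), rng)
    state.dispatched_cd8 += n_cd8
    state.dispatched_cd4 += n_cd4
    return n_cd8, n_cd4
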