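"""Independent oracles used by the unit and acceptance suites.

Everything here is deliberately brute-force (enumeration, fine-step
integration, closed forms) and independent of the implementation paths it
checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney by full enumeration of group assignments.

    U is the number of (x, y) pairs with x > y (+ half-ties); the two-sided
    p-value is the null probability of a U at least as far from nm/2 as the
    observed one, enumerated over all C(n+m, n) labelings of the pooled
    sample.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)

    def u_stat(x, y):
        x = x[:, None]
        return float((x > y).sum() + 0.5 * (x == y).sum())

    u_obs = u_stat(a, b)
    center = n * m / 2.0
    idx = set(range(n + m))
    count = total = 0
    for chosen in combinations(range(n + m), n):
        rest = list(idx - set(chosen))
        u = u_stat(pooled[list(chosen)], pooled[rest])
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return u_obs, count / total


def attrition_free_kill_time(T_attach: float, k: int, dt: float) -> float:
    """Event-driven time for k pinned attackers with pooled additive credit.

    With detachment disabled, pooled credit grows k·dt per step; the kill
    lands on the first step where the pool reaches T_attach.
    """
    steps = int(np.ceil(T_attach / (k * dt) - 1e-12))
    return steps * dt


def relax_exponential(d0: float, r_E: float, t: float) -> float:
    """Closed-form deformation decay d̂(t) = d̂(0)·exp(−r_E t) of the tether."""
    return d0 * np.exp(-r_E * t)


def tc_closed_form(phi_C: float, delta_C: float, t: float, tc0: float = 0.0) -> float:
    """T_C(t) for the antigen-free lymph node: relaxation to φ_C at rate δ_C."""
    return phi_C + (tc0 - phi_C) * np.exp(-delta_C * t)
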