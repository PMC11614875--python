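"""Compiled inner loop of the mechanics/motility substep.

The jitted kernel fuses pair forces, motility displacements, the
elasto-plastic tether update and the reflecting boundary into one pass over
the state arrays; it is numerically identical to the vectorized reference
path in :mod:`micromet.mechanics` (asserted by the test suite) except for
the coincident-center tie-break, which the kernel skips (exactly coincident
centers do not arise in engine runs; the library function handles them).
Falls back to the NumPy path when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False)
def _substep(
    pos,
    radii,
    pair_i,
    pair_j,
    cca,
    ccr,
    r_int,
    mu,
    dt,
    par_idx,
    anchors,
    r_e,
    r_p,
    mot_idx,
    mot_disp,
    domain,
    travel,
):
    n = pos.shape[0]
    disp = np.zeros((n, 2))
    for k in range(pair_i.shape[0]):
        i = pair_i[k]
        j = pair_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        d = (dx * dx + dy * dy) ** 0.5
        rsum = radii[i] + radii[j]
        reach = r_int * rsum
        if d >= reach or d == 0.0:
            continue
        mag = -cca * (1.0 - d / reach) ** 2
        if d < rsum:
            mag += ccr * (1.0 - d / rsum) ** 2
        f = dt * mag / mu
        ux = dx / d
        uy = dy / d
        disp[i, 0] += f * ux
        disp[i, 1] += f * uy
        disp[j, 0] -= f * ux
        disp[j, 1] -= f * uy
    for k in range(mot_idx.shape[0]):
        i = mot_idx[k]
        disp[i, 0] += mot_disp[k, 0]
        disp[i, 1] += mot_disp[k, 1]
    max_travel = 0.0
    for i in range(n):
        pos[i, 0] += disp[i, 0]
        pos[i, 1] += disp[i, 1]
        travel[i] += (disp[i, 0] * disp[i, 0] + disp[i, 1] * disp[i, 1]) ** 0.5
        if travel[i] > max_travel:
            max_travel = travel[i]
    for k in range(par_idx.shape[0]):
        i = par_idx[k]
        dx = anchors[k, 0] - pos[i, 0]
        dy = anchors[k, 1] - pos[i, 1]
        nrm = (dx * dx + dy * dy) ** 0.5
        if nrm > 0.0:
            s = dt * r_e * (nrm - radii[i]) / nrm
            pos[i, 0] += s * dx
            pos[i, 1] += s * dy
            anchors[k, 0] -= dt * r_p * dx
            anchors[k, 1] -= dt * r_p * dy
            travel[i] += abs(s) * nrm
            if travel[i] > max_travel:
                max_travel = travel[i]
    hi = domain * (1.0 - 1e-12)
    for i in range(n):
        for d2 in range(2):
            x = pos[i, d2]
            if x < 0.0:
                x = -x
            if x > domain:
                x = 2.0 * domain - x
            if x < 0.0:
                x = 0.0
            elif x > hi:
                x = hi
            pos[i, d2] = x
    return max_travel
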