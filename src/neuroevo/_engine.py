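"""Compiled inner loop for population-scale FORCE training.

The evolutionary dynamics trains up to a whole lattice of reservoirs per
generation, each for thousands of RLS steps; the arithmetic is identical to
the reference loop in :func:`neuroevo.reservoir.force_train` (the test
suite cross-checks them) but runs inside a numba kernel.  Units are trained
one after the other so each unit's RLS matrix stays cache-resident for its
whole episode; every scalar in the hot loops carries the working dtype so
the loops vectorise cleanly.

The RLS downdate ``P <- P - (P r)(P r)^T / c`` is not applied to ``P``
immediately: the scaled vectors ``u = P r / sqrt(c)`` are buffered and
merged into ``P`` in blocks, and the per-step product ``P r`` is corrected
by the buffered terms (``P_true r = P r - sum_v u_v (u_v . r)``).  This is
algebraically exact and touches the quadratic-size matrix far less often.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["train_kernel"]

#: Buffered rank-1 downdates merged into P per block.
MERGE_EVERY = 8


@njit(cache=True, fastmath=True)
def train_kernel(X, Fm, Bfb, Q, P, tgt,
                 dt, cadence, guard, check_every, out, err, div_step):
    """Train ``n_units`` reservoirs, one per target row; arrays modified in place.

    ``Q`` holds the per-unit recurrent matrices as a dense ``(n_units, n,
    n)`` stack: at the connection densities used here a contiguous
    matrix-vector product outruns indexed sparse gathers, and the memory
    cost is matched by the RLS matrices anyway.  ``div_step[b]`` must start at -1;
    it records the first step at which unit b tripped the divergence guard,
    at which point the unit's episode is abandoned (outputs zero-filled).
    On return ``P`` holds each unit's matrix with possibly unmerged
    downdates still buffered; episodes always start afresh, so ``P`` is not
    meaningful across calls.
    """
    n_units, n = X.shape
    n_steps = tgt.shape[1]
    zero = X.dtype.type(0.0)
    one = X.dtype.type(1.0)
    rb = np.empty(n, dtype=X.dtype)
    Pr = np.empty(n, dtype=X.dtype)
    V = np.empty((MERGE_EVERY, n), dtype=X.dtype)
    for b in range(n_units):
        xb = X[b]
        fb = Fm[b]
        bb = Bfb[b]
        Pb = P[b]
        Qb = Q[b]
        nv = 0
        for k in range(n_steps):
            y = zero
            for i in range(n):
                rb[i] = np.tanh(xb[i])
                y += fb[i] * rb[i]
            e = y - tgt[b, k]
            y_fb = y
            if k % cadence == 0:
                # Pr = P_true r, correcting for buffered downdates
                for i in range(n):
                    s = zero
                    row = Pb[i]
                    for j in range(n):
                        s += row[j] * rb[j]
                    Pr[i] = s
                for v in range(nv):
                    uv = V[v]
                    d = zero
                    for i in range(n):
                        d += uv[i] * rb[i]
                    for i in range(n):
                        Pr[i] -= uv[i] * d
                c = one
                for i in range(n):
                    c += rb[i] * Pr[i]
                coef = e / c
                y_fb = zero
                for i in range(n):
                    fb[i] -= coef * Pr[i]
                    y_fb += fb[i] * rb[i]
                sc = one / np.sqrt(c)
                for i in range(n):
                    V[nv, i] = Pr[i] * sc
                nv += 1
                if nv == MERGE_EVERY:
                    for i in range(n):
                        row = Pb[i]
                        for v in range(MERGE_EVERY):
                            coef_v = V[v, i]
                            uv = V[v]
                            for j in range(n):
                                row[j] -= coef_v * uv[j]
                    nv = 0
            # recurrent drive and Euler step
            for i in range(n):
                s = zero
                qrow = Qb[i]
                for j in range(n):
                    s += qrow[j] * rb[j]
                xb[i] += dt * (-xb[i] + s + bb[i] * y_fb)
            out[b, k] = y
            err[b, k] = e
            if k % check_every == 0 or k == n_steps - 1:
                peak = zero
                finite = True
                for i in range(n):
                    v_ = xb[i]
                    if not np.isfinite(v_):
                        finite = False
                        break
                    a = abs(v_)
                    if a > peak:
                        peak = a
                if not finite or peak > guard:
                    div_step[b] = k
                    for i in range(n):
                        xb[i] = zero
                    for kk in range(k + 1, n_steps):
                        out[b, kk] = zero
                        err[b, kk] = zero
                    break
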