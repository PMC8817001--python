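"""Brute-force oracle for Hartigan's dip, independent of the fast algorithm.

dip <= d iff some unimodal CDF G (convex left of the mode, concave right,
with at most one atom, at the mode) stays within a d-band of the ECDF.
Feasibility for a candidate mode is a small linear program over the values
of G at the unique sample points (piecewise-linear G with knots at sample
points is sufficient); the dip is found by bisection over d.  Slow — meant
for small samples only.
"""

import numpy as np
from scipy.optimize import linprog

_OPTS = {"primal_feasibility_tolerance": 1e-10, "dual_feasibility_tolerance": 1e-10}


def _convex_rows(pos, var, nv, sense):
    """sense +1: slopes nondecreasing (convex); -1: nonincreasing (concave)."""
    rows, rhs = [], []
    for i in range(len(pos) - 2):
        xp, xq, xr = pos[i], pos[i + 1], pos[i + 2]
        vp, vq, vr = var[i], var[i + 1], var[i + 2]
        row = np.zeros(nv)
        row[vq] += (xr - xq) + (xq - xp)
        row[vp] -= xr - xq
        row[vr] -= xq - xp
        rows.append(sense * row)
        rhs.append(0.0)
    return rows, rhs


def _feasible(u, f_hi, f_lo, d, mode_kind, M, m_pos=None):
    m = len(u)
    if mode_kind == "point":
        nv = m + 1
        ia = m
        bounds = []
        for i in range(m):
            if i == M:
                bounds.append((max(0.0, f_hi[i] - d), min(1.0, f_hi[i] + d)))
            else:
                bounds.append((max(0.0, f_hi[i] - d), min(1.0, f_lo[i] + d)))
        bounds.append((max(0.0, f_lo[M] - d), min(1.0, f_lo[M] + d)))
        chain = list(range(M)) + [ia] + list(range(M, m))
        left_pos, left_var = list(u[:M]) + [u[M]], list(range(M)) + [ia]
        right_pos, right_var = list(u[M:]), list(range(M, m))
    else:  # mode inside the gap (u_M, u_{M+1})
        nv = m + 2
        iA, iB = m, m + 1
        bounds = [
            (max(0.0, f_hi[i] - d), min(1.0, f_lo[i] + d)) for i in range(m)
        ]
        band = (max(0.0, f_hi[M] - d), min(1.0, f_hi[M] + d))
        bounds += [band, band]
        chain = list(range(M + 1)) + [iA, iB] + list(range(M + 1, m))
        left_pos, left_var = list(u[: M + 1]) + [m_pos], list(range(M + 1)) + [iA]
        right_pos, right_var = [m_pos] + list(u[M + 1 :]), [iB] + list(
            range(M + 1, m)
        )
    for lo, hi in bounds:
        if lo > hi + 1e-12:
            return False
    a_ub, b_ub = [], []
    for p, q in zip(chain, chain[1:]):
        row = np.zeros(nv)
        row[p], row[q] = 1, -1
        a_ub.append(row)
        b_ub.append(0.0)
    r, rr = _convex_rows(left_pos, left_var, nv, +1.0)
    a_ub += r
    b_ub += rr
    r, rr = _convex_rows(right_pos, right_var, nv, -1.0)
    a_ub += r
    b_ub += rr
    res = linprog(
        np.zeros(nv), A_ub=np.array(a_ub), b_ub=np.array(b_ub),
        bounds=bounds, method="highs", options=_OPTS,
    )
    return res.status == 0


def dip_band_oracle(samples, tol=1e-6, gap_grid=5):
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    u, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)
    f_hi = cum / n
    f_lo = np.concatenate([[0.0], cum[:-1]]) / n
    m = len(u)

    def feasible(d):
        for M in range(m):
            if _feasible(u, f_hi, f_lo, d, "point", M):
                return True
        for j in range(m - 1):
            for frac in np.linspace(0.02, 0.98, gap_grid):
                mp = u[j] + frac * (u[j + 1] - u[j])
                if _feasible(u, f_hi, f_lo, d, "gap", j, mp):
                    return True
        return False

    lo, hi = 0.0, 0.5
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
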