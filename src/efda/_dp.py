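"""Dynamic-programming solver for elastic pairwise alignment.

The optimal warp between two SRSFs ``q_ref`` and ``q_mov`` is found as a
monotone lattice path through the n x n grid of (reference index i, moving
index j) pairs, minimizing the discretized objective

    int (q_ref(t) - q_mov(gamma(t)) * sqrt(gammadot))^2 dt
        + lambda * int (sqrt(gammadot) - 1)^2 dt

Admissible path steps are offsets (a, b) with a, b in {1, ..., grid_stride}
and gcd(a, b) = 1, which bounds the local slope of gamma to
[1/grid_stride, grid_stride] and excludes degenerate flat or vertical
segments.  Edge costs are trapezoidal quadratures on the reference grid with
q_mov linearly interpolated at the exact rational positions j0 + k*b/a, so
the cost of a whole path equals the trapezoidal integral of the objective
along the piecewise-linear gamma the path defines.  Ties between
predecessors are broken by the first candidate in the (deterministically
ordered) slope set, which makes results reproducible across runs and
platforms.

For speed, the table pass precomputes, for every candidate step and every
interior quadrature point, the interpolated-and-scaled moving values
``(q_mov interpolated at fraction f) * sqrt(b/a)`` as row vectors; the DP
recursion then only does lookups and multiply-adds.  :func:`edge_cost`
prices a single edge with bit-identical arithmetic, so exhaustive-search
cross-checks can reproduce DP costs exactly.

The kernels here are internal; :mod:`efda.align` provides the public
surface.
"""

from __future__ import annotations

from functools import lru_cache
from math import gcd

import numpy as np
from numba import njit

__all__ = ["slope_set", "dp_pair", "edge_cost", "path_to_gamma", "quad_dist2"]

_BIG = 1e300


@lru_cache(maxsize=None)
def slope_set(grid_stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Coprime step offsets (a, b), a,b in 1..grid_stride, sorted by (a, b)."""
    if grid_stride < 1:
        raise ValueError("grid_stride must be >= 1")
    pairs = [
        (a, b)
        for a in range(1, grid_stride + 1)
        for b in range(1, grid_stride + 1)
        if gcd(a, b) == 1
    ]
    aa = np.array([p[0] for p in pairs], dtype=np.int64)
    bb = np.array([p[1] for p in pairs], dtype=np.int64)
    return aa, bb


@njit(cache=False)
def _frac_val(qm, j0, k, a, b):
    """q_mov interpolated at the exact rational index j0 + k*b/a."""
    pos = k * b
    off = pos // a
    rem = pos - off * a
    j = j0 + off
    if rem == 0:
        return qm[j]
    f = rem / a
    return qm[j] * (1.0 - f) + qm[j + 1] * f


@njit(cache=False)
def _edge_amp(qr, qm, i0, j0, a, b, dt):
    """Amplitude quadrature of one edge (i0,j0)->(i0+a, j0+b)."""
    sq = np.sqrt(b / a)
    acc = 0.0
    for k in range(a + 1):
        w = 0.5 if (k == 0 or k == a) else 1.0
        d = qr[i0 + k] - _frac_val(qm, j0, k, a, b) * sq
        acc += w * d * d
    return acc * dt


@njit(cache=False)
def _dp_table(qr, qm, lam, aa, bb, dt):
    n = qr.size
    nc = aa.size
    # CSR layout of the per-candidate quadrature points
    start = np.empty(nc + 1, dtype=np.int64)
    start[0] = 0
    for c in range(nc):
        start[c + 1] = start[c] + aa[c] + 1
    total = start[nc]
    woff = np.empty(total, dtype=np.int64)   # moving-index offset of point k
    wrow = np.empty(total, dtype=np.int64)   # row into the value table
    wgt = np.empty(total)                    # trapezoid weight
    sqs = np.empty(nc)
    pens = np.empty(nc)
    # value table: Vs[row, j] = (qm interpolated at j + frac) * sqrt(s)
    Vs = np.empty((total, n))
    for c in range(nc):
        a = aa[c]
        b = bb[c]
        s = b / a
        sq = np.sqrt(s)
        sqs[c] = sq
        pens[c] = lam * (sq - 1.0) * (sq - 1.0) * a * dt
        for k in range(a + 1):
            idx = start[c] + k
            pos = k * b
            off = pos // a
            rem = pos - off * a
            woff[idx] = off
            wgt[idx] = 0.5 if (k == 0 or k == a) else 1.0
            if rem == 0:
                for j in range(n):
                    Vs[idx, j] = qm[j] * sq
            else:
                f = rem / a
                for j in range(n - 1):
                    Vs[idx, j] = (qm[j] * (1.0 - f) + qm[j + 1] * f) * sq
                Vs[idx, n - 1] = qm[n - 1] * sq  # never referenced
            wrow[idx] = idx

    D = np.full((n, n), _BIG)
    choice = np.full((n, n), -1, dtype=np.int32)
    D[0, 0] = 0.0
    for i in range(1, n):
        for j in range(1, n):
            best = _BIG
            best_c = -1
            for c in range(nc):
                a = aa[c]
                b = bb[c]
                i0 = i - a
                j0 = j - b
                if i0 < 0 or j0 < 0:
                    continue
                prev = D[i0, j0]
                if prev >= _BIG:
                    continue
                acc = 0.0
                for idx in range(start[c], start[c + 1]):
                    k = idx - start[c]
                    d = qr[i0 + k] - Vs[idx, j0 + woff[idx]]
                    acc += wgt[idx] * d * d
                cand = prev + acc * dt + pens[c]
                if cand < best:
                    best = cand
                    best_c = c
            D[i, j] = best
            choice[i, j] = best_c
    return D, choice


def edge_cost(
    qr: np.ndarray,
    qm: np.ndarray,
    i0: int,
    j0: int,
    a: int,
    b: int,
    lam: float,
) -> float:
    """Total cost (amplitude quadrature + roughness penalty) of one edge.

    Bit-identical to the cost the DP table assigns to this edge, so
    exhaustive-search checks can price paths exactly.
    """
    dt = 1.0 / (qr.size - 1)
    sq = np.sqrt(b / a)
    pen = lam * (sq - 1.0) ** 2 * a * dt
    return float(_edge_amp(qr, qm, i0, j0, a, b, dt)) + pen


def _backtrack(choice, aa, bb):
    n = choice.shape[0]
    i, j = n - 1, n - 1
    nodes = [(i, j)]
    while (i, j) != (0, 0):
        c = choice[i, j]
        if c < 0:  # pragma: no cover - (n-1,n-1) is always reachable via (1,1)
            raise RuntimeError("DP backtrack hit an unreachable node")
        i -= int(aa[c])
        j -= int(bb[c])
        nodes.append((i, j))
    nodes.reverse()
    return nodes


def path_to_gamma(nodes: list[tuple[int, int]], n: int) -> np.ndarray:
    """Piecewise-linear gamma on the full uniform grid from path nodes."""
    ii = np.array([p[0] for p in nodes], dtype=float) / (n - 1)
    jj = np.array([p[1] for p in nodes], dtype=float) / (n - 1)
    gamma = np.interp(np.linspace(0.0, 1.0, n), ii, jj)
    gamma[0], gamma[-1] = 0.0, 1.0
    return gamma


def _path_values(qr, qm, nodes, lam):
    """Per-node warped values and cost split along a path.

    Returns (cL, cR, amp2, pen): cL/cR are the left/right limits of
    (q_mov o gamma) * sqrt(gammadot) at each reference node (they differ at
    path vertices where the slope changes), amp2 the accumulated amplitude
    quadrature and pen the accumulated penalty.  The pair (cL, cR) is exactly
    what the DP quadrature prices against q_ref, so templates built from
    their per-node average minimize the summed DP objective exactly.
    """
    n = qr.size
    dt = 1.0 / (n - 1)
    cL = np.empty(n)
    cR = np.empty(n)
    amp2 = 0.0
    pen = 0.0
    for (i0, j0), (i1, j1) in zip(nodes[:-1], nodes[1:]):
        a = i1 - i0
        b = j1 - j0
        sq = np.sqrt(b / a)
        pen += lam * (sq - 1.0) ** 2 * a * dt
        amp2 += float(_edge_amp(qr, qm, i0, j0, a, b, dt))
        for k in range(a + 1):
            c = float(_frac_val(qm, j0, k, a, b)) * sq
            if k == 0:
                cR[i0] = c
            elif k == a:
                cL[i1] = c
            else:
                cL[i0 + k] = c
                cR[i0 + k] = c
    cL[0] = cR[0]
    cR[n - 1] = cL[n - 1]
    return cL, cR, amp2, pen


def quad_dist2(qr: np.ndarray, cL: np.ndarray, cR: np.ndarray) -> float:
    """Squared amplitude distance of q_ref to a path's warped values.

    Same quadrature the DP accumulates: trapezoid weights, with vertex nodes
    split half/half between their left and right slope limits.
    """
    n = qr.size
    dt = 1.0 / (n - 1)
    w = np.full(n, dt)
    w[0] = w[-1] = 0.5 * dt
    return float(np.sum(w * 0.5 * ((qr - cL) ** 2 + (qr - cR) ** 2)))


def dp_pair(
    qr: np.ndarray,
    qm: np.ndarray,
    lam: float,
    grid_stride: int,
):
    """Optimal elastic warp of qm onto qr.

    Returns ``(gamma, total_cost, amp2, pen, cL, cR)`` where gamma is the
    optimal warp on the full grid, total_cost the minimized DP objective,
    amp2/pen its amplitude and penalty parts re-accumulated along the optimal
    path, and cL/cR the per-node warped-SRSF limits (see ``_path_values``).
    """
    qr = np.ascontiguousarray(qr, dtype=float)
    qm = np.ascontiguousarray(qm, dtype=float)
    n = qr.size
    if qm.size != n:
        raise ValueError(f"SRSF length mismatch: {n} vs {qm.size}")
    aa, bb = slope_set(grid_stride)
    D, choice = _dp_table(qr, qm, float(lam), aa, bb, 1.0 / (n - 1))
    nodes = _backtrack(choice, aa, bb)
    gamma = path_to_gamma(nodes, n)
    cL, cR, amp2, pen = _path_values(qr, qm, nodes, float(lam))
    return gamma, float(D[n - 1, n - 1]), amp2, pen, cL, cR
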