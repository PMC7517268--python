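"""Exact earth mover's distance for small discrete distributions.

The ground metric between binary purview states defaults to the Hamming
distance.  The solver is a successive-shortest-path min-cost transport on
the reduced problem (shared mass cancelled first), which is exact for
arbitrary non-negative ground metrics and fast for the tiny instances
(<= 64 states) that IIT repertoire comparisons produce.  It is optionally
JIT-compiled with numba; a pure-Python fallback keeps the package
dependency-light.
"""

from __future__ import annotations

import numpy as np

__all__ = ["emd", "hamming_ground"]

_MASS_TOL = 1e-12


def _solve_transport_py(sup, dem, cost):  # pragma: no cover - numba path preferred
    return _transport_impl(sup, dem, cost)


def _transport_impl(sup, dem, cost):
    """Min-cost transport: supplies ``sup`` to demands ``dem`` at ``cost``.

    Successive shortest augmenting paths with Bellman-Ford labelling on the
    bipartite residual graph.  Terminates because every augmentation
    saturates at least one source or sink.
    """
    k = sup.shape[0]
    m = dem.shape[0]
    f = np.zeros((k, m))
    srem = sup.copy()
    drem = dem.copy()
    total = 0.0
    for i in range(k):
        total += srem[i]
    dtot = 0.0
    for j in range(m):
        dtot += drem[j]
    if dtot < total:
        total = dtot
    INF = 1e18
    guard = 4 * (k + m) + 8
    ds = np.empty(k)
    dt = np.empty(m)
    ps = np.empty(k, np.int64)
    pt = np.empty(m, np.int64)
    while total > _MASS_TOL:
        for i in range(k):
            ds[i] = 0.0 if srem[i] > 1e-15 else INF
            ps[i] = -1
        for j in range(m):
            dt[j] = INF
            pt[j] = -1
        changed = True
        rounds = 0
        while changed and rounds < guard:
            changed = False
            rounds += 1
            for i in range(k):
                if ds[i] >= INF:
                    continue
                for j in range(m):
                    nd = ds[i] + cost[i, j]
                    if nd < dt[j] - 1e-15:
                        dt[j] = nd
                        pt[j] = i
                        changed = True
            for j in range(m):
                if dt[j] >= INF:
                    continue
                for i in range(k):
                    if f[i, j] > 1e-15:
                        nd = dt[j] - cost[i, j]
                        if nd < ds[i] - 1e-15:
                            ds[i] = nd
                            ps[i] = j
                            changed = True
        j0 = -1
        best = INF
        for j in range(m):
            if drem[j] > 1e-15 and dt[j] < best:
                best = dt[j]
                j0 = j
        if j0 < 0:
            break
        # bottleneck along the augmenting path
        amt = drem[j0]
        j = j0
        steps = 0
        while steps < guard:
            steps += 1
            i = pt[j]
            if ps[i] == -1:
                if srem[i] < amt:
                    amt = srem[i]
                break
            jj = ps[i]
            if f[i, jj] < amt:
                amt = f[i, jj]
            j = jj
        # apply the augmentation
        j = j0
        steps = 0
        while steps < guard:
            steps += 1
            i = pt[j]
            f[i, j] += amt
            if ps[i] == -1:
                srem[i] -= amt
                break
            jj = ps[i]
            f[i, jj] -= amt
            j = jj
        drem[j0] -= amt
        total -= amt
    c = 0.0
    for i in range(k):
        for j in range(m):
            c += f[i, j] * cost[i, j]
    return c


try:  # optional acceleration
    from numba import njit

    _solve_transport = njit(cache=True, fastmath=False)(_transport_impl)
except Exception:  # pragma: no cover
    _solve_transport = _transport_impl


_GROUND_CACHE: dict[int, np.ndarray] = {}


def hamming_ground(n_bits: int) -> np.ndarray:
    """Pairwise Hamming distances between the 2**n_bits binary states."""
    g = _GROUND_CACHE.get(n_bits)
    if g is None:
        states = np.arange(2**n_bits)
        xor = states[:, None] ^ states[None, :]
        g = np.zeros(xor.shape, dtype=float)
        for b in range(n_bits):
            g += (xor >> b) & 1
        g.setflags(write=False)
        _GROUND_CACHE[n_bits] = g
    return g


def _validate_ground(ground: np.ndarray, n: int) -> np.ndarray:
    ground = np.asarray(ground, dtype=float)
    if ground.shape != (n, n):
        raise ValueError("ground metric shape does not match distributions")
    if np.any(ground < -1e-12):
        raise ValueError("ground metric must be non-negative")
    if np.abs(np.diagonal(ground)).max(initial=0.0) > 1e-12:
        raise ValueError("ground metric must have a zero diagonal")
    if np.abs(ground - ground.T).max(initial=0.0) > 1e-9:
        raise ValueError("ground metric must be symmetric")
    return ground


def emd(p, q, ground: np.ndarray | None = None) -> float:
    """Exact earth mover's distance between two distributions.

    Parameters
    ----------
    p, q
        Probability vectors over the same state space (each sums to 1).
    ground
        Pairwise state distances.  When omitted, the state space must have
        a power-of-two size and the Hamming metric between the binary
        states is used.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.ndim != 1 or p.shape != q.shape:
        raise ValueError("distributions must be 1-D and of equal length")
    if min(p.min(), q.min()) < -1e-9:
        raise ValueError("distributions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6 or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("distributions must be normalized")
    n = p.shape[0]
    if ground is None:
        n_bits = n.bit_length() - 1
        if 2**n_bits != n:
            raise ValueError("cannot infer Hamming ground metric: size not 2**k")
        ground = hamming_ground(n_bits)
    else:
        ground = _validate_ground(ground, n)
    return _emd_reduced(p, q, ground)


def _emd_reduced(p: np.ndarray, q: np.ndarray, ground: np.ndarray) -> float:
    """EMD assuming validated inputs; shared mass is cancelled first."""
    diff = p - q
    src = np.flatnonzero(diff > 1e-14)
    snk = np.flatnonzero(diff < -1e-14)
    if src.size == 0 or snk.size == 0:
        return 0.0
    sup = diff[src]
    dem = -diff[snk]
    if src.size == 1:
        return float(dem @ ground[src[0], snk])
    if snk.size == 1:
        return float(sup @ ground[src, snk[0]])
    cost = np.ascontiguousarray(ground[np.ix_(src, snk)])
    return float(_solve_transport(np.ascontiguousarray(sup), np.ascontiguousarray(dem), cost))
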