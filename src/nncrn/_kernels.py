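"""Jit-compiled inner loops: rewiring chains, union-find percolation, BFS.

Graphs enter as CSR adjacency ``(indptr, data)`` with node ids 0..N-1.
``data`` has exactly 2M slots — one per ordered edge — so drawing a
uniform slot index draws a uniform ordered edge.  Degrees never change
under double-edge swaps, so the degree array and all degree-derived
structures are read-only.

Distance-2 pair statistics are held as exact int64 sums (pair count,
Σk, Σk², Σkk'), updated locally around the four swap endpoints; integer
arithmetic means the incremental state cannot drift, and the periodic
full recomputation acts as a corruption check rather than a drift fix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# outcome codes shared with the python layer
APPLIED, LAZY, STRUCTURAL, METROPOLIS = 0, 1, 2, 3


@njit(cache=True)
def _owner(indptr, slot):
    return np.searchsorted(indptr, slot, side="right") - 1


@njit(cache=True)
def _has_edge(indptr, adj, u, v):
    for i in range(indptr[u], indptr[u + 1]):
        if adj[i] == v:
            return True
    return False


@njit(cache=True)
def _replace_neighbor(indptr, adj, u, old, new):
    for i in range(indptr[u], indptr[u + 1]):
        if adj[i] == old:
            adj[i] = new
            return


@njit(cache=True)
def _apply_swap(indptr, adj, u1, u2, v1, v2):
    # (u1,u2),(v1,v2) -> (u1,v2),(v1,u2)
    _replace_neighbor(indptr, adj, u1, u2, v2)
    _replace_neighbor(indptr, adj, u2, u1, v1)
    _replace_neighbor(indptr, adj, v1, v2, u2)
    _replace_neighbor(indptr, adj, v2, v1, u1)


@njit(cache=True)
def full_d2_stats(indptr, adj, deg, mark, stamp):
    """Ordered-pair statistics over all pairs at distance exactly 2.

    ``mark`` is an int64 workspace of length N; ``stamp`` a monotonically
    increasing counter threaded through all callers so stale marks can
    never collide.
    """
    n = indptr.shape[0] - 1
    cnt = np.int64(0)
    s1 = np.int64(0)
    s2 = np.int64(0)
    s11 = np.int64(0)
    for a in range(n):
        stamp += 1
        mark[a] = stamp
        for i in range(indptr[a], indptr[a + 1]):
            mark[adj[i]] = stamp
        ka = deg[a]
        for i in range(indptr[a], indptr[a + 1]):
            w = adj[i]
            for j in range(indptr[w], indptr[w + 1]):
                y = adj[j]
                if mark[y] == stamp:
                    continue
                mark[y] = stamp
                cnt += 1
                s1 += ka
                s2 += ka * ka
                s11 += ka * deg[y]
    return cnt, s1, s2, s11, stamp


@njit(cache=True)
def _quartet_contrib(indptr, adj, deg, q, mark, stamp):
    """Statistics contribution of distance-2 pairs touching the four swap
    endpoints ``q`` (all distinct), each unordered pair counted once and
    entered with both orientations."""
    cnt = np.int64(0)
    s1 = np.int64(0)
    s2 = np.int64(0)
    s11 = np.int64(0)
    for t in range(4):
        a = q[t]
        stamp += 1
        mark[a] = stamp
        for i in range(indptr[a], indptr[a + 1]):
            mark[adj[i]] = stamp
        ka = deg[a]
        for i in range(indptr[a], indptr[a + 1]):
            w = adj[i]
            for j in range(indptr[w], indptr[w + 1]):
                y = adj[j]
                if mark[y] == stamp:
                    continue
                mark[y] = stamp
                if (y == q[0] or y == q[1] or y == q[2] or y == q[3]) and y < a:
                    continue  # quartet-internal pair, counted from the smaller id
                ky = deg[y]
                cnt += 2
                s1 += ka + ky
                s2 += ka * ka + ky * ky
                s11 += 2 * ka * ky
    return cnt, s1, s2, s11, stamp


@njit(cache=True)
def _r_of(cnt, s1, s2, s11):
    if cnt == 0:
        return 0.0
    n = float(cnt)
    mu = s1 / n
    var = s2 / n - mu * mu
    if var <= 0.0:
        return 0.0
    return (s11 / n - mu * mu) / var


@njit(cache=True)
def rewire_l1(indptr, adj, deg, jeff, n_steps, lazy_p, seed, trace_every, record_r2):
    """Distance-1 Metropolis chain (degree sequence preserved).

    Acceptance probability min(1, exp(jeff·Δr1)); the sign convention is
    resolved by the caller through ``jeff``.  Returns the final r1, the
    outcome counters and thinned traces.
    """
    np.random.seed(seed)
    n = indptr.shape[0] - 1
    two_m = adj.shape[0]
    s1 = np.int64(0)
    s2 = np.int64(0)
    s11 = np.int64(0)
    for u in range(n):
        ku = deg[u]
        for i in range(indptr[u], indptr[u + 1]):
            s1 += ku
            s2 += ku * ku
            s11 += ku * deg[adj[i]]
    nn = float(two_m)
    mu = s1 / nn
    var = s2 / nn - mu * mu
    counts = np.zeros(4, np.int64)
    n_tr = n_steps // trace_every if trace_every > 0 else 0
    tr_r1 = np.empty(n_tr, np.float64)
    tr_r2 = np.empty(n_tr if record_r2 else 0, np.float64)
    tr_out = np.zeros(n_tr, np.int64)
    mark = np.zeros(n, np.int64)
    stamp = np.int64(0)
    ti = 0
    last = LAZY
    for step in range(n_steps):
        if np.random.random() < lazy_p:
            counts[LAZY] += 1
            last = LAZY
        else:
            t1 = np.random.randint(two_m)
            t2 = np.random.randint(two_m)
            u1 = _owner(indptr, t1)
            u2 = adj[t1]
            v1 = _owner(indptr, t2)
            v2 = adj[t2]
            if u1 == v1 or u2 == v2 or u1 == v2 or v1 == u2:
                counts[STRUCTURAL] += 1
                last = STRUCTURAL
            elif _has_edge(indptr, adj, u1, v2) or _has_edge(indptr, adj, v1, u2):
                counts[STRUCTURAL] += 1
                last = STRUCTURAL
            else:
                ds11 = (
                    deg[u1] * deg[v2]
                    + deg[v1] * deg[u2]
                    - deg[u1] * deg[u2]
                    - deg[v1] * deg[v2]
                )
                dr = 2.0 * ds11 / (nn * var)
                if jeff * dr >= 0.0 or np.random.random() < np.exp(jeff * dr):
                    _apply_swap(indptr, adj, u1, u2, v1, v2)
                    s11 += 2 * ds11
                    counts[APPLIED] += 1
                    last = APPLIED
                else:
                    counts[METROPOLIS] += 1
                    last = METROPOLIS
        if trace_every > 0 and (step + 1) % trace_every == 0:
            tr_r1[ti] = (s11 / nn - mu * mu) / var
            if record_r2:
                c2, a2, b2, p2, stamp = full_d2_stats(indptr, adj, deg, mark, stamp)
                tr_r2[ti] = _r_of(c2, a2, b2, p2)
            tr_out[ti] = last
            ti += 1
    r1 = (s11 / nn - mu * mu) / var
    return r1, counts, tr_r1, tr_r2, tr_out


@njit(cache=True)
def rewire_l2(
    indptr,
    adj,
    deg,
    nbd_indptr,
    nbd_data,
    jeff,
    n_steps,
    lazy_p,
    seed,
    trace_every,
    recompute_every,
):
    """Distance-2 Metropolis chain (degree sequence AND joint degree
    profile at l=1 preserved).

    The second edge is drawn uniformly among ordered edges whose source
    degree matches the first edge's source: a uniform node among those of
    that degree (``nbd_*`` index) followed by a uniform neighbor.  Returns
    a status flag (nonzero if the periodic full recomputation ever
    disagreed with the incremental state), the final distance-2 pair
    statistics, outcome counters and thinned traces of r2.
    """
    np.random.seed(seed)
    n = indptr.shape[0] - 1
    two_m = adj.shape[0]
    mark = np.zeros(n, np.int64)
    stamp = np.int64(0)
    cnt, s1, s2, s11, stamp = full_d2_stats(indptr, adj, deg, mark, stamp)
    counts = np.zeros(4, np.int64)
    n_tr = n_steps // trace_every if trace_every > 0 else 0
    tr_r2 = np.empty(n_tr, np.float64)
    tr_out = np.zeros(n_tr, np.int64)
    q = np.empty(4, np.int64)
    ti = 0
    last = LAZY
    applied_since = 0
    status = 0
    for step in range(n_steps):
        if np.random.random() < lazy_p:
            counts[LAZY] += 1
            last = LAZY
        else:
            t1 = np.random.randint(two_m)
            u1 = _owner(indptr, t1)
            u2 = adj[t1]
            d = deg[u1]
            lo = nbd_indptr[d]
            hi = nbd_indptr[d + 1]
            v1 = nbd_data[lo + np.random.randint(hi - lo)]
            v2 = adj[indptr[v1] + np.random.randint(deg[v1])]
            if u1 == v1 or u2 == v2 or u1 == v2 or v1 == u2:
                counts[STRUCTURAL] += 1
                last = STRUCTURAL
            elif _has_edge(indptr, adj, u1, v2) or _has_edge(indptr, adj, v1, u2):
                counts[STRUCTURAL] += 1
                last = STRUCTURAL
            else:
                q[0] = u1
                q[1] = u2
                q[2] = v1
                q[3] = v2
                cb, s1b, s2b, s11b, stamp = _quartet_contrib(
                    indptr, adj, deg, q, mark, stamp
                )
                _apply_swap(indptr, adj, u1, u2, v1, v2)
                ca, s1a, s2a, s11a, stamp = _quartet_contrib(
                    indptr, adj, deg, q, mark, stamp
                )
                cn = cnt - cb + ca
                s1n = s1 - s1b + s1a
                s2n = s2 - s2b + s2a
                s11n = s11 - s11b + s11a
                dr = _r_of(cn, s1n, s2n, s11n) - _r_of(cnt, s1, s2, s11)
                if jeff * dr >= 0.0 or np.random.random() < np.exp(jeff * dr):
                    cnt, s1, s2, s11 = cn, s1n, s2n, s11n
                    counts[APPLIED] += 1
                    last = APPLIED
                    applied_since += 1
                    if recompute_every > 0 and applied_since >= recompute_every:
                        applied_since = 0
                        c2, a2, b2, p2, stamp = full_d2_stats(
                            indptr, adj, deg, mark, stamp
                        )
                        if c2 != cnt or a2 != s1 or b2 != s2 or p2 != s11:
                            status = 1
                            break
                else:
                    _apply_swap(indptr, adj, u1, v2, v1, u2)  # exact inverse
                    counts[METROPOLIS] += 1
                    last = METROPOLIS
        if trace_every > 0 and (step + 1) % trace_every == 0 and ti < n_tr:
            tr_r2[ti] = _r_of(cnt, s1, s2, s11)
            tr_out[ti] = last
            ti += 1
    return status, cnt, s1, s2, s11, counts, tr_r2, tr_out


# -- percolation -----------------------------------------------------------


@njit(cache=True)
def _find_root(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        nxt = parent[x]
        parent[x] = root
        x = nxt
    return root


@njit(cache=True)
def nz_edges(n_nodes, edges):
    """Newman–Ziff bond percolation: largest-component size after adding
    the first n edges (in the given order), for n = 0..M.  All nodes are
    always present."""
    parent = np.arange(n_nodes)
    size = np.ones(n_nodes, np.int64)
    m = edges.shape[0]
    out = np.empty(m + 1, np.int64)
    big = np.int64(1 if n_nodes > 0 else 0)
    out[0] = big
    for i in range(m):
        ru = _find_root(parent, edges[i, 0])
        rv = _find_root(parent, edges[i, 1])
        if ru != rv:
            if size[ru] < size[rv]:
                ru, rv = rv, ru
            parent[rv] = ru
            size[ru] += size[rv]
            if size[ru] > big:
                big = size[ru]
        out[i + 1] = big
    return out


@njit(cache=True)
def nz_nodes(indptr, adj, order):
    """Newman–Ziff site percolation: nodes are added in ``order``; an edge
    becomes active once both endpoints are present.  Returns the largest
    component among present nodes after n additions, n = 0..N."""
    n_nodes = indptr.shape[0] - 1
    parent = np.arange(n_nodes)
    size = np.ones(n_nodes, np.int64)
    present = np.zeros(n_nodes, np.uint8)
    out = np.empty(order.shape[0] + 1, np.int64)
    out[0] = 0
    big = np.int64(0)
    for i in range(order.shape[0]):
        v = order[i]
        present[v] = 1
        if big < 1:
            big = 1
        for j in range(indptr[v], indptr[v + 1]):
            w = adj[j]
            if present[w] == 1:
                rv = _find_root(parent, v)
                rw = _find_root(parent, w)
                if rv != rw:
                    if size[rv] < size[rw]:
                        rv, rw = rw, rv
                    parent[rw] = rv
                    size[rv] += size[rw]
                    if size[rv] > big:
                        big = size[rv]
        out[i + 1] = big
    return out


# -- shortest paths --------------------------------------------------------


@njit(cache=True)
def bfs_efficiency(indptr, adj, sources):
    """Sum of inverse distances, pair count and max distance over ordered
    pairs (s, j) with s in ``sources`` and j reachable from s, j != s."""
    n = indptr.shape[0] - 1
    dist = np.empty(n, np.int64)
    queue = np.empty(n, np.int64)
    total = 0.0
    pairs = np.int64(0)
    dmax = np.int64(0)
    for si in range(sources.shape[0]):
        s = sources[si]
        for i in range(n):
            dist[i] = -1
        dist[s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for j in range(indptr[u], indptr[u + 1]):
                w = adj[j]
                if dist[w] < 0:
                    dw = du + 1
                    dist[w] = dw
                    queue[tail] = w
                    tail += 1
                    total += 1.0 / dw
                    pairs += 1
                    if dw > dmax:
                        dmax = dw
    return total, pairs, dmax
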