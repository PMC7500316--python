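"""Compiled shortest-path kernels for the permutation-loop hot path.

Distances 1 and 2 (the bulk of pairs in dense graphs) are resolved by edge
tests and bitset common-neighbour intersections; rows containing farther or
unreachable pairs fall back to a bitset-frontier breadth-first search.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ONE = np.uint64(1)
_SIX = np.uint64(6)
_M63 = np.uint64(63)


@njit(cache=False)
def _pack_rows(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    nw = (n + 63) >> 6
    bits = np.zeros((n, nw), np.uint64)
    for u in range(n):
        for v in range(n):
            if adj[u, v] != 0:
                bits[u, v >> 6] |= _ONE << np.uint64(v & 63)
    return bits


@njit(cache=False)
def _bfs_row(bits, mask, members, k, s, row):
    """BFS distances from members[s] to all members, within the node set
    encoded by ``mask``; fills ``row`` (length k, -1 for unreachable)."""
    nw = bits.shape[1]
    reached = np.zeros(nw, np.uint64)
    frontier = np.zeros(nw, np.uint64)
    nxt = np.zeros(nw, np.uint64)
    for t in range(k):
        row[t] = -1.0
    g = members[s]
    reached[g >> 6] |= _ONE << np.uint64(g & 63)
    frontier[g >> 6] |= _ONE << np.uint64(g & 63)
    row[s] = 0.0
    d = 0.0
    while True:
        d += 1.0
        for w in range(nw):
            nxt[w] = np.uint64(0)
        for t in range(k):
            v = members[t]
            if frontier[v >> 6] & (_ONE << np.uint64(v & 63)):
                for w in range(nw):
                    nxt[w] |= bits[v, w]
        any_new = False
        for w in range(nw):
            nxt[w] &= mask[w] & ~reached[w]
            if nxt[w]:
                any_new = True
        if not any_new:
            return
        for t in range(k):
            v = members[t]
            if nxt[v >> 6] & (_ONE << np.uint64(v & 63)):
                row[t] = d
        for w in range(nw):
            reached[w] |= nxt[w]
            frontier[w] = nxt[w]


@njit(cache=False)
def all_pairs_bfs(adj: np.ndarray) -> np.ndarray:
    """Unweighted all-pairs shortest-path distances; inf for unreachable."""
    n = adj.shape[0]
    bits = _pack_rows(adj)
    nw = bits.shape[1]
    dist = np.full((n, n), -1.0)
    for u in range(n):
        dist[u, u] = 0.0
        for v in range(u + 1, n):
            if adj[u, v] != 0:
                dist[u, v] = 1.0
                dist[v, u] = 1.0
            else:
                for w in range(nw):
                    if bits[u, w] & bits[v, w]:
                        dist[u, v] = 2.0
                        dist[v, u] = 2.0
                        break
    mask = np.empty(nw, np.uint64)
    for w in range(nw):
        mask[w] = ~np.uint64(0)
    if n & 63:
        mask[nw - 1] = (_ONE << np.uint64(n & 63)) - _ONE
    members = np.arange(n)
    row = np.empty(n)
    for s in range(n):
        unresolved = False
        for v in range(n):
            if dist[s, v] < 0.0:
                unresolved = True
                break
        if not unresolved:
            continue
        _bfs_row(bits, mask, members, n, s, row)
        for v in range(n):
            dist[s, v] = row[v]
    for u in range(n):
        for v in range(n):
            if dist[u, v] < 0.0:
                dist[u, v] = np.inf
    return dist


@njit(cache=False)
def local_efficiency_sum(adj: np.ndarray) -> float:
    """Sum over nodes of the neighbour-subgraph global efficiency."""
    n = adj.shape[0]
    bits = _pack_rows(adj)
    nw = bits.shape[1]
    total = 0.0
    nb = np.empty(n, np.int64)
    row = np.empty(n)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j] != 0:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        dist = np.full((k, k), -1.0)
        need_bfs = False
        for u in range(k):
            dist[u, u] = 0.0
            bu = nb[u]
            for v in range(u + 1, k):
                bv = nb[v]
                if adj[bu, bv] != 0:
                    dist[u, v] = 1.0
                    dist[v, u] = 1.0
                else:
                    hit = False
                    for w in range(nw):
                        if bits[bu, w] & bits[bv, w] & bits[i, w]:
                            hit = True
                            break
                    if hit:
                        dist[u, v] = 2.0
                        dist[v, u] = 2.0
                    else:
                        need_bfs = True
        if need_bfs:
            for s in range(k):
                unresolved = False
                for v in range(k):
                    if dist[s, v] < 0.0:
                        unresolved = True
                        break
                if not unresolved:
                    continue
                _bfs_row(bits, bits[i], nb, k, s, row)
                for v in range(k):
                    dist[s, v] = row[v]
        inv_sum = 0.0
        for u in range(k):
            for v in range(u + 1, k):
                if dist[u, v] > 0.0:
                    inv_sum += 2.0 / dist[u, v]
        total += inv_sum / (k * (k - 1))
    return total
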