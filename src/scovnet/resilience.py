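"""Network resilience: giant-component decay under node removal.

A removal order (random, or by decreasing centrality) is applied one node at
a time; after each removal the size of the giant connected component (GCC)
is recorded, normalized by the GCC size of the intact network. Curves are
computed with the reverse union-find trick: removals are replayed backwards
as node additions, so a full N-step curve costs O(N + E) instead of N
connected-component sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .metrics import nodal_betweenness

__all__ = [
    "ResilienceCurve",
    "random_failure_curve",
    "targeted_attack_curve",
    "exact_random_failure_curve",
]


@dataclass
class ResilienceCurve:
    strategy: str  # random_failure | targeted_betweenness | targeted_degree
    n_removed: np.ndarray  # 0..N
    rel_gcc: np.ndarray  # relative giant-component size per n_removed
    n_random_orders: int | None = None
    seed: int | None = None


class _UnionFind:
    __slots__ = ("parent", "size", "max_size")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n
        self.max_size = 1 if n else 0

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return
        if self.size[rx] < self.size[ry]:
            rx, ry = ry, rx
        self.parent[ry] = rx
        self.size[rx] += self.size[ry]
        if self.size[rx] > self.max_size:
            self.max_size = self.size[rx]


def _neighbor_lists(adjacency: np.ndarray) -> list[np.ndarray]:
    a = np.asarray(adjacency) != 0
    return [np.flatnonzero(a[i]) for i in range(a.shape[0])]


def _gcc_size(adjacency: np.ndarray, alive=None) -> int:
    """GCC size via union-find over the (optionally masked) node set."""
    n = adjacency.shape[0]
    nodes = range(n) if alive is None else [i for i in range(n) if alive[i]]
    nodes = list(nodes)
    if not nodes:
        return 0
    pos = {v: k for k, v in enumerate(nodes)}
    uf = _UnionFind(len(nodes))
    a = np.asarray(adjacency) != 0
    for k, v in enumerate(nodes):
        for w in np.flatnonzero(a[v]):
            if w > v and w in pos:
                uf.union(k, pos[w])
    return uf.max_size


def _gcc_after_removals(order: np.ndarray, nbrs: list[np.ndarray]) -> np.ndarray:
    """GCC size after each prefix of ``order`` is removed (length N+1).

    Replays the order in reverse as additions; entry k is the GCC size once
    order[:k] has been removed.
    """
    n = len(nbrs)
    uf = _UnionFind(n)
    present = np.zeros(n, dtype=bool)
    out = np.zeros(n + 1, dtype=float)
    uf.max_size = 0
    for k in range(n - 1, -1, -1):
        v = int(order[k])
        present[v] = True
        if uf.max_size < 1:
            uf.max_size = 1
        for w in nbrs[v]:
            if present[w]:
                uf.union(v, int(w))
        out[k] = uf.max_size
    out[n] = 0.0
    return out


def random_failure_curve(
    adjacency: np.ndarray,
    n_orders: int = 100,
    seed: int | np.random.Generator = 0,
) -> ResilienceCurve:
    """Mean GCC-decay curve over ``n_orders`` uniformly random removal orders.

    Averaging over many orders removes the heavy noise of a single random
    pass; ``n_orders=1`` reproduces a single-realization curve.
    """
    a = np.asarray(adjacency)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    nbrs = _neighbor_lists(a)
    gcc0 = _gcc_size(a)
    acc = np.zeros(n + 1)
    for _ in range(n_orders):
        order = rng.permutation(n)
        acc += _gcc_after_removals(order, nbrs)
    curve = acc / (n_orders * gcc0)
    seed_val = -1 if isinstance(seed, np.random.Generator) else int(seed)
    return ResilienceCurve(
        strategy="random_failure",
        n_removed=np.arange(n + 1),
        rel_gcc=curve,
        n_random_orders=n_orders,
        seed=seed_val,
    )


def exact_random_failure_curve(adjacency: np.ndarray) -> ResilienceCurve:
    """Exact expectation of the random-failure curve by subset enumeration.

    After k uniformly random removals the surviving node set is a uniform
    k-subset, so the expected curve averages the GCC over all C(N, k)
    removal subsets. Exponential in N; guarded to N <= 16.
    """
    a = np.asarray(adjacency)
    n = a.shape[0]
    if n > 16:
        raise ValueError("exact enumeration limited to N <= 16 nodes")
    gcc0 = _gcc_size(a)
    curve = np.zeros(n + 1)
    curve[0] = 1.0
    nodes = list(range(n))
    for k in range(1, n):
        sizes = []
        for removed in combinations(nodes, k):
            alive = np.ones(n, dtype=bool)
            alive[list(removed)] = False
            sizes.append(_gcc_size(a, alive))
        curve[k] = np.mean(sizes) / gcc0
    return ResilienceCurve(
        strategy="random_failure",
        n_removed=np.arange(n + 1),
        rel_gcc=curve,
        n_random_orders=None,
        seed=None,
    )


def _centrality(adjacency: np.ndarray, rank_by: str) -> np.ndarray:
    if rank_by == "betweenness":
        return nodal_betweenness(adjacency).betweenness_raw
    if rank_by == "degree":
        return np.asarray(adjacency).sum(axis=1).astype(float)
    raise ValueError("rank_by must be 'betweenness' or 'degree'")


def targeted_attack_curve(
    adjacency: np.ndarray,
    rank_by: str = "betweenness",
    recompute: bool = False,
) -> ResilienceCurve:
    """GCC decay removing nodes by decreasing centrality; ties by node index.

    With ``recompute=False`` (default) the ranking is computed once on the
    intact network; with ``recompute=True`` the centrality is re-evaluated on
    the surviving subgraph before every removal.
    """
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not recompute:
        cent = _centrality(a, rank_by)
        order = np.lexsort((np.arange(n), -cent))
    else:
        remaining = list(range(n))
        sub = a.copy()
        order = []
        while remaining:
            cent = _centrality(sub, rank_by)
            pick = int(np.lexsort((np.arange(len(remaining)), -cent))[0])
            order.append(remaining.pop(pick))
            sub = np.delete(np.delete(sub, pick, axis=0), pick, axis=1)
        order = np.asarray(order)
    nbrs = _neighbor_lists(a)
    curve = _gcc_after_removals(np.asarray(order), nbrs) / _gcc_size(a)
    return ResilienceCurve(
        strategy=f"targeted_{rank_by}" + ("_recomputed" if recompute else ""),
        n_removed=np.arange(n + 1),
        rel_gcc=curve,
    )
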