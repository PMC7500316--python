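"""Independent brute-force graph-measure implementations used as test oracles.

Everything here is computed from first principles (triangle enumeration,
Floyd–Warshall distances, walk-count path counting, subset enumeration) and
shares no code with the package under test.
"""

from itertools import combinations

import numpy as np


def fw_distances(a):
    """Floyd–Warshall all-pairs distances."""
    a = np.asarray(a) != 0
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_cp(a):
    a = np.asarray(a) != 0
    n = a.shape[0]
    vals = []
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        k = len(nb)
        if k < 2:
            vals.append(0.0)
            continue
        tri = sum(1 for u, v in combinations(nb, 2) if a[u, v])
        vals.append(tri / (k * (k - 1) / 2))
    return float(np.mean(vals))


def brute_lp(a):
    d = fw_distances(a)
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(i + 1, n) if np.isfinite(d[i, j])]
    if not vals:
        raise ValueError("no edges")
    return float(np.mean(vals))


def brute_eglob(a):
    d = fw_distances(a)
    n = d.shape[0]
    if n < 2:
        return 0.0
    vals = [
        (1.0 / d[i, j]) if np.isfinite(d[i, j]) else 0.0
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


def brute_eloc(a):
    a = np.asarray(a) != 0
    n = a.shape[0]
    vals = []
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        if len(nb) < 2:
            vals.append(0.0)
            continue
        sub = a[np.ix_(nb, nb)].astype(float)
        vals.append(brute_eglob(sub))
    return float(np.mean(vals))


def brute_betweenness(a):
    """Shortest-path betweenness by walk-count path counting.

    The number of shortest s-t paths equals (A^d)_st for d = dist(s, t),
    and the number through v equals (A^d1)_sv (A^d2)_vt when
    d1 + d2 = d. Each unordered pair is counted once.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    d = fw_distances(a)
    maxd = int(np.nanmax(np.where(np.isfinite(d), d, 0)))
    powers = [np.eye(n)]
    for _ in range(maxd):
        powers.append(powers[-1] @ a)
    bt = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or d[s, t] == 0:
                continue
            dd = int(d[s, t])
            sigma = powers[dd][s, t]
            for v in range(n):
                if v in (s, t):
                    continue
                d1, d2 = d[s, v], d[v, t]
                if np.isfinite(d1) and np.isfinite(d2) and d1 + d2 == dd:
                    bt[v] += powers[int(d1)][s, v] * powers[int(d2)][v, t] / sigma
    return bt


def subset_mean_gcc_curve(a, nx_module):
    """Expected random-failure curve by exhaustive subset enumeration.

    A uniformly random removal order leaves, after k removals, a uniformly
    random (N-k)-subset, so the order-average curve equals the subset
    average; components come from networkx, independent of the package.
    """
    a = np.asarray(a)
    n = a.shape[0]
    g_full = nx_module.from_numpy_array(a)
    gcc0 = max(len(c) for c in nx_module.connected_components(g_full))
    curve = [1.0]
    for k in range(1, n):
        sizes = []
        for removed in combinations(range(n), k):
            g = g_full.copy()
            g.remove_nodes_from(removed)
            sizes.append(max(len(c) for c in nx_module.connected_components(g)))
        curve.append(float(np.mean(sizes)) / gcc0)
    curve.append(0.0)
    return np.array(curve)
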