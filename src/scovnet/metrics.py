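"""Binary undirected graph measures and small-world normalization.

Implements the standard segregation/integration measures used for brain
covariance networks — mean Watts–Strogatz clustering (Cp), characteristic
path length (Lp), Latora–Marchiori global and local efficiency, and Brandes
shortest-path betweenness — plus degree-preserving (Maslov–Sneppen) null
ensembles from which the normalized metrics gamma = Cp/Cp_rand,
lambda = Lp/Lp_rand and the small-world index sigma = gamma/lambda are
derived.

Conventions: nodes of degree < 2 contribute 0 to Cp and local efficiency;
Lp averages over connected pairs only and a ``disconnected`` flag records
whether any pair was unreachable (1/inf = 0 in the efficiencies). All
functions take a dense numpy adjacency (symmetric, binary, zero diagonal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._fast import all_pairs_bfs, local_efficiency_sum

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "NullEnsemble",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "nodal_betweenness",
    "global_metrics",
    "make_null_ensemble",
    "small_world",
    "distance_matrix",
]


@dataclass
class GlobalMetrics:
    cp: float
    lp: float
    e_glob: float
    e_loc: float
    disconnected: bool = False
    gamma: float | None = None
    lambda_: float | None = None
    sigma: float | None = None


@dataclass
class NodalMetrics:
    betweenness_raw: np.ndarray
    betweenness_norm: np.ndarray
    degenerate: bool = False  # mean raw betweenness was zero


@dataclass
class NullEnsemble:
    networks: list
    cp_rand: float
    lp_rand: float
    seed: int
    acceptance_ratio: float


def _check_adjacency(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    return a


def distance_matrix(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (inf for unreachable)."""
    a = _check_adjacency(adjacency)
    if a.shape[0] == 1:
        return np.zeros((1, 1))
    return all_pairs_bfs(np.ascontiguousarray(a != 0, dtype=np.uint8))


def clustering_coefficient(adjacency: np.ndarray) -> float:
    """Mean Watts–Strogatz clustering; degree-<2 nodes contribute 0."""
    a = _check_adjacency(adjacency)
    deg = a.sum(axis=1)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0
    possible = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(possible > 0, triangles / possible, 0.0)
    return float(c.mean())


def _lp_from_distances(dist: np.ndarray) -> tuple[float, bool]:
    # Off-diagonal handled implicitly: the diagonal contributes zeros to the
    # sum and is subtracted from the pair count.
    n = dist.shape[0]
    finite = np.isfinite(dist)
    count = int(finite.sum()) - n
    if count == 0:
        raise ValueError("characteristic path length undefined: graph has no edges")
    total = float(dist[finite].sum())
    return total / count, count < n * (n - 1)


def characteristic_path_length(adjacency: np.ndarray) -> float:
    """Mean shortest-path length over connected node pairs."""
    return _lp_from_distances(distance_matrix(adjacency))[0]


def _eglob_from_distances(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist  # diagonal zeros become inf, masked below
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum()) / (n * (n - 1))


def global_efficiency(adjacency: np.ndarray) -> float:
    """Mean of 1/d(i,j) over unordered pairs; disconnected pairs count 0."""
    return _eglob_from_distances(distance_matrix(adjacency))


def local_efficiency(adjacency: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbour subgraph."""
    a = _check_adjacency(adjacency)
    n = a.shape[0]
    total = local_efficiency_sum(np.ascontiguousarray(a != 0, dtype=np.uint8))
    return total / n


def nodal_betweenness(adjacency: np.ndarray) -> NodalMetrics:
    """Brandes shortest-path betweenness with fractional path crediting.

    betweenness_norm divides by the network-mean raw betweenness so the
    normalized values average to 1; when no shortest path passes through
    any node (e.g. a complete graph) the normalized vector is all zeros
    and ``degenerate`` is set.
    """
    a = _check_adjacency(adjacency)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=False)
    raw = np.array([bc[i] for i in range(a.shape[0])])
    mean = raw.mean()
    if mean == 0:
        return NodalMetrics(raw, np.zeros_like(raw), degenerate=True)
    return NodalMetrics(raw, raw / mean, degenerate=False)


def global_metrics(adjacency: np.ndarray) -> GlobalMetrics:
    """Cp, Lp, global and local efficiency from one shared distance matrix."""
    a = _check_adjacency(adjacency)
    dist = distance_matrix(a)
    lp, disco = _lp_from_distances(dist)
    return GlobalMetrics(
        cp=clustering_coefficient(a),
        lp=lp,
        e_glob=_eglob_from_distances(dist),
        e_loc=local_efficiency(a),
        disconnected=disco,
    )


# ---------------------------------------------------------------------------
# Degree-preserving nulls and small-world normalization
# ---------------------------------------------------------------------------

def double_edge_swap(
    adjacency: np.ndarray, n_attempts: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Maslov–Sneppen rewiring: attempt ``n_attempts`` double-edge swaps.

    Each attempt picks two edges (a,b), (c,d) and proposes (a,d), (c,b);
    proposals creating self-loops or multi-edges are rejected, so the degree
    sequence is preserved exactly. Returns (rewired adjacency, n_accepted).
    """
    a = (_check_adjacency(adjacency) != 0).astype(np.uint8)
    ei, ej = np.nonzero(np.triu(a))
    edges = np.column_stack([ei, ej])
    n_edges = len(edges)
    if n_edges < 2:
        return a.astype(float), 0
    pick_i = rng.integers(0, n_edges, size=n_attempts)
    pick_j = rng.integers(0, n_edges, size=n_attempts)
    flip = rng.integers(0, 2, size=n_attempts)
    accepted = 0
    for t in range(n_attempts):
        i = pick_i[t]
        j = pick_j[t]
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if flip[t]:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if a[u, y] or a[x, v]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, y] = a[y, u] = 1
        a[x, v] = a[v, x] = 1
        edges[i] = (u, y) if u < y else (y, u)
        edges[j] = (x, v) if x < v else (v, x)
        accepted += 1
    return a.astype(float), accepted


def make_null_ensemble(
    adjacency: np.ndarray,
    n_nulls: int = 20,
    seed: int | np.random.Generator = 0,
    swaps_per_edge: int = 10,
) -> NullEnsemble:
    """Ensemble of degree-matched randomized networks for metric normalization.

    Each null applies ``swaps_per_edge * E`` attempted double-edge swaps.
    Cp_rand and Lp_rand are arithmetic means over the ensemble. A warning is
    issued when the mean swap acceptance ratio falls below 10% (near-regular
    or nearly saturated graphs barely randomize).
    """
    a = _check_adjacency(adjacency)
    n_edges = int(a.sum()) // 2
    if n_edges < 2:
        raise ValueError("null ensemble needs at least 2 edges")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_attempts = swaps_per_edge * n_edges
    nulls = []
    cps = []
    lps = []
    acc_total = 0
    for _ in range(n_nulls):
        null, acc = double_edge_swap(a, n_attempts, rng)
        acc_total += acc
        nulls.append(null)
        dist = distance_matrix(null)
        cps.append(clustering_coefficient(null))
        lps.append(_lp_from_distances(dist)[0])
    ratio = acc_total / (n_attempts * n_nulls)
    if ratio < 0.10:
        warnings.warn(
            f"double-edge-swap acceptance ratio {ratio:.3f} < 0.10; "
            "nulls may be under-randomized",
            stacklevel=2,
        )
    seed_val = -1 if isinstance(seed, np.random.Generator) else int(seed)
    return NullEnsemble(
        networks=nulls,
        cp_rand=float(np.mean(cps)),
        lp_rand=float(np.mean(lps)),
        seed=seed_val,
        acceptance_ratio=ratio,
    )


def small_world(adjacency: np.ndarray, ensemble: NullEnsemble) -> GlobalMetrics:
    """Attach gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, sigma = gamma/lambda."""
    gm = global_metrics(adjacency)
    if ensemble.cp_rand == 0:
        raise ValueError("cp_rand is zero; gamma undefined")
    if not np.isfinite(ensemble.lp_rand) or ensemble.lp_rand == 0:
        raise ValueError("lp_rand undefined")
    gm.gamma = gm.cp / ensemble.cp_rand
    gm.lambda_ = gm.lp / ensemble.lp_rand
    gm.sigma = gm.gamma / gm.lambda_
    return gm
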