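"""Group covariance-network construction.

A cohort's regional values are first residualized against nuisance
covariates (age, sex, total intracranial volume) within the group, then
correlated across subjects to give an N x N Pearson matrix, which is
binarized at each density of a grid by keeping the top-K correlation-ranked
node pairs (K = round(density * N(N-1)/2)). Because thresholding consumes a
single fixed ranking, edge sets are nested along the density grid and every
result is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .synthetic import MorphometryCohort

__all__ = [
    "DensityGrid",
    "CovarianceNetwork",
    "residualize",
    "correlation_matrix",
    "rank_edges",
    "threshold_by_density",
    "threshold_grid",
    "validate_density_grid",
]

COVARIATE_COLUMNS = ("age", "sex", "tiv")


@dataclass(frozen=True)
class DensityGrid:
    """Density thresholds: start to stop inclusive, fixed step (default 0.10:0.02:0.50)."""

    start: float = 0.10
    stop: float = 0.50
    step: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.start <= self.stop < 1):
            raise ValueError("need 0 < start <= stop < 1")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    @property
    def densities(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        d = self.start + self.step * np.arange(n)
        return np.round(d[d <= self.stop + 1e-12], 10)

    @staticmethod
    def from_string(text: str) -> "DensityGrid":
        """Parse 'start:step:stop', e.g. '0.10:0.02:0.50'."""
        parts = [float(x) for x in text.split(":")]
        if len(parts) != 3:
            raise ValueError("expected start:step:stop")
        return DensityGrid(start=parts[0], step=parts[1], stop=parts[2])


@dataclass
class CovarianceNetwork:
    """A correlation matrix together with its binarization at one density."""

    r_matrix: np.ndarray
    adjacency: np.ndarray
    density: float  # achieved K / (N(N-1)/2)
    requested_density: float
    region_names: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def _design_matrix(covariates) -> np.ndarray:
    cols = [np.ones(len(covariates))]
    cols += [covariates[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
    return np.column_stack(cols)


def residualize(cohort: MorphometryCohort) -> np.ndarray:
    """OLS residuals of each region on [1, age, sex, tiv], fit within the group.

    Residuals have zero mean per region and are exactly orthogonal to every
    covariate column. Raises if the design matrix is rank deficient, naming
    the collinear covariates.
    """
    x = _design_matrix(cohort.covariates)
    return residualize_values(cohort.values, x)


def residualize_values(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residualize a value matrix against an explicit design matrix."""
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = ("intercept",) + COVARIATE_COLUMNS
        bad = [
            names[j] if j < len(names) else f"col{j}"
            for j in range(design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient covariate design; collinear: {bad}")
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def correlation_matrix(residuals: np.ndarray) -> np.ndarray:
    """Pearson correlations across subjects; diagonal set to 0 for network use."""
    resid = np.asarray(residuals, dtype=float)
    if resid.shape[0] < 3:
        raise ValueError("need at least 3 subjects for correlation")
    sd = resid.std(axis=0)
    if np.any(sd == 0):
        idx = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance regions at column indices {idx.tolist()}")
    r = np.corrcoef(resid, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return r


def rank_edges(r_matrix: np.ndarray, edge_rank: str = "signed"):
    """Deterministic ranking of all node pairs by correlation strength.

    'signed' ranks by descending r (positive co-variation enters first);
    'abs' ranks by descending |r|. Ties break by descending |r| then
    lexicographic (i, j). Returns (i_idx, j_idx) arrays of length N(N-1)/2.
    """
    n = r_matrix.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = r_matrix[iu, ju]
    if edge_rank == "signed":
        order = np.lexsort((ju, iu, -np.abs(vals), -vals))
    elif edge_rank == "abs":
        order = np.lexsort((ju, iu, -np.abs(vals)))
    else:
        raise ValueError("edge_rank must be 'signed' or 'abs'")
    return iu[order], ju[order]


def _adjacency_from_pairs(n: int, ei: np.ndarray, ej: np.ndarray) -> np.ndarray:
    a = np.zeros((n, n))
    a[ei, ej] = 1.0
    return a + a.T


def threshold_by_density(
    r_matrix: np.ndarray,
    density: float,
    region_names=None,
    edge_rank: str = "signed",
) -> CovarianceNetwork:
    """Binarize by keeping the K = round(density * N(N-1)/2) top-ranked pairs."""
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = r_matrix.shape[0]
    m = n * (n - 1) // 2
    k = int(round(density * m))
    if k < 1:
        raise ValueError(f"density {density} keeps zero edges on {n} nodes")
    ei, ej = rank_edges(r_matrix, edge_rank)
    adj = _adjacency_from_pairs(n, ei[:k], ej[:k])
    return CovarianceNetwork(
        r_matrix=r_matrix,
        adjacency=adj,
        density=k / m,
        requested_density=float(density),
        region_names=list(region_names) if region_names is not None else [],
    )


def threshold_grid(
    r_matrix: np.ndarray, grid: DensityGrid, edge_rank: str = "signed"
):
    """Yield (density, adjacency) along the grid, reusing one edge ranking."""
    n = r_matrix.shape[0]
    m = n * (n - 1) // 2
    ei, ej = rank_edges(r_matrix, edge_rank)
    for d in grid.densities:
        k = int(round(d * m))
        if k < 1:
            raise ValueError(f"density {d} keeps zero edges on {n} nodes")
        yield float(d), _adjacency_from_pairs(n, ei[:k], ej[:k])


def is_connected(adjacency: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(adjacency), directed=False)
    return n_comp == 1


def validate_density_grid(
    r_a: np.ndarray,
    r_b: np.ndarray,
    grid: DensityGrid,
    edge_rank: str = "signed",
) -> dict:
    """Report each group's minimum fully-connected grid density and warnings.

    The grid start should sit at or above the density where both groups'
    networks become connected; the grid stop should stay below 0.5, past
    which covariance networks approach random graphs.
    """
    report: dict = {"densities": grid.densities.tolist(), "warnings": []}
    for label, r in (("a", r_a), ("b", r_b)):
        min_conn = None
        flags = []
        for d, adj in threshold_grid(r, grid, edge_rank):
            conn = is_connected(adj)
            flags.append(conn)
            if conn and min_conn is None:
                min_conn = d
        report[f"group_{label}_connected"] = flags
        report[f"group_{label}_min_connected_density"] = min_conn
        if min_conn is None:
            report["warnings"].append(
                f"group {label}: network disconnected at every grid density"
            )
        elif grid.start < min_conn:
            report["warnings"].append(
                f"group {label}: grid start {grid.start} below minimum "
                f"connected density {min_conn}"
            )
    if grid.stop >= 0.5:
        report["warnings"].append(
            "grid stop >= 0.5: denser covariance networks are likely non-biological"
        )
    return report
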