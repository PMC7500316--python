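"""Synthetic two-group morphometry cohorts with known covariance topology.

Regional gray-matter volumes are drawn from a multivariate normal whose
correlation structure follows a ground-truth graph: every edge of the
topology is assigned a target correlation, the resulting matrix is repaired
to the nearest valid (positive semi-definite) correlation matrix by
eigenvalue clipping, and independent Gaussian measurement noise plus linear
covariate effects (age, sex, total intracranial volume) are added on top.
Because the generating covariance is known in closed form, every downstream
stage of the covariance-network pipeline can be tested against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "WattsStrogatz",
    "ErdosRenyi",
    "RingLattice",
    "HubSpoke",
    "ModularBridge",
    "CustomAdjacency",
    "GroundTruthSpec",
    "MorphometryCohort",
    "generate_cohort",
    "generate_paired_cohorts",
    "preset_pair",
    "default_region_names",
]

_EIG_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Topologies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WattsStrogatz:
    """Ring lattice with k neighbours per node, each edge rewired with prob p."""

    k: int = 6
    p: float = 0.05

    def build(self, n: int, seed: int) -> np.ndarray:
        g = nx.watts_strogatz_graph(n, self.k, self.p, seed=int(seed))
        return nx.to_numpy_array(g, dtype=float)


@dataclass(frozen=True)
class ErdosRenyi:
    p: float = 0.07

    def build(self, n: int, seed: int) -> np.ndarray:
        g = nx.gnp_random_graph(n, self.p, seed=int(seed))
        return nx.to_numpy_array(g, nodelist=range(n), dtype=float)


@dataclass(frozen=True)
class RingLattice:
    k: int = 6

    def build(self, n: int, seed: int) -> np.ndarray:
        g = nx.watts_strogatz_graph(n, self.k, 0.0, seed=0)
        return nx.to_numpy_array(g, dtype=float)


@dataclass(frozen=True)
class HubSpoke:
    """A small fully-connected hub core; every peripheral node attaches to all hubs.

    Removing the hubs disconnects the periphery entirely, making this the
    canonical worst case for targeted (centrality-ranked) attack.
    """

    n_hubs: int = 4

    def build(self, n: int, seed: int) -> np.ndarray:
        if not 0 < self.n_hubs < n:
            raise ValueError("n_hubs must be in (0, n_regions)")
        a = np.zeros((n, n))
        h = self.n_hubs
        a[:h, :h] = 1.0
        a[:h, h:] = 1.0
        a[h:, :h] = 1.0
        np.fill_diagonal(a, 0.0)
        return a


@dataclass(frozen=True)
class ModularBridge:
    """Two ring-lattice modules joined only through a single bridge node.

    Node 0 is the bridge: it connects to ``n_links`` nodes in each module and
    carries every shortest path between them, giving it dominant betweenness
    in the generating graph.
    """

    k: int = 6
    n_links: int = 3

    def build(self, n: int, seed: int) -> np.ndarray:
        if n < 2 * self.k + 3:
            raise ValueError("n too small for two ring modules")
        half = (n - 1) // 2
        m1 = nx.watts_strogatz_graph(half, self.k, 0.0, seed=0)
        m2 = nx.watts_strogatz_graph(n - 1 - half, self.k, 0.0, seed=0)
        a = np.zeros((n, n))
        a1 = nx.to_numpy_array(m1)
        a2 = nx.to_numpy_array(m2)
        a[1:half + 1, 1:half + 1] = a1
        a[half + 1:, half + 1:] = a2
        for j in range(self.n_links):
            a[0, 1 + j] = a[1 + j, 0] = 1.0
            a[0, half + 1 + j] = a[half + 1 + j, 0] = 1.0
        return a


@dataclass(frozen=True)
class CustomAdjacency:
    adjacency: tuple  # nested tuple so the dataclass stays hashable

    @staticmethod
    def from_array(a: np.ndarray) -> "CustomAdjacency":
        return CustomAdjacency(tuple(map(tuple, np.asarray(a, dtype=float))))

    def build(self, n: int, seed: int) -> np.ndarray:
        a = np.asarray(self.adjacency, dtype=float)
        if a.shape != (n, n):
            raise ValueError(f"custom adjacency shape {a.shape} != ({n}, {n})")
        return a


# ---------------------------------------------------------------------------
# Spec and cohort containers
# ---------------------------------------------------------------------------

def default_region_names(n: int) -> list[str]:
    """Atlas abbreviations for n = 90, generic labels otherwise."""
    if n == 90:
        from .atlas import load_atlas

        return list(load_atlas()["abbreviation"])
    return [f"R{i + 1:03d}" for i in range(n)]


@dataclass(frozen=True)
class GroundTruthSpec:
    """Generative model for one group's regional-volume table.

    Parameters
    ----------
    n_regions : number of atlas regions (network nodes).
    topology : ground-truth graph whose edges receive ``base_correlation``.
    base_correlation : target Pearson correlation on ground-truth edges,
        in [0, 1); 0 gives independent regions.
    covariate_effects : regression slopes of regional volume on
        (age [years], sex [0/1], tiv [ml]); identical across regions.
    noise_sd : SD of i.i.d. Gaussian measurement noise added per region
        (structured signal has unit SD, so noise_sd is a noise-to-signal ratio).
    mean_volume : baseline regional volume (arbitrary volume units).
    seed : data-generation seed (subject draws).
    topology_seed : seed for any randomness in the topology itself, kept
        separate so two specs that differ only in ``seed`` share a graph.
    """

    n_regions: int = 90
    topology: object = field(default_factory=WattsStrogatz)
    base_correlation: float = 0.5
    covariate_effects: tuple[float, float, float] = (-0.01, 0.15, 0.003)
    noise_sd: float = 0.2
    mean_volume: float = 10.0
    seed: int = 0
    topology_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError("n_regions must be >= 3")
        if not 0 <= self.base_correlation < 1:
            raise ValueError("base_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    # -- generating model, closed form -------------------------------------

    def ground_truth_adjacency(self) -> np.ndarray:
        a = self.topology.build(self.n_regions, self.topology_seed)
        a = np.asarray(a, dtype=float)
        if a.shape != (self.n_regions, self.n_regions):
            raise ValueError("topology returned wrong shape")
        if not np.allclose(a, a.T):
            raise ValueError("topology adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("topology adjacency must have zero diagonal")
        return (a != 0).astype(float)

    def signal_correlation(self) -> np.ndarray:
        """Correlation matrix of the structured signal after PSD repair."""
        a = self.ground_truth_adjacency()
        c = np.eye(self.n_regions) + self.base_correlation * a
        w, v = np.linalg.eigh(c)
        if w.min() < _EIG_FLOOR:
            w = np.clip(w, _EIG_FLOOR, None)
            c = (v * w) @ v.T
            d = np.sqrt(np.diag(c))
            c = c / np.outer(d, d)
            c = (c + c.T) / 2.0
            np.fill_diagonal(c, 1.0)
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError(
                f"covariance repair failed for spec {self!r}: matrix is not PSD"
            )
        return c

    def expected_residual_correlation(self) -> np.ndarray:
        """Correlation of the generated values once covariates are removed.

        The generated value is signal + noise with the signal at unit
        variance, so every off-diagonal entry of the repaired signal
        correlation is attenuated by 1 / (1 + noise_sd**2).
        """
        c = self.signal_correlation()
        r = c / (1.0 + self.noise_sd**2)
        np.fill_diagonal(r, 1.0)
        return r


@dataclass
class MorphometryCohort:
    """Subjects x regions morphometric table with per-subject covariates."""

    group_label: str
    values: np.ndarray  # (n_subjects, n_regions)
    covariates: pd.DataFrame  # columns: age, sex, tiv; index: subject ids
    region_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x regions)")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries")
        if len(self.region_names) != self.values.shape[1]:
            raise ValueError("region_names length must match value columns")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("region_names must be unique")
        if list(self.covariates.columns) != ["age", "sex", "tiv"]:
            raise ValueError("covariates must have columns [age, sex, tiv]")
        if len(self.covariates) != self.values.shape[0]:
            raise ValueError("covariates rows must match subjects")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    # Middle-aged cohort: age uniform over the study's recruitment range,
    # balanced sex, TIV in ml around a typical adult head size.
    age = rng.uniform(40.0, 67.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    tiv = rng.normal(1450.0, 130.0, size=n)
    return pd.DataFrame(
        {"age": age, "sex": sex, "tiv": tiv},
        index=[f"S{i + 1:03d}" for i in range(n)],
    )


def generate_cohort(
    spec: GroundTruthSpec,
    n_subjects: int = 31,
    group_label: str = "group",
    region_names: Sequence[str] | None = None,
) -> MorphometryCohort:
    """Draw a cohort of regional volumes from the spec's generating model.

    values = mean_volume + signal + covariates @ slopes + noise, with
    signal ~ MVN(0, signal_correlation) and noise ~ N(0, noise_sd**2) i.i.d.
    Reproducible from ``spec.seed``.
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    rng = np.random.default_rng(spec.seed)
    c = spec.signal_correlation()
    chol = np.linalg.cholesky(c + _EIG_FLOOR * np.eye(spec.n_regions))
    cov_df = _draw_covariates(n_subjects, rng)
    z = rng.standard_normal((n_subjects, spec.n_regions)) @ chol.T
    noise = spec.noise_sd * rng.standard_normal((n_subjects, spec.n_regions))
    slopes = np.asarray(spec.covariate_effects, dtype=float)
    shift = cov_df.to_numpy() @ slopes
    values = spec.mean_volume + z + noise + shift[:, None]
    names = (
        list(region_names)
        if region_names is not None
        else default_region_names(spec.n_regions)
    )
    return MorphometryCohort(group_label, values, cov_df, names)


def generate_paired_cohorts(
    spec_a: GroundTruthSpec,
    spec_b: GroundTruthSpec,
    n_a: int = 31,
    n_b: int = 31,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[MorphometryCohort, MorphometryCohort]:
    """Two cohorts sharing region identity; a null scenario when the specs
    differ only in their data seed."""
    if spec_a.n_regions != spec_b.n_regions:
        raise ValueError(
            f"n_regions mismatch: {spec_a.n_regions} != {spec_b.n_regions}"
        )
    names = default_region_names(spec_a.n_regions)
    a = generate_cohort(spec_a, n_a, labels[0], names)
    b = generate_cohort(spec_b, n_b, labels[1], names)
    return a, b


def preset_pair(
    name: str,
    seed: int = 0,
    n_regions: int = 90,
    base_correlation: float = 0.6,
    noise_sd: float = 0.2,
) -> tuple[GroundTruthSpec, GroundTruthSpec]:
    """Documented two-group scenarios for power and calibration studies.

    null
        Identical generating models, independent subject draws: the
        exchangeable-label scenario for type-I calibration.
    reduced_clustering
        Group A keeps a near-lattice small-world graph (k = 10, p = 0.05);
        group B rewires every edge (p = 1), destroying triangles while
        preserving density, so the built-in clustering difference is A > B.
    hub_spoke
        Group A small-world; group B hub-and-spoke, which collapses under
        targeted attack, so the built-in resilience ordering is A > B at
        intermediate removal counts.
    bridge
        Group A small-world; group B two modules joined through region 0,
        concentrating betweenness on the bridge region in group B.
    """
    common = dict(
        n_regions=n_regions, base_correlation=base_correlation, noise_sd=noise_sd
    )
    ws = WattsStrogatz(k=10, p=0.05)
    spec_a = GroundTruthSpec(topology=ws, seed=seed * 2 + 1, **common)
    if name == "null":
        topo_b = ws
    elif name == "reduced_clustering":
        topo_b = WattsStrogatz(k=10, p=1.0)
    elif name == "hub_spoke":
        topo_b = HubSpoke(n_hubs=5)
    elif name == "bridge":
        topo_b = ModularBridge(k=6, n_links=3)
    else:
        raise ValueError(f"unknown preset {name!r}")
    spec_b = dataclasses.replace(spec_a, topology=topo_b, seed=seed * 2 + 2)
    return spec_a, spec_b
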