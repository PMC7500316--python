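"""Nuisance regression, correlation, and density thresholding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scovnet import DensityGrid, correlation_matrix, threshold_by_density
from scovnet.network import (
    residualize,
    residualize_values,
    threshold_grid,
    validate_density_grid,
)
from scovnet.synthetic import ErdosRenyi, GroundTruthSpec, MorphometryCohort, generate_cohort


def _toy_cohort(values, age, sex, tiv):
    cov = pd.DataFrame({"age": age, "sex": sex, "tiv": tiv})
    names = [f"R{i}" for i in range(values.shape[1])]
    return MorphometryCohort("toy", values, cov, names)


class TestResidualize:
    def test_matches_normal_equations_oracle(self):
        """Six hand-set subjects: residuals must equal the explicit
        (X'X)^{-1} X'y solve."""
        values = np.array(
            [[1.0, 2.0], [2.0, 1.5], [3.0, 4.0], [2.5, 0.5], [4.0, 3.0], [1.5, 2.5]]
        )
        age = [45, 50, 55, 60, 65, 48]
        sex = [0, 1, 0, 1, 0, 1]
        tiv = [1400, 1500, 1450, 1550, 1480, 1420]
        cohort = _toy_cohort(values, age, sex, tiv)
        x = np.column_stack([np.ones(6), age, sex, tiv]).astype(float)
        beta = np.linalg.solve(x.T @ x, x.T @ values)
        expected = values - x @ beta
        np.testing.assert_allclose(residualize(cohort), expected, atol=1e-9)

    def test_residuals_orthogonal_to_covariates(self):
        spec = GroundTruthSpec(
            n_regions=8,
            topology=ErdosRenyi(0.3),
            covariate_effects=(0.05, 0.5, 0.002),
            seed=4,
        )
        cohort = generate_cohort(spec, 30)
        resid = residualize(cohort)
        assert np.allclose(resid.mean(axis=0), 0, atol=1e-10)
        for col in ("age", "sex", "tiv"):
            dots = resid.T @ cohort.covariates[col].to_numpy()
            assert np.allclose(dots, 0, atol=1e-6)

    def test_zero_covariate_effects_residuals_are_centered_values(self):
        spec = GroundTruthSpec(
            n_regions=6,
            topology=ErdosRenyi(0.3),
            covariate_effects=(0.0, 0.0, 0.0),
            seed=5,
        )
        cohort = generate_cohort(spec, 200)
        resid = residualize(cohort)
        centered = cohort.values - cohort.values.mean(axis=0)
        # covariates fit only noise: residuals close to centered raw values
        assert np.corrcoef(resid.ravel(), centered.ravel())[0, 1] > 0.99

    def test_collinear_design_named(self):
        x = np.column_stack([np.ones(5), np.arange(5), 2 * np.arange(5), np.ones(5)])
        with pytest.raises(ValueError, match="collinear"):
            residualize_values(np.random.default_rng(0).normal(size=(5, 3)), x)


class TestCorrelation:
    def test_hand_computed_toy_table(self):
        """4 subjects x 3 regions, r values frozen from the explicit Pearson
        formula sum((x-mx)(y-my)) / sqrt(sum sq)."""
        x = np.array([[1.0, 2.0, 5.0], [2.0, 1.0, 4.0], [3.0, 5.0, 1.0], [4.0, 4.0, 2.0]])
        r = correlation_matrix(x)
        def pearson(u, v):
            u = u - u.mean(); v = v - v.mean()
            return float(u @ v / np.sqrt((u @ u) * (v @ v)))
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else pearson(x[:, i], x[:, j])
                assert r[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicate_and_negated_regions(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 1))
        x = np.hstack([base, base, -base, rng.normal(size=(10, 1))])
        r = correlation_matrix(x)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_region_rejected(self):
        x = np.ones((5, 3))
        x[:, 0] = np.arange(5)
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(x)

    def test_shift_invariance_of_pipeline(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 5))
        r1 = correlation_matrix(x)
        x2 = x.copy()
        x2[:, 3] += 100.0
        np.testing.assert_allclose(correlation_matrix(x2), r1, atol=1e-10)


class TestThreshold:
    def _r(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(40, n))
        return correlation_matrix(x)

    def test_density_one_complete(self):
        net = threshold_by_density(self._r(), 1.0)
        n = net.n_nodes
        assert net.n_edges == n * (n - 1) // 2

    def test_single_edge_at_global_maximum(self):
        r = self._r()
        n = r.shape[0]
        net = threshold_by_density(r, 2 / (n * (n - 1)))
        assert net.n_edges == 1
        i, j = np.argwhere(np.triu(net.adjacency))[0]
        iu = np.triu_indices(n, 1)
        assert r[i, j] == r[iu].max()

    def test_top_k_matches_full_sort_oracle(self):
        r = self._r(5, seed=3)
        net = threshold_by_density(r, 0.4)
        pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        top4 = sorted(pairs, key=lambda p: -r[p])[:4]
        got = {tuple(p) for p in np.argwhere(np.triu(net.adjacency))}
        assert got == set(top4)

    def test_abs_ranking_mode(self):
        r = np.zeros((4, 4))
        r[0, 1] = r[1, 0] = -0.9
        r[2, 3] = r[3, 2] = 0.5
        r[0, 2] = r[2, 0] = 0.1
        net_signed = threshold_by_density(r, 2 / 6, edge_rank="signed")
        net_abs = threshold_by_density(r, 2 / 6, edge_rank="abs")
        assert net_signed.adjacency[0, 1] == 0  # negative edge excluded
        assert net_abs.adjacency[0, 1] == 1  # strongest magnitude included

    def test_zero_edges_rejected(self):
        with pytest.raises(ValueError, match="zero edges"):
            threshold_by_density(self._r(), 1e-4)

    def test_nested_edge_sets_along_grid(self):
        r = self._r(12, seed=4)
        grid = DensityGrid(0.1, 0.9, 0.1)
        prev = None
        prev_density = -1.0
        for d, adj in threshold_grid(r, grid):
            dens = adj.sum() / (12 * 11)
            assert dens >= prev_density
            prev_density = dens
            if prev is not None:
                assert np.all(adj >= prev)  # supersets
            prev = adj

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        """Any strictly increasing transform of r preserves the edge set."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(15, 7))
        r = correlation_matrix(x)
        r2 = np.tanh(2.0 * r)  # strictly monotone, rank preserving
        np.fill_diagonal(r2, 0.0)
        a1 = threshold_by_density(r, 0.3).adjacency
        a2 = threshold_by_density(r2, 0.3).adjacency
        np.testing.assert_array_equal(a1, a2)


class TestGridValidation:
    def test_complete_matrix_connected_everywhere(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 8))
        r = correlation_matrix(x)
        rep = validate_density_grid(r, r, DensityGrid(0.3, 0.9, 0.2))
        assert rep["group_a_min_connected_density"] is not None

    def test_two_block_matrix_flags_disconnection(self):
        # two blocks of perfectly correlated regions, no cross-correlation
        rng = np.random.default_rng(1)
        u = rng.normal(size=(50, 1)); v = rng.normal(size=(50, 1))
        noise = 0.01 * rng.normal(size=(50, 6))
        x = np.hstack([u, u, u, v, v, v]) + noise
        r = correlation_matrix(x)
        rep = validate_density_grid(r, r, DensityGrid(0.2, 0.2, 0.1))
        assert rep["group_a_connected"] == [False]
        assert any("disconnected" in w for w in rep["warnings"])

    def test_min_connected_density_matches_exhaustive_traversal(self, null_pair):
        import networkx as nx

        a, _ = null_pair
        r = correlation_matrix(residualize(a))
        grid = DensityGrid(0.05, 0.5, 0.05)
        rep = validate_density_grid(r, r, grid)
        expected = None
        for d, adj in threshold_grid(r, grid):
            if nx.is_connected(nx.from_numpy_array(adj)):
                expected = d
                break
        assert rep["group_a_min_connected_density"] == expected

    def test_high_stop_warns(self, null_pair):
        a, _ = null_pair
        r = correlation_matrix(residualize(a))
        rep = validate_density_grid(r, r, DensityGrid(0.3, 0.6, 0.1))
        assert any(">= 0.5" in w for w in rep["warnings"])
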