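"""Permutation machinery: exchangeability, determinism, AUC arithmetic."""

import numpy as np
import pytest

from scovnet import DensityGrid, preset_pair, generate_paired_cohorts
from scovnet.inference import (
    PermutationConfig,
    benjamini_hochberg,
    compare_nodal_betweenness,
    compare_resilience,
    metric_curves,
    permute_groups,
    run_global_comparison,
)


class TestPermuteGroups:
    def test_sizes_and_union_preserved(self, null_pair):
        a, b = null_pair
        pa, pb = permute_groups(a, b, seed=1, i=1)
        assert pa.n_subjects == a.n_subjects
        assert pb.n_subjects == b.n_subjects
        pooled = np.vstack([a.values, b.values])
        perm_pooled = np.vstack([pa.values, pb.values])
        assert np.array_equal(
            np.sort(pooled, axis=0), np.sort(perm_pooled, axis=0)
        )

    def test_reproducible_from_seed_and_index(self, null_pair):
        a, b = null_pair
        p1, _ = permute_groups(a, b, seed=2, i=7)
        p2, _ = permute_groups(a, b, seed=2, i=7)
        np.testing.assert_array_equal(p1.values, p2.values)
        p3, _ = permute_groups(a, b, seed=2, i=8)
        assert not np.array_equal(p1.values, p3.values)

    def test_assignment_frequency_matches_group_fraction(self, null_pair):
        a, b = null_pair
        n = a.n_subjects + b.n_subjects
        counts = np.zeros(n)
        n_iter = 600
        for i in range(n_iter):
            rng = np.random.default_rng([3, i])
            perm = rng.permutation(n)
            counts[perm[: a.n_subjects]] += 1
        freq = counts / n_iter
        expected = a.n_subjects / n
        assert np.all(np.abs(freq - expected) < 0.08)

    def test_identity_permutation_recovers_observed(self, null_pair, fast_config):
        """Permutation i = identity must reproduce the observed statistics
        exactly: the observed and permuted pipelines share every code path."""
        a, b = null_pair
        n = a.n_subjects + b.n_subjects
        pa, pb = permute_groups(a, b, seed=0, i=0, permutation=np.arange(n))
        ca = metric_curves(a, fast_config)
        cpa = metric_curves(pa, fast_config)
        for m in ca:
            np.testing.assert_array_equal(ca[m], cpa[m])


class TestGlobalComparison:
    def test_self_comparison_never_significant(self, null_pair, fast_config):
        a, _ = null_pair
        gc = run_global_comparison(a, a, fast_config)
        for m, res in gc.per_density.items():
            np.testing.assert_allclose(res.observed_diff, 0, atol=1e-12)
            assert not res.significant.any()
            assert np.all(res.p_value == 1.0)
        for m, res in gc.auc.items():
            assert res.diff == pytest.approx(0, abs=1e-12)
            assert not res.significant

    def test_auc_linearity_and_constant_curve(self, null_pair, fast_config):
        a, b = null_pair
        gc = run_global_comparison(a, b, fast_config)
        dens = gc.densities
        for m in gc.auc:
            diff_curve = gc.curves_a[m] - gc.curves_b[m]
            assert np.trapezoid(diff_curve, dens) == pytest.approx(
                gc.auc[m].auc_a - gc.auc[m].auc_b, abs=1e-12
            )
        # constant curve: auc = c * width
        c = 0.7
        width = dens[-1] - dens[0]
        assert np.trapezoid(np.full_like(dens, c), dens) == pytest.approx(c * width)

    def test_hand_entered_three_point_trapezoid(self):
        x = np.array([0.1, 0.2, 0.4])
        y = np.array([1.0, 3.0, 2.0])
        # hand trapezoid: 0.1*(1+3)/2 + 0.2*(3+2)/2 = 0.2 + 0.5
        assert np.trapezoid(y, x) == pytest.approx(0.7)

    def test_determinism_end_to_end(self, null_pair, fast_config):
        a, b = null_pair
        g1 = run_global_comparison(a, b, fast_config)
        g2 = run_global_comparison(a, b, fast_config)
        for m in g1.per_density:
            np.testing.assert_array_equal(
                g1.per_density[m].p_value, g2.per_density[m].p_value
            )
            assert g1.auc[m].p_value == g2.auc[m].p_value

    def test_effect_preset_gives_positive_cp_difference(self):
        spec_a, spec_b = preset_pair("reduced_clustering", seed=4)
        a, b = generate_paired_cohorts(spec_a, spec_b, 31, 31)
        cfg = PermutationConfig(
            n_perm=20, n_nulls=0, densities=DensityGrid(0.10, 0.46, 0.12), seed=5
        )
        gc = run_global_comparison(a, b, cfg)
        diff = gc.per_density["cp"].observed_diff
        assert (diff > 0).sum() > len(diff) / 2

    def test_sigma_included_when_nulls_requested(self, null_pair):
        a, b = null_pair
        cfg = PermutationConfig(
            n_perm=3, n_nulls=4, densities=DensityGrid(0.2, 0.4, 0.2), seed=6
        )
        gc = run_global_comparison(a, b, cfg)
        assert "sigma" in gc.per_density
        assert "sigma" in gc.auc


class TestNodalAndResilience:
    def test_self_comparison_nodal_all_zero(self, null_pair, fast_config):
        a, _ = null_pair
        res, table = compare_nodal_betweenness(a, a, fast_config)
        np.testing.assert_allclose(res.observed_diff, 0, atol=1e-12)
        assert not table["significant"].any()
        assert list(table.columns) == [
            "region", "betweenness_a", "betweenness_b", "diff", "p_value",
            "significant",
        ]

    def test_bridge_preset_raises_bridge_betweenness(self):
        """Group B's generator funnels all cross-module paths through region 0,
        so its betweenness AUC difference (A - B) is negative there.

        The grid sits below the generating graph's density (~0.068): above
        it, correlation transitivity lets indirect cross-module correlations
        enter as edges that bypass the bridge.
        """
        spec_a, spec_b = preset_pair("bridge", seed=3)
        a, b = generate_paired_cohorts(spec_a, spec_b, 60, 60)
        cfg = PermutationConfig(
            n_perm=5, n_nulls=0, densities=DensityGrid(0.03, 0.06, 0.01), seed=8
        )
        _, table = compare_nodal_betweenness(a, b, cfg)
        assert table["diff"].iloc[0] < 0

    def test_self_comparison_resilience(self, null_pair):
        a, _ = null_pair
        cfg = PermutationConfig(
            n_perm=5, n_nulls=0, densities=DensityGrid(0.2, 0.4, 0.1),
            n_orders=20, seed=9,
        )
        res, meta = compare_resilience(a, a, cfg, strategy="betweenness")
        np.testing.assert_allclose(res.observed_diff, 0, atol=1e-12)
        assert not res.significant.any()
        assert res.observed_diff[0] == 0 and res.observed_diff[-1] == 0

    def test_hub_spoke_group_collapses_under_attack(self):
        spec_a, spec_b = preset_pair("hub_spoke", seed=10, base_correlation=0.8,
                                     noise_sd=0.1)
        a, b = generate_paired_cohorts(spec_a, spec_b, 40, 40)
        cfg = PermutationConfig(
            n_perm=5, n_nulls=0, densities=DensityGrid(0.1, 0.3, 0.1), seed=11
        )
        res, meta = compare_resilience(a, b, cfg, strategy="betweenness")
        n = len(res.observed_diff) - 1
        mid = slice(n // 6, n // 2)
        assert res.observed_diff[mid].mean() > 0


def test_benjamini_hochberg_basic():
    p = np.array([0.001, 0.01, 0.04, 0.2, 0.9])
    rej = benjamini_hochberg(p, alpha=0.05)
    assert rej[0] and rej[1]
    assert not rej[4]
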