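import numpy as np
import pytest
from scipy import sparse, stats

from phaselock.inference import (
    CBPTConfig,
    TMap,
    cluster_permutation_test,
    find_clusters,
    pointwise_t,
    restrict_adjacency,
    rsn_group_test,
)
from phaselock.source_space import build_adjacency
from conftest import brute_force_components


def chain_adjacency(n):
    """1-D chain i -- i+1 as a sparse matrix."""
    rows = list(range(n - 1)) + list(range(1, n))
    cols = list(range(1, n)) + list(range(n - 1))
    return sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))


class TestPointwiseT:
    def test_identical_groups_give_zero(self):
        x = np.tile(np.array([[1.0], [2.0], [3.0]]), (2, 1))
        groups = ["a"] * 3 + ["b"] * 3
        tm = pointwise_t(x, groups)
        np.testing.assert_array_equal(tm.t, 0.0)

    def test_zero_variance_in_both_groups_warns_and_zeroes(self):
        x = np.full((6, 2), 3.0)
        with pytest.warns(RuntimeWarning, match="zero variance"):
            tm = pointwise_t(x, ["a"] * 3 + ["b"] * 3)
        np.testing.assert_array_equal(tm.t, 0.0)

    def test_hand_computed_pooled_t(self):
        # means 2 vs 5, pooled sd 1, se = sqrt(2/3): t = -3/0.8165 = -3.674
        x = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        tm = pointwise_t(x, ["a"] * 3 + ["b"] * 3)
        assert tm.t[0] == pytest.approx(-3.674, abs=5e-4)
        assert tm.df == 4

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_matches_scipy_reference(self, rng, variant):
        x = rng.normal(0, 1, (15, 20))
        groups = ["g1"] * 8 + ["g2"] * 7
        tm = pointwise_t(x, groups, variant=variant)
        ref = stats.ttest_ind(x[:8], x[8:], equal_var=(variant == "pooled"))
        np.testing.assert_allclose(tm.t, ref.statistic, atol=1e-10)

    def test_sign_convention_group1_larger_is_positive(self, rng):
        x = np.concatenate([rng.normal(5, 1, (10, 3)), rng.normal(0, 1, (10, 3))])
        groups = ["robust"] * 10 + ["frail"] * 10
        tm = pointwise_t(x, groups, group_order=("robust", "frail"))
        assert np.all(tm.t > 0)


class TestFindClusters:
    def _tmap(self, t, df=18):
        return TMap(t=np.asarray(t, dtype=float), n1=10, n2=10, df=df)

    def test_no_suprathreshold_sources_gives_empty_list(self):
        tm = self._tmap([0.1, -0.2, 0.3])
        assert find_clusters(tm, chain_adjacency(3), alpha=0.05) == []

    def test_hand_built_chain_masses(self):
        # threshold |t| > ~2.1 at alpha=0.05, df=18; t=(0,4,4,0,4)
        tm = self._tmap([0.0, 4.0, 4.0, 0.0, 4.0])
        clusters = find_clusters(tm, chain_adjacency(5), alpha=0.05)
        masses = sorted(c.mass for c in clusters)
        assert masses == [4.0, 8.0]
        assert all(c.sign == "positive" for c in clusters)

    def test_signs_split_before_connectivity(self):
        tm = self._tmap([4.0, -4.0, 4.0])
        clusters = find_clusters(tm, chain_adjacency(3), alpha=0.05)
        assert len(clusters) == 3  # adjacency cannot join opposite signs

    def test_matches_brute_force_flood_fill(self, rng, grid_flat):
        adj = build_adjacency(grid_flat)
        edges = adj.edges()
        for _ in range(10):
            t = rng.normal(0, 2, grid_flat.n_sources)
            tm = TMap(t=t, n1=10, n2=10, df=18)
            clusters = find_clusters(tm, adj, alpha=0.05)
            t_crit = stats.t.isf(0.025, 18)
            for sign, mask in (("positive", t > t_crit), ("negative", t < -t_crit)):
                want = brute_force_components(set(np.flatnonzero(mask)), edges)
                got = [
                    frozenset(c.indices.tolist())
                    for c in clusters
                    if c.sign == sign
                ]
                assert sorted(got, key=sorted) == sorted(want, key=sorted)

    def test_mass_is_exact_sum_of_member_t(self, rng, grid_flat):
        adj = build_adjacency(grid_flat)
        t = rng.normal(0, 3, grid_flat.n_sources)
        tm = TMap(t=t, n1=8, n2=8, df=14)
        for c in find_clusters(tm, adj, alpha=0.05):
            assert c.mass == t[c.indices].sum()


class TestClusterPermutationTest:
    def _data(self, rng, n1=10, n2=8, n_src=25, shift=None):
        x = rng.normal(0, 1, (n1 + n2, n_src))
        if shift is not None:
            region, delta = shift
            x[n1:, region] -= delta
        groups = ["robust"] * n1 + ["frail"] * n2
        return x, groups

    def test_fixed_seed_is_bit_identical(self, rng, grid_flat):
        adj = build_adjacency(grid_flat)
        x, groups = self._data(rng, shift=([3, 4, 8], 1.5))
        cfg = CBPTConfig(n_permutations=200, rng_seed=42)
        a = cluster_permutation_test(x, groups, adj, cfg)
        b = cluster_permutation_test(x, groups, adj, cfg)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert ca.p_value == cb.p_value
            assert ca.mass == cb.mass
            np.testing.assert_array_equal(ca.indices, cb.indices)

    def test_group_relabeling_flips_sign_not_p(self, rng, grid_flat):
        # exhaustive mode: the permutation null is the full relabeling set,
        # identical whichever group is named first
        adj = build_adjacency(grid_flat)
        x, groups = self._data(rng, n1=4, n2=4, shift=([6, 7, 11], 2.5))
        cfg = CBPTConfig(exhaustive=True)
        fwd = cluster_permutation_test(x, groups, adj, cfg, group_order=("robust", "frail"))
        rev = cluster_permutation_test(x, groups, adj, cfg, group_order=("frail", "robust"))
        fa = sorted((round(c.p_value, 12), abs(c.mass), c.sign) for c in fwd)
        ra = sorted((round(c.p_value, 12), abs(c.mass), c.sign) for c in rev)
        assert [(p, m) for p, m, _ in fa] == [(p, m) for p, m, _ in ra]
        flip = {"positive": "negative", "negative": "positive"}
        assert [s for _, _, s in fa] == [flip[s] for _, _, s in ra]

    def test_detects_implanted_shift(self, rng, grid_flat):
        adj = build_adjacency(grid_flat)
        region = [6, 7, 8, 11, 12]
        x, groups = self._data(rng, shift=(region, 2.0))
        cfg = CBPTConfig(n_permutations=500, rng_seed=1)
        res = cluster_permutation_test(x, groups, adj, cfg)
        best = res[0]
        assert best.p_value < 0.05
        assert best.sign == "positive"  # robust > frail after the frail deficit
        jacc = len(set(best.indices) & set(region)) / len(set(best.indices) | set(region))
        assert jacc >= 0.5

    def test_too_few_relabelings_raises(self, grid_flat):
        adj = build_adjacency(grid_flat)
        x = np.random.default_rng(0).normal(0, 1, (6, 25))
        groups = ["a"] * 3 + ["b"] * 3  # C(6,3) = 20 < 100
        with pytest.raises(ValueError, match="relabelings"):
            cluster_permutation_test(x, groups, adj, CBPTConfig(n_permutations=100))

    def test_monte_carlo_converges_to_exhaustive_p(self, rng, grid_flat):
        """For n1 = n2 = 4 the exact permutation null has C(8,4) = 70
        relabelings; the (1+k)/(N+1) Monte-Carlo estimate must approach it."""
        adj = build_adjacency(grid_flat)
        x = rng.normal(0, 1, (8, 25))
        x[4:, [6, 7, 11]] -= 2.5
        groups = ["robust"] * 4 + ["frail"] * 4
        exact = cluster_permutation_test(
            x, groups, adj, CBPTConfig(exhaustive=True, n_permutations=100)
        )
        mc = cluster_permutation_test(
            x, groups, adj,
            CBPTConfig(n_permutations=4000, rng_seed=9, allow_few_relabelings=True),
        )
        assert len(exact) == len(mc)
        for ce, cm in zip(exact, mc):
            assert cm.p_value == pytest.approx(ce.p_value, abs=0.03)

    def test_type_one_error_is_controlled_quick(self, grid_flat):
        """Small null simulation: any-cluster rejection rate near alpha."""
        adj = build_adjacency(grid_flat)
        hits = 0
        n_runs = 60
        for i in range(n_runs):
            r = np.random.default_rng(1000 + i)
            x = r.normal(0, 1, (16, 25))
            groups = ["robust"] * 9 + ["frail"] * 7
            res = cluster_permutation_test(
                x, groups, adj, CBPTConfig(n_permutations=250, rng_seed=i)
            )
            hits += any(c.p_value < 0.05 for c in res)
        assert hits / n_runs < 0.15  # generous bound for a 60-run check


class TestRSNGroupTest:
    def test_identical_groups_give_p_one(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        res = rsn_group_test(v, ["a"] * 3 + ["b"] * 3)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_reference(self, rng):
        v = rng.normal(0.3, 0.05, 30)
        groups = ["robust"] * 17 + ["frail"] * 13
        res = rsn_group_test(v, groups)
        ref = stats.ttest_ind(v[:17], v[17:], equal_var=True)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_rejection_rate_matches_analytic_power(self):
        """Delta = 1 SD with n = 34 vs 20: empirical rejection rate at
        alpha = 0.05 within 5 points of the noncentral-t power."""
        n1, n2, delta = 34, 20, 1.0
        df = n1 + n2 - 2
        ncp = delta / np.sqrt(1 / n1 + 1 / n2)
        tc = stats.t.isf(0.025, df)
        power = stats.nct.sf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp)
        rej = 0
        n_sim = 500
        r = np.random.default_rng(7)
        for _ in range(n_sim):
            a = r.normal(delta, 1, n1)
            b = r.normal(0, 1, n2)
            res = rsn_group_test(
                np.concatenate([a, b]), ["r"] * n1 + ["f"] * n2
            )
            rej += res.p < 0.05
        assert rej / n_sim == pytest.approx(power, abs=0.05)


class TestRestrictAdjacency:
    def test_subgraph_reindexing(self, grid_flat):
        adj = build_adjacency(grid_flat)
        keep = np.array([0, 1, 2, 10, 11])
        sub = restrict_adjacency(adj, keep)
        assert sub.shape == (5, 5)
        full = adj.to_sparse().toarray()
        np.testing.assert_array_equal(sub.toarray(), full[np.ix_(keep, keep)])
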