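"""Knet curve, AUK, permutation test and Knode ranking."""

import itertools

import numpy as np
import pytest

import netripley as nr
from netripley.kstat import _auk_batch, _trapezoid_weight_matrix
from netripley.network import NetworkError

from conftest import binary_weights, random_connected_network


def hand_knet_curve(dist, p, grid):
    """Pair-by-pair evaluation of the K-function, written independently."""
    n = len(p)
    pbar = p.mean()
    out = []
    for s in grid:
        total = 0.0
        for i in range(n):
            loo = (p.sum() - p[i]) / (n - 1)
            for j in range(n):
                if j == i:
                    continue
                if np.isfinite(dist[i, j]) and dist[i, j] <= s:
                    total += p[i] * (p[j] - loo)
        out.append(2.0 / (n * pbar**2) * total)
    return np.array(out)


class TestKnetCurve:
    def test_constant_weights_give_zero_curve(self, path5):
        d = nr.shortest_path_distances(path5)
        g = nr.distance_grid(d)
        curve = nr.knet_curve(d, nr.NodeWeights(np.full(5, 0.7)), g)
        np.testing.assert_allclose(curve.values, 0.0, atol=1e-12)

    def test_curve_starts_and_ends_at_zero(self, rng):
        net = random_connected_network(30, 0.15, rng)
        d = nr.shortest_path_distances(net)
        g = nr.distance_grid(d)
        w = nr.NodeWeights(rng.uniform(0, 1, 30))
        curve = nr.knet_curve(d, w, g)
        assert curve.values[0] == pytest.approx(0.0, abs=1e-12)
        assert curve.values[-1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_evaluation_on_path(self, path5):
        d = nr.shortest_path_distances(path5)
        g = nr.distance_grid(d)
        p = np.array([1.0, 1.0, 0.0, 0.0, 0.0])
        curve = nr.knet_curve(d, nr.NodeWeights(p, kind="binary"), g)
        np.testing.assert_allclose(curve.values, hand_knet_curve(d.values, p, g))

    def test_matches_hand_evaluation_random(self, rng):
        net = random_connected_network(12, 0.3, rng)
        d = nr.shortest_path_distances(net)
        g = nr.distance_grid(d)
        p = rng.uniform(0.1, 2.0, 12)
        curve = nr.knet_curve(d, nr.NodeWeights(p), g)
        np.testing.assert_allclose(
            curve.values, hand_knet_curve(d.values, p, g), atol=1e-10
        )

    def test_rescaling_leaves_curve_unchanged(self, rng):
        net = random_connected_network(15, 0.25, rng)
        d = nr.shortest_path_distances(net)
        g = nr.distance_grid(d)
        p = rng.uniform(0.1, 1.0, 15)
        c1 = nr.knet_curve(d, nr.NodeWeights(p), g)
        c2 = nr.knet_curve(d, nr.NodeWeights(7.3 * p), g)
        np.testing.assert_allclose(c1.values, c2.values, atol=1e-10)

    def test_zero_weights_rejected(self, path5):
        d = nr.shortest_path_distances(path5)
        with pytest.raises(NetworkError, match="positive"):
            nr.knet_curve(d, nr.NodeWeights(np.zeros(5)), nr.distance_grid(d))


class TestAuk:
    def test_zero_curve(self):
        c = nr.KCurve(np.array([0.0, 1.0, 2.0]), np.zeros(3))
        assert nr.auk(c) == 0.0

    def test_trapezoid_arithmetic(self):
        c = nr.KCurve(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 0.0]))
        assert nr.auk(c) == pytest.approx(1.0)

    def test_linearity(self, rng):
        grid = np.concatenate(([0.0], np.sort(rng.uniform(0.1, 5, 10))))
        vals = rng.normal(size=11)
        assert nr.auk(nr.KCurve(grid, 3.5 * vals)) == pytest.approx(
            3.5 * nr.auk(nr.KCurve(grid, vals))
        )

    def test_batch_auk_equals_curve_integration(self, rng):
        """The GEMM fast path is an identity with trapezoidal curve AUK."""
        net = random_connected_network(25, 0.15, rng)
        d = nr.shortest_path_distances(net)
        g = nr.distance_grid(d)
        tmat = _trapezoid_weight_matrix(d, g)
        for _ in range(5):
            p = rng.uniform(0.05, 1.0, 25)
            direct = nr.knet_curve(d, nr.NodeWeights(p), g).auk
            fast = _auk_batch(tmat, p[:, None])[0]
            assert fast == pytest.approx(direct, rel=1e-10)


class TestPermuteWeights:
    def test_multiset_conserved(self, rng):
        w = nr.NodeWeights(rng.uniform(0, 1, 50))
        out = nr.permute_weights(w, 3)
        assert sorted(out.values) == sorted(w.values)

    def test_seed_determinism(self, rng):
        w = nr.NodeWeights(rng.uniform(0, 1, 50))
        a = nr.permute_weights(w, 5).values
        b = nr.permute_weights(w, 5).values
        c = nr.permute_weights(w, 6).values
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_uniformity_binomial_check(self):
        w = nr.NodeWeights(np.array([1.0, 0.0, 0.0, 0.0]), kind="binary")
        rng = np.random.default_rng(0)
        counts = np.zeros(4)
        for _ in range(10_000):
            counts += nr.permute_weights(w, rng).values
        assert np.all(np.abs(counts - 2500) <= 150)


class TestKnetTest:
    def test_constant_weights_degenerate(self, path5):
        d = nr.shortest_path_distances(path5)
        with pytest.warns(UserWarning, match="degenerate"):
            res = nr.knet_test(d, nr.NodeWeights(np.ones(5)), n_perm=50, seed=0)
        assert res.p_value == 1.0

    def test_p_monotone_in_exact_enumeration_rank(self, rng):
        """Against a shared permutation null, the Z-test p-value orders hit
        placements exactly as their exact-enumeration AUK rank."""
        from scipy.stats import norm

        net = random_connected_network(6, 0.5, rng)
        d = nr.shortest_path_distances(net)
        g = nr.distance_grid(d)
        tmat = _trapezoid_weight_matrix(d, g)
        base = np.zeros(6)
        base[:2] = 1.0
        null = nr.knet_test(
            d, nr.NodeWeights(base, kind="binary"), n_perm=500, seed=11
        ).permuted_auks
        mu, sd = null.mean(), null.std(ddof=1)
        auks, ps = [], []
        for pair in itertools.combinations(range(6), 2):
            p = np.zeros(6)
            p[list(pair)] = 1.0
            a = _auk_batch(tmat, p[:, None])[0]
            auks.append(a)
            ps.append(norm.sf((a - mu) / sd))
        order = np.argsort(auks)
        assert np.all(np.diff(np.array(ps)[order]) <= 1e-12)

    def test_rescaling_leaves_z_and_p_unchanged(self, rng):
        net = random_connected_network(20, 0.2, rng)
        d = nr.shortest_path_distances(net)
        p = rng.uniform(0.1, 1.0, 20)
        r1 = nr.knet_test(d, nr.NodeWeights(p), n_perm=100, seed=4)
        r2 = nr.knet_test(d, nr.NodeWeights(11.0 * p), n_perm=100, seed=4)
        assert r1.z_score == pytest.approx(r2.z_score, rel=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    def test_clustered_hits_detected(self, rng):
        net = nr.generate_ba_network(200, 1, seed=5)
        d = nr.shortest_path_distances(net)
        hits = nr.sample_clustered_hits(net, d, cutoff=10, n_hits=5, seed=7)
        w = binary_weights(net, hits.members)
        res = nr.knet_test(d, w, n_perm=200, seed=8)
        assert res.p_value < 0.01


class TestKnodeScores:
    def test_constant_weights_zero_scores_id_tiebreak(self, path5):
        d = nr.shortest_path_distances(path5)
        table = nr.knode_scores(
            d, nr.NodeWeights(np.ones(5)), node_ids=path5.node_ids
        )
        assert np.all(table["score"] == 0.0)
        assert list(table.sort_values("rank").index) == sorted(path5.node_ids)

    def test_aggregation_reproduces_knet(self, rng):
        """sum_i p_i * Knode_i / pbar recovers the Knet AUK exactly."""
        net = random_connected_network(18, 0.2, rng)
        d = nr.shortest_path_distances(net)
        g = nr.distance_grid(d)
        p = rng.uniform(0.05, 1.0, 18)
        w = nr.NodeWeights(p)
        table = nr.knode_scores(d, w, grid=g, node_ids=net.node_ids)
        agg = float(p @ table["score"].values) / p.mean()
        assert agg == pytest.approx(nr.knet_curve(d, w, g).auk, rel=1e-9)

    def test_ranks_are_permutation(self, rng):
        net = random_connected_network(15, 0.25, rng)
        d = nr.shortest_path_distances(net)
        table = nr.knode_scores(d, nr.NodeWeights(rng.uniform(0.1, 1, 15)))
        assert sorted(table["rank"]) == list(range(1, 16))

    def test_planted_cluster_nodes_outrank_background(self):
        """Planted high-weight cluster nodes dominate the Knode ranking:
        their median rank beats the background's, and the best-ranked planted
        node beats a degree-matched outsider."""
        cfg = nr.RecoveryConfig(n_nodes=300, n_clusters=2)
        median_wins = 0
        matched_wins = 0
        n_trials = 40
        for trial in range(n_trials):
            net = nr.generate_ba_network(300, 1, seed=trial)
            d = nr.shortest_path_distances(net)
            w, truth = nr.assign_multicluster_weights(net, d, cfg, seed=trial)
            table = nr.knode_scores(d, w, node_ids=net.node_ids)
            r = table.loc[net.node_ids, "rank"].values
            if np.median(r[truth]) < np.median(r[~truth]):
                median_wins += 1
            deg = np.array([net.graph.degree[v] for v in net.node_ids])
            best = np.flatnonzero(truth)[np.argmin(r[truth])]
            rng = np.random.default_rng(trial + 5)
            candidates = np.flatnonzero((~truth) & (deg == deg[best]))
            if candidates.size and r[best] < r[rng.choice(candidates)]:
                matched_wins += 1
        assert median_wins >= 31
        assert matched_wins >= 38


class TestExtractTopModule:
    def test_whole_network(self, triangle, rng):
        d = nr.shortest_path_distances(triangle)
        t = nr.knode_scores(d, nr.NodeWeights(np.array([1.0, 1, 0]), kind="binary"),
                            node_ids=triangle.node_ids)
        mod = nr.extract_top_module(triangle, t, k=3)
        assert mod.n_nodes == 3 and mod.n_edges == 3

    def test_single_node(self, triangle):
        d = nr.shortest_path_distances(triangle)
        t = nr.knode_scores(d, nr.NodeWeights(np.array([1.0, 1, 0]), kind="binary"),
                            node_ids=triangle.node_ids)
        mod = nr.extract_top_module(triangle, t, k=1)
        assert mod.n_nodes == 1 and mod.n_edges == 0

    def test_edge_count_matches_induced_subgraph(self, rng):
        net = random_connected_network(40, 0.15, rng)
        d = nr.shortest_path_distances(net)
        t = nr.knode_scores(d, nr.NodeWeights(rng.uniform(0.1, 1, 40)),
                            node_ids=net.node_ids)
        mod = nr.extract_top_module(net, t, k=10)
        top = set(t.sort_values("rank").index[:10])
        expected = sum(
            1 for a, b in net.graph.edges if a in top and b in top
        )
        assert mod.n_edges == expected


class TestCompareNetworks:
    def _sets(self, net, rng, n_sets=3, size=25):
        out = []
        for i in range(n_sets):
            members = rng.choice(net.node_ids, size=size, replace=False)
            out.append(nr.GeneSet(f"S{i}", "", frozenset(members)))
        return out

    def test_identical_networks_zero_differential(self, rng):
        net = nr.generate_ba_network(120, 1, seed=3)
        d = nr.shortest_path_distances(net)
        sets = self._sets(net, rng)
        table = nr.compare_networks(sets, net, d, net, d, n_perm=50, seed=2)
        tested = table[~table["skipped"]]
        np.testing.assert_allclose(tested["z_diff"], 0.0, atol=1e-12)

    def test_size_filter_skips_small_sets(self, rng):
        net = nr.generate_ba_network(120, 1, seed=3)
        d = nr.shortest_path_distances(net)
        sets = self._sets(net, rng) + [
            nr.GeneSet("tiny", "", frozenset(net.node_ids[:5]))
        ]
        table = nr.compare_networks(sets, net, d, net, d, n_perm=50, seed=2)
        assert bool(table.loc["tiny", "skipped"])

    def test_no_qualifying_set_rejected(self, rng):
        net = nr.generate_ba_network(50, 1, seed=3)
        d = nr.shortest_path_distances(net)
        sets = [nr.GeneSet("tiny", "", frozenset(net.node_ids[:4]))]
        with pytest.raises(NetworkError, match="no gene set"):
            nr.compare_networks(sets, net, d, net, d, n_perm=50, seed=2)

    def test_planted_rewiring_detected(self):
        """A set clustered only on network B tops the z_B - z_A ranking."""
        wins = 0
        n_trials = 15
        for trial in range(n_trials):
            rng = np.random.default_rng(1000 + trial)
            net_a = nr.generate_ba_network(150, 1, seed=2000 + trial)
            net_b = nr.generate_ba_network(150, 1, seed=3000 + trial)
            d_a = nr.shortest_path_distances(net_a)
            d_b = nr.shortest_path_distances(net_b)
            planted = nr.sample_clustered_hits(net_b, d_b, cutoff=25, n_hits=25,
                                               seed=rng)
            planted = nr.GeneSet("planted", "", planted.members)
            decoys = [
                nr.GeneSet(f"D{i}", "", frozenset(
                    rng.choice(net_a.node_ids, size=25, replace=False)))
                for i in range(4)
            ]
            table = nr.compare_networks(
                [planted] + decoys, net_a, d_a, net_b, d_b, n_perm=100,
                seed=int(rng.integers(2**31)),
            )
            tested = table[~table["skipped"]]
            if tested["z_diff"].idxmin() == "planted":  # most negative z_A - z_B
                wins += 1
        assert wins >= n_trials - 1
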