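import itertools

import numpy as np
import pytest

from mapperplus import (
    AssignmentMatrix,
    WeightedGraph,
    expected_visits,
    modularity,
    nmi,
    transition_matrix,
    wla,
    wlcf,
)
from mapperplus.synthetic import planted_partition_graph

from conftest import clique_pair_graph, random_partition


def brute_force_modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    """Naive double-sum over all node pairs (independent oracle)."""
    k = adj.sum(axis=1)
    two_w = adj.sum()
    q = 0.0
    for u in range(len(labels)):
        for v in range(len(labels)):
            if labels[u] == labels[v]:
                q += adj[u, v] - k[u] * k[v] / two_w
    return q / two_w


def enumerate_walk_visits(adj: np.ndarray, starts, l_max: int) -> np.ndarray:
    """Expected visits by explicit enumeration of all walks of length <= l_max."""
    n = adj.shape[0]
    t = adj / adj.sum(axis=1, keepdims=True)
    visits = np.zeros(n)
    for start in starts:
        for length in range(1, l_max + 1):
            for walk in itertools.product(range(n), repeat=length):
                prob = 1.0
                prev = start
                for step in walk:
                    prob *= t[prev, step]
                    prev = step
                if prob > 0:
                    visits[walk[-1]] += prob
    return visits / len(starts)


class TestTransitionMatrix:
    def test_two_node_edge(self):
        g = WeightedGraph(adjacency=np.array([[0.0, 3.0], [3.0, 0.0]]))
        np.testing.assert_allclose(
            transition_matrix(g).toarray(), [[0.0, 1.0], [1.0, 0.0]]
        )

    def test_self_loop_row(self):
        g = WeightedGraph(adjacency=np.array([[1.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(transition_matrix(g).toarray()[0], [0.5, 0.5])

    def test_rows_stochastic(self):
        rng = np.random.default_rng(0)
        a = rng.random((15, 15))
        a = (a + a.T) / 2
        g = WeightedGraph(adjacency=a)
        rows = np.asarray(transition_matrix(g).sum(axis=1)).ravel()
        np.testing.assert_allclose(rows, 1.0, atol=1e-12)

    def test_isolated_node_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        with pytest.raises(ValueError):
            transition_matrix(WeightedGraph(adjacency=a))


class TestExpectedVisits:
    def test_unreachable_component_gets_zero(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        g = WeightedGraph(adjacency=a)
        u = AssignmentMatrix.from_labels([0, 0, 1, 1])
        v = expected_visits(transition_matrix(g), u, l_max=4)
        assert v[2, 0] == 0.0 and v[3, 0] == 0.0
        assert v[0, 1] == 0.0 and v[1, 1] == 0.0

    def test_single_self_loop_node_accumulates_l_max(self):
        g = WeightedGraph(adjacency=np.array([[2.0, 0.0], [0.0, 2.0]]))
        u = AssignmentMatrix.from_labels([0, 1])
        v = expected_visits(transition_matrix(g), u, l_max=5)
        assert v[0, 0] == pytest.approx(5.0)

    def test_path_graph_matches_walk_enumeration(self):
        # 3-node path, community = {end node 2}, l_max = 2
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1.0
        g = WeightedGraph(adjacency=a)
        u = AssignmentMatrix.from_labels([0, 0, 1])
        v = expected_visits(transition_matrix(g), u, l_max=2)
        oracle = enumerate_walk_visits(a, starts=[2], l_max=2)
        np.testing.assert_allclose(v[:, 1], oracle, atol=1e-12)
        oracle0 = enumerate_walk_visits(a, starts=[0, 1], l_max=2)
        np.testing.assert_allclose(v[:, 0], oracle0, atol=1e-12)

    def test_l_max_zero_rejected(self):
        g = WeightedGraph(adjacency=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            expected_visits(transition_matrix(g), AssignmentMatrix.from_labels([0, 1]), 0)


class TestWla:
    def test_clique_partition_is_fixed_point(self):
        g = clique_pair_graph(10)
        u0 = AssignmentMatrix.from_labels([0] * 10 + [1] * 10)
        out, converged = wla(g, u0)
        assert converged
        assert (out.labels() == u0.labels()).all()

    def test_single_community_returned_unchanged(self):
        g = clique_pair_graph(5)
        u0 = AssignmentMatrix.from_labels([0] * 10)
        out, converged = wla(g, u0)
        assert converged and out.m == 1

    def test_recovers_planted_blocks_from_noisy_start(self):
        g, planted = planted_partition_graph([30, 30], 0.5, 0.02, seed=11)
        rng = np.random.default_rng(11)
        noisy = planted.copy()
        flip = rng.choice(60, size=6, replace=False)  # 10% flipped
        noisy[flip] = 1 - noisy[flip]
        out, _ = wla(g, AssignmentMatrix.from_labels(noisy))
        assert nmi(out, AssignmentMatrix.from_labels(planted)) >= 0.9

    def test_output_is_true_partition(self):
        g, _ = planted_partition_graph([15, 15], 0.6, 0.1, seed=3)
        out, _ = wla(g, AssignmentMatrix.from_labels(np.arange(30) % 3))
        assert out.u.sum(axis=1).tolist() == [1] * 30

    def test_deterministic(self):
        g, _ = planted_partition_graph([20, 20], 0.5, 0.05, seed=5)
        u0 = AssignmentMatrix.from_labels(np.arange(40) % 2)
        a, _ = wla(g, u0)
        b, _ = wla(g, u0)
        assert (a.labels() == b.labels()).all()


class TestModularity:
    def test_two_triangles_half(self):
        a = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            a[i, j] = a[j, i] = 1.0
        g = WeightedGraph(adjacency=a)
        q = modularity(g, AssignmentMatrix.from_labels([0, 0, 0, 1, 1, 1]))
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_single_community_zero(self):
        g = clique_pair_graph(4)
        assert modularity(g, AssignmentMatrix.from_labels([0] * 8)) == pytest.approx(
            0.0, abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        a = (rng.random((n, n)) < 0.4) * rng.random((n, n))
        a = (a + a.T) / 2
        a += np.diag(rng.random(n))  # self-loops included
        a[a.sum(axis=1) == 0, 0] = 0.1  # avoid isolated nodes
        a = (a + a.T) / 2
        g = WeightedGraph(adjacency=a)
        labels = random_partition(n, 3, rng)
        q = modularity(g, AssignmentMatrix.from_labels(labels))
        assert q == pytest.approx(brute_force_modularity(a, labels), abs=1e-12)

    def test_random_partition_of_er_graph_near_zero(self):
        qs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = (rng.random((40, 40)) < 0.3).astype(float)
            a = np.triu(a, 1)
            a = a + a.T
            a[a.sum(axis=1) == 0, :] = 0  # keep symmetric; fix isolated below
            for i in np.flatnonzero(a.sum(axis=1) == 0):
                a[i, (i + 1) % 40] = a[(i + 1) % 40, i] = 1.0
            g = WeightedGraph(adjacency=a)
            labels = random_partition(40, 4, rng)
            qs.append(modularity(g, AssignmentMatrix.from_labels(labels)))
        assert max(abs(q) for q in qs) <= 0.1


class TestWlcf:
    @pytest.mark.parametrize("seed", range(10))
    def test_bridged_cliques_split_exactly(self, seed):
        g = clique_pair_graph(20)
        out, _ = wlcf(g, seed=seed)
        labels = out.labels()
        assert out.m == 2
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_complete_graph_single_community(self):
        # brute-force check: every 2-partition of K6 has Q <= 0
        a = np.ones((6, 6)) - np.eye(6)
        g = WeightedGraph(adjacency=a)
        for bits in range(1, 31):
            labels = [(bits >> i) & 1 for i in range(6)]
            assert modularity(g, AssignmentMatrix.from_labels(labels)) <= 1e-12
        out, _ = wlcf(g, seed=0)
        assert out.m == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_four_block_recovery(self, seed):
        g, planted = planted_partition_graph([50] * 4, 0.5, 0.05, seed=seed)
        out, _ = wlcf(g, seed=seed)
        assert out.m == 4
        assert nmi(out, AssignmentMatrix.from_labels(planted)) >= 0.95

    def test_relabeling_invariance_on_structured_graph(self):
        g = clique_pair_graph(15)
        rng = np.random.default_rng(9)
        perm = rng.permutation(30)
        a_perm = g.adjacency.toarray()[np.ix_(perm, perm)]
        out = wlcf(g, seed=0)[0]
        out_perm = wlcf(WeightedGraph(adjacency=a_perm), seed=0)[0]
        # permuting node ids must permute the (well-separated) partition
        back = np.empty(30, dtype=int)
        back[perm] = out_perm.labels()
        assert nmi(out, AssignmentMatrix.from_labels(back)) == pytest.approx(1.0)

    def test_isolated_node_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        with pytest.raises(ValueError):
            wlcf(WeightedGraph(adjacency=a), seed=0)
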