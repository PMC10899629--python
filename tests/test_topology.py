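import itertools
import math

import numpy as np
import pytest

from nervering import topology
from nervering.core import ConnectivityMatrix, Neuron, Roster
from nervering.errors import ValidationError


class TestVulnerability:
    def test_endpoints(self):
        rng = np.random.default_rng(0)
        adj = rng.random((12, 12)) < 0.3
        np.fill_diagonal(adj, False)
        curve = topology.vulnerability(adj, reps=5, seed=1)
        assert len(curve.n_components) == adj.sum() + 1
        assert curve.n_components[-1] == 12
        assert curve.largest_size[-1] == 1

    def test_three_node_path_exact_expected_curve(self):
        # edges A->B and B->C; both removal orders give the same curve:
        # 1 component/size 3, then 2 components/size 2, then 3 singletons
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 2] = True
        curve = topology.vulnerability(adj, reps=50, seed=2)
        np.testing.assert_allclose(curve.n_components, [1, 2, 3])
        np.testing.assert_allclose(curve.largest_size, [3, 2, 1])

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        adj = rng.random((15, 15)) < 0.2
        np.fill_diagonal(adj, False)
        a = topology.vulnerability(adj, reps=10, seed=7)
        b = topology.vulnerability(adj, reps=10, seed=7)
        np.testing.assert_array_equal(a.n_components, b.n_components)
        np.testing.assert_array_equal(a.largest_size, b.largest_size)

    def test_component_count_non_decreasing(self):
        rng = np.random.default_rng(4)
        adj = rng.random((10, 10)) < 0.25
        np.fill_diagonal(adj, False)
        curve = topology.vulnerability(adj, reps=1, seed=0)
        assert (np.diff(curve.n_components) >= 0).all()
        assert (np.diff(curve.n_components) <= 1).all()
        assert (np.diff(curve.largest_size) <= 0).all()


def matrix_from_edges(names, edges, pairs=None):
    roster = Roster([Neuron(n, "inter", (pairs or {}).get(n)) for n in names])
    W = np.zeros((len(names), len(names)))
    for a, b, w in edges:
        W[roster.index(a), roster.index(b)] = w
    return ConnectivityMatrix(roster, W)


class TestCollapseLR:
    def test_all_singletons_identity(self):
        m = matrix_from_edges("ABC", [("A", "B", 2.0), ("B", "C", 1.0)])
        merged = topology.collapse_lr(m)
        np.testing.assert_array_equal(merged.W, m.W)

    def test_pair_weights_sum(self):
        m = matrix_from_edges(
            ["AL", "AR", "X"],
            [("AL", "X", 2.0), ("AR", "X", 3.0)],
            pairs={"AL": "A", "AR": "A"},
        )
        merged = topology.collapse_lr(m)
        a = merged.roster.index("A")
        x = merged.roster.index("X")
        assert merged.W[a, x] == 5.0

    def test_conserves_total_weight(self, default_ensemble):
        m = default_ensemble["dauer"]
        merged = topology.collapse_lr(m)
        assert len(merged.roster) == 97
        assert merged.W.sum() == pytest.approx(m.W.sum())

    def test_collapse_commutes_with_binarization(self, rng):
        names = ["AL", "AR", "BL", "BR", "C"]
        pairs = {"AL": "A", "AR": "A", "BL": "B", "BR": "B"}
        for _ in range(5):
            W = (rng.random((5, 5)) < 0.4) * rng.random((5, 5))
            np.fill_diagonal(W, 0)
            roster = Roster([Neuron(n, "inter", pairs.get(n)) for n in names])
            m = ConnectivityMatrix(roster, W)
            merged = topology.collapse_lr(m)
            np.testing.assert_array_equal(
                merged.binarize(exclude_autapses=False), merged.W > 0
            )

    def test_bad_pair_map_rejected(self):
        m = matrix_from_edges("AB", [("A", "B", 1.0)])
        with pytest.raises(ValidationError):
            topology.collapse_lr(m, {"G": ["A"]})  # B missing


def clique_edges(names):
    return [(a, b, 1.0) for a in names for b in names if a != b]


class TestDetectModules:
    def test_two_disconnected_cliques(self):
        """CNM must find the two 5-cliques; the oracle is exhaustive
        modularity maximization over all bipartitions of the 10 nodes."""
        names = list("ABCDEFGHIJ")
        edges = clique_edges(names[:5]) + clique_edges(names[5:])
        m = matrix_from_edges(names, edges)
        part = topology.detect_modules(m)
        got = {frozenset(mod) for mod in part.modules}
        assert got == {frozenset(names[:5]), frozenset(names[5:])}
        # exhaustive oracle: no bipartition beats the reported modularity
        import networkx as nx

        U = (m.W + m.W.T) > 0
        G = nx.from_numpy_array(U)
        best = -1.0
        for size in range(1, 6):
            for combo in itertools.combinations(range(10), size):
                partition = [set(combo), set(range(10)) - set(combo)]
                best = max(best, nx.community.modularity(G, partition))
        assert part.modularity == pytest.approx(best)

    def test_single_clique_single_module(self):
        names = list("ABCDE")
        m = matrix_from_edges(names, clique_edges(names))
        part = topology.detect_modules(m)
        assert len(part.modules) == 1 and part.modules[0] == set(names)

    def test_edgeless_graph_no_modules(self):
        m = matrix_from_edges("ABC", [])
        assert topology.detect_modules(m).modules == []

    def test_ring_of_planted_cliques(self, rng):
        """Four 6-cliques joined by single bridges are recovered exactly."""
        names = [f"N{i}" for i in range(24)]
        edges = []
        for c in range(4):
            edges += clique_edges(names[6 * c:6 * c + 6])
        for c in range(4):  # sparse ring bridges
            edges.append((names[6 * c], names[(6 * c + 6) % 24], 1.0))
        m = matrix_from_edges(names, edges)
        part = topology.detect_modules(m)
        expected = {frozenset(names[6 * c:6 * c + 6]) for c in range(4)}
        assert {frozenset(mod) for mod in part.modules} == expected

    def test_beats_trivial_partition(self):
        names = list("ABCDEFGH")
        edges = clique_edges(names[:4]) + clique_edges(names[4:])
        m = matrix_from_edges(names, edges)
        part = topology.detect_modules(m)
        # one-module partition has modularity 0
        assert part.modularity > 0.0


class TestModuleSimilarity:
    def test_identical(self):
        assert topology.module_similarity({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert topology.module_similarity({"a"}, {"b"}) == 0.0

    def test_partial_overlap(self):
        assert topology.module_similarity({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_both_empty_undefined(self):
        assert math.isnan(topology.module_similarity(set(), set()))


class TestDetectHubs:
    def test_empty_network_threshold_zero(self):
        adj = np.zeros((6, 6), dtype=bool)
        adj[0, 1] = True  # p stays ~0.03; give one neuron out-degree 1
        report = topology.detect_hubs(adj, list("ABCDEF"), reps=50, seed=0)
        assert report.threshold < 1.0
        assert report.hubs == ["A"]

    def test_complete_digraph_no_hubs(self):
        adj = np.ones((8, 8), dtype=bool)
        np.fill_diagonal(adj, False)
        report = topology.detect_hubs(adj, reps=20, seed=0)
        assert report.threshold == pytest.approx(7.0)
        assert report.hubs == []

    def test_threshold_matches_binomial_maximum_oracle(self):
        """The ER threshold is E[max of n iid Binomial(n-1, p)]; check the
        100-rep estimate against a large Monte-Carlo oracle."""
        rng = np.random.default_rng(99)
        n, p = 40, 0.2
        adj = rng.random((n, n)) < p
        np.fill_diagonal(adj, False)
        p_hat = adj.sum() / (n * (n - 1))
        oracle = rng.binomial(n - 1, p_hat, size=(20000, n)).max(axis=1)
        se = oracle.std() / math.sqrt(100)  # SE of a 100-rep mean
        report = topology.detect_hubs(adj, reps=100, seed=1)
        assert abs(report.threshold - oracle.mean()) < 3 * se
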