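import itertools
import math

import numpy as np
import pytest

import oracles
from vocnet import semantic_network as sn
from vocnet.io_datasets import FeatureNormsLexicon


def net_from_edges(nodes, edges):
    return sn.SemanticNetwork(nodes=frozenset(nodes), edges=frozenset(edges))


TOY_LEXICON = FeatureNormsLexicon(
    {"w1": ["f1", "f2", "f3"], "w2": ["f1", "f2"], "w3": ["f3"]}
)


class TestBuildNetwork:
    def test_two_shared_features_required_by_default(self):
        net = sn.build_network({"w1", "w2", "w3"}, TOY_LEXICON)
        assert net.edges == {("w1", "w2")}
        assert net.nodes == {"w1", "w2", "w3"}  # isolates kept

    def test_threshold_one_admits_single_overlaps(self):
        net = sn.build_network({"w1", "w2", "w3"}, TOY_LEXICON, min_shared=1)
        assert net.edges == {("w1", "w2"), ("w1", "w3")}

    def test_single_word_yields_one_node_no_edges(self):
        net = sn.build_network({"w1"}, TOY_LEXICON)
        assert (net.n, net.n_edges) == (1, 0)

    def test_unknown_words_dropped_empty_network_valid(self):
        net = sn.build_network({"zzz", "yyy"}, TOY_LEXICON)
        assert net.n == 0

    def test_threshold_monotonicity_on_random_lexicons(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            words = [f"w{i}" for i in range(10)]
            lex = FeatureNormsLexicon(
                {
                    w: [f"f{j}" for j in rng.choice(12, size=rng.integers(1, 6), replace=False)]
                    for w in words
                }
            )
            edges_by_m = [
                sn.build_network(words, lex, min_shared=m).edges for m in (1, 2, 3)
            ]
            assert edges_by_m[2] <= edges_by_m[1] <= edges_by_m[0]


class TestWorkedExample:
    """The four-node, five-edge noun network used as the standard example."""

    def test_edge_reconstruction(self, worked_example_network):
        assert worked_example_network.edges == {
            ("apple", "eye"),
            ("apple", "ball"),
            ("ball", "eye"),
            ("balloon", "eye"),
            ("ball", "balloon"),
        }

    def test_metric_values(self, worked_example_network):
        m = sn.compute_all_metrics(worked_example_network)
        assert m.mpl == pytest.approx(7 / 6)
        assert m.gcc == pytest.approx(5 / 6)
        assert m.mean_degree == pytest.approx(2.5)
        assert m.mean_betweenness == pytest.approx(0.25)
        assert m.mean_harmonic == pytest.approx(11 / 12)

    def test_node_level_values(self, worked_example_network):
        net = worked_example_network
        assert sn.degree(net, "eye") == 3
        assert sn.local_clustering(net, "eye") == pytest.approx(2 / 3)
        assert sn.distance(net, "apple", "balloon") == 2

    def test_transitivity_variant_differs(self, worked_example_network):
        assert sn.global_clustering(
            worked_example_network, "transitivity"
        ) == pytest.approx(0.75)


class TestSmallGraphConventions:
    @pytest.mark.parametrize(
        "nodes,edges,expect",
        [
            # triangle: all pairs adjacent
            ("abc", [("a", "b"), ("b", "c"), ("a", "c")], dict(mpl=1.0, gcc=1.0, bc=0.0)),
            # path a-b-c: distances 1,1,2; b carries the single a-c pair
            ("abc", [("a", "b"), ("b", "c")], dict(mpl=4 / 3, gcc=0.0, bc=1 / 3)),
        ],
    )
    def test_tiny_graphs(self, nodes, edges, expect):
        net = net_from_edges(nodes, edges)
        assert sn.mean_path_length(net) == pytest.approx(expect["mpl"])
        assert sn.global_clustering(net) == pytest.approx(expect["gcc"])
        assert sn.mean_betweenness(net) == pytest.approx(expect["bc"])

    def test_complete_graph_k4_zero_betweenness_unit_harmonic(self):
        net = net_from_edges("abcd", list(itertools.combinations("abcd", 2)))
        assert sn.mean_betweenness(net) == 0.0
        assert sn.mean_harmonic_centrality(net) == pytest.approx(1.0)

    def test_star_mean_degree(self):
        net = net_from_edges("hxyz", [("h", "x"), ("h", "y"), ("h", "z")])
        assert sn.mean_degree(net) == pytest.approx(1.5)

    def test_isolated_nodes_zero_harmonic(self):
        net = net_from_edges("abc", [])
        assert sn.mean_harmonic_centrality(net) == 0.0

    @pytest.mark.parametrize("nodes,edges", [((), ()), (("a",), ())])
    def test_degenerate_networks_all_zero_with_flags(self, nodes, edges):
        m = sn.compute_all_metrics(net_from_edges(nodes, edges))
        assert (m.mpl, m.gcc, m.mean_degree, m.mean_betweenness, m.mean_harmonic) == (
            0, 0, 0, 0, 0,
        )
        assert m.quality_flags

    def test_self_loops_rejected(self):
        with pytest.raises(ValueError):
            net_from_edges("ab", [("a", "a")])


def random_graphs(n_graphs=200, max_n=12, seed=1234):
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_n + 1))
        p = rng.choice([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
        nodes = [f"v{i:02d}" for i in range(n)]
        edges = [
            (u, v) for u, v in itertools.combinations(nodes, 2) if rng.random() < p
        ]
        yield nodes, edges


def assert_matches_bruteforce(nodes, edges, tol=1e-9):
    net = net_from_edges(nodes, edges)
    adj = oracles.adjacency(nodes, edges)
    m = sn.compute_all_metrics(net)
    assert m.mpl == pytest.approx(oracles.mean_path_length(adj), abs=tol)
    assert m.gcc == pytest.approx(oracles.mean_local_clustering(adj), abs=tol)
    assert m.mean_degree == pytest.approx(oracles.mean_degree(adj), abs=tol)
    assert m.mean_betweenness == pytest.approx(oracles.mean_betweenness(adj), abs=tol)
    assert m.mean_harmonic == pytest.approx(oracles.mean_harmonic(adj), abs=tol)
    assert sn.global_clustering(net, "transitivity") == pytest.approx(
        oracles.transitivity(adj), abs=tol
    )


class TestOracleEquivalence:
    def test_metrics_match_bruteforce_on_random_graphs(self):
        for nodes, edges in random_graphs():
            assert_matches_bruteforce(nodes, edges)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        for nodes, edges in random_graphs(n_graphs=20, seed=77):
            perm = dict(zip(nodes, rng.permutation(nodes)))
            renamed = [(perm[u], perm[v]) for u, v in edges]
            m1 = sn.compute_all_metrics(net_from_edges(nodes, edges))
            m2 = sn.compute_all_metrics(net_from_edges(list(perm.values()), renamed))
            assert m1.as_dict() == pytest.approx(m2.as_dict())


class TestMonotonicityAndBounds:
    def test_adding_edge_raises_md_and_never_raises_mpl_on_connected_pairs(self):
        nodes = "abcde"
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
        net = net_from_edges(nodes, edges)
        base_dists = {
            (u, v): sn.distance(net, u, v)
            for u, v in itertools.combinations(nodes, 2)
            if math.isfinite(sn.distance(net, u, v))
        }
        bigger = net_from_edges(nodes, edges + [("a", "e")])
        assert sn.mean_degree(bigger) > sn.mean_degree(net)
        for (u, v), d in base_dists.items():
            assert sn.distance(bigger, u, v) <= d

    def test_bounds_on_random_graphs(self):
        for nodes, edges in random_graphs(n_graphs=40, seed=5):
            net = net_from_edges(nodes, edges)
            m = sn.compute_all_metrics(net)
            assert 0.0 <= m.gcc <= 1.0
            assert 0.0 <= m.mean_harmonic <= 1.0
            assert 0.0 <= m.mean_degree <= net.n - 1
            if net.n_edges:
                assert m.mpl >= 1.0
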