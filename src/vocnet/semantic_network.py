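"""Noun-feature networks and their five structure measures.

A child's lexico-semantic network has one node per produced noun found in
the feature-norms lexicon, and an undirected edge between two nouns that
share at least ``min_shared`` (default 2) discrete semantic features. Five
summary measures describe the network:

MPL
    mean shortest-path length over connected (finite-distance) node pairs;
GCC
    global clustering coefficient, taken as the *mean of per-node local
    clustering coefficients* with degree<2 nodes contributing 0 (a
    transitivity-ratio variant is available via ``variant="transitivity"``);
MD
    mean degree, ``2|E|/n``;
mean BC
    mean unnormalized betweenness centrality (endpoints excluded, each
    unordered pair counted once, fractional credit over tied shortest paths);
mean HC
    mean harmonic centrality, the sum of inverse distances to the other
    ``n-1`` nodes divided by ``n-1`` (unreachable nodes contribute 0).

Degenerate networks (empty, singleton, or with no connected pair) return
all-zero metrics together with a quality flag, so downstream models always
receive numbers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from vocnet.io_datasets import DatasetBundle, FeatureNormsLexicon

logger = logging.getLogger(__name__)

__all__ = [
    "SemanticNetwork",
    "NetworkMetrics",
    "build_network",
    "mean_path_length",
    "global_clustering",
    "mean_degree",
    "mean_betweenness",
    "mean_harmonic_centrality",
    "compute_all_metrics",
    "degree",
    "local_clustering",
    "distance",
    "metrics_table",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("MPL", "GCC", "MD", "meanBC", "meanHC")


@dataclass(frozen=True)
class SemanticNetwork:
    """An undirected, simple graph over word identifiers."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self):
        canon = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) references a missing node")
            canon.add((u, v) if u <= v else (v, u))
        object.__setattr__(self, "edges", frozenset(canon))

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def build_network(
    produced_words,
    lexicon: FeatureNormsLexicon,
    min_shared: int = 2,
) -> SemanticNetwork:
    """Link produced nouns sharing at least ``min_shared`` semantic features.

    Words absent from the lexicon are silently dropped from the node set
    (they are non-nouns or unlisted items); an entirely empty intersection
    yields a valid empty network with a logged warning.
    """
    if min_shared < 1:
        raise ValueError(f"min_shared must be >= 1, got {min_shared}")
    words = set(produced_words)
    nodes = sorted(w for w in words if w in lexicon)
    if words and not nodes:
        logger.warning("none of %d produced words found in lexicon", len(words))
    feats = {w: lexicon.features(w) for w in nodes}
    edges = {
        (u, v)
        for u, v in itertools.combinations(nodes, 2)
        if len(feats[u] & feats[v]) >= min_shared
    }
    return SemanticNetwork(nodes=frozenset(nodes), edges=frozenset(edges))


def _all_finite_distances(g: nx.Graph) -> dict:
    return dict(nx.all_pairs_shortest_path_length(g))


def mean_path_length(net: SemanticNetwork) -> float:
    """Mean shortest-path distance over unordered connected node pairs.

    Pairs in different components are excluded; a network with no connected
    pair (including the empty network) returns 0 by convention.
    """
    g = net.to_networkx()
    total = 0
    count = 0
    for u, dists in _all_finite_distances(g).items():
        for v, d in dists.items():
            if u < v:
                total += d
                count += 1
    return total / count if count else 0.0


def global_clustering(net: SemanticNetwork, variant: str = "mean-local") -> float:
    """Global clustering coefficient.

    ``"mean-local"`` (default) averages per-node local clustering over all
    nodes, with nodes of degree < 2 contributing 0; ``"transitivity"``
    returns 3 x triangles / connected triples. Both are 0 for an edgeless
    network.
    """
    g = net.to_networkx()
    if g.number_of_nodes() == 0:
        return 0.0
    if variant == "mean-local":
        return float(nx.average_clustering(g, count_zeros=True))
    if variant == "transitivity":
        return float(nx.transitivity(g))
    raise ValueError(f"unknown GCC variant {variant!r}")


def mean_degree(net: SemanticNetwork) -> float:
    """Average degree, ``2|E|/n``; 0 for the empty network."""
    return 2.0 * net.n_edges / net.n if net.n else 0.0


def mean_betweenness(net: SemanticNetwork, normalized: bool = False) -> float:
    """Mean betweenness centrality over all nodes.

    Unnormalized by default: each node's value is the sum over unordered
    pairs of other nodes of the fraction of shortest paths between them that
    pass through the node. ``normalized=True`` divides each node's value by
    ``(n-1)(n-2)/2``.
    """
    if net.n == 0:
        return 0.0
    bc = nx.betweenness_centrality(net.to_networkx(), normalized=normalized)
    return float(sum(bc.values()) / len(bc))


def mean_harmonic_centrality(net: SemanticNetwork) -> float:
    """Mean of per-node harmonic centralities, each normalized by ``n-1``.

    A node's harmonic centrality is the sum of reciprocal shortest-path
    distances to every other node (0 for unreachable nodes); dividing by
    ``n-1`` puts it in [0, 1]. Networks with fewer than 2 nodes return 0.
    """
    if net.n < 2:
        return 0.0
    hc = nx.harmonic_centrality(net.to_networkx())
    return float(sum(hc.values()) / (len(hc) * (net.n - 1)))


def degree(net: SemanticNetwork, node: str) -> int:
    return int(net.to_networkx().degree[node])


def local_clustering(net: SemanticNetwork, node: str) -> float:
    return float(nx.clustering(net.to_networkx(), node))


def distance(net: SemanticNetwork, u: str, v: str) -> float:
    """Shortest-path length between two nodes; ``inf`` if unreachable."""
    try:
        return float(nx.shortest_path_length(net.to_networkx(), u, v))
    except nx.NetworkXNoPath:
        return float("inf")


@dataclass(frozen=True)
class NetworkMetrics:
    """The five structure summaries plus size and quality metadata."""

    mpl: float
    gcc: float
    mean_degree: float
    mean_betweenness: float
    mean_harmonic: float
    n_nodes: int
    n_edges: int
    quality_flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "MPL": self.mpl,
            "GCC": self.gcc,
            "MD": self.mean_degree,
            "meanBC": self.mean_betweenness,
            "meanHC": self.mean_harmonic,
        }


def compute_all_metrics(
    net: SemanticNetwork,
    gcc_variant: str = "mean-local",
    bc_normalized: bool = False,
) -> NetworkMetrics:
    """Compute the five measures in one pass over shared shortest paths."""
    flags: list[str] = []
    n = net.n
    if n == 0:
        flags.append("empty")
    elif n == 1:
        flags.append("singleton")
    if n < 2 or net.n_edges == 0:
        if n >= 1 and net.n_edges == 0 and n > 1:
            flags.append("edgeless")
        return NetworkMetrics(0.0, 0.0, 0.0, 0.0, 0.0, n, net.n_edges, tuple(flags))

    g = net.to_networkx()
    dists = _all_finite_distances(g)
    total = 0
    count = 0
    inv_sum = 0.0
    for u, du in dists.items():
        for v, d in du.items():
            if u == v:
                continue
            inv_sum += 1.0 / d
            if u < v:
                total += d
                count += 1
    mpl = total / count if count else 0.0
    if not count:
        flags.append("no_connected_pairs")
    if not nx.is_connected(g):
        flags.append("disconnected")
    mean_hc = inv_sum / (n * (n - 1))
    return NetworkMetrics(
        mpl=mpl,
        gcc=global_clustering(net, gcc_variant),
        mean_degree=mean_degree(net),
        mean_betweenness=mean_betweenness(net, bc_normalized),
        mean_harmonic=mean_hc,
        n_nodes=n,
        n_edges=net.n_edges,
        quality_flags=tuple(flags),
    )


def metrics_table(
    bundle: DatasetBundle,
    min_shared: int = 2,
    gcc_variant: str = "mean-local",
    bc_normalized: bool = False,
) -> pd.DataFrame:
    """Per-child network metrics for every record in a bundle.

    Returns one row per (child_id, age_months) with the five measures, node
    and edge counts, and semicolon-joined quality flags.
    """
    rows = []
    for rec in bundle.records:
        net = build_network(rec.produced_words, bundle.lexicon, min_shared)
        m = compute_all_metrics(net, gcc_variant, bc_normalized)
        row = {
            "child_id": rec.child_id,
            "age_months": rec.age_months,
            "age_band": rec.age_band,
            "n_nodes": m.n_nodes,
            "n_edges": m.n_edges,
            **m.as_dict(),
            "quality_flags": ";".join(m.quality_flags),
        }
        rows.append(row)
    return pd.DataFrame(rows)
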