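"""Brute-force graph-metric oracles, independent of the package internals.

Everything here works on a plain adjacency dict {node: set(neighbours)} and
uses only BFS and exhaustive path enumeration, so it can cross-check the
networkx-backed implementations without sharing any code path with them.
Intended for graphs with at most ~12 nodes.
"""

from collections import deque
from itertools import combinations


def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def all_shortest_paths(adj, s, t):
    """Every shortest s-t path, by BFS-layer backtracking."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def back(node, path):
        if node == s:
            paths.append([s] + path[::-1])
            return
        for w in adj[node]:
            if dist.get(w, -1) == dist[node] - 1:
                back(w, path + [node])

    back(t, [])
    return paths


def mean_path_length(adj):
    total = count = 0
    for u in adj:
        for v, d in bfs_distances(adj, u).items():
            if u < v:
                total += d
                count += 1
    return total / count if count else 0.0


def local_clustering(adj, v):
    nbrs = list(adj[v])
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(1 for a, b in combinations(nbrs, 2) if b in adj[a])
    return links / (k * (k - 1) / 2)


def mean_local_clustering(adj):
    if not adj:
        return 0.0
    return sum(local_clustering(adj, v) for v in adj) / len(adj)


def transitivity(adj):
    triangles = 0
    triples = 0
    for v in adj:
        k = len(adj[v])
        triples += k * (k - 1) // 2
        triangles += sum(1 for a, b in combinations(adj[v], 2) if b in adj[a])
    return triangles / triples if triples else 0.0


def mean_degree(adj):
    if not adj:
        return 0.0
    return sum(len(adj[v]) for v in adj) / len(adj)


def betweenness(adj):
    """Unnormalized betweenness: per node, sum over unordered pairs of other
    nodes of (shortest paths through it) / (all shortest paths)."""
    bc = {v: 0.0 for v in adj}
    for s, t in combinations(sorted(adj), 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in adj:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            bc[v] += through / len(paths)
    return bc


def mean_betweenness(adj):
    if not adj:
        return 0.0
    bc = betweenness(adj)
    return sum(bc.values()) / len(bc)


def mean_harmonic(adj):
    n = len(adj)
    if n < 2:
        return 0.0
    total = 0.0
    for v in adj:
        dv = bfs_distances(adj, v)
        total += sum(1.0 / d for u, d in dv.items() if u != v) / (n - 1)
    return total / n
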