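"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths of the package (and of the graph
library's centrality/shortest-path algorithms): betweenness is computed by
explicit enumeration of every geodesic, and shortest-path orders by
repeated matrix powers of the adjacency matrix (a pair is a neighbor of
order l when l is the smallest power with a nonzero walk count).
"""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx
import numpy as np


def bfs_distances(g: nx.Graph, s):
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in g[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def enumerate_geodesics(g: nx.Graph, s, t) -> list[list]:
    """All shortest s-t paths, by DFS along the BFS layering."""
    dist = bfs_distances(g, s)
    if t not in dist:
        return []
    out: list[list] = []

    def dfs(node, path):
        if node == t:
            out.append(list(path))
            return
        for v in g[node]:
            if dist.get(v) == len(path):
                path.append(v)
                dfs(v, path)
                path.pop()

    dfs(s, [s])
    return [p for p in out if len(p) - 1 == dist[t]]


def betweenness_oracle(g: nx.Graph) -> dict[tuple, float]:
    """Edge betweenness by exhaustive geodesic enumeration.

    Fractional splitting over co-minimal geodesics; normalized by
    N(N-1)/2.  Only feasible for tiny graphs.
    """
    n = g.number_of_nodes()
    npairs = n * (n - 1) / 2
    b = {tuple(sorted(e)): 0.0 for e in g.edges()}
    for s, t in itertools.combinations(sorted(g.nodes()), 2):
        paths = enumerate_geodesics(g, s, t)
        if not paths:
            continue
        w = 1.0 / len(paths)
        for path in paths:
            for u, v in zip(path, path[1:]):
                b[tuple(sorted((u, v)))] += w
    return {e: v / npairs for e, v in b.items()}


def neighborhood_oracle(g: nx.Graph, nodelist) -> np.ndarray:
    """Shortest-path orders via matrix powers of the adjacency matrix.

    order(i, j) = smallest l >= 1 with (A^l)_ij > 0; 0 on the diagonal and
    for pairs with no connecting walk of any length.
    """
    a = (nx.to_numpy_array(g, nodelist=nodelist) > 0).astype(np.int64)
    n = a.shape[0]
    order = np.zeros((n, n), dtype=int)
    power = np.eye(n, dtype=np.int64)
    seen = np.eye(n, dtype=bool)
    for l in range(1, n):
        power = (power @ a > 0).astype(np.int64)
        new = (power > 0) & ~seen
        order[new] = l
        seen |= new
    return order


def congruence_Q_bruteforce(phi_sets: list[frozenset], psi_sets: list[frozenset]) -> int:
    """Max matched organisms over every many-to-one community map.

    The side with more communities is the source; every function from
    source communities to target communities is tried.
    """
    if len(phi_sets) >= len(psi_sets):
        source, target = phi_sets, psi_sets
    else:
        source, target = psi_sets, phi_sets
    best = 0
    for mapping in itertools.product(range(len(target)), repeat=len(source)):
        q = sum(
            len(src & target[mapping[i]]) for i, src in enumerate(source)
        )
        best = max(best, q)
    return best


def random_graph_suite(n_graphs: int, max_n: int = 8, seed: int = 0):
    """Seeded suite of small random graphs with string node labels."""
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_n + 1))
        p = float(rng.uniform(0.15, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes()})
        graphs.append(g)
    return graphs
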