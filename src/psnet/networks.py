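"""Threshold network families and standard graph measures.

A similarity matrix S defines, for each threshold sigma, an unweighted
simple graph with an edge (i, j) exactly when ``S_ij >= sigma`` (i != j).
Sweeping sigma over [0, 100] yields a nested family: raising the threshold
can only remove edges.  sigma = 0 gives the complete graph; no score can
reach 101, so sigma = 101 gives the edgeless graph.  Missing scores count
as similarity 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix

__all__ = [
    "ThresholdNetwork",
    "MeasureSet",
    "build_network",
    "largest_component_size",
    "network_measures",
    "measures_table",
]


@dataclass
class ThresholdNetwork:
    """An unweighted simple graph over labeled nodes, at threshold `sigma`.

    Isolated nodes are kept: the node set is always the full label set.
    `sigma` is None for graphs not derived from a similarity matrix
    (e.g. sampled random graphs).
    """

    graph: nx.Graph
    sigma: float | None = None

    @property
    def labels(self) -> list[str]:
        return list(self.graph.nodes())

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        return self.graph.edges()

    def adjacency(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=self.labels, dtype=float)

    @classmethod
    def from_edges(cls, labels, edges, sigma=None) -> "ThresholdNetwork":
        g = nx.Graph()
        g.add_nodes_from(labels)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            g.add_edge(u, v)
        return cls(g, sigma=sigma)


def build_network(S: SimilarityMatrix, sigma: float) -> ThresholdNetwork:
    """Threshold a symmetrized similarity matrix at `sigma`.

    Requires min-symmetrized input; raises otherwise.  Valid sigma range is
    [0, 101]: 0 yields the complete graph, 101 the edgeless one.
    """
    if not S.symmetric:
        raise ValueError("similarity matrix must be symmetrized first")
    if not 0 <= sigma <= 101:
        raise ValueError(f"sigma {sigma} outside [0, 101]")
    vals = S.dense(missing=0.0)
    np.fill_diagonal(vals, -1.0)  # the diagonal never places edges
    i, j = np.nonzero(np.triu(vals >= sigma, k=1))
    labels = S.labels
    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from((labels[a], labels[b]) for a, b in zip(i, j))
    return ThresholdNetwork(g, sigma=sigma)


def largest_component_size(net: ThresholdNetwork) -> int:
    """Size N_c of the largest connected component (1 for edgeless graphs)."""
    if net.n == 0:
        raise ValueError("empty node set")
    return max(len(c) for c in nx.connected_components(net.graph))


@dataclass
class MeasureSet:
    """Standard scalar and distributional measures of one network."""

    n: int
    n_edges: int
    mean_degree: float
    degree_distribution: dict[int, float]
    node_clustering: dict[str, float]
    clustering: float
    clustering_by_degree: dict[int, float]
    mean_shortest_path: float
    n_connected_pairs: int
    diameter: int
    largest_component: int

    def to_row(self) -> dict[str, float]:
        return {
            "N": self.n,
            "L": self.n_edges,
            "mean_degree": self.mean_degree,
            "C": self.clustering,
            "mean_d": self.mean_shortest_path,
            "D": self.diameter,
            "N_c": self.largest_component,
        }


def network_measures(net: ThresholdNetwork) -> MeasureSet:
    """Compute the full measure set for one network.

    Mean shortest path and diameter are taken over connected node pairs
    only (distances between components are ill-defined); the number of
    connected pairs is reported alongside.  Nodes of degree < 2 get
    clustering coefficient 0.
    """
    from .neighborhood import neighborhood_matrix

    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty node set")
    degrees = dict(g.degree())
    mean_degree = 2 * g.number_of_edges() / n
    p_k: dict[int, float] = {}
    for k in degrees.values():
        p_k[k] = p_k.get(k, 0.0) + 1.0 / n
    c_i = nx.clustering(g)  # 0 for degree < 2
    clustering = sum(c_i.values()) / n
    c_by_k: dict[int, float] = {}
    for k in sorted(set(degrees.values())):
        nodes = [v for v, kv in degrees.items() if kv == k]
        c_by_k[k] = sum(c_i[v] for v in nodes) / len(nodes)

    nbm = neighborhood_matrix(net)
    d = nbm.entries
    off = ~np.eye(n, dtype=bool)
    connected = off & (d > 0)
    n_pairs = int(connected.sum()) // 2
    mean_d = float(d[connected].mean()) if n_pairs else float("nan")
    return MeasureSet(
        n=n,
        n_edges=g.number_of_edges(),
        mean_degree=mean_degree,
        degree_distribution=p_k,
        node_clustering=dict(c_i),
        clustering=clustering,
        clustering_by_degree=c_by_k,
        mean_shortest_path=mean_d,
        n_connected_pairs=n_pairs,
        diameter=nbm.diameter,
        largest_component=largest_component_size(net),
    )


def measures_table(S: SimilarityMatrix, sigmas) -> pd.DataFrame:
    """One row of scalar measures per threshold, for the sweep export."""
    rows = []
    for sigma in sigmas:
        m = network_measures(build_network(S, sigma)).to_row()
        rows.append({"sigma": sigma, **m})
    return pd.DataFrame(rows)
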