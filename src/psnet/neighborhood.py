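"""Neighborhood matrices and the inter-network distance delta.

Two nodes are neighbors of order l when the shortest path between them has
l edges.  Collecting all orders gives the neighborhood matrix M-hat, whose
(i, j) entry is the shortest-path order d(i, j), with 0 on the diagonal and
— by convention, to sidestep the indeterminacy of distances across
components — 0 for disconnected pairs.  The largest finite entry is the
diameter D.

The distance between two networks alpha and beta on the same labeled node
set is the mean absolute difference of their diameter-normalized
neighborhood matrices:

    delta(alpha, beta) = (1/N^2) * sum_ij | d_a(i,j)/D(a) - d_b(i,j)/D(b) |

summed over all N^2 ordered pairs (the diagonal contributes 0).  An
edgeless network has D = 0 and its normalized entries are defined as 0.
Sharp peaks of delta along a parameter sweep mark abrupt topological
change; that is what the critical-threshold scan consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .networks import ThresholdNetwork

__all__ = ["NeighborhoodMatrix", "neighborhood_matrix", "delta"]


@dataclass
class NeighborhoodMatrix:
    """Integer matrix of shortest-path orders for one network."""

    labels: list[str]
    entries: np.ndarray  # int, symmetric, zero diagonal, 0 = disconnected

    def __post_init__(self) -> None:
        e = np.asarray(self.entries)
        n = len(self.labels)
        if e.shape != (n, n):
            raise ValueError("entries shape does not match labels")
        self.entries = e.astype(int)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def diameter(self) -> int:
        """Largest finite shortest-path order (0 for an edgeless graph)."""
        return int(self.entries.max()) if self.entries.size else 0

    def normalized(self) -> np.ndarray:
        """Entries divided by the diameter (all zeros when D = 0)."""
        d = self.diameter
        if d == 0:
            return np.zeros_like(self.entries, dtype=float)
        return self.entries / d

    def permute(self, order: Sequence[str]) -> "NeighborhoodMatrix":
        """Reorder rows/columns to `order` (e.g. a dendrogram leaf order)."""
        if sorted(order) != sorted(self.labels):
            raise ValueError("order must be a permutation of the labels")
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = [pos[l] for l in order]
        return NeighborhoodMatrix(list(order), self.entries[np.ix_(idx, idx)])


def neighborhood_matrix(net: ThresholdNetwork) -> NeighborhoodMatrix:
    """All-pairs shortest-path orders of `net` (BFS; 0 where disconnected)."""
    n = net.n
    if n == 0:
        return NeighborhoodMatrix([], np.zeros((0, 0), dtype=int))
    adj = csr_array(net.adjacency())
    d = shortest_path(adj, method="D", unweighted=True, directed=False)
    d[np.isinf(d)] = 0
    return NeighborhoodMatrix(net.labels, d.astype(int))


def delta(a: NeighborhoodMatrix, b: NeighborhoodMatrix) -> float:
    """Distance between two same-labeled networks' neighborhood matrices.

    Both matrices must carry the same labels in the same order (the
    pipeline always compares networks built over one dataset, so no node
    re-enumeration search is needed).  Non-negative, zero on identical
    normalized entries, symmetric in its arguments.
    """
    if a.labels != b.labels:
        raise ValueError("neighborhood matrices have mismatched labels/order")
    n = a.n
    if n == 0:
        return 0.0
    return float(np.abs(a.normalized() - b.normalized()).sum() / (n * n))
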