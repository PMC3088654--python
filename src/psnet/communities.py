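"""Edge-betweenness community decomposition (Newman-Girvan) with a full
removal trace.

The betweenness b_ij of an edge is the fraction of the N(N-1)/2 node-pair
geodesics that pass through it (geodesic multiplicity splits fractionally;
disconnected pairs contribute nothing).  The decomposition repeatedly
recomputes betweenness and removes the single edge with the largest value
until no edge remains, recording the removal order and every step at which
a component splits in two.  The result is a dendrogram: one branch per
component at r = 0, and N single-node communities at r = L.

Two quantities guide the choice of a partition from the trace: the network
distance delta(m, m+1) between the graphs after m and m+1 removals, whose
peaks mark branching events far more sharply than the modularity function
Q, and Q itself as the classical comparator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .networks import ThresholdNetwork
from .neighborhood import NeighborhoodMatrix, delta as _delta, neighborhood_matrix
from .scan import DeltaProfile

__all__ = [
    "UNASSIGNED",
    "Partition",
    "SplitEvent",
    "Dendrogram",
    "edge_betweenness",
    "gn_decompose",
    "delta_removal_profile",
    "modularity_Q",
    "partition_at",
    "choose_partition",
    "leaf_order",
]

#: community id of nodes in components below the minimum community size
UNASSIGNED = -1

_TIE_TOL = 1e-12


@dataclass
class Partition:
    """A node -> community-id assignment (id ``UNASSIGNED`` = -1 allowed)."""

    assignment: dict[str, int]

    @property
    def n(self) -> int:
        return len(self.assignment)

    @property
    def community_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def members(self, community: int) -> frozenset[str]:
        return frozenset(n for n, c in self.assignment.items() if c == community)

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.assignment.values():
            out[c] = out.get(c, 0) + 1
        return out

    def as_sets(self, include_unassigned: bool = True) -> list[frozenset[str]]:
        ids = self.community_ids
        if not include_unassigned:
            ids = [c for c in ids if c != UNASSIGNED]
        return [self.members(c) for c in ids]

    def restrict(self, nodes) -> "Partition":
        nodes = set(nodes)
        return Partition({n: c for n, c in self.assignment.items() if n in nodes})

    def relabel_canonical(self) -> "Partition":
        """Renumber communities 1..k in order of first appearance (keeps -1)."""
        mapping: dict[int, int] = {}
        out: dict[str, int] = {}
        for node, c in self.assignment.items():
            if c == UNASSIGNED:
                out[node] = UNASSIGNED
                continue
            if c not in mapping:
                mapping[c] = len(mapping) + 1
            out[node] = mapping[c]
        return Partition(out)

    def equivalent(self, other: "Partition") -> bool:
        """Same grouping up to community renaming (unassigned kept apart)."""
        if set(self.assignment) != set(other.assignment):
            return False
        a = {frozenset(s) for s in self.as_sets(include_unassigned=False)}
        b = {frozenset(s) for s in other.as_sets(include_unassigned=False)}
        mine = {n for n, c in self.assignment.items() if c == UNASSIGNED}
        theirs = {n for n, c in other.assignment.items() if c == UNASSIGNED}
        return a == b and mine == theirs


@dataclass(frozen=True)
class SplitEvent:
    """A removal step at which one component split into two."""

    step: int  # r, 1-based removal index
    side_a: frozenset[str]
    side_b: frozenset[str]

    @property
    def parent(self) -> frozenset[str]:
        return self.side_a | self.side_b


@dataclass
class Dendrogram:
    """Removal trace of a Newman-Girvan decomposition."""

    labels: list[str]
    edges: list[tuple[str, str]]  # original edge set, canonical order
    removal_trace: list[tuple[str, str]]  # edge removed at step r = index+1
    split_events: list[SplitEvent]

    @property
    def n_removals(self) -> int:
        return len(self.removal_trace)

    def components_at(self, r: int) -> list[frozenset[str]]:
        """Connected components after the first `r` removals."""
        if not 0 <= r <= self.n_removals:
            raise ValueError(f"r must be in [0, {self.n_removals}]")
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.edges)
        g.remove_edges_from(self.removal_trace[:r])
        return [frozenset(c) for c in nx.connected_components(g)]

    # -- tree structure -------------------------------------------------

    def _split_of(self) -> dict[frozenset[str], SplitEvent]:
        return {ev.parent: ev for ev in self.split_events}

    def roots(self) -> list[frozenset[str]]:
        """Components at r = 0, ordered by smallest contained label."""
        return sorted(self.components_at(0), key=min)

    def leaf_order(self) -> list[str]:
        """Crossing-free drawing order of the nodes.

        Every community at every recorded split is contiguous in this
        permutation.  Deterministic: children (and roots) are visited in
        order of their smallest contained label.
        """
        split_of = self._split_of()
        order: list[str] = []

        def visit(group: frozenset[str]) -> None:
            if len(group) == 1:
                order.extend(group)
                return
            ev = split_of.get(group)
            if ev is None:  # never split: emit members sorted by label
                order.extend(sorted(group))
                return
            for side in sorted((ev.side_a, ev.side_b), key=min):
                visit(side)

        for root in self.roots():
            visit(root)
        return order

    def newick(self) -> str:
        """Newick text; internal nodes are labeled with the split step r."""
        split_of = self._split_of()

        def render(group: frozenset[str]) -> str:
            if len(group) == 1:
                return next(iter(group))
            ev = split_of.get(group)
            if ev is None:
                return "(" + ",".join(sorted(group)) + ")"
            kids = sorted((ev.side_a, ev.side_b), key=min)
            return "(" + ",".join(render(k) for k in kids) + f"){ev.step}"
        roots = self.roots()
        if len(roots) == 1:
            return render(roots[0]) + ";"
        return "(" + ",".join(render(r) for r in roots) + ");"


def edge_betweenness(net: ThresholdNetwork) -> dict[tuple[str, str], float]:
    """Betweenness b_ij of every edge.

    b_ij is the number of geodesics through (i, j) — co-minimal geodesics
    counted fractionally — divided by N(N-1)/2.  Keys are label pairs
    sorted ascending.
    """
    b = nx.edge_betweenness_centrality(net.graph, normalized=True)
    return {tuple(sorted((u, v))): float(val) for (u, v), val in b.items()}


def _max_betweenness_edge(g: nx.Graph) -> tuple[str, str]:
    b = nx.edge_betweenness_centrality(g, normalized=True)
    bmax = max(b.values())
    candidates = [
        tuple(sorted((u, v))) for (u, v), val in b.items() if val >= bmax - _TIE_TOL
    ]
    return min(candidates)


def gn_decompose(net: ThresholdNetwork) -> Dendrogram:
    """Full Newman-Girvan decomposition of `net`.

    One edge is removed per iteration, with betweenness recomputed on the
    current graph each time; ties go to the lexicographically smallest
    (min-label, max-label) pair, which makes the trace reproducible.
    """
    g = net.graph.copy()
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    trace: list[tuple[str, str]] = []
    splits: list[SplitEvent] = []
    step = 0
    while g.number_of_edges() > 0:
        u, v = _max_betweenness_edge(g)
        g.remove_edge(u, v)
        step += 1
        trace.append((u, v))
        if not nx.has_path(g, u, v):
            side_u = frozenset(nx.node_connected_component(g, u))
            side_v = frozenset(nx.node_connected_component(g, v))
            a, b = sorted((side_u, side_v), key=min)
            splits.append(SplitEvent(step, a, b))
    return Dendrogram(list(net.labels), edges, trace, splits)


def delta_removal_profile(
    dendrogram: Dendrogram, net: ThresholdNetwork
) -> DeltaProfile:
    """delta(m, m+1) between the graphs after m and m+1 removals.

    Peaks of this profile flag the branching events of the dendrogram.
    """
    if not dendrogram.removal_trace:
        raise ValueError("removal trace is empty")
    g = net.graph.copy()
    prev = neighborhood_matrix(ThresholdNetwork(g))
    params = []
    deltas = []
    for m, edge in enumerate(dendrogram.removal_trace):
        g.remove_edge(*edge)
        cur = neighborhood_matrix(ThresholdNetwork(g))
        params.append(m)
        deltas.append(_delta(prev, cur))
        prev = cur
    return DeltaProfile(np.asarray(params, dtype=float), np.asarray(deltas), 1.0)


def modularity_Q(net: ThresholdNetwork, partition: Partition) -> float:
    """Newman-Girvan modularity Q = sum_c (e_cc - a_c^2).

    e_cc is the fraction of edges with both ends in community c and a_c the
    fraction of edge endpoints in c.  Every node of the network must be
    assigned; each UNASSIGNED node counts as its own singleton community.
    Undefined (raises) for edgeless networks.
    """
    L = net.n_edges
    if L == 0:
        raise ValueError("modularity undefined for an edgeless network")
    missing = set(net.labels) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    comm = dict(partition.assignment)
    fresh = itertools.count(start=min(comm.values(), default=0) - 1, step=-1)
    for node, c in comm.items():
        if c == UNASSIGNED:
            comm[node] = next(fresh)
    e: dict[int, float] = {}
    a: dict[int, float] = {}
    for u, v in net.edges():
        cu, cv = comm[u], comm[v]
        a[cu] = a.get(cu, 0.0) + 1.0
        a[cv] = a.get(cv, 0.0) + 1.0
        if cu == cv:
            e[cu] = e.get(cu, 0.0) + 1.0
    q = 0.0
    for c, deg in a.items():
        q += e.get(c, 0.0) / L - (deg / (2.0 * L)) ** 2
    return q


def _components_to_partition(
    components: Sequence[frozenset[str]], min_community_size: int = 1
) -> Partition:
    """Number components 1..k by smallest label; small ones -> UNASSIGNED."""
    assignment: dict[str, int] = {}
    next_id = 1
    for comp in sorted(components, key=min):
        if len(comp) < min_community_size:
            for node in comp:
                assignment[node] = UNASSIGNED
        else:
            for node in comp:
                assignment[node] = next_id
            next_id += 1
    return Partition(dict(sorted(assignment.items())))


def partition_at(
    dendrogram: Dendrogram, r: int, min_community_size: int = 1
) -> Partition:
    """Partition into connected components after `r` removals.

    Components are numbered 1..k in order of their smallest label;
    components below `min_community_size` are labeled UNASSIGNED (the
    isolated nodes and small sub-graphs that do not constitute a
    community of their own).
    """
    return _components_to_partition(dendrogram.components_at(r), min_community_size)


def choose_partition(
    dendrogram: Dendrogram,
    net: ThresholdNetwork,
    rule: str = "delta_peak",
    min_community_size: int = 5,
    profile: DeltaProfile | None = None,
) -> Partition:
    """Select a partition from the removal trace.

    rule = "delta_peak" (default)
        Candidate cuts are the intact graph (r = 0) and the partitions
        just after each peak of the delta(m, m+1) removal profile (the
        branching events); among the candidates the one with the largest
        modularity Q is returned.  delta locates the branchings far more
        sharply than Q does, but a single peak magnitude does not rank
        nested splits — an early large detachment can out-peak the later
        split that completes the module structure — so Q arbitrates among
        the delta-flagged cuts only.
    rule = "max_modularity"
        Classical comparator: the partition maximizing Q over all r.

    `profile` may pass a precomputed removal profile to avoid recomputing.
    Components smaller than `min_community_size` are labeled UNASSIGNED.
    """
    L = dendrogram.n_removals
    if L == 0:
        return partition_at(dendrogram, 0, min_community_size)
    if rule == "delta_peak":
        if profile is None:
            profile = delta_removal_profile(dendrogram, net)
        candidates = [0] + [int(m) + 1 for m in profile.peaks]
        if np.any(profile.deltas > 0):
            # the largest step overall is a branching candidate even when
            # it sits at the start of the trace (bridge removals do)
            candidates.append(int(profile.params[int(np.argmax(profile.deltas))]) + 1)
        best_r, best_q = None, -np.inf
        for r in sorted(set(candidates)):
            q = modularity_Q(net, partition_at(dendrogram, r))
            if q > best_q + _TIE_TOL:
                best_r, best_q = r, q
        return partition_at(dendrogram, best_r, min_community_size)
    if rule == "max_modularity":
        best_r, best_q = 0, -np.inf
        for r in range(L + 1):
            q = modularity_Q(net, partition_at(dendrogram, r))
            if q > best_q + _TIE_TOL:
                best_r, best_q = r, q
        return partition_at(dendrogram, best_r, min_community_size)
    raise ValueError(f"unknown rule: {rule!r}")


def leaf_order(dendrogram: Dendrogram) -> list[str]:
    """Module-level alias of :meth:`Dendrogram.leaf_order`."""
    return dendrogram.leaf_order()
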