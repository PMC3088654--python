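"""Synthetic fixtures with known ground truth.

Two generators:

* planted-partition similarity matrices — blocks of sequences with high
  within-block and low between-block similarity plus truncated-normal
  noise, optionally with isoforms (near-duplicate sequences of one
  organism's protein, scoring ~100 with their original).  These emulate
  the modular structure a protein-family similarity matrix shows when the
  organisms fall into well-separated clades.
* Erdos-Renyi G(N, p) graphs for calibrating the delta profile and the
  largest-component curve against the classical percolation picture:
  a giant component emerges near p_cr ~ 1/N, where its size scales as
  N^(2/3).

Both are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .communities import Partition
from .neighborhood import delta as _delta, neighborhood_matrix
from .networks import ThresholdNetwork, largest_component_size
from .scan import DeltaProfile
from .similarity import OrganismTable, SimilarityMatrix

__all__ = [
    "PlantedSpec",
    "ERSpec",
    "planted_similarity",
    "er_graph",
    "er_delta_sweep",
    "ERSweepResult",
]


@dataclass
class PlantedSpec:
    """Parameters of a planted-partition similarity matrix.

    sizes
        Nodes per block (one entry per block).
    mu_in, mu_out
        Mean percent similarity within / between blocks; 0 <= mu_out <
        mu_in <= 100 is required for the blocks to be recoverable.
    sd
        Noise standard deviation (scores are clipped to [0, 100]).
    isoform_rate
        Expected number of extra near-copies per organism (Poisson);
        isoforms share the organism id and score ~100 with each other.
    """

    sizes: tuple[int, ...] = (10, 10, 10)
    mu_in: float = 75.0
    mu_out: float = 25.0
    sd: float = 3.0
    isoform_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.sizes = tuple(int(s) for s in self.sizes)
        if any(s < 1 for s in self.sizes):
            raise ValueError("block sizes must be >= 1")
        if not (0 <= self.mu_out < self.mu_in <= 100):
            raise ValueError("need 0 <= mu_out < mu_in <= 100")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.isoform_rate < 0:
            raise ValueError("isoform_rate must be >= 0")


def planted_similarity(
    spec: PlantedSpec,
) -> tuple[SimilarityMatrix, Partition, OrganismTable]:
    """Generate a planted-partition matrix with its ground truth.

    Returns the symmetric similarity matrix, the true block partition of
    all sequences (isoforms inherit their original's block), and an
    organism table in which isoforms share their original's organism.
    """
    rng = np.random.default_rng(spec.seed)
    block_of: list[int] = []
    organisms: list[str] = []
    labels: list[str] = []
    for b, size in enumerate(spec.sizes, start=1):
        for i in range(size):
            org = f"org_b{b}_{i:03d}"
            labels.append(f"seq_b{b}_{i:03d}")
            organisms.append(org)
            block_of.append(b)
            n_iso = rng.poisson(spec.isoform_rate)
            for k in range(int(n_iso)):
                labels.append(f"seq_b{b}_{i:03d}_iso{k + 1}")
                organisms.append(org)
                block_of.append(b)
    n = len(labels)
    same_org = np.equal.outer(organisms, organisms)
    same_block = np.equal.outer(block_of, block_of)
    mu = np.where(same_block, spec.mu_in, spec.mu_out)
    mu = np.where(same_org, 100.0, mu)
    noise = rng.normal(0.0, spec.sd, size=(n, n))
    noise = np.triu(noise, k=1)
    values = np.clip(mu + noise + noise.T, 0.0, 100.0)
    values = np.triu(values, k=1) + np.triu(values, k=1).T
    np.fill_diagonal(values, 100.0)
    S = SimilarityMatrix(
        labels, values, organism_of=dict(zip(labels, organisms)), symmetric=True
    )
    truth = Partition(dict(zip(labels, block_of)))
    table = OrganismTable([(l, o, ()) for l, o in zip(labels, organisms)])
    return S, truth, table


@dataclass
class ERSpec:
    """An Erdos-Renyi G(N, p) sample: N nodes, independent edges w.p. p."""

    n: int
    p: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def er_graph(spec: ERSpec) -> ThresholdNetwork:
    """Sample one G(N, p) graph (nodes labeled v000, v001, ...)."""
    rng = np.random.default_rng(spec.seed)
    labels = [f"v{i:03d}" for i in range(spec.n)]
    u = rng.random((spec.n, spec.n))
    i, j = np.nonzero(np.triu(u <= spec.p, k=1))
    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from((labels[a], labels[b]) for a, b in zip(i, j))
    return ThresholdNetwork(g)


@dataclass
class ERSweepResult:
    """Averaged delta profile and largest-component curve over G(N, p)."""

    p_grid: np.ndarray  # len m
    delta_samples: np.ndarray  # (reps, m - 1): delta(p_k, p_{k+1}) per sample
    nc_samples: np.ndarray  # (reps, m): N_c(p_k) per sample

    @property
    def delta_mean(self) -> np.ndarray:
        return self.delta_samples.mean(axis=0)

    @property
    def nc_mean(self) -> np.ndarray:
        return self.nc_samples.mean(axis=0)

    def mean_profile(self) -> DeltaProfile:
        """Averaged delta(p, p + dp) as a DeltaProfile over the lower p."""
        step = float(self.p_grid[1] - self.p_grid[0])
        return DeltaProfile(self.p_grid[:-1], self.delta_mean, step)


def er_delta_sweep(
    n: int,
    p_grid=None,
    reps: int = 10,
    seed: int = 0,
) -> ERSweepResult:
    """delta and N_c along a p sweep of G(N, p), averaged over samples.

    Within one sample the graphs along the grid are coupled through a
    single uniform weight per node pair (edge present at p iff its weight
    is <= p), so consecutive graphs are nested exactly as in the
    similarity-threshold construction and delta(p, p + dp) measures the
    topological change caused by the added edges.  The default grid is 26
    evenly spaced points on [0, 5/N], covering the percolation window
    around p_cr ~ 1/N.
    """
    if p_grid is None:
        p_grid = np.linspace(0.0, 5.0 / n, 26)
    p_grid = np.asarray(p_grid, dtype=float)
    if np.any(p_grid < 0) or np.any(p_grid > 1):
        raise ValueError("p_grid must lie in [0, 1]")
    if len(p_grid) < 2 or not np.all(np.diff(p_grid) > 0):
        raise ValueError("p_grid must be increasing with >= 2 points")
    rng = np.random.default_rng(seed)
    labels = [f"v{i:03d}" for i in range(n)]
    m = len(p_grid)
    delta_samples = np.empty((reps, m - 1))
    nc_samples = np.empty((reps, m))
    for rep in range(reps):
        u = rng.random((n, n))
        u = np.triu(u, k=1) + np.triu(u, k=1).T
        np.fill_diagonal(u, np.inf)
        prev = None
        for k, p in enumerate(p_grid):
            i, j = np.nonzero(np.triu(u <= p, k=1))
            g = nx.Graph()
            g.add_nodes_from(labels)
            g.add_edges_from((labels[a], labels[b]) for a, b in zip(i, j))
            net = ThresholdNetwork(g)
            nc_samples[rep, k] = largest_component_size(net)
            cur = neighborhood_matrix(net)
            if prev is not None:
                delta_samples[rep, k - 1] = _delta(prev, cur)
            prev = cur
    return ERSweepResult(p_grid, delta_samples, nc_samples)
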