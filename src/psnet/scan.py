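"""Critical-threshold scan: the delta(sigma, sigma + step) profile.

Raising the similarity threshold removes edges; most removals barely move
shortest-path structure, but at a few thresholds the topology changes
abruptly (a module detaches, the giant component breaks up).  Plotting the
network distance delta between consecutive thresholds exposes those events
as sharp peaks.  The network at the largest peak — the critical network —
is where the modular structure is best separated and is the one handed to
community decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .neighborhood import delta as _delta
from .neighborhood import neighborhood_matrix
from .networks import ThresholdNetwork, build_network
from .similarity import SimilarityMatrix

__all__ = [
    "DeltaProfile",
    "find_peaks",
    "delta_profile",
    "select_critical_network",
    "critical_networks",
]


def find_peaks(params: Sequence[float], deltas: Sequence[float]):
    """Locate local maxima of a profile.

    A peak is an interior point (or plateau of equal values) strictly
    greater than both flanking values; a plateau reports its smallest
    parameter.  Grid endpoints are never peaks.  The global peak is the
    peak of largest delta (ties: smallest parameter); with no interior
    peaks but a nonzero profile it falls back to the overall argmax, and
    on an all-zero profile it is None.

    Returns ``(peaks, global_peak)``.
    """
    params = np.asarray(params, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    if params.ndim != 1 or params.shape != deltas.shape:
        raise ValueError("params and deltas must be equal-length 1-D")
    if len(params) >= 2 and not np.all(np.diff(params) > 0):
        raise ValueError("params must be strictly increasing")
    n = len(params)
    peaks: list[float] = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and deltas[j + 1] == deltas[i]:
            j += 1
        # plateau params[i..j]; interior iff it does not touch either end
        if j < n - 1 and deltas[i] > deltas[i - 1] and deltas[i] > deltas[j + 1]:
            peaks.append(float(params[i]))
        i = j + 1
    if not np.any(deltas > 0):
        return peaks, None
    if peaks:
        vals = {p: float(deltas[np.searchsorted(params, p)]) for p in peaks}
        best = max(vals.values())
        global_peak = min(p for p, v in vals.items() if v == best)
    else:
        global_peak = float(params[int(np.argmax(deltas))])
    return peaks, global_peak


@dataclass
class DeltaProfile:
    """An ordered (parameter, delta) profile with detected peaks.

    The parameter is a similarity threshold sigma in the critical scan, an
    edge-removal count m in the decomposition trace, or an attachment
    probability p for random-graph calibration.
    """

    params: np.ndarray
    deltas: np.ndarray
    step: float
    peaks: list[float] = field(init=False)
    global_peak: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.deltas = np.asarray(self.deltas, dtype=float)
        if np.any(self.deltas < 0):
            raise ValueError("delta values must be non-negative")
        self.peaks, self.global_peak = find_peaks(self.params, self.deltas)

    def __len__(self) -> int:
        return len(self.params)

    def to_rows(self):
        """(param, delta, is_peak) rows for TSV export."""
        peakset = set(self.peaks)
        return [
            (float(p), float(d), p in peakset)
            for p, d in zip(self.params, self.deltas)
        ]


def delta_profile(
    S: SimilarityMatrix,
    sigma_min: float = 0,
    sigma_max: float = 100,
    step: float = 1,
) -> DeltaProfile:
    """delta between networks at consecutive thresholds over a sigma grid.

    The grid runs from `sigma_min` to `sigma_max` inclusive; the point at
    sigma compares the networks at sigma and sigma + step (so networks up
    to sigma_max + step are built).  Defaults: integer thresholds 0..100,
    step 1 percentage point.  Each neighborhood matrix is computed once.
    """
    if not S.symmetric:
        raise ValueError("similarity matrix must be symmetrized first")
    if step <= 0:
        raise ValueError("step must be positive")
    if sigma_min >= sigma_max:
        raise ValueError("sigma_min must be < sigma_max")
    grid = np.arange(sigma_min, sigma_max + step / 2, step)
    deltas = np.empty(len(grid))
    prev = neighborhood_matrix(build_network(S, grid[0]))
    for i, sigma in enumerate(grid):
        nxt = neighborhood_matrix(build_network(S, min(sigma + step, 101.0)))
        deltas[i] = _delta(prev, nxt)
        prev = nxt
    return DeltaProfile(grid, deltas, step)


def select_critical_network(S: SimilarityMatrix, profile: DeltaProfile) -> ThresholdNetwork:
    """The network at the profile's global peak sigma_max."""
    if profile.global_peak is None:
        raise ValueError("profile has no peak (all-zero delta)")
    return build_network(S, profile.global_peak)


def critical_networks(S: SimilarityMatrix, profile: DeltaProfile) -> dict[float, ThresholdNetwork]:
    """Networks at every detected peak sigma_cr, keyed by threshold."""
    return {p: build_network(S, p) for p in profile.peaks}
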