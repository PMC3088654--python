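"""Thin plotting layer: delta profiles and neighborhood-matrix heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .neighborhood import NeighborhoodMatrix
from .scan import DeltaProfile

__all__ = ["plot_profile", "plot_neighborhood_heatmap"]


def plot_profile(profile: DeltaProfile, path: str, xlabel: str = "sigma") -> None:
    """Line plot of delta versus the sweep parameter, with peaks marked."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(profile.params, profile.deltas, lw=1.2, color="#1f4e79")
    if profile.peaks:
        peakset = set(profile.peaks)
        px = [p for p in profile.params if p in peakset]
        py = [profile.deltas[list(profile.params).index(p)] for p in px]
        ax.plot(px, py, "rv", ms=6, label="peaks")
        ax.legend(frameon=False)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(r"$\delta$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_neighborhood_heatmap(
    nbm: NeighborhoodMatrix, path: str, order=None
) -> None:
    """Color plot of the neighborhood matrix.

    Entries 1..D run through a blue-to-red ramp (immediate neighbors blue,
    farthest pairs red); off-diagonal zeros — disconnected pairs — are
    gray, so detached communities stand out as gray-separated blocks.
    Pass a dendrogram leaf order as `order` to make modules contiguous.
    """
    if order is not None:
        nbm = nbm.permute(order)
    d = nbm.diameter
    entries = nbm.entries.astype(float)
    masked = np.ma.masked_where(entries == 0, entries)
    ramp = plt.get_cmap("jet", max(d, 1))
    cmap = ListedColormap(ramp(np.linspace(0, 1, max(d, 1))))
    cmap.set_bad("#bbbbbb")
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(masked, cmap=cmap, vmin=0.5, vmax=d + 0.5, interpolation="nearest")
    if d >= 1:
        fig.colorbar(im, ax=ax, ticks=range(1, d + 1), label="d(i, j)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
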