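"""Similarity matrices and organism metadata.

The central object is :class:`SimilarityMatrix`: a square, labeled matrix of
pairwise similarity scores in ``[0, 100]`` (BLAST percent identity in the
typical use), possibly asymmetric as read from raw alignment output.  All
downstream network construction requires the min-symmetrized form
``S_ij = min(S_ij, S_ji)``.

Missing pairs (no alignment hit in either direction) are stored as NaN and
behave as similarity 0 when networks are built: absence of detectable
similarity never creates an edge at any threshold >= 1.  The diagonal is
stored as 100 (self similarity) but is never used to place edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["SimilarityMatrix", "OrganismTable", "filter_min_organisms"]


def _check_labels(labels: Sequence[str]) -> list[str]:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate labels: {dupes}")
    for l in labels:
        if "\t" in l or "\n" in l:
            raise ValueError(f"label contains tab/newline: {l!r}")
    return labels


@dataclass
class SimilarityMatrix:
    """Labeled n x n similarity scores with optional organism mapping.

    Parameters
    ----------
    labels
        Ordered, unique sequence identifiers.
    values
        Square float array; NaN marks a missing (unobserved) pair.  Present
        scores must lie in ``[0, 100]``.  The diagonal is forced to 100.
    organism_of
        Optional map from sequence label to organism name.
    symmetric
        Whether min-symmetrization has been applied.
    """

    labels: list[str]
    values: np.ndarray
    organism_of: dict[str, str] | None = None
    symmetric: bool = False
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        v = np.asarray(self.values, dtype=float).copy()
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} != ({n}, {n})")
        finite = v[~np.isnan(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("similarity scores must lie in [0, 100]")
        if n:
            np.fill_diagonal(v, 100.0)
        if self.symmetric:
            off = ~np.eye(n, dtype=bool)
            a, b = v[off], v.T[off]
            same = (a == b) | (np.isnan(a) & np.isnan(b))
            if not np.all(same):
                raise ValueError("symmetric=True but values are not symmetric")
        self.values = v
        self._index = {l: i for i, l in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def symmetrize(self) -> "SimilarityMatrix":
        """Return the min-symmetrized matrix: ``S_ij = min(S_ij, S_ji)``.

        A pair missing in either direction stays missing (NaN); downstream
        it counts as similarity 0.  Idempotent.
        """
        v = np.minimum(self.values, self.values.T)  # NaN propagates
        return SimilarityMatrix(
            list(self.labels), v, organism_of=self.organism_of, symmetric=True
        )

    def dense(self, missing: float = 0.0) -> np.ndarray:
        """Values with NaN replaced by `missing` (default 0)."""
        return np.where(np.isnan(self.values), missing, self.values)

    def permute(self, order: Sequence[str]) -> "SimilarityMatrix":
        """Reorder rows and columns to `order` (a permutation of labels)."""
        if sorted(order) != sorted(self.labels):
            raise ValueError("order must be a permutation of the labels")
        idx = [self._index[l] for l in order]
        return SimilarityMatrix(
            list(order),
            self.values[np.ix_(idx, idx)],
            organism_of=self.organism_of,
            symmetric=self.symmetric,
        )


@dataclass
class OrganismTable:
    """Rows of (sequence_id, organism, taxonomy path)."""

    rows: list[tuple[str, str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        norm = []
        for row in self.rows:
            seq_id, organism = row[0], row[1]
            taxonomy = tuple(row[2]) if len(row) > 2 and row[2] else ()
            if seq_id in seen:
                raise ValueError(f"duplicate sequence_id: {seq_id}")
            seen.add(seq_id)
            norm.append((seq_id, organism, taxonomy))
        self.rows = norm

    @property
    def organism_of(self) -> dict[str, str]:
        return {seq: org for seq, org, _ in self.rows}

    @property
    def organisms(self) -> list[str]:
        out: list[str] = []
        for _, org, _ in self.rows:
            if org not in out:
                out.append(org)
        return out

    def taxonomy_of(self, seq_id: str) -> tuple[str, ...]:
        for seq, _, tax in self.rows:
            if seq == seq_id:
                return tax
        raise KeyError(seq_id)


def filter_min_organisms(
    table: OrganismTable,
    per_protein_groups: Mapping[str, Iterable[str]],
    threshold: int,
) -> set[str]:
    """Retain proteins present in strictly more than `threshold` organisms.

    `per_protein_groups` maps a protein name to the sequence ids annotated
    with it; the distinct-organism count of those sequences must exceed
    `threshold` (strict inequality) for the protein to be retained.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    org = table.organism_of
    kept: set[str] = set()
    for protein, seq_ids in per_protein_groups.items():
        orgs = set()
        for s in seq_ids:
            if s not in org:
                raise KeyError(f"sequence id {s!r} not in organism table")
            orgs.add(org[s])
        if len(orgs) > threshold:
            kept.add(protein)
    return kept
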