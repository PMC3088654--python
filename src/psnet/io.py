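"""Readers and writers for the external formats the pipeline touches.

Supported formats
-----------------
* BLAST tabular hits (12-column ``-outfmt 6`` convention) -> raw
  :class:`~psnet.similarity.SimilarityMatrix`
* square similarity matrix TSV (labels in first row and column, empty cell
  = missing)
* organism map TSV (sequence_id, organism, semicolon-joined taxonomy)
* Pajek ``.net`` network export
* newick dendrogram export (internal nodes labeled with the removal step)
* partition TSV (node_id, community_id)

All files are UTF-8; labels may not contain tabs or newlines.
"""

from __future__ import annotations

import io as _io
from os import PathLike
from typing import IO, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .similarity import OrganismTable, SimilarityMatrix

__all__ = [
    "read_blast_tabular",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_organism_tsv",
    "write_organism_tsv",
    "write_pajek",
    "write_newick",
    "read_partition_tsv",
    "write_partition_tsv",
]

PathOrIO = Union[str, "PathLike[str]", IO[str]]

#: column layout of BLAST tabular output (-outfmt 6)
BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def _opened(f: PathOrIO, mode: str):
    if hasattr(f, "read") or hasattr(f, "write"):
        return f, False
    return open(f, mode, encoding="utf-8"), True


def read_blast_tabular(
    source: PathOrIO | Iterable[str], score_field: str = "percent_identity"
) -> SimilarityMatrix:
    """Build a raw (possibly asymmetric) similarity matrix from BLAST hits.

    Each line must have 12 tab- or whitespace-separated columns following the
    tabular convention (query, subject, percent identity, ...).  The matrix
    entry (query, subject) is the percent identity of the retained HSP; when
    a pair produced several HSPs the one with the highest bitscore is kept
    (ties: first occurrence).  Labels are the union of query and subject ids
    in order of first appearance; unobserved pairs are missing.
    """
    if score_field != "percent_identity":
        raise ValueError(f"unsupported score_field: {score_field!r}")
    if isinstance(source, (str, PathLike)):
        handle, close = _opened(source, "r")
        lines: Iterable[str] = handle
    else:
        handle, close = None, False
        lines = source

    labels: list[str] = []
    seen: dict[str, int] = {}
    best: dict[tuple[str, str], tuple[float, float]] = {}  # (q,s) -> (bitscore, pident)
    try:
        for lineno, line in enumerate(lines, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 12:
                raise ValueError(
                    f"line {lineno}: expected 12 BLAST tabular columns, got {len(parts)}"
                )
            q, s = parts[0], parts[1]
            try:
                pident = float(parts[2])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: unparseable numeric field") from exc
            if not 0.0 <= pident <= 100.0:
                raise ValueError(
                    f"line {lineno}: percent identity {pident} outside [0, 100]"
                )
            for ident in (q, s):
                if ident not in seen:
                    seen[ident] = len(labels)
                    labels.append(ident)
            key = (q, s)
            if key not in best or bitscore > best[key][0]:
                best[key] = (bitscore, pident)
    finally:
        if close:
            handle.close()

    n = len(labels)
    values = np.full((n, n), np.nan)
    for (q, s), (_, pident) in best.items():
        values[seen[q], seen[s]] = pident
    return SimilarityMatrix(labels, values, symmetric=False)


def read_matrix_tsv(f: PathOrIO, symmetric: bool = False) -> SimilarityMatrix:
    """Read a labeled square matrix TSV (empty cell = missing pair)."""
    df = pd.read_csv(f, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if row_labels != col_labels:
        raise ValueError("matrix TSV row labels differ from column labels")
    vals = df.to_numpy()
    out = np.full(vals.shape, np.nan)
    nonempty = vals != ""
    out[nonempty] = vals[nonempty].astype(float)
    return SimilarityMatrix(row_labels, out, symmetric=symmetric)


def write_matrix_tsv(S: SimilarityMatrix, f: PathOrIO) -> None:
    """Write a matrix TSV; missing values become empty cells."""
    df = pd.DataFrame(S.values, index=S.labels, columns=S.labels)
    df.to_csv(f, sep="\t", na_rep="")


def read_organism_tsv(f: PathOrIO) -> OrganismTable:
    """Read (sequence_id, organism[, taxonomy]) rows; taxonomy is ';'-joined."""
    handle, close = _opened(f, "r")
    rows: list[tuple[str, str, tuple[str, ...]]] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected >= 2 tab-separated columns")
            tax = tuple(t for t in parts[2].split(";") if t) if len(parts) > 2 else ()
            rows.append((parts[0], parts[1], tax))
    finally:
        if close:
            handle.close()
    return OrganismTable(rows)


def write_organism_tsv(table: OrganismTable, f: PathOrIO) -> None:
    handle, close = _opened(f, "w")
    try:
        for seq, org, tax in table.rows:
            handle.write(f"{seq}\t{org}\t{';'.join(tax)}\n")
    finally:
        if close:
            handle.close()


def write_pajek(net, f: PathOrIO, community_of: Mapping[str, int] | None = None) -> None:
    """Write a network as a Pajek ``.net`` file (1-based vertex indices).

    `community_of`, if given, is written as the vertex partition attribute
    (third column of the vertex lines), which Pajek renders as node color.
    """
    labels = list(net.labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate node labels")
    idx = {l: i + 1 for i, l in enumerate(labels)}
    handle, close = _opened(f, "w")
    try:
        handle.write(f"*Vertices {len(labels)}\n")
        for l in labels:
            if community_of is not None:
                handle.write(f'{idx[l]} "{l}" {community_of[l]}\n')
            else:
                handle.write(f'{idx[l]} "{l}"\n')
        handle.write("*Edges\n")
        for u, v in net.edges():
            a, b = sorted((idx[u], idx[v]))
            handle.write(f"{a} {b}\n")
    finally:
        if close:
            handle.close()


def write_newick(dendrogram, f: PathOrIO) -> None:
    """Write a dendrogram in newick form (internal labels = split step r)."""
    handle, close = _opened(f, "w")
    try:
        handle.write(dendrogram.newick() + "\n")
    finally:
        if close:
            handle.close()


def read_partition_tsv(f: PathOrIO):
    """Read a (node_id, community_id) TSV into a Partition."""
    from .communities import Partition

    handle, close = _opened(f, "r")
    assignment: dict[str, int] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated columns")
            node, comm = parts
            if node in assignment:
                raise ValueError(f"line {lineno}: duplicate node id {node!r}")
            assignment[node] = int(comm)
    finally:
        if close:
            handle.close()
    return Partition(assignment)


def write_partition_tsv(partition, f: PathOrIO) -> None:
    handle, close = _opened(f, "w")
    try:
        for node, comm in partition.assignment.items():
            handle.write(f"{node}\t{comm}\n")
    finally:
        if close:
            handle.close()
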