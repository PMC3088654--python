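"""Congruence between classifications produced by different networks.

Different proteins give different similarity networks over overlapping
organism sets, and hence different classifications.  The congruence index
G(phi, psi) measures their agreement: count the R(phi, psi) organisms
present in both classifications, find the community correspondence that
maximizes the number Q(phi, psi) of organisms placed in corresponding
communities, and report G = Q / R.  When the two classifications have
different numbers of communities the correspondence maps the finer side
many-to-one into the coarser, so a partition that merely refines the other
scores G = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import UNASSIGNED, Partition
from .similarity import OrganismTable

__all__ = [
    "CongruenceResult",
    "organism_partition",
    "congruence_index",
    "congruence_table",
    "upper_triangle_mean_pct",
]


@dataclass
class CongruenceResult:
    """R common organisms, Q best matches, G = Q/R, and the community map."""

    R: int
    Q: int
    G: float
    mapping: dict[int, int]  # community of the finer partition -> coarser


def organism_partition(p: Partition, table: OrganismTable) -> Partition:
    """Collapse a sequence-level partition to organism level.

    Each organism gets the community holding the majority of its assigned
    sequences (ties: smallest community id).  Organisms all of whose
    sequences are unassigned stay unassigned.  Every sequence node must
    have an organism record.
    """
    org_of = table.organism_of
    votes: dict[str, dict[int, int]] = {}
    for seq, comm in p.assignment.items():
        if seq not in org_of:
            raise KeyError(f"sequence {seq!r} has no organism record")
        org = org_of[seq]
        votes.setdefault(org, {})
        votes[org][comm] = votes[org].get(comm, 0) + 1
    out: dict[str, int] = {}
    for org, counts in votes.items():
        assigned = {c: k for c, k in counts.items() if c != UNASSIGNED}
        if not assigned:
            out[org] = UNASSIGNED
            continue
        top = max(assigned.values())
        out[org] = min(c for c, k in assigned.items() if k == top)
    return Partition(dict(sorted(out.items())))


def congruence_index(
    phi: Partition, psi: Partition, include_unassigned: bool = False
) -> CongruenceResult:
    """Congruence index G(phi, psi) between two organism partitions.

    The partitions may cover different organism sets; only the R organisms
    in both count.  The partition with more communities (restricted to the
    common organisms) is mapped many-to-one onto the other: each source
    community goes to the target community with which it shares the most
    organisms, and Q is the total shared count.  By default unassigned
    organisms are dropped from R, since the leftover class is not a
    community.  Raises when R = 0.
    """

    def eligible(p: Partition) -> set[str]:
        if include_unassigned:
            return set(p.assignment)
        return {o for o, c in p.assignment.items() if c != UNASSIGNED}

    common = eligible(phi) & eligible(psi)
    R = len(common)
    if R == 0:
        raise ValueError("no common organisms (R = 0); congruence undefined")
    a = phi.restrict(common)
    b = psi.restrict(common)
    # map the side with more communities into the other
    if len(a.community_ids) >= len(b.community_ids):
        source, target = a, b
    else:
        source, target = b, a
    target_members = {c: target.members(c) for c in target.community_ids}
    Q = 0
    mapping: dict[int, int] = {}
    for c in source.community_ids:
        members = source.members(c)
        overlaps = {
            t: len(members & tm) for t, tm in target_members.items()
        }
        best = max(overlaps.values())
        tgt = min(t for t, k in overlaps.items() if k == best)
        mapping[c] = tgt
        Q += best
    return CongruenceResult(R=R, Q=Q, G=Q / R, mapping=mapping)


def congruence_table(
    partitions: dict[str, Partition],
    table: OrganismTable | None = None,
    include_unassigned: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Pairwise G matrix for named classifications, plus the mean.

    `partitions` are sequence-level when an organism table is given (they
    are collapsed first) or organism-level otherwise.  Pairs with no
    common organisms are left missing and excluded from the mean, which is
    taken over the strictly-upper-triangle entries and reported as a
    percentage.
    """
    names = list(partitions)
    if len(names) < 2:
        raise ValueError("need at least 2 partitions")
    parts = {
        name: organism_partition(p, table) if table is not None else p
        for name, p in partitions.items()
    }
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            try:
                g = congruence_index(parts[x], parts[y], include_unassigned).G
            except ValueError:
                continue
            mat.loc[x, y] = g
            mat.loc[y, x] = g
    return mat, upper_triangle_mean_pct(mat)


def upper_triangle_mean_pct(mat: pd.DataFrame) -> float:
    """Mean of the strictly-upper-triangle entries, as a percentage.

    Missing entries are excluded.  This is the single summary number
    quoted for a table of pairwise congruence values.
    """
    vals = mat.to_numpy(dtype=float)
    iu = np.triu_indices(vals.shape[0], k=1)
    upper = vals[iu]
    upper = upper[~np.isnan(upper)]
    if upper.size == 0:
        raise ValueError("no defined pairwise entries")
    return float(upper.mean() * 100.0)
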