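"""Cluster-consistency analysis between two clustering solutions.

The degree of overlap between a gene cluster ``c_i`` from one solution
and ``c_j`` from another is

    d_ij = 100 * |c_i & c_j| / max(|c_i|, |c_j|),

i.e. 100 on identical clusters, 0 on disjoint ones. Full k_A x k_B
overlap matrices support heatmap-style comparison of two consensus
solutions, and concept-correspondence tables relate the disjoint blocks
of two concept lattices by their minimum per-group cluster overlap.
The adjusted Rand index is provided for partition-level agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from .containers import Partition
from .fca import FormalConcept, FormalContext, derive

__all__ = [
    "OverlapMatrix",
    "overlap_degree",
    "overlap_matrix",
    "concept_correspondence",
    "adjusted_rand",
]


def overlap_degree(c_i: set, c_j: set) -> float:
    """Percentage overlap of two non-empty gene clusters (0..100)."""
    c_i, c_j = set(c_i), set(c_j)
    if not c_i or not c_j:
        raise ValueError("overlap degree is undefined for empty clusters")
    return 100.0 * len(c_i & c_j) / max(len(c_i), len(c_j))


@dataclass
class OverlapMatrix:
    """Pairwise cluster overlap percentages between two solutions."""

    row_labels: list[str]
    col_labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("overlap matrix shape does not match its labels")
        if self.d.size and (self.d.min() < 0 or self.d.max() > 100):
            raise ValueError("overlap degrees must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.row_labels, columns=self.col_labels)


def overlap_matrix(part_a: Partition, part_b: Partition) -> OverlapMatrix:
    """Full k_A x k_B overlap matrix on the partitions' common genes.

    Both partitions are restricted to their gene intersection first; a
    cluster left empty by the restriction scores 0 against everything.
    """
    common = set(part_a.gene_ids) & set(part_b.gene_ids)
    if not common:
        raise ValueError("the partitions share no genes")
    sets_a = [s & common for s in part_a.as_sets()]
    sets_b = [s & common for s in part_b.as_sets()]
    d = np.zeros((part_a.k, part_b.k))
    for i, ca in enumerate(sets_a):
        for j, cb in enumerate(sets_b):
            d[i, j] = overlap_degree(ca, cb) if ca and cb else 0.0
    return OverlapMatrix(
        row_labels=[f"A{i}" for i in range(part_a.k)],
        col_labels=[f"B{j}" for j in range(part_b.k)],
        d=d,
    )


def _cluster_members_by_group(
    concept: FormalConcept, context: FormalContext
) -> dict[str, set[str]]:
    by_group: dict[str, set[str]] = {}
    attr = {a.global_id: a for a in context.attributes}
    for cid in concept.intent:
        a = attr[cid]
        by_group[a.group] = derive(context, clusters=[cid])
    return by_group


def concept_correspondence(
    concepts_a: list[FormalConcept],
    concepts_b: list[FormalConcept],
    min_overlap_pct: float = 20.0,
    context_a: FormalContext | None = None,
    context_b: FormalContext | None = None,
) -> list[tuple[int, int, float]]:
    """Correspondence table between two concept lists.

    With both contexts supplied, a concept pair is scored by the
    *minimum*, over the groups named in both intents, of the overlap
    degree between the groups' member clusters; without contexts, the
    own-extents of the concepts are compared directly. Pairs scoring
    below ``min_overlap_pct`` are omitted. Returns ``(index_a, index_b,
    pct)`` triples.
    """
    table: list[tuple[int, int, float]] = []
    use_contexts = context_a is not None and context_b is not None
    members_a = (
        [_cluster_members_by_group(c, context_a) for c in concepts_a] if use_contexts else None
    )
    members_b = (
        [_cluster_members_by_group(c, context_b) for c in concepts_b] if use_contexts else None
    )
    for i, ca in enumerate(concepts_a):
        for j, cb in enumerate(concepts_b):
            if use_contexts:
                shared_groups = set(members_a[i]) & set(members_b[j])
                if not shared_groups:
                    continue
                pct = min(
                    overlap_degree(members_a[i][g], members_b[j][g])
                    for g in sorted(shared_groups)
                )
            else:
                if ca.own_extent is None or cb.own_extent is None:
                    raise ValueError("concepts need own-extents (run compute_support)")
                if not ca.own_extent or not cb.own_extent:
                    continue
                pct = overlap_degree(ca.own_extent, cb.own_extent)
            if pct >= min_overlap_pct:
                table.append((i, j, pct))
    return table


def adjusted_rand(part_a: Partition, part_b: Partition) -> float:
    """Adjusted Rand index between two partitions of the same gene set.

    Chance-corrected pair-counting agreement: 1 iff the partitions are
    identical up to cluster relabelling; around 0 for independent ones.
    """
    if set(part_a.gene_ids) != set(part_b.gene_ids):
        raise ValueError("partitions must cover the same gene set")
    order = {g: i for i, g in enumerate(part_a.gene_ids)}
    la = np.asarray(part_a.labels)
    lb = np.empty_like(la)
    for g, l in zip(part_b.gene_ids, part_b.labels):
        lb[order[g]] = l
    n = la.size
    contingency = np.zeros((part_a.k, part_b.k), dtype=np.int64)
    np.add.at(contingency, (la, lb), 1)
    sum_comb = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))
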