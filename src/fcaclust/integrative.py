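"""Weighted aggregation of per-experiment partitions into a group consensus.

The Integrative engine works on one group of gene-intersected
experiments. Cluster centers are first initialized jointly by running
k-means on the column-wise concatenation of the group's matrices, which
fixes a shared cluster labelling; the concatenated centroids are split
back into per-experiment blocks that seed a k-means run on each
experiment. Each per-experiment partition is then relabelled (optimal
assignment on the k x k contingency table) to match the shared
labelling, experiments receive quality weights proportional to their
standardized-gene counts, and the aligned one-hot partitions are
averaged with those weights into a soft partition. Hard consensus
labels are the row-wise argmax; ties break toward the lowest cluster
index and are counted, since tied genes are precisely the ones whose
membership the downstream concept analysis keeps track of.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import ExpressionMatrix, Partition
from .partitioning import kpartition
from .preprocess import QualityWeights, compute_weights, standardize

__all__ = [
    "SoftPartition",
    "IntegrativeResult",
    "init_centers_concat",
    "align_partition",
    "aggregate",
    "harden",
    "integrative_consensus",
]

_TIE_RTOL = 1e-9


@dataclass
class SoftPartition:
    """Fractional cluster memberships; each gene row sums to 1."""

    gene_ids: list[str]
    membership: np.ndarray  # m x k

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=float)
        if self.membership.ndim != 2 or self.membership.shape[0] != len(self.gene_ids):
            raise ValueError("membership must be m x k with one row per gene")
        if np.any(self.membership < -1e-12):
            raise ValueError("memberships must be non-negative")
        sums = self.membership.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")

    @property
    def k(self) -> int:
        return self.membership.shape[1]


@dataclass
class IntegrativeResult:
    partition: Partition
    soft: SoftPartition
    weights: QualityWeights
    tie_genes: list[str] = field(default_factory=list)


def init_centers_concat(
    group: list[ExpressionMatrix], k: int, seed: int = 0, **kpartition_kwargs
) -> tuple[Partition, list[np.ndarray]]:
    """Joint center initialization on the concatenated group matrix.

    Returns the partition of the concatenated matrix (the shared
    labelling) and the per-experiment centroid blocks obtained by
    splitting the concatenated centroids at the experiments' column
    boundaries.
    """
    if not group:
        raise ValueError("group must contain at least one matrix")
    genes = group[0].gene_ids
    widths = []
    blocks_data = []
    for m in group:
        if m.gene_ids != genes:
            raise ValueError(
                "all matrices of the group must share the same gene set; "
                "run intersect_genes first"
            )
        widths.append(m.n_conditions)
        blocks_data.append(m.dense_values())
    concat_values = np.concatenate(blocks_data, axis=1)
    labels = [f"{m.name or i}:{c}" for i, m in enumerate(group) for c in m.condition_labels]
    concat = ExpressionMatrix(
        gene_ids=list(genes),
        condition_labels=labels,
        values=concat_values,
        name="concat",
    )
    part = kpartition(concat, k, method="mean", seed=seed, **kpartition_kwargs)
    splits = np.cumsum(widths)[:-1]
    blocks = [b.copy() for b in np.split(part.centroids, splits, axis=1)]
    return part, blocks


def align_partition(reference: Partition, other: Partition) -> Partition:
    """Relabel ``other`` to maximize label agreement with ``reference``.

    Solves the optimal assignment on the k x k contingency table, so the
    post-alignment agreement is the best achievable by any cluster
    relabelling and never below the original.
    """
    if reference.k != other.k:
        raise ValueError(f"partitions have different k ({reference.k} vs {other.k})")
    if reference.gene_ids != other.gene_ids:
        raise ValueError("partitions must cover the same gene set in the same order")
    k = reference.k
    contingency = np.zeros((k, k), dtype=int)
    np.add.at(contingency, (np.asarray(other.labels), np.asarray(reference.labels)), 1)
    rows, cols = linear_sum_assignment(-contingency)
    mapping = np.empty(k, dtype=int)
    mapping[rows] = cols
    new_labels = mapping[np.asarray(other.labels)]
    centroids = None
    if other.centroids is not None:
        centroids = np.empty_like(other.centroids)
        centroids[mapping] = other.centroids
    return Partition(
        gene_ids=list(other.gene_ids),
        labels=new_labels,
        k=k,
        centroids=centroids,
        objective=other.objective,
    )


def aggregate(partitions: list[Partition], weights: QualityWeights) -> SoftPartition:
    """Weighted average of aligned one-hot partition indicators."""
    if len(partitions) != len(weights):
        raise ValueError(
            f"{len(partitions)} partitions but {len(weights)} weights"
        )
    genes = partitions[0].gene_ids
    k = partitions[0].k
    for p in partitions[1:]:
        if p.gene_ids != genes:
            raise ValueError("all partitions must cover the same gene set")
        if p.k != k:
            raise ValueError("all partitions must have the same k")
    membership = np.zeros((len(genes), k), dtype=float)
    for w_i, p in zip(weights.weights, partitions):
        membership[np.arange(len(genes)), np.asarray(p.labels)] += w_i
    return SoftPartition(gene_ids=list(genes), membership=membership)


def harden(soft: SoftPartition) -> tuple[Partition, list[str]]:
    """Row-argmax hard labels; ties -> lowest cluster index, tied genes listed."""
    labels = soft.membership.argmax(axis=1)
    maxima = soft.membership.max(axis=1, keepdims=True)
    tied_rows = (np.isclose(soft.membership, maxima, rtol=_TIE_RTOL, atol=1e-12).sum(axis=1) > 1)
    ties = [g for g, t in zip(soft.gene_ids, tied_rows) if t]
    part = Partition(gene_ids=list(soft.gene_ids), labels=labels, k=soft.k)
    return part, ties


def integrative_consensus(
    group: list[ExpressionMatrix],
    k: int,
    seed: int = 0,
    weights: QualityWeights | None = None,
    **kpartition_kwargs,
) -> IntegrativeResult:
    """Full Integrative pipeline on one preprocessed group of experiments.

    ``weights`` may be supplied when quality was assessed on the
    pre-normalized matrices; by default they are derived from the
    standardized-gene counts of ``group`` itself.
    """
    concat_part, blocks = init_centers_concat(group, k, seed=seed, **kpartition_kwargs)
    counts = []
    per_matrix: list[Partition] = []
    for mat, block in zip(group, blocks):
        part = kpartition(mat, k, method="mean", seed=seed, initial_centers=block,
                          **kpartition_kwargs)
        per_matrix.append(align_partition(concat_part, part))
        _, count = standardize(mat)
        counts.append(count)
    if weights is None:
        weights = compute_weights(counts)
    soft = aggregate(per_matrix, weights)
    partition, ties = harden(soft)
    partition.centroids = concat_part.centroids
    return IntegrativeResult(partition=partition, soft=soft, weights=weights, tie_genes=ties)
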