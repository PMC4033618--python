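"""Internal cluster validation: Connectivity, Silhouette Index and k selection.

Connectivity penalizes nearest neighbours that end up in different
clusters: for each gene ``i`` and each of its ``L`` nearest neighbours
``m_i(j)`` (by Euclidean distance, ``j = 1..L``), a penalty ``1/j`` is
added when the neighbour is not co-clustered with ``i``. It ranges from
0 to infinity and should be minimized.

The Silhouette Index is the mean over genes of ``(b_i - a_i) /
max(a_i, b_i)`` where ``a_i`` is the average distance to the gene's
co-cluster members and ``b_i`` the minimum over other clusters of the
average distance to that cluster. It lies in [-1, 1]; higher is better.

The number of clusters is chosen by scanning k (default 2..10),
computing Connectivity for each k, and taking the "elbow": the interior
k with the largest discrete second difference of the index. Across the
experiments of a group, the prevailing (modal) optimum is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .containers import ExpressionMatrix, Partition
from .partitioning import kpartition

__all__ = [
    "ValidationScores",
    "connectivity",
    "silhouette",
    "scan_k",
    "select_optimal_k",
    "prevailing_k",
]

DEFAULT_NEIGHBORS = 10


@dataclass
class ValidationScores:
    """Per-k validation indices for one expression matrix."""

    per_k: dict[int, tuple[float, float]] = field(default_factory=dict)
    neighbor_count: int = DEFAULT_NEIGHBORS

    def connectivity_map(self) -> dict[int, float]:
        return {k: v[0] for k, v in self.per_k.items()}

    def silhouette_map(self) -> dict[int, float]:
        return {k: v[1] for k, v in self.per_k.items()}

    def ks(self) -> list[int]:
        return sorted(self.per_k)


def _neighbor_order(dist_row: np.ndarray, self_index: int) -> np.ndarray:
    """Indices of the other genes sorted by distance, ties -> lower index."""
    order = np.argsort(dist_row, kind="stable")
    return order[order != self_index]


def connectivity(
    matrix: ExpressionMatrix, partition: Partition, L: int = DEFAULT_NEIGHBORS
) -> float:
    """Connectivity of ``partition`` on ``matrix`` with ``L`` neighbours."""
    X = matrix.dense_values()
    m = X.shape[0]
    if L < 1:
        raise ValueError("L must be >= 1")
    if L >= m:
        raise ValueError(f"L={L} must be smaller than the gene count ({m})")
    labels = np.asarray(partition.labels)
    if len(partition.gene_ids) != m:
        raise ValueError("partition does not match the matrix gene set")
    d = squareform(pdist(X, metric="euclidean"))
    total = 0.0
    inv = 1.0 / np.arange(1, L + 1)
    for i in range(m):
        nbrs = _neighbor_order(d[i], i)[:L]
        total += inv[labels[nbrs] != labels[i]].sum()
    return float(total)


def silhouette(matrix: ExpressionMatrix, partition: Partition) -> float:
    """Mean silhouette width of ``partition`` on ``matrix`` (k >= 2)."""
    if partition.k < 2:
        raise ValueError("silhouette requires k >= 2 (b_i undefined otherwise)")
    X = matrix.dense_values()
    m = X.shape[0]
    labels = np.asarray(partition.labels)
    if len(partition.gene_ids) != m:
        raise ValueError("partition does not match the matrix gene set")
    d = squareform(pdist(X, metric="euclidean"))
    sizes = np.bincount(labels, minlength=partition.k)
    occupied = np.flatnonzero(sizes > 0)
    if occupied.size < 2:
        raise ValueError("silhouette requires at least two non-empty clusters")
    # sum of distances from each gene to each cluster
    cluster_sums = np.zeros((m, partition.k))
    for c in occupied:
        cluster_sums[:, c] = d[:, labels == c].sum(axis=1)
    s = np.zeros(m)
    for i in range(m):
        c = labels[i]
        if sizes[c] == 1:
            s[i] = 0.0  # singleton convention
            continue
        a = cluster_sums[i, c] / (sizes[c] - 1)
        others = [o for o in occupied if o != c]
        b = min(cluster_sums[i, o] / sizes[o] for o in others)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def scan_k(
    matrix: ExpressionMatrix,
    k_min: int = 2,
    k_max: int = 10,
    method: str = "mean",
    seed: int = 0,
    L: int = DEFAULT_NEIGHBORS,
    **kpartition_kwargs,
) -> ValidationScores:
    """Cluster ``matrix`` for each k in ``[k_min, k_max]``, scoring each run."""
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    if k_max > matrix.n_genes:
        raise ValueError(f"k_max={k_max} exceeds the gene count ({matrix.n_genes})")
    scores = ValidationScores(neighbor_count=L)
    for k in range(k_min, k_max + 1):
        part = kpartition(matrix, k, method=method, seed=seed, **kpartition_kwargs)
        scores.per_k[k] = (
            connectivity(matrix, part, L=L),
            silhouette(matrix, part),
        )
    return scores


def select_optimal_k(conn_by_k: Mapping[int, float]) -> int:
    """Elbow rule: the interior k with the largest second difference.

    Given Connectivity values over consecutive k, returns the k
    maximizing ``(v(k-1) - v(k)) - (v(k) - v(k+1))``, i.e. the sharpest
    local flattening of the curve. Ties break toward the smallest k.
    """
    ks = sorted(conn_by_k)
    if len(ks) < 3:
        raise ValueError("need at least three consecutive k values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k values must be consecutive")
    best_k, best_score = None, -np.inf
    for k in ks[1:-1]:
        score = (conn_by_k[k - 1] - conn_by_k[k]) - (conn_by_k[k] - conn_by_k[k + 1])
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    return int(best_k)


def prevailing_k(ks: list[int]) -> int:
    """Modal value of per-experiment optima; ties break toward the smallest."""
    if not ks:
        raise ValueError("empty list of k values")
    values, counts = np.unique(np.asarray(ks, dtype=int), return_counts=True)
    return int(values[counts.argmax()])
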