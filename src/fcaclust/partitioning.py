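"""k-means, k-medians and k-medoids partitioning with a shared Lloyd-style loop.

All three methods alternate an assignment step (each gene joins the
cluster with the nearest center) with a center-recomputation step, until
the labelling stabilizes. They differ in the center definition and in
the distance that makes that center optimal for its cluster:

================  ==================  =========================
method            center              distance / objective
================  ==================  =========================
``mean``          per-dim average     squared Euclidean
``median``        per-dim median      Manhattan (L1)
``medoid``        central member      Euclidean
================  ==================  =========================

Pairing each center rule with the distance it minimizes makes the
clustering objective provably non-increasing across iterations (the
per-dimension median is the L1 minimizer, not the Euclidean one; a
medoid always self-assigns, so re-selecting it among the new members
can only lower the within-cluster distance sum).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .containers import ExpressionMatrix, Partition

__all__ = ["assign", "recompute_centers", "kpartition", "METHOD_METRIC"]

#: distance metric paired with each center-recomputation method
METHOD_METRIC = {"mean": "sqeuclidean", "median": "cityblock", "medoid": "euclidean"}


def assign(points: np.ndarray, centroids: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Label each point with its nearest centroid (ties -> lowest index)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if points.shape[1] != centroids.shape[1]:
        raise ValueError(
            f"dimension mismatch: points are {points.shape[1]}-D, "
            f"centroids are {centroids.shape[1]}-D"
        )
    if centroids.shape[0] < 1:
        raise ValueError("need at least one centroid")
    d = cdist(points, centroids, metric=metric)
    return d.argmin(axis=1)


def _center(points: np.ndarray, method: str) -> np.ndarray:
    if method == "mean":
        return points.mean(axis=0)
    if method == "median":
        return np.median(points, axis=0)
    if method == "medoid":
        d = cdist(points, points, metric="euclidean")
        return points[d.sum(axis=1).argmin()]
    raise ValueError(f"unknown center method {method!r}")


def recompute_centers(
    points: np.ndarray,
    labels: np.ndarray,
    k: int,
    method: str = "mean",
    previous: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Recompute the ``k`` cluster centers from an assignment.

    An empty cluster is re-seeded with the point farthest from its
    currently assigned centroid (``previous`` supplies the centroids for
    that repair; without it the repair falls back to the farthest point
    from the grand center). Returns ``(centers, repaired)``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if method not in METHOD_METRIC:
        raise ValueError(f"unknown center method {method!r}")
    metric = METHOD_METRIC[method]
    n = points.shape[1]
    centers = np.zeros((k, n), dtype=float)
    empty: list[int] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            empty.append(c)
        else:
            centers[c] = _center(points[members], method)
    repaired = bool(empty)
    if empty:
        if previous is not None:
            ref = np.asarray(previous, dtype=float)[labels]
        else:
            ref = np.broadcast_to(points.mean(axis=0), points.shape)
        dist_own = np.array(
            [cdist(points[i : i + 1], ref[i : i + 1], metric=metric)[0, 0] for i in range(points.shape[0])]
        )
        used: set[int] = set()
        for c in empty:
            order = np.argsort(-dist_own, kind="stable")
            pick = next(i for i in order if i not in used)
            used.add(int(pick))
            centers[c] = points[pick]
    return centers, repaired


def _objective(points: np.ndarray, centers: np.ndarray, labels: np.ndarray, metric: str) -> float:
    d = cdist(points, centers, metric=metric)
    return float(d[np.arange(points.shape[0]), labels].sum())


def _init_centers(points: np.ndarray, k: int, rng: np.random.Generator, init: str, metric: str) -> np.ndarray:
    m = points.shape[0]
    if init == "random":
        idx = rng.choice(m, size=k, replace=False)
        return points[idx].copy()
    if init == "maximin":
        # farthest-first traversal from a random start: guarantees every
        # well-separated cluster receives a seed
        chosen = [int(rng.integers(m))]
        mind = cdist(points, points[chosen], metric=metric).ravel()
        for _ in range(1, k):
            nxt = int(mind.argmax())
            chosen.append(nxt)
            mind = np.minimum(mind, cdist(points, points[nxt : nxt + 1], metric=metric).ravel())
        return points[chosen].copy()
    raise ValueError(f"unknown init {init!r}")


def kpartition(
    matrix: ExpressionMatrix,
    k: int,
    method: str = "mean",
    seed: int = 0,
    max_iter: int = 100,
    init: str = "maximin",
    n_init: int = 3,
    initial_centers: np.ndarray | None = None,
) -> Partition:
    """Partition the genes of ``matrix`` into ``k`` clusters.

    Runs ``n_init`` restarts (ignored when ``initial_centers`` is given)
    and returns the solution with the lowest objective. The per-iteration
    objective trace of the winning run is kept on the returned
    :class:`~fcaclust.containers.Partition`; it is non-increasing.
    Deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.n_genes:
        raise ValueError(f"k={k} exceeds the number of genes ({matrix.n_genes})")
    if method not in METHOD_METRIC:
        raise ValueError(f"unknown center method {method!r}")
    points = matrix.dense_values()
    metric = METHOD_METRIC[method]
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    restarts = 1 if initial_centers is not None else max(1, int(n_init))
    for _ in range(restarts):
        if initial_centers is not None:
            centers = np.asarray(initial_centers, dtype=float).copy()
            if centers.shape != (k, matrix.n_conditions):
                raise ValueError("initial_centers must be k x n")
        else:
            centers = _init_centers(points, k, rng, init, metric)
        labels = np.full(points.shape[0], -1, dtype=int)
        last_repair = False
        trace: list[float] = []
        for _it in range(max_iter):
            new_labels = assign(points, centers, metric=metric)
            if np.array_equal(new_labels, labels) and not last_repair:
                break
            labels = new_labels
            centers, last_repair = recompute_centers(points, labels, k, method, previous=centers)
            trace.append(_objective(points, centers, labels, metric))
        obj = _objective(points, centers, labels, metric)
        if best is None or obj < best[0]:
            best = (obj, labels.copy(), centers.copy(), trace)

    obj, labels, centers, trace = best
    return Partition(
        gene_ids=list(matrix.gene_ids),
        labels=labels,
        k=k,
        centroids=centers,
        objective=obj,
        objective_trace=trace,
    )
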