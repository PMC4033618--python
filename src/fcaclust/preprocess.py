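"""Missing-value handling, per-group gene intersection and quality weighting.

The preprocessing sequence mirrors common practice for multi-experiment
time-course compendia: rows with more than a given fraction of missing
entries (default 25%, strict "more than") are dropped, remaining gaps are
imputed, each group of experiments is restricted to its common genes, and
profiles are standardized gene-wise. The number of genes that can actually
be standardized (non-degenerate variance) serves as a per-experiment
quality score, normalized into aggregation weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix

__all__ = [
    "QualityWeights",
    "filter_missing",
    "impute",
    "intersect_genes",
    "standardize",
    "compute_weights",
]


@dataclass
class QualityWeights:
    """Normalized per-experiment aggregation weights (sum to 1)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or self.weights.size == 0:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")

    def __len__(self) -> int:
        return self.weights.size

    def __getitem__(self, i: int) -> float:
        return float(self.weights[i])


def filter_missing(matrix: ExpressionMatrix, max_missing_frac: float = 0.25) -> ExpressionMatrix:
    """Drop gene rows whose missing fraction strictly exceeds the threshold.

    A row with exactly ``max_missing_frac`` missing entries is retained
    (the cutoff is "more than"). Row order is preserved. Raises if no
    row survives.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = matrix.missing_mask.mean(axis=1)
    keep = frac <= max_missing_frac + 1e-12
    if not keep.any():
        raise ValueError(
            f"matrix {matrix.name or '<unnamed>'}: all rows exceed the "
            f"{max_missing_frac:.0%} missing threshold"
        )
    rows = np.flatnonzero(keep)
    return ExpressionMatrix(
        gene_ids=[matrix.gene_ids[i] for i in rows],
        condition_labels=list(matrix.condition_labels),
        values=matrix.values[rows].copy(),
        missing_mask=matrix.missing_mask[rows].copy(),
        name=matrix.name,
    )


def impute(matrix: ExpressionMatrix, method: str = "linear_interpolation") -> ExpressionMatrix:
    """Fill remaining missing entries along the condition (time) axis.

    ``linear_interpolation`` interpolates between the nearest observed
    neighbours of each gap and extends flat at the row edges;
    ``row_mean`` substitutes the row mean of the observed values.
    Observed values are never altered. A fully missing row is an error
    (it should have been filtered out beforehand).
    """
    if method not in ("linear_interpolation", "row_mean"):
        raise ValueError(f"unknown imputation method {method!r}")
    values = matrix.values.copy()
    n = matrix.n_conditions
    cols = np.arange(n, dtype=float)
    for i in range(matrix.n_genes):
        miss = matrix.missing_mask[i]
        if not miss.any():
            continue
        obs = ~miss
        if not obs.any():
            raise ValueError(
                f"gene {matrix.gene_ids[i]!r} has no observed values; "
                "filter fully-missing rows before imputing"
            )
        if method == "linear_interpolation":
            values[i, miss] = np.interp(cols[miss], cols[obs], values[i, obs])
        else:
            values[i, miss] = values[i, obs].mean()
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        condition_labels=list(matrix.condition_labels),
        values=values,
        missing_mask=np.zeros_like(matrix.missing_mask),
        name=matrix.name,
    )


def intersect_genes(group: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix of a group to the genes present in all of them.

    Gene order follows the first matrix. Raises on an empty intersection.
    """
    if not group:
        raise ValueError("group must contain at least one matrix")
    common = set(group[0].gene_ids)
    for m in group[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("no gene is shared by all matrices of the group")
    ordered = [g for g in group[0].gene_ids if g in common]
    return [m.subset_genes(ordered) for m in group]


def standardize(
    matrix: ExpressionMatrix, eps: float = 1e-12
) -> tuple[ExpressionMatrix, int]:
    """Gene-wise z-scoring; returns the matrix and the standardized-gene count.

    A gene row with sample standard deviation above ``eps`` is replaced
    by ``(x - mean) / sd`` and counted as standardized; a (near-)constant
    row is mean-centered only and not counted. The count is the
    experiment's quality score for :func:`compute_weights`.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    values = matrix.dense_values().copy()
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    standardizable = (sds > eps).ravel()
    values -= means
    values[standardizable] /= sds[standardizable]
    out = ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        condition_labels=list(matrix.condition_labels),
        values=values,
        missing_mask=np.zeros_like(matrix.missing_mask),
        name=matrix.name,
    )
    return out, int(standardizable.sum())


def compute_weights(standardized_counts: list[int]) -> QualityWeights:
    """Normalize per-experiment standardized-gene counts into weights."""
    counts = np.asarray(standardized_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one count")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all quality counts are zero; weights undefined")
    return QualityWeights(weights=counts / total)
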