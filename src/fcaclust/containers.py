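"""Core in-memory containers shared across the package.

An :class:`ExpressionMatrix` holds one experiment's gene x condition table
(real values plus a missing-value mask), a :class:`Partition` a hard
clustering of a gene set, and a :class:`GroupManifest` the assignment of
experiments to groups of related experiments (e.g. by synchronization
method in cell-cycle time courses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "Partition",
    "GroupManifest",
    "ExperimentGroup",
]


@dataclass
class ExpressionMatrix:
    """One experiment: ``m`` genes by ``n`` conditions or time points.

    Parameters
    ----------
    gene_ids
        Ordered, unique, case-sensitive gene identifiers (length ``m``).
    condition_labels
        Ordered condition / time-point labels (length ``n``).
    values
        ``m x n`` float array. Entries under the missing mask are
        ignored; all other entries must be finite.
    missing_mask
        ``m x n`` boolean array, ``True`` where the measurement is absent.
    name
        Optional experiment name (defaults to empty).
    """

    gene_ids: list[str]
    condition_labels: list[str]
    values: np.ndarray
    missing_mask: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.condition_labels = [str(c) for c in self.condition_labels]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        m, n = self.values.shape
        if self.missing_mask is None:
            self.missing_mask = np.zeros((m, n), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (m, n):
            raise ValueError(
                f"missing_mask shape {self.missing_mask.shape} does not "
                f"match values shape {(m, n)}"
            )
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.condition_labels) != n:
            raise ValueError(
                f"{len(self.condition_labels)} condition labels for {n} columns"
            )
        if m < 1:
            raise ValueError("matrix must contain at least one gene")
        if n < 2:
            raise ValueError("matrix must contain at least two conditions")
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise ValueError(f"duplicate gene ID {g!r}")
            seen.add(g)
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-finite value outside the missing mask")

    # -- convenience ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes`` in the given order."""
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            gene_ids=list(genes),
            condition_labels=list(self.condition_labels),
            values=self.values[rows].copy(),
            missing_mask=self.missing_mask[rows].copy(),
            name=self.name,
        )

    def dense_values(self) -> np.ndarray:
        """Values array, raising if any entry is still missing."""
        if self.has_missing():
            raise ValueError(
                f"matrix {self.name or '<unnamed>'} still contains missing "
                "values; impute first"
            )
        return self.values


@dataclass
class Partition:
    """A hard clustering of a gene set into ``k`` clusters.

    ``labels[i]`` is the cluster index (in ``[0, k)``) of ``gene_ids[i]``.
    ``centroids`` optionally stores the ``k x n`` cluster centers that
    produced the labelling, and ``objective`` the final clustering
    objective value.
    """

    gene_ids: list[str]
    labels: np.ndarray
    k: int
    centroids: np.ndarray | None = None
    objective: float | None = None
    objective_trace: list[float] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.gene_ids) == 0:
            raise ValueError("partitions must cover a non-empty gene set")
        if self.labels.shape != (len(self.gene_ids),):
            raise ValueError("labels must be one integer per gene")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs in partition")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError(f"labels must lie in [0, {self.k})")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def cluster_members(self, c: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == c]

    def as_sets(self) -> list[set[str]]:
        """Cluster index -> set of member gene IDs (possibly empty)."""
        out: list[set[str]] = [set() for _ in range(self.k)]
        for g, l in zip(self.gene_ids, self.labels):
            out[int(l)].add(g)
        return out

    def label_of(self) -> dict[str, int]:
        return {g: int(l) for g, l in zip(self.gene_ids, self.labels)}


@dataclass
class GroupManifest:
    """Ordered assignment of experiment files to named groups.

    ``groups`` maps each group name, in order, to the ordered list of
    expression-matrix paths (or IDs) it contains. ``criterion_note``
    records the grouping criterion as free text (e.g. "synchronization
    method").
    """

    groups: list[tuple[str, list[str]]]
    criterion_note: str = ""

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("manifest must define at least one group")
        seen: set[str] = set()
        for name, members in self.groups:
            if name in seen:
                raise ValueError(f"duplicate group name {name!r}")
            seen.add(name)
            if not members:
                raise ValueError(f"group {name!r} lists no experiments")

    @property
    def r(self) -> int:
        """Number of experiment groups."""
        return len(self.groups)

    def sizes(self) -> tuple[int, ...]:
        return tuple(len(members) for _, members in self.groups)

    def names(self) -> list[str]:
        return [name for name, _ in self.groups]


@dataclass
class ExperimentGroup:
    """A named group of (loaded) related experiments."""

    name: str
    matrices: list[ExpressionMatrix] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError(f"experiment group {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)
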