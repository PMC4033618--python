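"""Reading and writing expression matrices, partitions and group manifests.

File dialects (documented with examples in ``docs/file_formats.md``):

* Expression matrix: UTF-8, tab-separated; first row = condition labels,
  first column = gene IDs; missing entries are empty cells or the
  ``missing_token`` (default ``"NA"``).
* Partition: two-column TSV ``gene<TAB>cluster`` with a header line.
* Group manifest: a small YAML file with a ``groups`` list; each entry
  has a ``name`` and an ``experiments`` list of matrix paths.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

import numpy as np
import yaml

from .containers import ExperimentGroup, ExpressionMatrix, GroupManifest, Partition

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_partition",
    "write_partition",
    "read_group_manifest",
    "write_group_manifest",
    "load_groups",
]

DEFAULT_MISSING_TOKEN = "NA"


def read_expression_matrix(
    path: str | os.PathLike,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    name: str | None = None,
) -> ExpressionMatrix:
    """Read a tab-separated gene x condition table.

    The missing mask is ``True`` exactly where a cell equals
    ``missing_token`` or is empty. Errors name the offending gene ID,
    row number or cell coordinates.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if len(rows) < 2:
        raise ValueError(f"{path}: expected a header row and at least one gene row")
    header = rows[0]
    condition_labels = header[1:]
    n = len(condition_labels)
    if n < 2:
        raise ValueError(f"{path}: expected at least two condition columns")
    gene_ids: list[str] = []
    seen: set[str] = set()
    values = np.zeros((len(rows) - 1, n), dtype=float)
    mask = np.zeros((len(rows) - 1, n), dtype=bool)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != n + 1:
            raise ValueError(
                f"{path}: row {r} has {len(row)} fields, expected {n + 1}"
            )
        gene = row[0]
        if gene in seen:
            raise ValueError(f"{path}: duplicate gene ID {gene!r}")
        seen.add(gene)
        gene_ids.append(gene)
        for c, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "" or cell == missing_token:
                mask[r - 2, c] = True
                continue
            try:
                values[r - 2, c] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at gene {gene!r}, "
                    f"column {condition_labels[c]!r} (row {r}, column {c + 2})"
                ) from None
    return ExpressionMatrix(
        gene_ids=gene_ids,
        condition_labels=condition_labels,
        values=values,
        missing_mask=mask,
        name=name if name is not None else path.stem,
    )


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> None:
    """Write ``matrix`` as TSV; floats are serialized losslessly (%.17g)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("gene\t" + "\t".join(matrix.condition_labels) + "\n")
        for i, gene in enumerate(matrix.gene_ids):
            cells = [
                missing_token if matrix.missing_mask[i, j] else format(matrix.values[i, j], ".17g")
                for j in range(matrix.n_conditions)
            ]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


def write_partition(partition: Partition, path: str | os.PathLike) -> None:
    """Write a two-column TSV ``gene<TAB>cluster`` (one data line per gene)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("gene\tcluster\n")
        for gene, label in zip(partition.gene_ids, partition.labels):
            fh.write(f"{gene}\t{int(label)}\n")


def read_partition(path: str | os.PathLike, k: int | None = None) -> Partition:
    """Read a partition written by :func:`write_partition`.

    ``k`` defaults to ``max(label) + 1``.
    """
    path = Path(path)
    gene_ids: list[str] = []
    labels: list[int] = []
    with path.open("r", encoding="utf-8") as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if lineno == 1 and fields[:2] == ["gene", "cluster"]:
            continue
        if len(fields) != 2:
            raise ValueError(f"{path}: line {lineno} is not two tab-separated fields")
        gene_ids.append(fields[0])
        try:
            labels.append(int(fields[1]))
        except ValueError:
            raise ValueError(
                f"{path}: non-integer cluster index {fields[1]!r} on line {lineno}"
            ) from None
    if not gene_ids:
        raise ValueError(f"{path}: partition file contains no genes")
    arr = np.asarray(labels, dtype=int)
    return Partition(gene_ids=gene_ids, labels=arr, k=k if k is not None else int(arr.max()) + 1)


def read_group_manifest(path: str | os.PathLike) -> GroupManifest:
    """Read a YAML group manifest.

    Expected structure::

        criterion: synchronization method
        groups:
          - name: elutriation
            experiments: [elu1.tsv, elu2.tsv, elu3.tsv]
          - name: cdc25
            experiments: [cdc25-1.tsv, ...]
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "groups" not in doc:
        raise ValueError(f"{path}: manifest must be a mapping with a 'groups' list")
    groups: list[tuple[str, list[str]]] = []
    for entry in doc["groups"]:
        if not isinstance(entry, dict) or "name" not in entry or "experiments" not in entry:
            raise ValueError(
                f"{path}: each group needs 'name' and 'experiments' keys, got {entry!r}"
            )
        members = [str(p) for p in (entry["experiments"] or [])]
        groups.append((str(entry["name"]), members))
    return GroupManifest(groups=groups, criterion_note=str(doc.get("criterion", "")))


def write_group_manifest(manifest: GroupManifest, path: str | os.PathLike) -> None:
    doc = {
        "criterion": manifest.criterion_note,
        "groups": [
            {"name": name, "experiments": list(members)}
            for name, members in manifest.groups
        ],
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_groups(
    manifest: GroupManifest,
    base_dir: str | os.PathLike | None = None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> list[ExperimentGroup]:
    """Load every matrix referenced by ``manifest``.

    Relative paths are resolved against ``base_dir`` (default: cwd).
    An unknown matrix path raises at load time, naming the group.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    out: list[ExperimentGroup] = []
    for name, members in manifest.groups:
        matrices = []
        for member in members:
            p = Path(member)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(
                    f"group {name!r}: expression matrix {member!r} not found "
                    f"(resolved to {p})"
                )
            matrices.append(read_expression_matrix(p, missing_token=missing_token))
        out.append(ExperimentGroup(name=name, matrices=matrices))
    return out
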