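"""Synthetic multi-group expression compendia with planted cluster structure.

The generator emulates a cell-cycle time-course compendium: groups of
related experiments (as if synchronized by different methods), each
experiment a gene x time-point matrix. Every gene carries a peak phase
on the cycle; within a group with ``k_g`` clusters, the gene is planted
in the cluster whose prototype phase (``k_g`` equally spaced phases) is
nearest its own. A gene's profile in an experiment is its cluster
prototype ``sin(2*pi*t/T + phase_c)`` sampled at that experiment's time
points, plus i.i.d. Gaussian noise of standard deviation ``sigma``.
Missing entries are masked uniformly at random, capped per row below
the default 25% filtering threshold so preprocessing keeps every gene.
Gene sets may overlap only partially across groups, as in real
compendia where each experiment loses different genes to quality
filtering. Generation is fully deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import ExperimentGroup, ExpressionMatrix, GroupManifest
from .io import write_expression_matrix, write_group_manifest

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "generate_compendium",
    "default_paper_like_spec",
    "write_compendium",
]


@dataclass
class SyntheticSpec:
    """Parameters of a planted-structure compendium."""

    n_groups: int = 3
    experiments_per_group: tuple[int, ...] = (3, 4, 2)
    k_per_group: tuple[int, ...] = (4, 6, 5)
    n_genes: int = 374
    genes_per_group: tuple[int, ...] | None = (286, 350, 374)
    overlap_frac: float = 0.75
    timepoints_range: tuple[int, int] = (12, 20)
    noise_sd: float = 0.05
    missing_rate: float = 0.02
    missing_row_cap: float = 0.25
    period: float = 150.0
    seed: int = 0
    group_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("need at least one group")
        for name, tup in (
            ("experiments_per_group", self.experiments_per_group),
            ("k_per_group", self.k_per_group),
        ):
            if len(tup) != self.n_groups:
                raise ValueError(f"{name} must have one entry per group")
        if any(k < 2 for k in self.k_per_group):
            raise ValueError("every group needs k >= 2")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing rate must lie in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.timepoints_range[0] < 2 or self.timepoints_range[1] < self.timepoints_range[0]:
            raise ValueError("invalid time-point range")
        if self.genes_per_group is not None:
            if len(self.genes_per_group) != self.n_groups:
                raise ValueError("genes_per_group must have one entry per group")
            if max(self.genes_per_group) > self.n_genes:
                raise ValueError("a group cannot contain more genes than exist")
            if sum(self.genes_per_group) < self.n_genes:
                raise ValueError(
                    "group gene counts cannot cover all genes "
                    f"(sum {sum(self.genes_per_group)} < N={self.n_genes})"
                )
        if not 0.0 <= self.overlap_frac <= 1.0:
            raise ValueError("overlap fraction must lie in [0, 1]")
        if self.n_genes < max(self.k_per_group):
            raise ValueError("need at least k genes")

    def names(self) -> list[str]:
        if self.group_names is not None:
            return list(self.group_names)
        return [f"group{i + 1}" for i in range(self.n_groups)]


@dataclass
class PlantedTruth:
    """Ground-truth labels used as the oracle in every recovery test."""

    per_group_labels: dict[str, dict[str, int]] = field(default_factory=dict)
    phases: dict[str, float] = field(default_factory=dict)

    def membership_sets(self, k_offsets: dict[str, int]) -> dict[str, set[int]]:
        """Per-gene set of globally numbered planted clusters."""
        out: dict[str, set[int]] = {}
        for group, labels in self.per_group_labels.items():
            off = k_offsets[group]
            for g, c in labels.items():
                out.setdefault(g, set()).add(off + c)
        return out

    def group_partition_labels(self, group: str, gene_ids: list[str]) -> np.ndarray:
        return np.array([self.per_group_labels[group][g] for g in gene_ids], dtype=int)


def _assign_gene_sets(spec: SyntheticSpec, rng: np.random.Generator) -> list[list[int]]:
    """Per-group gene index lists: full coverage, requested sizes/overlap."""
    N, r = spec.n_genes, spec.n_groups
    if spec.genes_per_group is not None:
        sizes = list(spec.genes_per_group)
    else:
        core = round(spec.overlap_frac * N)
        extra = N - core
        per = math.ceil(extra / r)
        sizes = [min(N, core + per) for _ in range(r)]
    members: list[set[int]] = [set() for _ in range(r)]
    capacity = np.array(sizes, dtype=float)
    # every gene gets a home group (coverage), drawn by remaining capacity
    for gi in rng.permutation(N):
        probs = np.clip(capacity, 0, None)
        if probs.sum() == 0:
            raise ValueError("group sizes cannot cover all genes")
        g = rng.choice(r, p=probs / probs.sum())
        members[g].add(int(gi))
        capacity[g] -= 1
    # top the groups up to their target sizes
    for g in range(r):
        deficit = sizes[g] - len(members[g])
        if deficit > 0:
            pool = np.array(sorted(set(range(N)) - members[g]))
            members[g] |= set(int(x) for x in rng.choice(pool, size=deficit, replace=False))
    return [sorted(m) for m in members]


def generate_compendium(
    spec: SyntheticSpec,
) -> tuple[list[ExperimentGroup], PlantedTruth]:
    """Generate all experiment groups plus the planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    N = spec.n_genes
    width = len(str(N))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(N)]
    phases = rng.uniform(0.0, 2.0 * math.pi, size=N)
    gene_sets = _assign_gene_sets(spec, rng)
    names = spec.names()

    truth = PlantedTruth(phases={g: float(p) for g, p in zip(gene_ids, phases)})
    groups: list[ExperimentGroup] = []
    for gidx, name in enumerate(names):
        k = spec.k_per_group[gidx]
        proto_phases = 2.0 * math.pi * np.arange(k) / k
        rows = gene_sets[gidx]
        row_phases = phases[rows]
        # planted label: prototype phase nearest the gene's own (circular)
        diff = np.abs(row_phases[:, None] - proto_phases[None, :])
        circ = np.minimum(diff, 2.0 * math.pi - diff)
        labels = circ.argmin(axis=1)
        truth.per_group_labels[name] = {
            gene_ids[i]: int(l) for i, l in zip(rows, labels)
        }
        matrices = []
        for e in range(spec.experiments_per_group[gidx]):
            lo, hi = spec.timepoints_range
            n_t = int(rng.integers(lo, hi + 1))
            t = np.linspace(0.0, spec.period, n_t, endpoint=False)
            proto = np.sin(
                2.0 * math.pi * t[None, :] / spec.period + proto_phases[labels][:, None]
            )
            noise = rng.normal(0.0, spec.noise_sd, size=proto.shape) if spec.noise_sd > 0 else 0.0
            values = proto + noise
            mask = rng.random(size=proto.shape) < spec.missing_rate
            mask = _cap_row_missing(mask, spec.missing_row_cap, rng)
            matrices.append(
                ExpressionMatrix(
                    gene_ids=[gene_ids[i] for i in rows],
                    condition_labels=[f"t{j}" for j in range(n_t)],
                    values=values,
                    missing_mask=mask,
                    name=f"{name}_e{e + 1}",
                )
            )
        groups.append(ExperimentGroup(name=name, matrices=matrices))
    return groups, truth


def _cap_row_missing(mask: np.ndarray, cap: float, rng: np.random.Generator) -> np.ndarray:
    """Unmask random entries of rows that would exceed the missing cap."""
    mask = mask.copy()
    n = mask.shape[1]
    limit = int(math.floor(cap * n))
    for i in range(mask.shape[0]):
        excess = int(mask[i].sum()) - limit
        if excess > 0:
            on = np.flatnonzero(mask[i])
            off = rng.choice(on, size=excess, replace=False)
            mask[i, off] = False
    return mask


def default_paper_like_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Three synchronization-method groups of 3/4/2 experiments.

    Emulates a nine-time-course cell-cycle compendium: per-group cluster
    counts (4, 6, 5) — hence 15 clusters in total in the pooled context —
    374 distinct genes in the union, and per-group common-gene counts
    (286, 350, 374).
    """
    params = dict(
        n_groups=3,
        experiments_per_group=(3, 4, 2),
        k_per_group=(4, 6, 5),
        n_genes=374,
        genes_per_group=(286, 350, 374),
        group_names=("elutriation", "cdc25", "combined"),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


def write_compendium(
    groups: list[ExperimentGroup],
    truth: PlantedTruth,
    out_dir,
    criterion_note: str = "synthetic grouping",
) -> GroupManifest:
    """Write matrices as TSV, a YAML manifest, and truth label TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries: list[tuple[str, list[str]]] = []
    for group in groups:
        files = []
        for mat in group.matrices:
            fname = f"{mat.name}.tsv"
            write_expression_matrix(mat, out / fname)
            files.append(fname)
        entries.append((group.name, files))
    manifest = GroupManifest(groups=entries, criterion_note=criterion_note)
    write_group_manifest(manifest, out / "manifest.yaml")
    with (out / "truth.tsv").open("w", encoding="utf-8") as fh:
        fh.write("group\tgene\tcluster\n")
        for group, labels in truth.per_group_labels.items():
            for g, c in labels.items():
                fh.write(f"{group}\t{g}\t{c}\n")
    return manifest
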