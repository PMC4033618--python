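"""End-to-end orchestration of the three-step consensus workflow.

1. *Initialization*: load the experiment groups, filter rows with too
   many missing values, impute the rest, restrict each group to its
   common genes and (optionally) standardize profiles; choose the
   per-group cluster count, either explicitly or automatically via the
   Connectivity elbow scan and the prevailing per-experiment optimum.
2. *Clustering*: run the chosen consensus engine (PSO-based or
   Integrative) on each group separately.
3. *Concept analysis*: pool the group partitions into a formal context,
   enumerate the concept lattice, compute supports and extract the
   final disjoint gene partition.

Every intermediate is written to the output directory together with a
machine-readable JSON run report; all randomness derives from a single
seed recorded in the report.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import ExperimentGroup, ExpressionMatrix, Partition
from .fca import build_context, compute_support, disjoint_partition, enumerate_concepts, order_lattice
from .integrative import integrative_consensus
from .io import load_groups, read_group_manifest, write_partition
from .preprocess import compute_weights, filter_missing, impute, intersect_genes, standardize
from .pso import PSOParams, pso_consensus
from .validation import DEFAULT_NEIGHBORS, connectivity, prevailing_k, scan_k, select_optimal_k, silhouette

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Everything one run needs; see the field defaults for conventions."""

    manifest_path: str | None = None
    groups: list[ExperimentGroup] | None = None   # alternative to manifest_path
    engine: str = "pso"                           # "pso" | "integrative"
    k: dict[str, int] | int | str = "auto"        # per-group, shared, or "auto"
    k_min: int = 2
    k_max: int = 10
    max_missing_frac: float = 0.25
    impute_method: str = "linear_interpolation"
    standardize: bool = True
    neighbor_count: int = DEFAULT_NEIGHBORS
    pso: PSOParams | None = None
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.engine not in ("pso", "integrative"):
            raise ValueError(f"unknown consensus engine {self.engine!r}")
        if isinstance(self.k, int) and self.k < 2:
            raise ValueError("explicit k must be >= 2")
        if self.manifest_path is None and self.groups is None:
            raise ValueError("provide either manifest_path or in-memory groups")


@dataclass
class RunReport:
    seed: int = 0
    engine: str = ""
    r: int = 0
    K: int = 0
    n_genes_total: int = 0
    k_per_group: dict[str, int] = field(default_factory=dict)
    genes_per_group: dict[str, int] = field(default_factory=dict)
    tie_counts: dict[str, int] = field(default_factory=dict)
    n_concepts: int = 0
    n_zero_support: int = 0
    n_blocks: int = 0
    n_distinct_membership_sets: int = 0
    validation: dict[str, dict[str, float]] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    group_partitions: dict[str, Partition] = field(default_factory=dict)
    final_partition: Partition | None = None
    lattice: object = None
    context: object = None

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "engine": self.engine,
            "r": self.r,
            "K": self.K,
            "n_genes_total": self.n_genes_total,
            "k_per_group": self.k_per_group,
            "genes_per_group": self.genes_per_group,
            "tie_counts": self.tie_counts,
            "n_concepts": self.n_concepts,
            "n_zero_support": self.n_zero_support,
            "n_blocks": self.n_blocks,
            "n_distinct_membership_sets": self.n_distinct_membership_sets,
            "validation": self.validation,
            "timings": {k: round(v, 4) for k, v in self.timings.items()},
        }
        return json.dumps(payload, indent=2)


def _preprocess_group(group: ExperimentGroup, config: RunConfig) -> tuple[list[ExpressionMatrix], list[int]]:
    mats = [filter_missing(m, config.max_missing_frac) for m in group.matrices]
    mats = [impute(m, config.impute_method) for m in mats]
    mats = intersect_genes(mats)
    counts = []
    if config.standardize:
        std = []
        for m in mats:
            sm, count = standardize(m)
            std.append(sm)
            counts.append(count)
        mats = std
    else:
        counts = [standardize(m)[1] for m in mats]
    return mats, counts


def _choose_k(group_name: str, mats: list[ExpressionMatrix], config: RunConfig, seed: int) -> int:
    if isinstance(config.k, dict):
        return int(config.k[group_name])
    if isinstance(config.k, int):
        return config.k
    optima = []
    for m in mats:
        k_max = min(config.k_max, m.n_genes)
        scores = scan_k(m, k_min=config.k_min, k_max=k_max, seed=seed, L=config.neighbor_count)
        optima.append(select_optimal_k(scores.connectivity_map()))
    return prevailing_k(optima)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow; returns the run report.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs written so far are retained next to a ``FAILED`` marker.
    """
    report = RunReport(seed=config.seed, engine=config.engine)
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        t0 = time.perf_counter()
        if config.groups is not None:
            groups = config.groups
        else:
            manifest = read_group_manifest(config.manifest_path)
            groups = load_groups(manifest, base_dir=Path(config.manifest_path).parent)
        report.r = len(groups)
        report.timings["load"] = time.perf_counter() - t0

        seed_seq = np.random.SeedSequence(config.seed)
        group_seeds = seed_seq.generate_state(len(groups))

        stage = "preprocess"
        t0 = time.perf_counter()
        prepped: list[tuple[ExperimentGroup, list[ExpressionMatrix], list[int]]] = []
        for group in groups:
            mats, counts = _preprocess_group(group, config)
            prepped.append((group, mats, counts))
            report.genes_per_group[group.name] = mats[0].n_genes
        report.timings["preprocess"] = time.perf_counter() - t0

        stage = "select_k"
        t0 = time.perf_counter()
        k_per_group: dict[str, int] = {}
        for (group, mats, _), gseed in zip(prepped, group_seeds):
            k_per_group[group.name] = _choose_k(group.name, mats, config, int(gseed))
        report.k_per_group = k_per_group
        report.timings["select_k"] = time.perf_counter() - t0

        stage = "consensus"
        t0 = time.perf_counter()
        group_partitions: list[tuple[str, Partition]] = []
        for (group, mats, counts), gseed in zip(prepped, group_seeds):
            k = k_per_group[group.name]
            if config.engine == "pso":
                params = config.pso or PSOParams()
                params = PSOParams(w=params.w, c1=params.c1, c2=params.c2,
                                   max_iter=params.max_iter, seed=int(gseed))
                result = pso_consensus(mats, k, params)
                report.tie_counts[group.name] = 0
                part = result.partition
            else:
                result = integrative_consensus(
                    mats, k, seed=int(gseed), weights=compute_weights(counts)
                )
                report.tie_counts[group.name] = len(result.tie_genes)
                part = result.partition
            group_partitions.append((group.name, part))
            report.group_partitions[group.name] = part
            if out is not None:
                write_partition(part, out / f"partition_{group.name}.tsv")
        report.timings["consensus"] = time.perf_counter() - t0

        stage = "validate"
        t0 = time.perf_counter()
        for (group, mats, _), (_, part) in zip(prepped, group_partitions):
            for mat in mats:
                L = min(config.neighbor_count, mat.n_genes - 1)
                report.validation[mat.name] = {
                    "silhouette": silhouette(mat, part),
                    "connectivity": connectivity(mat, part, L=L),
                }
        report.timings["validate"] = time.perf_counter() - t0

        stage = "fca"
        t0 = time.perf_counter()
        context = build_context(group_partitions)
        concepts = enumerate_concepts(context)
        lattice = order_lattice(concepts, context)
        compute_support(lattice, context)
        final = disjoint_partition(lattice)
        report.context = context
        report.lattice = lattice
        report.final_partition = final
        report.K = context.n_clusters
        report.n_genes_total = context.n_genes
        report.n_concepts = len(lattice)
        report.n_zero_support = sum(1 for c in lattice.concepts if c.support == 0)
        report.n_blocks = final.k
        membership_sets = {
            frozenset(np.flatnonzero(context.incidence[i]).tolist())
            for i in range(context.n_genes)
        }
        report.n_distinct_membership_sets = len(membership_sets)
        if report.n_blocks != report.n_concepts - report.n_zero_support:
            raise AssertionError("block count does not match positive-support concepts")
        if report.n_blocks != report.n_distinct_membership_sets:
            raise AssertionError("block count does not match distinct membership sets")
        report.timings["fca"] = time.perf_counter() - t0

        stage = "write"
        if out is not None:
            context.to_tsv(out / "context.tsv")
            lattice.to_json_lines(out / "lattice.jsonl")
            lattice.to_dot(out / "lattice.dot")
            write_partition(final, out / "final_partition.tsv")
            with (out / "scores.tsv").open("w", encoding="utf-8") as fh:
                fh.write("experiment\tsilhouette\tconnectivity\n")
                for name, sc in report.validation.items():
                    fh.write(f"{name}\t{sc['silhouette']:.6f}\t{sc['connectivity']:.6f}\n")
            (out / "report.json").write_text(report.to_json(), encoding="utf-8")
        return report
    except Exception as exc:
        if out is not None:
            (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n", encoding="utf-8")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
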