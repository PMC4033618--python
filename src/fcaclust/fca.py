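"""Formal concept analysis over gene x cluster membership contexts.

After each group of experiments has produced its consensus partition,
the groups' clusterings are pooled into a single binary *formal
context*: genes are the objects, the K = k_1 + ... + k_r clusters of
all groups are the attributes (numbered contiguously with a per-group
offset, e.g. 0-3 / 4-9 / 10-14 for three groups), and a cell is set
whenever the gene belongs to the cluster. A gene that is absent from a
group simply has no incidence with that group's clusters.

A *formal concept* is a Galois-closed pair (extent X of genes, intent Y
of clusters): X is the maximal gene set belonging to every cluster of
Y, and Y the maximal cluster set containing every gene of X. The
concepts, ordered by extent inclusion (equivalently reverse intent
inclusion), form a complete lattice. Concepts are enumerated with
Ganter's NextClosure algorithm in lectic order, which is deterministic
and needs no more memory than the output.

Each gene has a unique *object concept* — the concept whose intent is
exactly the gene's cluster-membership set. The genes owning a concept
form its *own extent*; ``support = |own extent| / N``. Concepts with
positive support partition the genes into disjoint blocks (two genes
share a block iff they have identical membership sets), which is the
final consensus clustering over the whole compendium.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .containers import Partition

__all__ = [
    "ClusterAttribute",
    "FormalContext",
    "FormalConcept",
    "ConceptLattice",
    "build_context",
    "derive",
    "enumerate_concepts",
    "order_lattice",
    "compute_support",
    "disjoint_partition",
    "filter_concepts",
    "fca_partition",
]

MAX_CONTEXT_CELLS = 10**7


@dataclass(frozen=True)
class ClusterAttribute:
    """One context attribute: a cluster, tagged with its source group."""

    global_id: int
    group: str
    local_index: int

    @property
    def label(self) -> str:
        return f"{self.group}:{self.local_index}"


@dataclass
class FormalContext:
    """Binary genes x clusters incidence."""

    gene_ids: list[str]
    attributes: list[ClusterAttribute]
    incidence: np.ndarray  # N x K booleans

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)
        N, K = len(self.gene_ids), len(self.attributes)
        if self.incidence.shape != (N, K):
            raise ValueError(f"incidence must be {N} x {K}")
        ids = [a.global_id for a in self.attributes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cluster (attribute) IDs in context")
        if len(set(self.gene_ids)) != N:
            raise ValueError("duplicate gene IDs in context")
        if N * K > MAX_CONTEXT_CELLS:
            raise ValueError(
                f"context has {N * K} cells, above the {MAX_CONTEXT_CELLS} guard; "
                "reduce the context before enumerating concepts"
            )
        # each group's clustering is a partition: at most one incidence
        # per (gene, group)
        groups = {a.group for a in self.attributes}
        for g in groups:
            cols = [j for j, a in enumerate(self.attributes) if a.group == g]
            if np.any(self.incidence[:, cols].sum(axis=1) > 1):
                raise ValueError(
                    f"group {g!r} assigns some gene to more than one cluster"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_clusters(self) -> int:
        return len(self.attributes)

    # -- bitset views ---------------------------------------------------
    def row_bits(self) -> list[int]:
        """Per-gene attribute sets as K-bit integers (bit j = attribute j)."""
        weights = 1 << np.arange(self.n_clusters, dtype=object)
        return [int((self.incidence[i] * weights).sum()) for i in range(self.n_genes)]

    def col_bits(self) -> list[int]:
        """Per-attribute gene sets as N-bit integers (bit i = gene i)."""
        weights = 1 << np.arange(self.n_genes, dtype=object)
        return [int((self.incidence[:, j] * weights).sum()) for j in range(self.n_clusters)]

    def to_tsv(self, path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("gene\t" + "\t".join(a.label for a in self.attributes) + "\n")
            for i, g in enumerate(self.gene_ids):
                fh.write(g + "\t" + "\t".join("1" if v else "0" for v in self.incidence[i]) + "\n")


@dataclass
class FormalConcept:
    """A closed (extent, intent) pair with its own-extent and support."""

    extent: frozenset[str]
    intent: frozenset[int]          # attribute global_ids
    own_extent: frozenset[str] | None = None
    support: float | None = None
    lectic_rank: int = -1


@dataclass
class ConceptLattice:
    concepts: list[FormalConcept]
    order: list[tuple[int, int]] = field(default_factory=list)  # (a, b): a is a subconcept of b
    hasse_edges: list[tuple[int, int]] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    attributes: list[ClusterAttribute] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.concepts)

    @property
    def top_index(self) -> int:
        """The concept with the largest extent (all genes)."""
        return max(range(len(self.concepts)), key=lambda i: len(self.concepts[i].extent))

    @property
    def bottom_index(self) -> int:
        return min(range(len(self.concepts)), key=lambda i: len(self.concepts[i].extent))

    def positive_concepts(self) -> list[FormalConcept]:
        return [c for c in self.concepts if c.support and c.support > 0]

    def to_json_lines(self, path) -> None:
        """One concept per line: extent, intent, own-extent, support."""
        with Path(path).open("w", encoding="utf-8") as fh:
            for c in self.concepts:
                fh.write(json.dumps({
                    "extent": sorted(c.extent),
                    "intent": sorted(c.intent),
                    "own_extent": sorted(c.own_extent) if c.own_extent is not None else None,
                    "support": c.support,
                }) + "\n")

    def to_dot(self, path) -> None:
        """Hasse diagram in Graphviz DOT format (edges point upward)."""
        lines = ["digraph lattice {", "  rankdir=BT;"]
        for i, c in enumerate(self.concepts):
            intent = ",".join(str(a) for a in sorted(c.intent))
            sup = f"{c.support:.3f}" if c.support is not None else "?"
            lines.append(
                f'  n{i} [label="{{{intent}}}\\n|X|={len(c.extent)} s={sup}"];'
            )
        for a, b in self.hasse_edges:
            lines.append(f"  n{a} -> n{b};")
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------


def build_context(partitions: Sequence[tuple[str, Partition]]) -> FormalContext:
    """Pool one consensus partition per group into a formal context.

    Cluster attributes are numbered contiguously across groups in the
    given order. The gene universe is the union of the partitions' gene
    sets, ordered by first appearance.
    """
    if not partitions:
        raise ValueError("need at least one group partition")
    names = [name for name, _ in partitions]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names")
    gene_ids: list[str] = []
    seen: set[str] = set()
    for _, part in partitions:
        for g in part.gene_ids:
            if g not in seen:
                seen.add(g)
                gene_ids.append(g)
    attributes: list[ClusterAttribute] = []
    offset = 0
    for name, part in partitions:
        for c in range(part.k):
            attributes.append(ClusterAttribute(global_id=offset + c, group=name, local_index=c))
        offset += part.k
    N, K = len(gene_ids), len(attributes)
    incidence = np.zeros((N, K), dtype=bool)
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    offset = 0
    for name, part in partitions:
        for g, label in zip(part.gene_ids, part.labels):
            incidence[gene_row[g], offset + int(label)] = True
        offset += part.k
    return FormalContext(gene_ids=gene_ids, attributes=attributes, incidence=incidence)


def derive(
    context: FormalContext,
    genes: Iterable[str] | None = None,
    clusters: Iterable[int] | None = None,
) -> set:
    """Galois derivation.

    With ``genes`` given: the set of cluster global-IDs containing every
    listed gene. With ``clusters`` given: the set of genes belonging to
    every listed cluster. An empty input set derives to the full
    opposite side.
    """
    if (genes is None) == (clusters is None):
        raise ValueError("pass exactly one of genes= or clusters=")
    if genes is not None:
        gene_row = {g: i for i, g in enumerate(context.gene_ids)}
        rows = [gene_row[g] for g in genes]
        mask = np.ones(context.n_clusters, dtype=bool)
        for i in rows:
            mask &= context.incidence[i]
        return {context.attributes[j].global_id for j in np.flatnonzero(mask)}
    attr_col = {a.global_id: j for j, a in enumerate(context.attributes)}
    cols = [attr_col[c] for c in clusters]
    mask = np.ones(context.n_genes, dtype=bool)
    for j in cols:
        mask &= context.incidence[:, j]
    return {context.gene_ids[i] for i in np.flatnonzero(mask)}


def _closure_bits(intent: int, cols: list[int], full_extent: int, K: int) -> tuple[int, int]:
    """(closed intent, extent) for an attribute bitset ``intent``."""
    extent = full_extent
    y = intent
    while y:
        j = (y & -y).bit_length() - 1
        extent &= cols[j]
        y &= y - 1
    closed = 0
    for j in range(K):
        if cols[j] & extent == extent:
            closed |= 1 << j
    return closed, extent


def enumerate_concepts(context: FormalContext) -> list[FormalConcept]:
    """All formal concepts of ``context`` in lectic (NextClosure) order."""
    N, K = context.n_genes, context.n_clusters
    cols = context.col_bits()
    full_extent = (1 << N) - 1
    full_intent = (1 << K) - 1

    concepts_bits: list[tuple[int, int]] = []
    intent, extent = _closure_bits(0, cols, full_extent, K)
    concepts_bits.append((extent, intent))
    while intent != full_intent:
        for i in reversed(range(K)):
            if intent >> i & 1:
                continue
            mask = (1 << i) - 1
            candidate = (intent & mask) | (1 << i)
            new_intent, new_extent = _closure_bits(candidate, cols, full_extent, K)
            if (new_intent & mask) == (intent & mask):
                intent, extent = new_intent, new_extent
                concepts_bits.append((extent, intent))
                break
        else:  # pragma: no cover - the full intent always terminates the scan
            break

    out: list[FormalConcept] = []
    for rank, (ext_bits, int_bits) in enumerate(concepts_bits):
        extent = frozenset(
            context.gene_ids[i] for i in range(N) if ext_bits >> i & 1
        )
        intent_set = frozenset(
            context.attributes[j].global_id for j in range(K) if int_bits >> j & 1
        )
        out.append(FormalConcept(extent=extent, intent=intent_set, lectic_rank=rank))
    return out


def order_lattice(
    concepts: list[FormalConcept],
    context: FormalContext | None = None,
) -> ConceptLattice:
    """Order concepts by extent inclusion; also computes the Hasse diagram."""
    n = len(concepts)
    order: list[tuple[int, int]] = []
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for a in range(n):
        for b in range(n):
            if a != b and concepts[a].extent < concepts[b].extent:
                order.append((a, b))
                g.add_edge(a, b)
    hasse = sorted(nx.transitive_reduction(g).edges())
    lattice = ConceptLattice(
        concepts=concepts,
        order=order,
        hasse_edges=hasse,
        gene_ids=list(context.gene_ids) if context is not None else [],
        attributes=list(context.attributes) if context is not None else [],
    )
    return lattice


def compute_support(lattice: ConceptLattice, context: FormalContext) -> ConceptLattice:
    """Fill own-extents and supports from the genes' object concepts.

    A gene's object concept is the concept whose intent equals the
    gene's own cluster-membership set; supports therefore sum to 1 over
    the lattice.
    """
    by_intent: dict[frozenset[int], FormalConcept] = {c.intent: c for c in lattice.concepts}
    own: dict[frozenset[int], set[str]] = {c.intent: set() for c in lattice.concepts}
    for i, gene in enumerate(context.gene_ids):
        memberships = frozenset(
            context.attributes[j].global_id
            for j in np.flatnonzero(context.incidence[i])
        )
        if memberships not in by_intent:
            raise ValueError(
                f"gene {gene!r} has membership set {sorted(memberships)} with no "
                "matching concept; the lattice does not belong to this context"
            )
        own[memberships].add(gene)
    N = context.n_genes
    for c in lattice.concepts:
        c.own_extent = frozenset(own[c.intent])
        c.support = len(c.own_extent) / N
    lattice.gene_ids = list(context.gene_ids)
    lattice.attributes = list(context.attributes)
    return lattice


def disjoint_partition(lattice: ConceptLattice) -> Partition:
    """The final disjoint gene partition: one block per positive-support concept.

    Blocks are ordered by decreasing support, ties by lectic intent
    order. Covers all N genes of the context.
    """
    if any(c.support is None for c in lattice.concepts):
        raise ValueError("run compute_support before extracting the partition")
    blocks = sorted(
        (c for c in lattice.concepts if c.support > 0),
        key=lambda c: (-c.support, c.lectic_rank),
    )
    label_of: dict[str, int] = {}
    for b, concept in enumerate(blocks):
        for g in concept.own_extent:
            label_of[g] = b
    gene_ids = list(lattice.gene_ids)
    missing = [g for g in gene_ids if g not in label_of]
    if missing:
        raise ValueError(f"genes not covered by any positive-support concept: {missing[:5]}")
    labels = np.array([label_of[g] for g in gene_ids], dtype=int)
    return Partition(gene_ids=gene_ids, labels=labels, k=len(blocks))


def filter_concepts(
    lattice: ConceptLattice,
    min_support: float = 0.0,
    intent_size: int | None = None,
) -> list[FormalConcept]:
    """Concepts with support strictly above ``min_support``.

    When ``intent_size`` is given, only concepts whose intent has exactly
    that many clusters are returned (e.g. one cluster per group).
    """
    if any(c.support is None for c in lattice.concepts):
        raise ValueError("run compute_support before filtering")
    out = [c for c in lattice.concepts if c.support > min_support]
    if intent_size is not None:
        out = [c for c in out if len(c.intent) == intent_size]
    return out


def fca_partition(
    partitions: Sequence[tuple[str, Partition]],
) -> tuple[FormalContext, ConceptLattice, Partition]:
    """Convenience: context -> concepts -> ordered lattice -> disjoint partition."""
    context = build_context(partitions)
    concepts = enumerate_concepts(context)
    lattice = order_lattice(concepts, context)
    compute_support(lattice, context)
    return context, lattice, disjoint_partition(lattice)
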