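import numpy as np
import pytest

from conftest import random_partition
from fcaclust import (
    build_context,
    compute_support,
    derive,
    disjoint_partition,
    enumerate_concepts,
    fca_partition,
    filter_concepts,
    order_lattice,
)
from fcaclust.containers import Partition
from fcaclust.fca import ClusterAttribute, FormalContext
from oracles import brute_force_concepts


def make_context(incidence, groups=None):
    incidence = np.asarray(incidence, dtype=bool)
    n, k = incidence.shape
    if groups is None:
        groups = [f"grp{j}" for j in range(k)]  # one group per attribute
    attrs = [ClusterAttribute(global_id=j, group=groups[j], local_index=0) for j in range(k)]
    return FormalContext([f"g{i + 1}" for i in range(n)], attrs, incidence)


def random_context(rng, max_obj=12, max_attr=8):
    """Random context whose per-group columns are mutually exclusive."""
    n = int(rng.integers(1, max_obj + 1))
    k = int(rng.integers(1, max_attr + 1))
    incidence = rng.random((n, k)) < rng.uniform(0.2, 0.8)
    return make_context(incidence)


@pytest.fixture
def worked_example():
    """g1:{C1}, g2:{C1,C2}, g3:{C2}, g4:{C3} with 6 concepts."""
    return make_context([[1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1]])


class TestEnumerateConcepts:
    def test_worked_example_concepts(self, worked_example):
        concepts = enumerate_concepts(worked_example)
        got = {(c.extent, c.intent) for c in concepts}
        expected = {
            (frozenset({"g1", "g2", "g3", "g4"}), frozenset()),
            (frozenset({"g1", "g2"}), frozenset({0})),
            (frozenset({"g2", "g3"}), frozenset({1})),
            (frozenset({"g2"}), frozenset({0, 1})),
            (frozenset({"g4"}), frozenset({2})),
            (frozenset(), frozenset({0, 1, 2})),
        }
        assert got == expected

    def test_full_context_has_single_concept(self):
        concepts = enumerate_concepts(make_context(np.ones((4, 3))))
        assert len(concepts) == 1

    def test_empty_incidence_has_top_and_bottom(self):
        concepts = enumerate_concepts(make_context(np.zeros((3, 2))))
        assert len(concepts) == 2
        extents = {c.extent for c in concepts}
        assert frozenset() in extents and frozenset({"g1", "g2", "g3"}) in extents

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_closure_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ctx = random_context(rng)
        concepts = enumerate_concepts(ctx)
        got = {
            (frozenset(ctx.gene_ids.index(g) for g in c.extent),
             frozenset(sorted(c.intent)))
            for c in concepts
        }
        assert got == brute_force_concepts(ctx.incidence)
        assert len(concepts) == len(got)  # no duplicates
        ranks = [c.lectic_rank for c in concepts]
        assert ranks == sorted(ranks)

    def test_cell_guard(self, monkeypatch):
        import fcaclust.fca as fca_mod

        monkeypatch.setattr(fca_mod, "MAX_CONTEXT_CELLS", 5)
        with pytest.raises(ValueError, match="guard"):
            make_context(np.zeros((3, 2)))


class TestDerive:
    def test_empty_cluster_set_derives_all_genes(self, worked_example):
        assert derive(worked_example, clusters=[]) == {"g1", "g2", "g3", "g4"}

    def test_single_gene_derives_membership_set(self, worked_example):
        assert derive(worked_example, genes=["g2"]) == {0, 1}

    @pytest.mark.parametrize("seed", range(10))
    def test_double_derivation_is_a_closure(self, seed):
        rng = np.random.default_rng(seed)
        ctx = random_context(rng, max_obj=8, max_attr=6)
        genes = list(rng.choice(ctx.gene_ids, size=min(3, ctx.n_genes), replace=False))
        closure = derive(ctx, clusters=derive(ctx, genes=genes))
        assert set(genes) <= closure
        again = derive(ctx, clusters=derive(ctx, genes=sorted(closure)))
        assert again == closure


class TestLatticeOrder:
    def test_worked_example_order(self, worked_example):
        concepts = enumerate_concepts(worked_example)
        lattice = order_lattice(concepts, worked_example)
        by_intent = {c.intent: i for i, c in enumerate(concepts)}
        top = lattice.concepts[lattice.top_index]
        bottom = lattice.concepts[lattice.bottom_index]
        assert top.intent == frozenset() and len(top.extent) == 4
        assert bottom.extent == frozenset() and bottom.intent == frozenset({0, 1, 2})
        assert (by_intent[frozenset({0, 1})], by_intent[frozenset({0})]) in lattice.order

    def test_extent_inclusion_iff_reverse_intent_inclusion(self):
        rng = np.random.default_rng(5)
        ctx = random_context(rng)
        lattice = order_lattice(enumerate_concepts(ctx), ctx)
        for a in lattice.concepts:
            for b in lattice.concepts:
                assert (a.extent <= b.extent) == (b.intent <= a.intent)

    @pytest.mark.parametrize("seed", range(5))
    def test_meets_and_joins_exist(self, seed):
        rng = np.random.default_rng(seed)
        ctx = random_context(rng, max_obj=7, max_attr=5)
        lattice = order_lattice(enumerate_concepts(ctx), ctx)
        extents = [c.extent for c in lattice.concepts]
        for a in extents:
            for b in extents:
                lower = [e for e in extents if e <= a and e <= b]
                upper = [e for e in extents if e >= a and e >= b]
                meet = max(lower, key=len)
                join = min(upper, key=len)
                assert all(e <= meet for e in lower)   # unique greatest lower bound
                assert all(join <= e for e in upper)   # unique least upper bound

    def test_hasse_edges_are_transitive_reduction(self, worked_example):
        lattice = order_lattice(enumerate_concepts(worked_example), worked_example)
        assert set(lattice.hasse_edges) <= set(lattice.order)
        # top covers exactly the three attribute concepts in this example
        incoming_top = [e for e in lattice.hasse_edges if e[1] == lattice.top_index]
        assert len(incoming_top) == 3


class TestSupportAndPartition:
    def test_worked_example_supports(self, worked_example):
        concepts = enumerate_concepts(worked_example)
        lattice = compute_support(order_lattice(concepts, worked_example), worked_example)
        by_intent = {c.intent: c for c in lattice.concepts}
        assert by_intent[frozenset()].support == 0.0
        assert by_intent[frozenset({0, 1, 2})].support == 0.0
        for intent in ({0}, {1}, {0, 1}, {2}):
            assert by_intent[frozenset(intent)].support == pytest.approx(0.25)

    def test_worked_example_partition_is_four_singletons(self, worked_example):
        _, lattice, part = fca_partition_from_context(worked_example)
        assert part.k == 4
        assert sorted(np.bincount(part.labels).tolist()) == [1, 1, 1, 1]

    @pytest.mark.parametrize("seed", range(15))
    def test_supports_sum_to_one_and_blocks_cover(self, seed):
        rng = np.random.default_rng(seed)
        ctx = random_context(rng)
        _, lattice, part = fca_partition_from_context(ctx)
        assert sum(c.support for c in lattice.concepts) == pytest.approx(1.0)
        own = [c.own_extent for c in lattice.concepts if c.own_extent]
        assert sum(len(o) for o in own) == ctx.n_genes     # coverage
        union = set().union(*own) if own else set()
        assert union == set(ctx.gene_ids)                  # disjoint + cover
        assert part.n_genes == ctx.n_genes
        distinct = {tuple(row.tolist()) for row in ctx.incidence}
        assert part.k == len(distinct)

    def test_identical_membership_sets_share_a_block(self):
        ctx = make_context([[1, 0], [1, 0], [0, 1]])
        _, _, part = fca_partition_from_context(ctx)
        labels = part.label_of()
        assert labels["g1"] == labels["g2"] != labels["g3"]


class TestBuildContext:
    def _partitions(self, rng, shared_genes, ks):
        return [
            (f"group{i}", random_partition(rng, shared_genes, k))
            for i, k in enumerate(ks)
        ]

    def test_attribute_count_is_sum_of_ks(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        ctx = build_context(self._partitions(rng, genes, (4, 6, 5)))
        assert ctx.n_clusters == 15
        # contiguous offset numbering per group
        assert [a.global_id for a in ctx.attributes] == list(range(15))
        assert {a.group for a in ctx.attributes[:4]} == {"group0"}
        assert {a.group for a in ctx.attributes[4:10]} == {"group1"}

    def test_incidence_one_cell_per_covering_group(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(10)]
        parts = self._partitions(rng, genes, (3, 4, 2))
        ctx = build_context(parts)
        assert np.all(ctx.incidence.sum(axis=1) == 3)
        partial = [("only", random_partition(rng, genes[:4], 2))] + parts[:1]
        ctx2 = build_context(partial)
        row = ctx2.gene_ids.index(genes[5])  # absent from the first group
        assert ctx2.incidence[row].sum() == 1

    def test_duplicate_group_names_rejected(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(6)]
        parts = [("g", random_partition(rng, genes, 2)), ("g", random_partition(rng, genes, 2))]
        with pytest.raises(ValueError, match="duplicate group"):
            build_context(parts)

    @pytest.mark.parametrize("seed", range(10))
    def test_positive_concepts_have_one_cluster_per_covering_group(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(25)]
        subsets = [genes, genes[:20], genes[5:]]
        parts = [
            (f"grp{i}", random_partition(rng, subset, int(rng.integers(2, 5))))
            for i, subset in enumerate(subsets)
        ]
        ctx, lattice, part = fca_partition(parts)
        group_of = {a.global_id: a.group for a in ctx.attributes}
        covered_by = {name: set(p.gene_ids) for name, p in parts}
        for concept in lattice.positive_concepts():
            per_group = {}
            for cid in concept.intent:
                per_group.setdefault(group_of[cid], []).append(cid)
            assert all(len(v) == 1 for v in per_group.values())
            g = next(iter(concept.own_extent))
            covering = {name for name, members in covered_by.items() if g in members}
            assert set(per_group) == covering

    def test_final_partition_refines_each_group_partition(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        parts = self._partitions(rng, genes, (3, 4))
        _, _, final = fca_partition(parts)
        for _, gp in parts:
            labels = gp.label_of()
            for block in final.as_sets():
                covered = {labels[g] for g in block if g in labels}
                assert len(covered) <= 1  # every block maps into one cluster


class TestFilterConcepts:
    def test_intent_size_selects_one_cluster_per_group(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        parts = [(f"grp{i}", random_partition(rng, genes, k)) for i, k in enumerate((3, 4, 3))]
        ctx, lattice, _ = fca_partition(parts)
        group_of = {a.global_id: a.group for a in ctx.attributes}
        picked = filter_concepts(lattice, min_support=0.03, intent_size=3)
        assert picked  # shared gene set -> every object concept has 3 clusters
        for c in picked:
            assert len({group_of[cid] for cid in c.intent}) == 3

    def test_support_bounds(self, worked_example):
        _, lattice, _ = fca_partition_from_context(worked_example)
        assert len(filter_concepts(lattice, min_support=0.0)) == 4
        assert filter_concepts(lattice, min_support=1.0) == []


def fca_partition_from_context(ctx):
    concepts = enumerate_concepts(ctx)
    lattice = compute_support(order_lattice(concepts, ctx), ctx)
    return ctx, lattice, disjoint_partition(lattice)


def test_exports_smoke(tmp_path, worked_example):
    _, lattice, _ = fca_partition_from_context(worked_example)
    lattice.to_json_lines(tmp_path / "lat.jsonl")
    lattice.to_dot(tmp_path / "lat.dot")
    worked_example.to_tsv(tmp_path / "ctx.tsv")
    assert len((tmp_path / "lat.jsonl").read_text().strip().split("\n")) == 6
    assert (tmp_path / "lat.dot").read_text().startswith("digraph")
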