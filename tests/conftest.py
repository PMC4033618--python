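import numpy as np
import pytest

from fcaclust import ExpressionMatrix, Partition, SyntheticSpec, generate_compendium


@pytest.fixture
def four_points_matrix() -> ExpressionMatrix:
    """Four 1-D genes {0, 1, 10, 11} (padded with a zero column)."""
    return ExpressionMatrix(
        gene_ids=["a", "b", "c", "d"],
        condition_labels=["t0", "t1"],
        values=np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [11.0, 0.0]]),
    )


@pytest.fixture
def paired_partition() -> Partition:
    """{a,b} vs {c,d} over the four-points matrix."""
    return Partition(["a", "b", "c", "d"], np.array([0, 0, 1, 1]), k=2)


@pytest.fixture
def crossed_partition() -> Partition:
    """{a,c} vs {b,d} over the four-points matrix."""
    return Partition(["a", "b", "c", "d"], np.array([0, 1, 0, 1]), k=2)


def random_matrix(rng: np.random.Generator, m: int, n: int, name: str = "rand") -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(m)],
        condition_labels=[f"t{j}" for j in range(n)],
        values=rng.normal(size=(m, n)),
        name=name,
    )


def random_partition(rng: np.random.Generator, gene_ids: list, k: int) -> Partition:
    labels = rng.integers(0, k, size=len(gene_ids))
    labels[: min(k, len(gene_ids))] = np.arange(min(k, len(gene_ids)))  # no empty cluster
    return Partition(list(gene_ids), labels, k=k)


@pytest.fixture
def small_planted():
    """One group, four well-separated planted clusters, light noise."""
    spec = SyntheticSpec(
        n_groups=1,
        experiments_per_group=(2,),
        k_per_group=(4,),
        n_genes=80,
        genes_per_group=(80,),
        timepoints_range=(12, 12),
        noise_sd=0.05,
        missing_rate=0.0,
        seed=11,
    )
    return generate_compendium(spec)


@pytest.fixture
def paper_like():
    """The full three-group compendium with planted truth."""
    from fcaclust import default_paper_like_spec

    spec = default_paper_like_spec(seed=5)
    return generate_compendium(spec)


def truth_partition(truth, group_name: str, gene_ids: list) -> Partition:
    labels = truth.group_partition_labels(group_name, gene_ids)
    return Partition(list(gene_ids), labels, k=int(labels.max()) + 1)
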