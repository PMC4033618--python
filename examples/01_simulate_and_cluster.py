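"""Generate a small planted compendium and recover its clusters with k-means.

Builds one group of two cell-cycle-like time courses with four planted
phase clusters, runs k-means at the true k, and scores the recovery.
"""

from fcaclust import SyntheticSpec, adjusted_rand, generate_compendium, kpartition
from fcaclust.containers import Partition

spec = SyntheticSpec(
    n_groups=1, experiments_per_group=(2,), k_per_group=(4,),
    n_genes=120, genes_per_group=(120,), timepoints_range=(12, 12),
    noise_sd=0.05, missing_rate=0.0, seed=42,
)
groups, truth = generate_compendium(spec)
matrix = groups[0].matrices[0]
print(f"experiment {matrix.name}: {matrix.n_genes} genes x {matrix.n_conditions} time points")

part = kpartition(matrix, k=4, seed=0)
labels = truth.group_partition_labels(groups[0].name, matrix.gene_ids)
planted = Partition(matrix.gene_ids, labels, k=4)
ari = adjusted_rand(part, planted)

print(f"k-means objective (SSE): {part.objective:.3f}")
print(f"adjusted Rand index vs planted truth: {ari:.3f}")
print("ARI 1.0 means the four planted phase clusters were recovered exactly",
      "(up to label order); the small objective reflects only the sigma=0.05 noise.")
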