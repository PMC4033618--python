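# Methods

`fcaclust` derives a single disjoint gene partition from a compendium of
related expression experiments in three steps: (1) the experiments are
divided into groups of related datasets (e.g. by synchronization method
in cell-cycle time courses) and preprocessed; (2) a consensus clustering
engine reduces each group to one gene partition; (3) the group
partitions are pooled into a binary gene x cluster context whose concept
lattice yields the final partition over *all* genes of the compendium,
including genes observed in only some groups.

## Preprocessing

* **Missing-value filter.** A gene row is dropped when *strictly more*
  than `max_missing_frac` (default 0.25) of its entries are missing; a
  row at exactly the threshold is kept. The filter is idempotent.
* **Imputation.** Remaining gaps are filled by linear interpolation
  along the time axis (flat extension at the row edges), or by the row
  mean. Both are simple deterministic rules chosen because the inputs
  are short time courses; observed values are never altered.
* **Gene intersection.** Within a group, every matrix is restricted to
  the genes present in all of the group's matrices, in the order of the
  first matrix. Across groups no restriction is applied — that is the
  point of the concept-analysis step.
* **Standardization and quality weights.** A gene row is *standardized*
  when its sample standard deviation exceeds `eps` (default 1e-12), in
  which case it is z-scored; near-constant rows are mean-centered only.
  The count of standardized genes is the experiment's quality score;
  within a group the scores are normalized to weights summing to 1.
  The `sd > eps` criterion is this package's concrete definition of a
  "standardizable" profile; it makes the quality weight computable and
  testable.

## Base partitioning

Three center-based methods share one assign/recompute loop that stops
when the labelling is stable (or after `max_iter = 100` iterations):

| method   | center               | distance & objective |
|----------|----------------------|----------------------|
| `mean`   | per-dimension mean   | squared Euclidean    |
| `median` | per-dimension median | Manhattan (L1)       |
| `medoid` | most central member  | Euclidean            |

Each center rule is paired with the distance it actually minimizes.
This matters for the descent guarantee: the per-dimension median is the
L1 minimizer, not the Euclidean one, and pairing it with a Euclidean
objective produces non-monotone runs (observed in roughly a quarter of
random trials). With the pairings above, the recorded per-iteration
objective is provably non-increasing — for medoids because a medoid is
always a member of its own cluster after reassignment (distance 0 to
itself), so re-selecting the best member can only lower the
within-cluster distance sum.

* **Initialization.** Default is a farthest-first traversal (maximin)
  from a seeded random start, with `n_init = 3` restarts keeping the
  lowest objective. Uniform random seeding is available (`init=
  "random"`) but covers `k` well-separated clusters only with
  probability `k!/k^k` (about 9% at k=4), which makes it unreliable for
  recovering planted structure; farthest-first seeds every
  well-separated cluster by construction. D²-sampled seeding
  (k-means++) is deliberately not implemented.
* **Empty clusters** are re-seeded with the point farthest from its
  currently assigned centroid — deterministic, keeps `k` fixed, and
  does not disturb the objective trace (an empty cluster owns no
  points).
* **Ties** in assignment go to the lowest centroid index; all
  randomness flows through a single integer seed, so equal seeds give
  bitwise-equal partitions.

## Validation indices and choosing k

* **Connectivity** penalizes nearest neighbours split across clusters:
  for each gene `i` and its `j`-th nearest neighbour (Euclidean,
  `j = 1..L`, distance ties to the lower row index), a penalty `1/j`
  accrues when the neighbour is not co-clustered. Range `[0, inf)`,
  lower is better. The neighbourhood size `L` (default 10) is an
  explicit parameter: summing over as many neighbours as there are
  array conditions would tie the index to the column count rather than
  to a neighbourhood of genes, so a standard neighbour-count parameter
  is used instead.
* **Silhouette Index** is the mean of `(b_i - a_i)/max(a_i, b_i)` with
  `a_i` the average distance to co-cluster members and `b_i` the best
  average distance to another cluster; genes in singleton clusters
  contribute 0 (the usual convention; `a_i` is undefined there). Range
  `[-1, 1]`, higher is better.
* **Elbow rule.** Scanning `k = 2..10`, the selected k maximizes the
  discrete second difference of Connectivity,
  `(v(k-1) - v(k)) - (v(k) - v(k+1))`, ties to the smallest k. This is
  a deterministic, parameter-free reading of "the sharpest local change
  of the index". Single-experiment elbows are noisy (on planted data
  the rule finds the true k in roughly 85% of draws); the per-group
  cluster count is therefore the *prevailing* (modal, ties to
  smallest) optimum across the group's experiments.

## PSO-based consensus engine

One particle per experiment: a `k x n_i` centroid matrix in the
experiment's own condition space (`n_i` may differ between particles),
initialized by k-means on that experiment with zero velocities, and the
personal best set to this initial solution. Each sweep: genes are
assigned to the nearest centroids, the sum-of-squared-errors fitness is
evaluated on the particle's own matrix, personal bests are updated
(strictly-lower replacement), the global best is the minimum personal
best (ties to the lowest particle index), and velocities are updated as

    v <- w v + c1 phi1 (pbest - c) + c2 phi2 g,
    g  = gbest[:, :n_i] - c   if n_g >= n_i,   else 0,

followed by the standard position update `c <- c + v`. Defaults
`w = 0.72`, `c1 = c2 = 1.49` are the classic good-convergence
constants; `max_iter = 50`. `phi1, phi2 ~ U[0, 1]` are drawn once per
particle update and shared across dimensions, which keeps single
updates reproducible and testable. Because the experiments have
different widths, the social pull is only applied when the global best
has at least the particle's dimensionality, truncating to the first
`n_i` coordinates when it is wider. The returned consensus is the gene
labelling of the global best at termination, whose fitness trace is
non-increasing by best-so-far bookkeeping. The SSE fitness, the
position update, the truncation rule and the choice of the global
best's labelling as the final answer are this package's concrete
design decisions for parts of the scheme that admit several readings.

## Integrative consensus engine

1. k-means on the column-wise concatenation of the group's matrices
   fixes a shared labelling; the concatenated centroids are split at
   the column boundaries into per-experiment seed blocks.
2. k-means on each experiment, seeded with its block.
3. Each per-experiment partition is relabelled to the shared labelling
   by optimal assignment (Hungarian method on the k x k contingency
   table), so aggregation is label-consistent.
4. The aligned one-hot indicator matrices are averaged with the quality
   weights into a soft partition (rows sum to 1).
5. Hard labels are the row-wise argmax; a tie means the weighted
   evidence genuinely splits between clusters — ties break
   deterministically to the lowest cluster index and the tied genes are
   counted and reported, since such genes are exactly what the concept
   analysis downstream is designed to handle. Indicator (one-hot)
   aggregation was chosen over co-membership aggregation; with aligned
   labels the two coincide at the argmax for the unanimous case and the
   indicator form keeps the weights' meaning transparent.

## Formal concept analysis step

The pooled context has the N compendium genes as objects and the
`K = k_1 + ... + k_r` group clusters as attributes, numbered
contiguously per group (e.g. 0-3 / 4-9 / 10-14 for three groups);
`(i, j)` is set when gene i is in cluster j. A concept is a
Galois-closed pair (extent, intent); concepts are enumerated with
Ganter's NextClosure algorithm in lectic order — deterministic,
duplicate-free, and memory-proportional to the output. An exhaustive
close-every-attribute-subset enumeration exists only in the test suite
as the independent oracle. A guard rejects contexts above 10^7 cells.

Every gene has an *object concept*: the concept whose intent equals the
gene's cluster-membership set (such intents are always closed). The
genes owning a concept form its **own extent**, and
`support = |own extent| / N`. Consequences, all asserted as invariants:
supports sum to 1; own extents are pairwise disjoint and cover all
genes; the positive-support concepts are in bijection with the distinct
membership sets and form the final disjoint partition (blocks ordered
by decreasing support, then lectic rank). Because each group's
clustering is a partition, a concept intent carries at most one cluster
per group, and the intent of an object concept has exactly one cluster
per group covering that gene — so with r groups over a shared gene set,
every block-defining concept combines exactly r clusters. The final
partition refines each group partition on the genes it covers.

The support definition above is the package's own: it is the one under
which "concepts with support 0" are precisely those that are no gene's
object concept, making `concepts - zero-support = blocks` an identity
the pipeline checks at run time.

## Cluster-consistency analysis

The overlap degree between clusters `c_i`, `c_j` is
`d_ij = 100 |c_i ∩ c_j| / max(|c_i|, |c_j|)`: 100 iff the sets are
equal, 0 iff disjoint. Overlap matrices are computed on the partitions'
common genes. Concept-correspondence tables score a pair of concepts
(one from each of two lattices) by the *minimum*, over the groups named
in both intents, of the overlap degree between the groups' member
clusters; pairs under the reporting threshold (default 20%) are
omitted. When contexts are not available the own-extents are compared
directly. The adjusted Rand index (closed-form contingency evaluation)
serves partition-level comparison; the scikit-learn implementation is
used in the tests as an independent cross-check, never as the
implementation.

## Synthetic compendium generator

The generator emulates a multi-group cell-cycle compendium. Each gene
carries a peak phase drawn uniformly on the cycle; a group with `k_g`
clusters uses `k_g` equally spaced prototype phases, and a gene's
planted label is the prototype nearest its phase — so a gene peaks
consistently across groups even though the groups cluster at different
resolutions. An experiment samples `n_i` equally spaced time points
over one period (`T = 150` time units, `n_i` drawn from 12..20) of the
prototype sinusoid and adds i.i.d. Gaussian noise. Defaults:

| parameter            | default           | why                              |
|----------------------|-------------------|----------------------------------|
| groups / experiments | 3 groups of 3/4/2 | mirrors a nine-time-course corpus with three synchronization protocols |
| clusters per group   | (4, 6, 5)         | 15 pooled clusters in the context |
| genes (union)        | 374               | with per-group common-gene counts (286, 350, 374) |
| noise sd             | 0.05              | small against the >= 1 inter-prototype distance; recovery is expected, the test is of the machinery |
| missing rate         | 0.02, capped at 25% per row | gaps survive preprocessing without changing the gene sets |

What the generator does **not** model: dye and array batch effects,
autocorrelated or heteroscedastic noise, non-periodic and unregulated
genes, amplitude variation, synchronization-decay across the time
course, and structured (non-uniform) missingness. Passing recovery
tests therefore demonstrates that the pipeline's machinery is correct
and internally consistent under controlled separability — not that the
engines would reach ARI 1 on real arrays, where cluster boundaries are
genuinely ambiguous.

## Numerical conventions and problem sizes

* All ties (assignment, argmax hardening, elbow, prevailing k, global
  best) break toward the lowest index, so every routine is a pure
  function of its seed.
* Float comparisons in invariants use 1e-9 absolute tolerance; weights
  sum to 1 within 1e-12; matrix round-trips serialize floats with
  `%.17g` and are exact.
* The test and acceptance suites run the full three-group compendium at
  its default size (374 genes, 9 experiments) — small enough to
  enumerate its ~50-concept lattice in milliseconds — and exercise the
  concept enumerator against the exhaustive oracle on hundreds of
  random contexts up to 12 objects x 8 attributes, the scale at which
  `2^K` closure enumeration is still instant.

## Known limitations

* The imputation methods are intentionally simple; profiles with long
  gaps in fast-changing regions are filled crudely.
* Connectivity is computed from the full pairwise distance matrix
  (O(m^2)); fine for compendium-scale gene sets, not for whole-genome
  matrices.
* The concept lattice grows with the number of distinct membership
  sets; with many groups of fine partitions the context guard will
  trigger before memory does.
* The PSO engine explores centroid space around the k-means initials;
  with the default constants it rarely escapes to qualitatively
  different optima on well-separated data, which is also why its
  global-best trace is flat in the noise-free examples.
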