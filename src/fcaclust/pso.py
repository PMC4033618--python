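"""Particle-swarm consensus clustering of one group of related experiments.

Each experiment of the group is one particle: a ``k x n_i`` matrix of
cluster centroids in that experiment's own condition space (experiments
may have different numbers of time points ``n_i``). Particles are
initialized by running k-means on their own matrix, with zero
velocities. Every sweep, each particle assigns its genes to the nearest
centroids, evaluates the sum-of-squared-errors fitness on its own
matrix, and updates its personal best; the global best is the best
personal best across the swarm. Velocities follow the standard update

    v <- w*v + c1*phi1*(pbest - c) + c2*phi2*g,

where the social pull ``g = gbest - c`` is only applied when the global
best lives in a space of at least the particle's dimensionality
(``n_g >= n_i``; the first ``n_i`` coordinates are used when
``n_g > n_i``) and is zero otherwise. ``phi1``/``phi2`` are drawn
uniformly from [0, 1] once per particle update and shared across
dimensions. The consensus partition returned is the gene labelling of
the global best at termination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .containers import ExpressionMatrix, Partition
from .partitioning import assign, kpartition

__all__ = ["PSOParams", "Particle", "GlobalBest", "PSOResult",
           "init_particles", "fitness", "update_velocity", "pso_consensus"]


@dataclass
class PSOParams:
    """Swarm hyper-parameters; the defaults give good convergence."""

    w: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    max_iter: int = 50
    seed: int = 0
    fitness: str = "sse"

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.2:
            raise ValueError("inertia weight w must lie in [0, 1.2]")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("acceleration constants must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.fitness != "sse":
            raise ValueError(f"unknown fitness {self.fitness!r}")


@dataclass
class Particle:
    """One experiment's candidate solution and its personal best."""

    centroids: np.ndarray          # k x n_i
    velocities: np.ndarray         # k x n_i
    pbest_centroids: np.ndarray
    pbest_fitness: float
    pbest_labels: np.ndarray

    def __post_init__(self) -> None:
        if self.velocities.shape != self.centroids.shape:
            raise ValueError("velocity shape must equal centroid shape")

    @property
    def n_dims(self) -> int:
        return self.centroids.shape[1]


@dataclass
class GlobalBest:
    centroids: np.ndarray
    n_dims: int
    fitness: float
    labels: np.ndarray
    particle_index: int


@dataclass
class PSOResult:
    partition: Partition
    gbest_trace: list[float] = field(default_factory=list)
    gbest_particle: int = -1


def fitness(matrix: ExpressionMatrix | np.ndarray, centroids: np.ndarray) -> float:
    """Sum over genes of squared Euclidean distance to the nearest centroid."""
    X = matrix.dense_values() if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, float)
    d = cdist(X, np.asarray(centroids, float), metric="sqeuclidean")
    return float(d.min(axis=1).sum())


def init_particles(
    group: list[ExpressionMatrix], k: int, seed: int = 0, **kpartition_kwargs
) -> list[Particle]:
    """k-means initialization of one particle per experiment, zero velocities."""
    if not group:
        raise ValueError("group must contain at least one matrix")
    genes = group[0].gene_ids
    for m in group[1:]:
        if m.gene_ids != genes:
            raise ValueError(
                "all matrices of the group must share the same gene set; "
                "run intersect_genes first"
            )
    child_seeds = np.random.SeedSequence(seed).generate_state(len(group))
    particles = []
    for mat, s in zip(group, child_seeds):
        part = kpartition(mat, k, method="mean", seed=int(s), **kpartition_kwargs)
        particles.append(
            Particle(
                centroids=part.centroids.copy(),
                velocities=np.zeros_like(part.centroids),
                pbest_centroids=part.centroids.copy(),
                pbest_fitness=float(part.objective),
                pbest_labels=np.asarray(part.labels).copy(),
            )
        )
    return particles


def update_velocity(
    particle: Particle,
    gbest: GlobalBest,
    params: PSOParams,
    rng: np.random.Generator | None = None,
    phi1: float | None = None,
    phi2: float | None = None,
) -> np.ndarray:
    """New velocity matrix for ``particle`` (not applied in place).

    ``phi1``/``phi2`` may be forced (e.g. for worked examples); otherwise
    they are drawn from ``rng`` uniformly on [0, 1], one pair per call.
    """
    if rng is None and (phi1 is None or phi2 is None):
        raise ValueError("provide an rng or force both phi values")
    if phi1 is None:
        phi1 = float(rng.random())
    if phi2 is None:
        phi2 = float(rng.random())
    n_i = particle.n_dims
    cognitive = particle.pbest_centroids - particle.centroids
    if gbest.n_dims >= n_i:
        social = gbest.centroids[:, :n_i] - particle.centroids
    else:
        social = np.zeros_like(particle.centroids)
    return (
        params.w * particle.velocities
        + params.c1 * phi1 * cognitive
        + params.c2 * phi2 * social
    )


def _global_best(particles: list[Particle]) -> GlobalBest:
    fits = [p.pbest_fitness for p in particles]
    i = int(np.argmin(fits))  # ties -> lowest particle index
    p = particles[i]
    return GlobalBest(
        centroids=p.pbest_centroids.copy(),
        n_dims=p.n_dims,
        fitness=p.pbest_fitness,
        labels=p.pbest_labels.copy(),
        particle_index=i,
    )


def pso_consensus(
    group: list[ExpressionMatrix],
    k: int,
    params: PSOParams | None = None,
    **kpartition_kwargs,
) -> PSOResult:
    """Run the swarm on a gene-intersected, imputed group of experiments.

    Returns the global-best gene labelling as the group consensus
    partition, together with the per-iteration global-best fitness trace
    (non-increasing by construction).
    """
    params = params or PSOParams()
    particles = init_particles(group, k, seed=params.seed, **kpartition_kwargs)
    data = [m.dense_values() for m in group]
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).generate_state(1)[0] ^ 0x5F5F)
    trace: list[float] = []
    gbest = _global_best(particles)
    for _ in range(params.max_iter):
        for p, X in zip(particles, data):
            labels = assign(X, p.centroids, metric="euclidean")
            fit = fitness(X, p.centroids)
            if fit < p.pbest_fitness:
                p.pbest_fitness = fit
                p.pbest_centroids = p.centroids.copy()
                p.pbest_labels = labels
        gbest = _global_best(particles)
        trace.append(gbest.fitness)
        for p in particles:
            p.velocities = update_velocity(p, gbest, params, rng=rng)
            p.centroids = p.centroids + p.velocities
    partition = Partition(
        gene_ids=list(group[0].gene_ids),
        labels=gbest.labels,
        k=k,
        centroids=gbest.centroids,
        objective=gbest.fitness,
    )
    return PSOResult(partition=partition, gbest_trace=trace, gbest_particle=gbest.particle_index)
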