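import numpy as np
import pytest

from conftest import random_matrix, truth_partition
from fcaclust import (
    PSOParams,
    adjusted_rand,
    fitness,
    init_particles,
    intersect_genes,
    kpartition,
    pso_consensus,
    update_velocity,
)
from fcaclust.pso import GlobalBest, Particle


def _one_d_particle(v=0.5, c=2.0, p=3.0):
    return Particle(
        centroids=np.array([[c]]),
        velocities=np.array([[v]]),
        pbest_centroids=np.array([[p]]),
        pbest_fitness=0.0,
        pbest_labels=np.array([0]),
    )


class TestParams:
    def test_defaults_are_convergent_constants(self):
        p = PSOParams()
        assert (p.w, p.c1, p.c2) == (0.72, 1.49, 1.49)

    def test_bounds(self):
        with pytest.raises(ValueError):
            PSOParams(w=1.5)
        with pytest.raises(ValueError):
            PSOParams(c1=-0.1)


class TestInitParticles:
    def test_one_particle_per_matrix_with_matching_shapes(self):
        rng = np.random.default_rng(0)
        group = [random_matrix(rng, 20, n, name=f"m{n}") for n in (3, 4, 2)]
        particles = init_particles(group, k=3, seed=1)
        assert [p.centroids.shape for p in particles] == [(3, 3), (3, 4), (3, 2)]

    def test_velocities_start_at_zero(self):
        rng = np.random.default_rng(1)
        group = [random_matrix(rng, 15, 4)]
        (p,) = init_particles(group, k=2, seed=0)
        assert not p.velocities.any()
        assert np.array_equal(p.pbest_centroids, p.centroids)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        group = [random_matrix(rng, 15, 4)]
        a = init_particles(group, k=3, seed=9)
        b = init_particles(group, k=3, seed=9)
        assert np.array_equal(a[0].centroids, b[0].centroids)

    def test_mismatched_gene_sets_rejected(self):
        rng = np.random.default_rng(3)
        m1 = random_matrix(rng, 10, 3)
        m2 = random_matrix(rng, 10, 3)
        m2.gene_ids = [g + "_x" for g in m2.gene_ids]
        with pytest.raises(ValueError, match="same gene set"):
            init_particles([m1, m2], k=2, seed=0)


class TestFitness:
    def test_sum_of_squared_distances(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert fitness(X, np.array([[0.5], [10.5]])) == pytest.approx(1.0)

    def test_zero_when_centroids_equal_points(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        assert fitness(X, X.copy()) == pytest.approx(0.0)

    def test_unused_far_centroid_changes_nothing(self):
        X = np.array([[0.0], [1.0]])
        near = np.array([[0.5]])
        padded = np.array([[0.5], [1000.0]])
        assert fitness(X, near) == fitness(X, padded)


class TestUpdateVelocity:
    def test_hand_computed_update_with_social_pull(self):
        gbest = GlobalBest(np.array([[4.0]]), n_dims=1, fitness=0.0,
                           labels=np.array([0]), particle_index=0)
        v = update_velocity(_one_d_particle(), gbest, PSOParams(), phi1=1.0, phi2=1.0)
        # 0.72*0.5 + 1.49*(3-2) + 1.49*(4-2)
        assert v[0, 0] == pytest.approx(4.83)

    def test_social_term_zero_when_gbest_is_narrower(self):
        gbest = GlobalBest(np.array([[4.0]]), n_dims=0, fitness=0.0,
                           labels=np.array([0]), particle_index=0)
        v = update_velocity(_one_d_particle(), gbest, PSOParams(), phi1=1.0, phi2=1.0)
        assert v[0, 0] == pytest.approx(1.85)

    def test_wider_gbest_is_truncated(self):
        particle = _one_d_particle(v=0.0, c=2.0, p=2.0)
        gbest = GlobalBest(np.array([[4.0, 99.0]]), n_dims=2, fitness=0.0,
                           labels=np.array([0]), particle_index=0)
        v = update_velocity(particle, gbest, PSOParams(), phi1=1.0, phi2=1.0)
        assert v[0, 0] == pytest.approx(1.49 * 2.0)

    def test_fixed_point(self):
        particle = _one_d_particle(v=0.0, c=2.0, p=2.0)
        gbest = GlobalBest(np.array([[2.0]]), n_dims=1, fitness=0.0,
                           labels=np.array([0]), particle_index=0)
        v = update_velocity(particle, gbest, PSOParams(), phi1=1.0, phi2=1.0)
        assert v[0, 0] == 0.0

    def test_requires_rng_or_forced_phis(self):
        gbest = GlobalBest(np.array([[2.0]]), 1, 0.0, np.array([0]), 0)
        with pytest.raises(ValueError, match="rng"):
            update_velocity(_one_d_particle(), gbest, PSOParams())


class TestPsoConsensus:
    @pytest.mark.parametrize("seed", range(5))
    def test_global_best_trace_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(25)]
        group = []
        for n in (3, 4):
            m = random_matrix(rng, 25, n)
            m.gene_ids = list(genes)
            group.append(m)
        result = pso_consensus(group, k=3, params=PSOParams(seed=seed, max_iter=20))
        trace = np.array(result.gbest_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_noise_free_group_recovers_planted_truth(self, small_planted):
        groups, truth = small_planted
        mats = intersect_genes(list(groups[0].matrices))
        result = pso_consensus(mats, k=4, params=PSOParams(seed=1))
        ref = truth_partition(truth, groups[0].name, result.partition.gene_ids)
        assert adjusted_rand(result.partition, ref) == pytest.approx(1.0)

    def test_zero_coefficients_freeze_the_swarm(self):
        rng = np.random.default_rng(7)
        group = [random_matrix(rng, 20, 3)]
        params = PSOParams(w=0.0, c1=0.0, c2=0.0, max_iter=5, seed=0)
        particles = init_particles(group, k=2, seed=0)
        frozen = particles[0].centroids.copy()
        result = pso_consensus(group, k=2, params=params)
        # the velocity update collapses to zero, so the k-means init is final
        assert result.gbest_trace[0] == result.gbest_trace[-1]
        part = kpartition(group[0], 2, seed=np.random.SeedSequence(0).generate_state(1)[0])
        assert np.array_equal(np.sort(frozen, axis=0), np.sort(part.centroids, axis=0))

    def test_single_particle_never_worse_than_kmeans_init(self):
        rng = np.random.default_rng(8)
        group = [random_matrix(rng, 30, 4)]
        params = PSOParams(c2=0.0, seed=3, max_iter=30)
        result = pso_consensus(group, k=3, params=params)
        init_fit = result.gbest_trace[0]
        assert result.gbest_trace[-1] <= init_fit + 1e-12

    def test_deterministic(self, small_planted):
        groups, _ = small_planted
        mats = intersect_genes(list(groups[0].matrices))
        a = pso_consensus(mats, k=4, params=PSOParams(seed=2))
        b = pso_consensus(mats, k=4, params=PSOParams(seed=2))
        assert np.array_equal(a.partition.labels, b.partition.labels)
        assert a.gbest_trace == b.gbest_trace
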