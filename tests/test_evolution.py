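"""Genetic-algorithm operators, fitness and the full evolutionary loop."""

import numpy as np
import pytest

import spikevo as sv
from spikevo.evolution import fitness_from_error, genome_to_synapses, network_output_times


@pytest.fixture(scope="module")
def iris_topology():
    return sv.NetworkShape(17, 12, 1)


class TestPopulation:
    def test_gene_count_matches_topology(self, iris_topology):
        rng = np.random.default_rng(0)
        pop = sv.init_population(iris_topology, sv.GAConfig(), rng)
        assert len(pop) == 100
        assert all(g.n_genes == 2 * (17 * 12 + 12 * 1) == 432 for g in pop)

    def test_initial_genes_within_bounds(self, iris_topology):
        pop = sv.init_population(iris_topology, sv.GAConfig(), np.random.default_rng(1))
        for g in pop:
            assert np.all((g.weights >= -0.25) & (g.weights <= 1.0))
            assert np.all((g.delays >= 1) & (g.delays <= 6))

    def test_same_seed_identical_population(self, iris_topology):
        a = sv.init_population(iris_topology, sv.GAConfig(), np.random.default_rng(9))
        b = sv.init_population(iris_topology, sv.GAConfig(), np.random.default_rng(9))
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.weights, gb.weights)
            np.testing.assert_array_equal(ga.delays, gb.delays)

    def test_genome_round_trips_to_synapse_matrices(self, iris_topology):
        g = sv.init_population(iris_topology, sv.GAConfig(pop_size=2), np.random.default_rng(2))[0]
        ih, ho = genome_to_synapses(g, iris_topology)
        assert ih.weights.shape == (17, 12) and ho.weights.shape == (12, 1)
        np.testing.assert_array_equal(
            np.concatenate([ih.weights.ravel(), ho.weights.ravel()]), g.weights
        )


class TestFitness:
    @pytest.mark.parametrize("e,f", [(0.0, 1.0), (1.0, 0.5), (0.5, 1 / 1.5)])
    def test_inverse_error_form(self, e, f):
        assert fitness_from_error(e) == pytest.approx(f)

    def test_half_sse_of_two_instances(self):
        # actual [11, 12] vs desired [11, 13]: SSE = 0.5*(0 + 1) = 0.5
        out = np.array([11.0, 12.0])
        desired = np.array([11.0, 13.0])
        sse = 0.5 * np.sum((out - desired) ** 2)
        assert sse == 0.5
        assert fitness_from_error(sse) == pytest.approx(1 / 1.5)

    def test_perfect_outputs_give_unit_fitness(self):
        # a network that cannot fire scores at the sentinel T; give it
        # target T so the error is exactly zero
        shape = sv.NetworkShape(2, 2, 1)
        genome = sv.Genome(np.zeros(shape.n_synapses), np.ones(shape.n_synapses))
        cfg = sv.LIFConfig()
        spikes = np.array([[0.0, 0.0]])
        rec = sv.evaluate_fitness(genome, spikes, np.array([cfg.t_total]), shape, cfg)
        assert rec.sse == 0.0 and rec.fitness == 1.0

    def test_silent_output_penalised_at_horizon(self):
        shape = sv.NetworkShape(2, 2, 1)
        genome = sv.Genome(np.zeros(shape.n_synapses), np.ones(shape.n_synapses))
        cfg = sv.LIFConfig()
        rec = sv.evaluate_fitness(genome, np.array([[0.0, 0.0]]), np.array([11.0]), shape, cfg)
        assert rec.sse == pytest.approx(0.5 * (cfg.t_total - 11.0) ** 2)

    def test_mse_is_dataset_size_invariant(self):
        shape = sv.NetworkShape(2, 2, 1)
        rng = np.random.default_rng(3)
        genome = sv.Genome(rng.uniform(-0.25, 1, shape.n_synapses), rng.integers(1, 7, shape.n_synapses))
        cfg = sv.LIFConfig()
        one = sv.evaluate_fitness(genome, np.array([[0.0, 1.0]]), np.array([12.0]), shape, cfg)
        three = sv.evaluate_fitness(
            genome, np.array([[0.0, 1.0]] * 3), np.array([12.0] * 3), shape, cfg
        )
        assert three.mse == pytest.approx(one.mse)
        assert three.sse == pytest.approx(3 * one.sse)


class TestSelection:
    def test_pair_of_two_with_distinct_fitness(self):
        # linear ranks (1, 2) => better parent drawn with probability 2/3
        rng = np.random.default_rng(0)
        draws = [sv.rank_select([0.2, 0.8], 1, rng)[0] for _ in range(6000)]
        flat = np.array(draws).ravel()
        assert np.mean(flat == 1) == pytest.approx(2 / 3, abs=0.03)

    def test_tied_fitness_ranked_by_index(self):
        rng = np.random.default_rng(1)
        draws = np.array([sv.rank_select([0.5, 0.5], 1, rng)[0] for _ in range(6000)]).ravel()
        # stable sort keeps index 0 as the worse rank
        assert np.mean(draws == 1) == pytest.approx(2 / 3, abs=0.03)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            sv.rank_select([], 1, np.random.default_rng(0))


class TestCrossoverAndMutation:
    def test_blend_children_between_parents(self):
        rng = np.random.default_rng(4)
        p1 = np.array([0.5, -0.2, 0.9])
        p2 = np.array([0.3, 0.8, -0.1])
        for _ in range(50):
            c1, c2 = sv.arithmetic_crossover(p1, p2, rng)
            lo, hi = np.minimum(p1, p2), np.maximum(p1, p2)
            assert np.all(c1 >= lo - 1e-12) and np.all(c1 <= hi + 1e-12)
            assert np.all(c2 >= lo - 1e-12) and np.all(c2 <= hi + 1e-12)

    def test_blend_endpoints(self):
        class FixedRng:
            def __init__(self, values):
                self.values = iter(values)

            def uniform(self, size=None):
                return next(self.values)

        p1, p2 = np.array([0.5]), np.array([0.3])
        c1, c2 = sv.arithmetic_crossover(p1, p2, FixedRng([0.0, 1.0]))
        assert c1[0] == 0.5 and c2[0] == 0.5  # r1=0 -> c1=p1; r2=1 -> c2=p1
        c1, _ = sv.arithmetic_crossover(p1, p2, FixedRng([0.5, 0.5]))
        assert c1[0] == pytest.approx(0.4)

    def test_single_point_swap_all_cut_points(self):
        d1 = np.array([1, 2, 3, 4])
        d2 = np.array([5, 6, 7, 8])

        class CutRng:
            def __init__(self, cut):
                self.cut = cut

            def integers(self, lo, hi):
                assert lo == 1 and hi == 4
                return self.cut

        for cut in (1, 2, 3):
            c1, c2 = sv.single_point_crossover(d1, d2, CutRng(cut))
            np.testing.assert_array_equal(c1, np.concatenate([d1[:cut], d2[cut:]]))
            np.testing.assert_array_equal(c2, np.concatenate([d2[:cut], d1[cut:]]))
            np.testing.assert_array_equal(np.sort(np.concatenate([c1, c2])),
                                          np.sort(np.concatenate([d1, d2])))

    def test_identical_parents_identical_children(self):
        d = np.array([2, 4, 6])
        c1, c2 = sv.single_point_crossover(d, d, np.random.default_rng(0))
        np.testing.assert_array_equal(c1, d)
        np.testing.assert_array_equal(c2, d)

    def test_too_short_delay_vector_rejected(self):
        with pytest.raises(ValueError):
            sv.single_point_crossover(np.array([1]), np.array([2]), np.random.default_rng(0))

    def test_mutation_rate_zero_is_identity(self):
        genes = np.linspace(-0.25, 1, 10)
        out = sv.uniform_mutation(genes, (-0.25, 1.0), 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, genes)

    def test_mutation_rate_one_stays_in_bounds(self):
        rng = np.random.default_rng(1)
        out = sv.uniform_mutation(np.full(200, 5.0), (-0.25, 1.0), 1.0, rng)
        assert np.all((out >= -0.25) & (out <= 1.0))

    def test_integer_mutation_stays_integer_in_bounds(self):
        rng = np.random.default_rng(2)
        out = sv.uniform_mutation(np.full(200, 3), (1, 6), 1.0, rng, integer_mode=True)
        assert out.dtype.kind == "i"
        assert np.all((out >= 1) & (out <= 6))


@pytest.fixture(scope="module")
def short_run(two_class_dataset):
    model = sv.SpikingClassifier(
        two_class_dataset.features,
        two_class_dataset.labels,
        n_hidden=6,
        ga=sv.GAConfig(max_generations=15),
    )
    return model, model.fit(seed=5)


class TestEvolve:
    def test_best_fitness_non_decreasing(self, short_run):
        _, res = short_run
        assert np.all(np.diff(res.trace.best_fitness) >= -1e-12)

    def test_genes_stay_bounded_after_evolution(self, short_run):
        _, res = short_run
        g = res.genome
        assert np.all((g.weights >= -0.25) & (g.weights <= 1.0))
        assert np.all((g.delays >= 1) & (g.delays <= 6))

    def test_identical_seed_identical_trace(self, short_run):
        model, res = short_run
        again = model.fit(seed=5)
        np.testing.assert_array_equal(res.trace.best_fitness, again.trace.best_fitness)
        np.testing.assert_array_equal(res.trace.train_accuracy, again.trace.train_accuracy)
        np.testing.assert_array_equal(res.genome.weights, again.genome.weights)

    def test_trace_length_and_convergence_bounds(self, short_run):
        _, res = short_run
        assert len(res.trace.best_fitness) == 16  # init + 15 offspring generations
        assert 1 <= res.trace.convergence_generation <= 15

    def test_single_instance_target_reachable(self):
        # one training instance with a reachable target: near-perfect fitness
        ds = sv.make_synthetic(n_per_class=1, k_classes=2, n_features=2,
                               class_separation=4.0, noise_sd=0.5, seed=1)
        model = sv.SpikingClassifier(
            ds.features[:1], [ds.labels[0]], n_hidden=4,
            ga=sv.GAConfig(pop_size=60, max_generations=60),
        )
        res = model.fit(seed=2)
        assert res.trace.best_fitness[-1] > 0.99

    def test_elitism_carries_top_genomes_forward(self, two_class_dataset):
        from spikevo.evolution import _next_generation, evaluate_fitness

        model = sv.SpikingClassifier(two_class_dataset.features, two_class_dataset.labels,
                                     n_hidden=4, ga=sv.GAConfig(pop_size=12, max_generations=1))
        rng = np.random.default_rng(0)
        pop = sv.init_population(model.shape, model.ga, rng)[:12]
        targets = model.codebook.target_times(model.labels)
        for g in pop:
            g.fitness = evaluate_fitness(g, model.spike_matrix, targets, model.shape, model.lif).fitness
        cfg = sv.GAConfig(pop_size=12, elite_frac=0.25, max_generations=1)
        nxt = _next_generation(pop, cfg, rng)
        top = sorted(pop, key=lambda g: -g.fitness)[: cfg.n_elite]
        for elite, copied in zip(top, nxt[: cfg.n_elite]):
            np.testing.assert_array_equal(elite.weights, copied.weights)
            np.testing.assert_array_equal(elite.delays, copied.delays)
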