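"""Neuroevolution: genome operators, decoding, fitness, and the GA loop."""

import numpy as np
import pytest

from seroblot.cnn import prepare_tensors
from seroblot.deepga import (ConvGene, DeepGAConfig, Genome, GenomeBounds,
                             best_published_genome, crossover, decode, evolve,
                             fitness, mutate, random_genome)
from seroblot.nn import softmax
from seroblot.cnn import build_network

SMALL_BOUNDS = GenomeBounds(filters=(2, 8), kernels=(3, 5), neurons=(2, 16),
                            n_conv=(1, 3), n_dense=(1, 2))


def _ga_config(**overrides):
    defaults = dict(population_size=4, n_generations=3, tournament_size=2,
                    fitness_epochs=4, seed=2, bounds=SMALL_BOUNDS)
    defaults.update(overrides)
    return DeepGAConfig(**defaults)


class TestRandomGenome:
    def test_deterministic_under_seed(self):
        a = random_genome(SMALL_BOUNDS, np.random.default_rng(3))
        b = random_genome(SMALL_BOUNDS, np.random.default_rng(3))
        assert a == b

    def test_draws_respect_bounds_and_vary_in_length(self):
        rng = np.random.default_rng(0)
        lengths = set()
        for _ in range(1000):
            g = random_genome(SMALL_BOUNDS, rng)  # __post_init__ validates
            lengths.add(len(g.conv_genes))
        assert len(lengths) >= 2


class TestDecode:
    def test_published_genome_architecture(self):
        genome = best_published_genome()
        spec = decode(genome, (256, 256, 1), 3)
        assert len(spec.conv_blocks) == 4
        assert tuple(b.filters for b in spec.conv_blocks) == (5, 2, 6, 4)
        assert spec.dense_blocks == (8, 3)

    def test_minimal_genome_maps_one_to_one(self):
        g = Genome((ConvGene(4, 3, False),), (6,), SMALL_BOUNDS)
        spec = decode(g, (16, 16, 1), 2)
        assert len(spec.conv_blocks) == 1 and spec.dense_blocks == (6,)

    def test_decoded_forward_pass_is_simplex(self):
        rng = np.random.default_rng(1)
        spec = decode(best_published_genome(), (32, 32, 1), 3)
        net = build_network(spec, rng)
        probs = softmax(net.forward(
            rng.standard_normal((2, 1, 32, 32)).astype(np.float32)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_excess_pools_repaired_not_crashed(self):
        bounds = GenomeBounds(n_conv=(1, 6))
        conv = tuple(ConvGene(3, 3, True) for _ in range(6))
        g = Genome(conv, (4,), bounds)
        spec = decode(g, (8, 8, 1), 2)  # only 3 halvings fit an 8-pixel side
        assert sum(b.pool is not None for b in spec.conv_blocks) == 3
        assert "pools_disabled=3" in spec.notes


class TestOperators:
    def test_identical_parents_give_identical_offspring(self):
        g = random_genome(SMALL_BOUNDS, np.random.default_rng(4))
        c1, c2 = crossover(g, g, np.random.default_rng(0), crossover_rate=1.0)
        assert c1 == g and c2 == g

    def test_zero_rate_copies_parents(self):
        rng = np.random.default_rng(5)
        a, b = (random_genome(SMALL_BOUNDS, rng) for _ in range(2))
        assert crossover(a, b, np.random.default_rng(0), 0.0) == (a, b)

    def test_offspring_genes_traceable_to_parents(self):
        rng = np.random.default_rng(6)
        a = Genome((ConvGene(2, 3, True), ConvGene(3, 5, False)), (4,),
                   SMALL_BOUNDS)
        b = Genome((ConvGene(5, 3, False), ConvGene(6, 5, True),
                    ConvGene(7, 3, True)), (8, 9), SMALL_BOUNDS)
        pool = set(a.conv_genes) | set(b.conv_genes)
        dense_pool = set(a.dense_genes) | set(b.dense_genes)
        for _ in range(50):
            for child in crossover(a, b, rng, 1.0):
                assert SMALL_BOUNDS.n_conv[0] <= len(child.conv_genes) <= \
                    SMALL_BOUNDS.n_conv[1]
                assert set(child.conv_genes) <= pool
                assert set(child.dense_genes) <= dense_pool

    def test_zero_mutation_rate_is_identity(self):
        g = random_genome(SMALL_BOUNDS, np.random.default_rng(7))
        assert mutate(g, np.random.default_rng(0), 0.0) == g

    def test_add_never_chosen_at_max_length(self):
        bounds = SMALL_BOUNDS
        conv = tuple(ConvGene(4, 3, False) for _ in range(bounds.n_conv[1]))
        dense = tuple(4 for _ in range(bounds.n_dense[1]))
        g = Genome(conv, dense, bounds)
        rng = np.random.default_rng(8)
        for _ in range(1000):
            m = mutate(g, rng, 1.0)
            assert len(m.conv_genes) <= bounds.n_conv[1]
            assert len(m.dense_genes) <= bounds.n_dense[1]

    def test_operators_closed_over_bounds(self):
        """Long chains of mutation/crossover never leave the gene bounds
        (validation runs inside Genome construction)."""
        rng = np.random.default_rng(9)
        pop = [random_genome(SMALL_BOUNDS, rng) for _ in range(6)]
        for _ in range(2000):
            i, j = rng.integers(0, len(pop), size=2)
            c1, c2 = crossover(pop[i], pop[j], rng, 0.7)
            pop[int(rng.integers(0, len(pop)))] = mutate(c1, rng, 0.5)
            pop[int(rng.integers(0, len(pop)))] = mutate(c2, rng, 0.5)


@pytest.fixture(scope="module")
def separable_dataset(separable_strips):
    return prepare_tensors(separable_strips, "gray", size=16)


class TestFitness:
    def test_deterministic_for_same_genome_and_seed(self, separable_dataset):
        g = Genome((ConvGene(4, 3, True),), (8,), SMALL_BOUNDS)
        cfg = _ga_config()
        assert fitness(g, separable_dataset, cfg) == \
            fitness(g, separable_dataset, cfg)

    def test_separable_fixture_scores_high(self, separable_dataset):
        g = Genome((ConvGene(4, 3, True),), (8,), SMALL_BOUNDS)
        assert fitness(g, separable_dataset, _ga_config()) >= 0.95

    def test_uninformative_images_score_chance_level(self):
        # identical inputs for all classes force a constant prediction
        x = np.zeros((30, 1, 8, 8), dtype=np.float32)
        labels = ["cancer"] * 10 + ["benign"] * 10 + ["healthy"] * 10
        g = Genome((ConvGene(2, 3, False),), (2,), SMALL_BOUNDS)
        fit = fitness(g, (x, labels), _ga_config(fitness_epochs=2))
        assert 0.15 <= fit <= 0.55


class TestEvolve:
    def test_zero_generations_returns_initial_best(self, separable_dataset):
        best, hist = evolve(separable_dataset, _ga_config(n_generations=0))
        assert len(hist.best_fitness) == 1
        assert best == hist.best_genomes[0]

    def test_elitism_makes_best_fitness_non_decreasing(self, separable_dataset):
        _, hist = evolve(separable_dataset, _ga_config())
        assert all(b >= a for a, b in zip(hist.best_fitness,
                                          hist.best_fitness[1:]))
        assert hist.best_fitness[-1] >= hist.best_fitness[0]

    def test_fully_deterministic_under_seed(self, separable_dataset):
        cfg = _ga_config()
        best1, hist1 = evolve(separable_dataset, cfg)
        best2, hist2 = evolve(separable_dataset, cfg)
        assert best1 == best2
        assert hist1.best_fitness == hist2.best_fitness
        assert hist1.mean_fitness == hist2.mean_fitness


def test_genome_json_round_trip():
    g = best_published_genome(kernel=5)
    assert Genome.from_json(g.to_json()) == g
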