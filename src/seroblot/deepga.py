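"""Genetic-algorithm neuroevolution of small CNN architectures.

A genome is a variable-length list of convolutional genes (filters, kernel
size, optional 2x2 pool) plus a list of fully connected widths; it decodes
to an :class:`~seroblot.cnn.ArchitectureSpec`.  Evolution is a generational
GA with tournament selection (size 4), one-point crossover (rate 0.7),
single-operation mutation (rate 0.5) and elitism, with short-training test
accuracy as the single-objective fitness (10 epochs in the study).

Study settings: population 20, 50 generations.  The best published
architecture (4 conv layers of 5, 2, 6, 4 filters and fully connected
layers of 8 and 3 neurons) is available canned via :func:`best_published_genome`.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .cnn import ArchitectureSpec, ConvBlock, build_network
from .metrics import HoldoutConfig, holdout_split

__all__ = [
    "ConvGene",
    "GenomeBounds",
    "Genome",
    "DeepGAConfig",
    "EvolutionHistory",
    "random_genome",
    "decode",
    "crossover",
    "mutate",
    "fitness",
    "evolve",
    "best_published_genome",
]


@dataclass(frozen=True)
class ConvGene:
    filters: int
    kernel: int
    pool: bool


@dataclass(frozen=True)
class GenomeBounds:
    filters: tuple[int, int] = (2, 64)
    kernels: tuple[int, ...] = (3, 5, 7, 9)
    neurons: tuple[int, int] = (2, 128)
    n_conv: tuple[int, int] = (1, 6)
    n_dense: tuple[int, int] = (1, 3)


@dataclass(frozen=True)
class Genome:
    conv_genes: tuple[ConvGene, ...]
    dense_genes: tuple[int, ...]
    bounds: GenomeBounds = field(default_factory=GenomeBounds)

    def __post_init__(self) -> None:
        b = self.bounds
        if not b.n_conv[0] <= len(self.conv_genes) <= b.n_conv[1]:
            raise ValueError("conv gene count out of bounds")
        if not b.n_dense[0] <= len(self.dense_genes) <= b.n_dense[1]:
            raise ValueError("dense gene count out of bounds")
        for g in self.conv_genes:
            if not b.filters[0] <= g.filters <= b.filters[1]:
                raise ValueError("filter count out of bounds")
            if g.kernel not in b.kernels:
                raise ValueError("kernel size out of bounds")
        for w in self.dense_genes:
            if not b.neurons[0] <= w <= b.neurons[1]:
                raise ValueError("dense width out of bounds")

    def key(self) -> tuple:
        return (tuple((g.filters, g.kernel, g.pool) for g in self.conv_genes),
                self.dense_genes)

    def to_json(self) -> str:
        return json.dumps({
            "conv_genes": [asdict(g) for g in self.conv_genes],
            "dense_genes": list(self.dense_genes),
        })

    @staticmethod
    def from_json(text: str, bounds: GenomeBounds | None = None) -> "Genome":
        raw = json.loads(text)
        return Genome(
            tuple(ConvGene(**g) for g in raw["conv_genes"]),
            tuple(raw["dense_genes"]),
            bounds or GenomeBounds(),
        )


@dataclass(frozen=True)
class DeepGAConfig:
    """Evolution settings (study defaults)."""

    population_size: int = 20
    n_generations: int = 50
    crossover_rate: float = 0.7
    mutation_rate: float = 0.5
    tournament_size: int = 4
    fitness_epochs: int = 10
    seed: int = 0
    elitism_count: int = 1
    train_fraction: float = 0.70
    batch_size: int = 16
    learning_rate: float = 1e-3
    bounds: GenomeBounds = field(default_factory=GenomeBounds)

    def __post_init__(self) -> None:
        if self.population_size < self.tournament_size:
            raise ValueError("population must be >= tournament size")
        for rate in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class EvolutionHistory:
    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_genomes: list[Genome] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "best_genomes": [json.loads(g.to_json())
                                 for g in self.best_genomes],
            }, fh, indent=2)


def random_genome(bounds: GenomeBounds, rng: np.random.Generator) -> Genome:
    """Uniform draws within the gene bounds."""
    n_conv = int(rng.integers(bounds.n_conv[0], bounds.n_conv[1] + 1))
    n_dense = int(rng.integers(bounds.n_dense[0], bounds.n_dense[1] + 1))
    conv = tuple(
        ConvGene(
            filters=int(rng.integers(bounds.filters[0], bounds.filters[1] + 1)),
            kernel=int(rng.choice(bounds.kernels)),
            pool=bool(rng.integers(0, 2)),
        )
        for _ in range(n_conv)
    )
    dense = tuple(
        int(rng.integers(bounds.neurons[0], bounds.neurons[1] + 1))
        for _ in range(n_dense)
    )
    return Genome(conv, dense, bounds)


def decode(genome: Genome, input_shape: tuple[int, int, int],
           n_classes: int) -> ArchitectureSpec:
    """Genome -> architecture; shape-unsafe pool flags are disabled.

    Conv genes map in order to same-padded batch-norm ReLU blocks with an
    optional 2x2 pool; a pool that would collapse a spatial dimension below
    one pixel is dropped and the repair recorded in the spec notes.
    """
    rows, cols = input_shape[0], input_shape[1]
    blocks = []
    repaired = 0
    for gene in genome.conv_genes:
        pool = None
        if gene.pool:
            if rows // 2 >= 1 and cols // 2 >= 1:
                pool = (2, 2)
                rows, cols = rows // 2, cols // 2
            else:
                repaired += 1
        blocks.append(ConvBlock(gene.filters, gene.kernel, pool=pool))
    notes = "deepga" if repaired == 0 else f"deepga;pools_disabled={repaired}"
    return ArchitectureSpec(input_shape, tuple(blocks), genome.dense_genes,
                            n_classes, notes=notes)


def _length_safe_cuts(la: int, lb: int, lo: int, hi: int,
                      rng: np.random.Generator) -> tuple[int, int]:
    valid = [(a, b) for a in range(la + 1) for b in range(lb + 1)
             if lo <= a + (lb - b) <= hi and lo <= b + (la - a) <= hi]
    return valid[int(rng.integers(0, len(valid)))]


def crossover(parent_a: Genome, parent_b: Genome,
              rng: np.random.Generator,
              crossover_rate: float = 0.7) -> tuple[Genome, Genome]:
    """With probability ``crossover_rate``, one-point crossover applied
    independently to the conv and dense gene lists; otherwise copies.

    Cut points are uniform over the pairs that keep both offspring lengths
    within bounds, so offspring are always valid genomes.
    """
    if rng.random() >= crossover_rate:
        return parent_a, parent_b
    b = parent_a.bounds
    ca, cb = list(parent_a.conv_genes), list(parent_b.conv_genes)
    i, j = _length_safe_cuts(len(ca), len(cb), *b.n_conv, rng)
    conv1, conv2 = tuple(ca[:i] + cb[j:]), tuple(cb[:j] + ca[i:])
    da, db = list(parent_a.dense_genes), list(parent_b.dense_genes)
    i, j = _length_safe_cuts(len(da), len(db), *b.n_dense, rng)
    dense1, dense2 = tuple(da[:i] + db[j:]), tuple(db[:j] + da[i:])
    return Genome(conv1, dense1, b), Genome(conv2, dense2, b)


def mutate(genome: Genome, rng: np.random.Generator,
           mutation_rate: float = 0.5) -> Genome:
    """With probability ``mutation_rate``, apply exactly one mutation chosen
    uniformly among the feasible operations: perturb one gene value, add a
    conv/dense gene (below max), remove one (above min), toggle a pool flag."""
    if rng.random() >= mutation_rate:
        return genome
    b = genome.bounds
    conv = list(genome.conv_genes)
    dense = list(genome.dense_genes)
    ops = ["perturb", "toggle_pool"]
    if len(conv) < b.n_conv[1] or len(dense) < b.n_dense[1]:
        ops.append("add")
    if len(conv) > b.n_conv[0] or len(dense) > b.n_dense[0]:
        ops.append("remove")
    op = ops[int(rng.integers(0, len(ops)))]
    if op == "perturb":
        # positions: conv filters, conv kernels, dense widths
        pos = int(rng.integers(0, 2 * len(conv) + len(dense)))
        if pos < len(conv):
            g = conv[pos]
            conv[pos] = ConvGene(
                int(rng.integers(b.filters[0], b.filters[1] + 1)), g.kernel, g.pool
            )
        elif pos < 2 * len(conv):
            g = conv[pos - len(conv)]
            conv[pos - len(conv)] = ConvGene(
                g.filters, int(rng.choice(b.kernels)), g.pool
            )
        else:
            dense[pos - 2 * len(conv)] = int(
                rng.integers(b.neurons[0], b.neurons[1] + 1)
            )
    elif op == "toggle_pool":
        pos = int(rng.integers(0, len(conv)))
        g = conv[pos]
        conv[pos] = ConvGene(g.filters, g.kernel, not g.pool)
    elif op == "add":
        targets = []
        if len(conv) < b.n_conv[1]:
            targets.append("conv")
        if len(dense) < b.n_dense[1]:
            targets.append("dense")
        target = targets[int(rng.integers(0, len(targets)))]
        if target == "conv":
            pos = int(rng.integers(0, len(conv) + 1))
            conv.insert(pos, ConvGene(
                int(rng.integers(b.filters[0], b.filters[1] + 1)),
                int(rng.choice(b.kernels)),
                bool(rng.integers(0, 2)),
            ))
        else:
            pos = int(rng.integers(0, len(dense) + 1))
            dense.insert(pos, int(rng.integers(b.neurons[0], b.neurons[1] + 1)))
    else:  # remove
        targets = []
        if len(conv) > b.n_conv[0]:
            targets.append("conv")
        if len(dense) > b.n_dense[0]:
            targets.append("dense")
        target = targets[int(rng.integers(0, len(targets)))]
        if target == "conv":
            conv.pop(int(rng.integers(0, len(conv))))
        else:
            dense.pop(int(rng.integers(0, len(dense))))
    return Genome(tuple(conv), tuple(dense), b)


def _genome_seed(genome: Genome, seed: int) -> int:
    return (zlib.crc32(genome.to_json().encode()) ^ (seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def fitness(genome: Genome, dataset: tuple[np.ndarray, list[str]],
            config: DeepGAConfig) -> float:
    """Short-training test accuracy of the decoded network, in [0, 1].

    One stratified 70/30 split derived from the config seed; network init
    and shuffling derive from (genome, seed), so the value is deterministic.
    A training failure logs a warning and scores 0.
    """
    x, labels = dataset
    class_list = sorted(set(labels), key=str)
    y = np.array([class_list.index(lab) for lab in labels])
    tr, te = holdout_split(
        labels,
        HoldoutConfig(train_fraction=config.train_fraction, n_runs=1,
                      seed=config.seed),
        run_index=0,
    )
    spec = decode(genome, (x.shape[2], x.shape[3], x.shape[1]), len(class_list))
    rng = np.random.default_rng(np.random.SeedSequence(_genome_seed(genome,
                                                                    config.seed)))
    net = build_network(spec, rng)
    try:
        nn.train_network(net, x[tr], y[tr], config.fitness_epochs, rng,
                         batch_size=config.batch_size, lr=config.learning_rate)
    except nn.TrainingFailure as exc:
        warnings.warn(f"fitness evaluation failed ({exc}); scoring 0")
        return 0.0
    return float((net.predict(x[te]) == y[te]).mean())


def _tournament(fits: list[float], rng: np.random.Generator, size: int) -> int:
    contenders = rng.choice(len(fits), size=size, replace=False)
    return int(max(contenders, key=lambda i: (fits[i], -i)))


def evolve(dataset: tuple[np.ndarray, list[str]],
           config: DeepGAConfig) -> tuple[Genome, EvolutionHistory]:
    """Generational GA over architectures; returns the best genome found.

    Each generation carries the ``elitism_count`` best genomes unchanged and
    fills the rest via tournament selection, crossover and mutation.  With
    elitism the best-fitness trajectory is non-decreasing.  Fitness values
    are cached per genome, and the whole run is deterministic under the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xDEE]))
    cache: dict[tuple, float] = {}

    def eval_genome(g: Genome) -> float:
        k = g.key()
        if k not in cache:
            cache[k] = fitness(g, dataset, config)
        return cache[k]

    population = [random_genome(config.bounds, rng)
                  for _ in range(config.population_size)]
    history = EvolutionHistory()

    def record(pop: list[Genome], fits: list[float]) -> None:
        best = int(np.argmax(fits))
        history.best_fitness.append(fits[best])
        history.mean_fitness.append(float(np.mean(fits)))
        history.best_genomes.append(pop[best])

    fits = [eval_genome(g) for g in population]
    record(population, fits)
    for _ in range(config.n_generations):
        elite_idx = sorted(range(len(fits)), key=lambda i: (-fits[i], i))
        next_pop = [population[i] for i in elite_idx[:config.elitism_count]]
        while len(next_pop) < config.population_size:
            pa = population[_tournament(fits, rng, config.tournament_size)]
            pb = population[_tournament(fits, rng, config.tournament_size)]
            for child in crossover(pa, pb, rng, config.crossover_rate):
                if len(next_pop) < config.population_size:
                    next_pop.append(mutate(child, rng, config.mutation_rate))
        population = next_pop
        fits = [eval_genome(g) for g in population]
        record(population, fits)
    best_overall = int(np.argmax(history.best_fitness))
    return history.best_genomes[best_overall], history


def best_published_genome(kernel: int = 3) -> Genome:
    """The best evolved architecture reported for this task, as a genome:
    conv filters (5, 2, 6, 4) and fully connected widths (8, 3).

    The published description does not state the kernel sizes ("filters of
    different sizes"); they default to 3 and are overridable.
    """
    conv = tuple(ConvGene(f, kernel, pool=True) for f in (5, 2, 6, 4))
    return Genome(conv, (8, 3))
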