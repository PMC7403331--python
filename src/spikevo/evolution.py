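"""Elitist real-coded genetic algorithm over synaptic weights and delays.

A genome is the flat parameter vector of the whole network: a real weight
gene and an integer delay gene for every synapse (M*N + N*P synapses, hence
2*(M*N + N*P) genes).  Fitness of a genome on the training set is

    f = 1 / (1 + e),      e = (1/n) * (1/2) * sum_i (t_out_i - t_target_i)^2

i.e. the mean over instances of the half squared error between the output
neuron's first-spike time and the class target time; instances whose output
neuron stays silent are scored at the simulation horizon T (the worst
legal spike time), which keeps the error finite.  Raw SSE is logged too.

Each generation the best ``elite_frac`` of the population is copied
unchanged (so best fitness never decreases); the remaining 80% of slots
are filled by linear rank selection of parents over the whole population,
hybrid crossover (arithmetic blending on weight genes, single-point swap
on delay genes, applied per pair with probability ``crossover_rate``) and
per-gene uniform mutation within the gene bounds (integer-valued for
delays).  Elite slots themselves are never crossed or mutated — elitism
protects the best genomes from replacement, while still letting them
breed; restricting parents to the non-elite remainder cuts the best
building blocks out of recombination and empirically stalls training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encoding import ClassCodebook, ConfigurationError
from .lif import LIFConfig, NetworkShape, SynapseSet, forward_pass_batch

__all__ = [
    "GAConfig",
    "Genome",
    "FitnessRecord",
    "TrainingTrace",
    "fitness_from_error",
    "init_population",
    "genome_to_synapses",
    "network_output_times",
    "evaluate_fitness",
    "rank_select",
    "arithmetic_crossover",
    "single_point_crossover",
    "uniform_mutation",
    "evolve",
]


@dataclass(frozen=True)
class GAConfig:
    """Hyper-parameters of the evolutionary trainer.

    pop_size        : population size (default 100)
    elite_frac      : fraction copied unchanged each generation (default 0.2)
    crossover_rate  : probability a selected pair is actually crossed (default 0.8)
    mutation_rate   : per-gene replacement probability (default 0.1)
    max_generations : number of offspring generations (default 1000)
    weight_bounds   : closed real interval for weight genes, default (-0.25, 1)
    delay_bounds    : inclusive integer interval for delay genes, default (1, 6)
    per_gene_crossover : draw the blending coefficients r1, r2 per gene
        instead of once per crossover event (default off).
    """

    pop_size: int = 100
    elite_frac: float = 0.2
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    max_generations: int = 1000
    weight_bounds: tuple = (-0.25, 1.0)
    delay_bounds: tuple = (1, 6)
    per_gene_crossover: bool = False

    def __post_init__(self):
        if self.pop_size < 2:
            raise ConfigurationError("pop_size must be at least 2")
        if not 0 < self.elite_frac < 1:
            raise ConfigurationError("elite_frac must lie in (0, 1)")
        if not 0 <= self.crossover_rate <= 1:
            raise ConfigurationError("crossover_rate must lie in [0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ConfigurationError("mutation_rate must lie in [0, 1]")
        if self.weight_bounds[0] >= self.weight_bounds[1]:
            raise ConfigurationError("weight bounds must be ordered")
        if self.delay_bounds[0] >= self.delay_bounds[1]:
            raise ConfigurationError("delay bounds must be ordered")

    @property
    def n_elite(self) -> int:
        return max(1, int(round(self.pop_size * self.elite_frac)))


@dataclass
class Genome:
    """Flat parameter vector: real weight genes + integer delay genes."""

    weights: np.ndarray
    delays: np.ndarray
    fitness: float | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.delays = np.asarray(self.delays, dtype=int)
        if self.weights.shape != self.delays.shape:
            raise ValueError("weight and delay gene vectors must have equal length")

    @property
    def n_genes(self) -> int:
        """Total gene count, weights plus delays."""
        return 2 * self.weights.size

    def copy(self) -> "Genome":
        return Genome(self.weights.copy(), self.delays.copy(), self.fitness)


@dataclass(frozen=True)
class FitnessRecord:
    """Error and fitness of one genome on a training set."""

    sse: float
    mse: float
    fitness: float


def fitness_from_error(e: float) -> float:
    """f = 1/(1+e): maps error 0 to fitness 1, monotone decreasing in e."""
    if e < 0:
        raise ValueError("error must be non-negative")
    return 1.0 / (1.0 + e)


def init_population(shape: NetworkShape, cfg: GAConfig, rng: np.random.Generator) -> list:
    """Random initial population.

    Weight genes ~ Uniform(weight_bounds); delay genes uniform integers on
    the inclusive delay_bounds.
    """
    lo_w, hi_w = cfg.weight_bounds
    lo_d, hi_d = cfg.delay_bounds
    n = shape.n_synapses
    return [
        Genome(
            weights=rng.uniform(lo_w, hi_w, size=n),
            delays=rng.integers(lo_d, hi_d + 1, size=n),
        )
        for _ in range(cfg.pop_size)
    ]


def genome_to_synapses(genome: Genome, shape: NetworkShape) -> tuple[SynapseSet, SynapseSet]:
    """Unflatten a genome into the two layers' (pre, post) matrices."""
    m, n, p = shape.n_input, shape.n_hidden, shape.n_output
    if genome.weights.size != shape.n_synapses:
        raise ValueError(
            f"genome has {genome.weights.size} synapses, topology needs {shape.n_synapses}"
        )
    w_ih = genome.weights[: m * n].reshape(m, n)
    w_ho = genome.weights[m * n :].reshape(n, p)
    d_ih = genome.delays[: m * n].reshape(m, n)
    d_ho = genome.delays[m * n :].reshape(n, p)
    return SynapseSet(w_ih, d_ih), SynapseSet(w_ho, d_ho)


def network_output_times(genome: Genome, spike_matrix: np.ndarray, shape: NetworkShape, lif_cfg: LIFConfig) -> np.ndarray:
    """Output-neuron first-spike time per instance (NaN where silent)."""
    ih, ho = genome_to_synapses(genome, shape)
    _, out = forward_pass_batch(spike_matrix, ih, ho, lif_cfg)
    return out


def evaluate_fitness(
    genome: Genome,
    spike_matrix: np.ndarray,
    target_times: np.ndarray,
    shape: NetworkShape,
    lif_cfg: LIFConfig,
) -> FitnessRecord:
    """Score a genome on encoded training data.

    Silent outputs are penalised with the sentinel time T before the error
    is computed, so fitness is always defined.  Selection uses the
    size-invariant MSE form of the error.
    """
    out = network_output_times(genome, spike_matrix, shape, lif_cfg)
    out = np.where(np.isfinite(out), out, lif_cfg.t_total)
    sse = 0.5 * float(np.sum((out - np.asarray(target_times, dtype=float)) ** 2))
    mse = sse / out.size
    return FitnessRecord(sse=sse, mse=mse, fitness=fitness_from_error(mse))


def rank_select(fitnesses, n_pairs: int, rng: np.random.Generator) -> list:
    """Draw parent pairs by linear rank from a fitness pool.

    The worst genome gets rank 1, the best rank n; selection probability
    is rank/sum(ranks).  Ties keep their original order (stable sort), so
    equal-fitness genomes are ranked by index.  Returns index pairs into
    the pool.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("cannot select parents from an empty pool")
    order = np.argsort(f, kind="stable")  # ascending: worst first
    ranks = np.empty(f.size)
    ranks[order] = np.arange(1, f.size + 1)
    p = ranks / ranks.sum()
    draws = rng.choice(f.size, size=2 * n_pairs, p=p)
    return [(int(draws[2 * k]), int(draws[2 * k + 1])) for k in range(n_pairs)]


def arithmetic_crossover(p1, p2, rng: np.random.Generator, per_gene: bool = False):
    """Blend two real gene vectors:

        c1 = p1 - r1*(p1 - p2),   c2 = p2 + r2*(p1 - p2),

    r1, r2 ~ Uniform[0, 1] drawn once per crossover event (or per gene).
    Children always lie in the per-gene interval spanned by the parents,
    so bounded parents yield bounded children.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("parent vectors must have equal length")
    size = p1.shape if per_gene else None
    r1 = rng.uniform(size=size)
    r2 = rng.uniform(size=size)
    diff = p1 - p2
    return p1 - r1 * diff, p2 + r2 * diff


def single_point_crossover(d1, d2, rng: np.random.Generator):
    """Swap tails of two integer gene vectors at a uniform cut in {1..len-1}."""
    d1 = np.asarray(d1)
    d2 = np.asarray(d2)
    if d1.shape != d2.shape:
        raise ValueError("parent vectors must have equal length")
    if d1.size < 2:
        raise ValueError("single-point crossover needs at least 2 genes")
    cut = int(rng.integers(1, d1.size))
    c1 = np.concatenate([d1[:cut], d2[cut:]])
    c2 = np.concatenate([d2[:cut], d1[cut:]])
    return c1, c2


def uniform_mutation(genes, bounds, rate: float, rng: np.random.Generator, integer_mode: bool = False):
    """Replace each gene, independently with probability ``rate``, by a
    uniform draw lb + r3*(ub - lb); in integer mode the replacement is a
    uniform integer on the inclusive bounds."""
    lb, ub = bounds
    if lb >= ub:
        raise ValueError("bounds must be ordered")
    if not 0 <= rate <= 1:
        raise ValueError("mutation rate must lie in [0, 1]")
    genes = np.asarray(genes).copy()
    mask = rng.uniform(size=genes.size) < rate
    k = int(mask.sum())
    if k:
        if integer_mode:
            genes[mask] = rng.integers(int(lb), int(ub) + 1, size=k)
        else:
            genes[mask] = lb + rng.uniform(size=k) * (ub - lb)
    return genes


@dataclass
class TrainingTrace:
    """Per-generation log of an evolutionary run.

    Row 0 is the random initial population; rows 1..max_generations are
    offspring generations.  Elitism makes ``best_fitness`` non-decreasing.
    """

    best_fitness: np.ndarray
    mean_fitness: np.ndarray
    best_sse: np.ndarray
    train_accuracy: np.ndarray
    best_genome: Genome
    seed: int | None = None

    @property
    def n_generations(self) -> int:
        return len(self.best_fitness) - 1

    @property
    def convergence_generation(self) -> int:
        """Last generation with a strict improvement in best-genome training
        accuracy (at least 1, since the efficiency metric divides by it)."""
        acc = np.asarray(self.train_accuracy)
        best_so_far = np.maximum.accumulate(acc)
        improved = np.flatnonzero(acc > np.concatenate([[-np.inf], best_so_far[:-1]]))
        g = int(improved[-1]) if improved.size else 0
        return max(g, 1)

    @property
    def final_train_accuracy(self) -> float:
        return float(self.train_accuracy[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.best_fitness)),
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "best_sse": self.best_sse,
                "train_accuracy": self.train_accuracy,
            }
        )


def _next_generation(population: list, cfg: GAConfig, rng: np.random.Generator) -> list:
    """One generational step: elitist copy + rank-selected, crossed, mutated offspring."""
    order = np.argsort([-g.fitness for g in population], kind="stable")
    elites = [population[i].copy() for i in order[: cfg.n_elite]]
    pool = list(population)
    pool_fitness = [g.fitness for g in pool]

    offspring: list = []
    need = cfg.pop_size - len(elites)
    while len(offspring) < need:
        (i, j) = rank_select(pool_fitness, 1, rng)[0]
        p1, p2 = pool[i], pool[j]
        if rng.uniform() < cfg.crossover_rate:
            w1, w2 = arithmetic_crossover(p1.weights, p2.weights, rng, per_gene=cfg.per_gene_crossover)
            d1, d2 = single_point_crossover(p1.delays, p2.delays, rng)
        else:
            w1, w2 = p1.weights.copy(), p2.weights.copy()
            d1, d2 = p1.delays.copy(), p2.delays.copy()
        for w, d in ((w1, d1), (w2, d2)):
            if len(offspring) >= need:
                break
            w = uniform_mutation(w, cfg.weight_bounds, cfg.mutation_rate, rng)
            d = uniform_mutation(d, cfg.delay_bounds, cfg.mutation_rate, rng, integer_mode=True)
            offspring.append(Genome(w, d))
    return elites + offspring


def evolve(
    spike_matrix: np.ndarray,
    labels,
    codebook: ClassCodebook,
    shape: NetworkShape,
    lif_cfg: LIFConfig,
    ga_cfg: GAConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TrainingTrace:
    """Train the network on encoded data and return the full trace.

    ``spike_matrix`` is the (n, M) matrix of encoded input spike times,
    ``labels`` the class label per instance.  Runs exactly
    ``max_generations`` offspring generations.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    spike_matrix = np.asarray(spike_matrix, dtype=float)
    if spike_matrix.ndim != 2 or spike_matrix.shape[0] == 0:
        raise ValueError("spike_matrix must be a non-empty (n, M) matrix")
    labels = list(labels)
    targets = codebook.target_times(labels)

    def score(pop):
        recs = []
        for g in pop:
            rec = evaluate_fitness(g, spike_matrix, targets, shape, lif_cfg)
            g.fitness = rec.fitness
            recs.append(rec)
        return recs

    def best_accuracy(pop):
        best = max(range(len(pop)), key=lambda i: (pop[i].fitness, -i))
        out = network_output_times(pop[best], spike_matrix, shape, lif_cfg)
        pred = [codebook.decode(t, lif_cfg.t_total) for t in out]
        return pop[best], 100.0 * float(np.mean([p == y for p, y in zip(pred, labels)]))

    population = init_population(shape, ga_cfg, rng)
    best_f, mean_f, best_sse, acc = [], [], [], []
    for gen in range(ga_cfg.max_generations + 1):
        if gen > 0:
            population = _next_generation(population, ga_cfg, rng)
        recs = score(population)
        fits = np.array([r.fitness for r in recs])
        i_best = int(np.argmax(fits))
        best_f.append(float(fits[i_best]))
        mean_f.append(float(fits.mean()))
        best_sse.append(recs[i_best].sse)
        _, a = best_accuracy(population)
        acc.append(a)

    best_genome = max(population, key=lambda g: g.fitness).copy()
    return TrainingTrace(
        best_fitness=np.array(best_f),
        mean_fitness=np.array(mean_f),
        best_sse=np.array(best_sse),
        train_accuracy=np.array(acc),
        best_genome=best_genome,
        seed=seed,
    )
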