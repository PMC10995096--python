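"""Real-coded genetic algorithm over network initial weights (the GA-BP
hybrid).

Every network weight and bias is flattened into one chromosome (v1
row-major, then b1, then w2, then b2), each gene bounded in (-1, 1).  The
GA minimizes the network squared error E through the fitness transform
``1 / (1 + E)``, using roulette-wheel selection, arithmetic crossover
(convex combination, so children stay within bounds) and uniform resampling
mutation, with elitism so the best fitness never decreases.  The best
chromosome found seeds backpropagation fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (BPRegressor, NetworkParams, NetworkTopology,
                      TrainConfig, error_E, train_bp)

__all__ = [
    "GAConfig",
    "FitnessRecord",
    "GENE_BOUND",
    "encode",
    "decode",
    "fitness",
    "select_roulette",
    "crossover",
    "mutate",
    "evolve",
    "ga_bp_train",
    "GABPRegressor",
]

GENE_BOUND = 1.0


@dataclass(frozen=True)
class GAConfig:
    """GA settings; defaults are the study values (N=20, 100 generations,
    Pe=0.3, Pm=0.1)."""

    population_size: int = 20
    generations: int = 100
    crossover_prob: float = 0.3
    mutation_prob: float = 0.1
    elitism_count: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 <= self.elitism_count < self.population_size):
            raise ValueError("elitism_count must be < population_size")


@dataclass(frozen=True)
class FitnessRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_E: float


def encode(params: NetworkParams) -> np.ndarray:
    """Flatten parameters into a chromosome (v1 row-major, b1, w2, b2)."""
    return np.concatenate([params.v1.ravel(), params.b1,
                           params.w2.ravel(), params.b2])


def decode(chromosome: np.ndarray, topology: NetworkTopology) -> NetworkParams:
    """Inverse of :func:`encode`; exact round-trip."""
    c = np.asarray(chromosome, dtype=float)
    if c.shape != (topology.n_genes,):
        raise ValueError(
            f"chromosome length {c.size} != expected {topology.n_genes}")
    t = topology
    i = 0
    v1 = c[i:i + t.n_in * t.n_hidden].reshape(t.n_in, t.n_hidden)
    i += t.n_in * t.n_hidden
    b1 = c[i:i + t.n_hidden]
    i += t.n_hidden
    w2 = c[i:i + t.n_hidden * t.n_out].reshape(t.n_hidden, t.n_out)
    i += t.n_hidden * t.n_out
    b2 = c[i:]
    return NetworkParams(v1, b1, w2, b2)


def fitness(chromosome: np.ndarray, X, y, topology: NetworkTopology,
            output_activation: str = "sigmoid") -> float:
    """``1 / (1 + E)`` — strictly decreasing in E, in (0, 1]."""
    e = error_E(decode(chromosome, topology), X, y, output_activation)
    return 1.0 / (1.0 + e)


def select_roulette(population: np.ndarray, fitnesses: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Fitness-proportional selection of one parent."""
    f = np.asarray(fitnesses, dtype=float)
    total = f.sum()
    if total <= 0 or np.any(f < 0):
        raise ValueError("fitnesses must be positive for roulette selection")
    idx = rng.choice(len(population), p=f / total)
    return population[idx]


def crossover(parent_a: np.ndarray, parent_b: np.ndarray, pe: float,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic crossover with probability ``pe``.

    When triggered, children are the convex pair ``alpha*a + (1-alpha)*b``
    and ``(1-alpha)*a + alpha*b`` with one alpha ~ U(0,1) per pair, hence
    within gene bounds whenever the parents are.
    """
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    if rng.random() >= pe:
        return a.copy(), b.copy()
    alpha = rng.random()
    return alpha * a + (1 - alpha) * b, (1 - alpha) * a + alpha * b


def mutate(chromosome: np.ndarray, pm: float, rng: np.random.Generator,
           bound: float = GENE_BOUND) -> np.ndarray:
    """Per-gene mutation: with probability ``pm`` resample the gene
    uniformly in (-bound, bound)."""
    c = np.asarray(chromosome, dtype=float).copy()
    hit = rng.random(c.shape) < pm
    c[hit] = rng.uniform(-bound, bound, int(hit.sum()))
    return c


def evolve(X, y, topology: NetworkTopology, config: GAConfig,
           output_activation: str = "sigmoid",
           rng: np.random.Generator | None = None
           ) -> tuple[np.ndarray, list[FitnessRecord]]:
    """Run the genetic search and return the best-ever chromosome.

    Each generation: evaluate fitness, carry over ``elitism_count`` best
    unchanged, then fill the population with roulette-selected parents put
    through crossover and mutation.  With ``generations = 0`` this reduces
    to the best of the random initial population.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = topology.n_genes
    pop = rng.uniform(-GENE_BOUND, GENE_BOUND, (config.population_size, n))

    def eval_pop(p):
        return np.array([fitness(c, X, y, topology, output_activation)
                         for c in p])

    history: list[FitnessRecord] = []
    fits = eval_pop(pop)
    best_idx = int(np.argmax(fits))
    best = pop[best_idx].copy()
    best_fit = float(fits[best_idx])
    history.append(FitnessRecord(0, best_fit, float(fits.mean()),
                                 1.0 / best_fit - 1.0))
    for gen in range(1, config.generations + 1):
        order = np.argsort(fits)[::-1]
        next_pop = [pop[i].copy() for i in order[:config.elitism_count]]
        while len(next_pop) < config.population_size:
            pa = select_roulette(pop, fits, rng)
            pb = select_roulette(pop, fits, rng)
            ca, cb = crossover(pa, pb, config.crossover_prob, rng)
            next_pop.append(mutate(ca, config.mutation_prob, rng))
            if len(next_pop) < config.population_size:
                next_pop.append(mutate(cb, config.mutation_prob, rng))
        pop = np.array(next_pop)
        fits = eval_pop(pop)
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best = pop[gen_best].copy()
        history.append(FitnessRecord(gen, best_fit, float(fits.mean()),
                                     1.0 / best_fit - 1.0))
    return best, history


def ga_bp_train(X, y, topology: NetworkTopology, ga_config: GAConfig,
                train_config: TrainConfig,
                rng: np.random.Generator | None = None):
    """GA global search followed by BP local refinement.

    Returns ``(params_final, report)`` where the report carries the GA
    fitness history and the BP error history.  With ``generations = 0``
    this degenerates to plain BP from the best random chromosome of the
    initial population.
    """
    best, ga_history = evolve(X, y, topology, ga_config,
                              train_config.output_activation, rng)
    params0 = decode(best, topology)
    params, bp_history = train_bp(params0, X, y, train_config)
    report = {"ga_history": ga_history, "bp_history": bp_history,
              "ga_best_E": ga_history[-1].best_E, "final_E": bp_history[-1]}
    return params, report


class GABPRegressor(BPRegressor):
    """GA-initialized backpropagation regressor (the GA-BP hybrid).

    Identical to :class:`~lqci.network.BPRegressor` except that the initial
    weights and biases are the best chromosome found by the genetic search
    (defaults N=20, 100 generations, Pe=0.3, Pm=0.1) instead of a single
    random draw.  After :meth:`fit`, ``ga_history_`` holds the
    per-generation :class:`FitnessRecord` trace and ``ga_best_E_`` the
    training error of the chromosome handed to backpropagation.
    """

    def __init__(self, n_hidden: int = 6, learning_rate: float = 0.001,
                 target_error: float = 0.001, max_epochs: int = 200_000,
                 momentum: float = 0.9, output_activation: str = "sigmoid",
                 y_margin: float = 0.1, init_bound: float = 1.0,
                 population_size: int = 20, generations: int = 100,
                 crossover_prob: float = 0.3, mutation_prob: float = 0.1,
                 elitism_count: int = 1, random_state: int | None = None):
        super().__init__(n_hidden=n_hidden, learning_rate=learning_rate,
                         target_error=target_error, max_epochs=max_epochs,
                         momentum=momentum,
                         output_activation=output_activation,
                         y_margin=y_margin, init_bound=init_bound,
                         random_state=random_state)
        self.population_size = population_size
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.elitism_count = elitism_count

    def _initial_params(self, topology, Xs, ys, rng):
        config = GAConfig(population_size=self.population_size,
                          generations=self.generations,
                          crossover_prob=self.crossover_prob,
                          mutation_prob=self.mutation_prob,
                          elitism_count=self.elitism_count)
        best, history = evolve(Xs, ys, topology, config,
                               self.output_activation, rng)
        self.ga_history_ = history
        self.ga_best_E_ = history[-1].best_E
        return decode(best, topology)
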