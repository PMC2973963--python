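"""Genetic-algorithm wrapper search over factor subsets.

A chromosome is a fixed-length string of factor ids in which 0 marks an
empty position; the decoded object is the set of distinct non-zero ids, so
one population explores subset sizes from 2 up to the chromosome length in
parallel.  Selection is by tournament, recombination by single-point
crossover (probability 0.7), and mutation is multi-point: a first mutation
fires with probability 0.1 and each further mutation on the same chromosome
continues with probability 0.25 (a geometric chain).  Exact fitness ties are
broken toward the smaller subset (complexity regularization), then
lexicographically.

The whole search is restarted n times (default 30) from different seeds; the
per-restart best subsets feed the combinatorial interaction ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, PhenotypeLabels
from .fitness import EnsembleConfig, EnsembleEvaluator, FitnessBreakdown

CROSSOVER_PROB = 0.7
MUTATION_PROB = 0.1
MUTATION_CHAIN_PROB = 0.25
EMPTY = 0  # gene value marking an empty chromosome position


@dataclass(frozen=True)
class GAConfig:
    """Search-budget parameters; defaults suit a 20-factor dataset."""

    chromosome_size: int = 15
    population_size: int = 40
    generations: int = 8
    tournament_size: int = 3
    crossover_prob: float = CROSSOVER_PROB
    mutation_prob: float = MUTATION_PROB
    mutation_chain_prob: float = MUTATION_CHAIN_PROB
    elitism: int = 1
    restarts: int = 30
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.chromosome_size < 2:
            raise ValueError("chromosome_size must be >= 2")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")
        if not 1 <= self.tournament_size <= self.population_size:
            raise ValueError("tournament_size must be in [1, population_size]")
        for p in (self.crossover_prob, self.mutation_prob, self.mutation_chain_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


def default_ga_config(n_factors: int, restarts: int = 30, master_seed: int = 0) -> GAConfig:
    """Scale the search budget with the number of candidate factors.

    Interpolates linearly between (d=15, p=40, g=8, t=3) at 20 factors and
    (d=25, p=340, g=20, t=7) at 100 factors, clamped to those ranges.
    """
    frac = min(max((n_factors - 20) / 80.0, 0.0), 1.0)
    return GAConfig(
        chromosome_size=round(15 + 10 * frac),
        population_size=round(40 + 300 * frac),
        generations=round(8 + 12 * frac),
        tournament_size=round(3 + 4 * frac),
        restarts=restarts,
        master_seed=master_seed,
    )


@dataclass
class Chromosome:
    """Gene string plus its cached fitness; genes index factors from 1."""

    genes: np.ndarray
    fitness: FitnessBreakdown | None = None
    _decoded: tuple[int, ...] | None = None

    def decode(self) -> tuple[int, ...]:
        """Distinct non-zero gene values as sorted 0-based factor indices.

        Genes are never modified after construction, so the result is cached.
        """
        if self._decoded is None:
            nz = self.genes[self.genes != EMPTY]
            self._decoded = tuple(int(g) - 1 for g in np.unique(nz))
        return self._decoded

    def copy(self) -> "Chromosome":
        return Chromosome(self.genes.copy(), self.fitness, self._decoded)


@dataclass
class BestSubsetRecord:
    """Outcome of one GA restart."""

    subset: tuple[int, ...]
    factor_ids: tuple[str, ...]
    fitness: FitnessBreakdown
    trace: list[float] = field(default_factory=list)
    run_seed: int = 0


def _n_distinct(genes: np.ndarray) -> int:
    return np.unique(genes[genes != EMPTY]).size


def _repair(genes: np.ndarray, n_factors: int, rng: np.random.Generator) -> np.ndarray:
    """Zero duplicate ids beyond their first occurrence; re-grow to >= 2 ids."""
    seen: set[int] = set()
    for i, g in enumerate(genes):
        if g == EMPTY:
            continue
        if g in seen:
            genes[i] = EMPTY
        else:
            seen.add(int(g))
    while _n_distinct(genes) < 2:
        pos = int(rng.integers(genes.size))
        genes[pos] = int(rng.integers(1, n_factors + 1))
    return genes


def random_chromosome(
    config: GAConfig, n_factors: int, rng: np.random.Generator
) -> Chromosome:
    while True:
        genes = np.where(
            rng.random(config.chromosome_size) < 0.5,
            EMPTY,
            rng.integers(1, n_factors + 1, size=config.chromosome_size),
        ).astype(np.int32)
        if _n_distinct(genes) >= 2:
            return Chromosome(genes)


def initialize_population(
    config: GAConfig, n_factors: int, seed: int | np.random.Generator
) -> list[Chromosome]:
    """p random chromosomes, each decoding to at least two distinct factors."""
    if n_factors < 2:
        raise ValueError("need at least two candidate factors")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [random_chromosome(config, n_factors, rng) for _ in range(config.population_size)]


def _rank_key(c: Chromosome) -> tuple[float, int, tuple[int, ...]]:
    """Sort key: fitness desc, then subset size asc, then lexicographic ids."""
    subset = c.decode()
    assert c.fitness is not None
    return (-c.fitness.combined, len(subset), subset)


def tournament_select(
    population: list[Chromosome], t: int, rng: np.random.Generator
) -> Chromosome:
    """Best of t uniform draws (with replacement); ties favour smaller subsets."""
    picks = rng.integers(len(population), size=t)
    return min((population[i] for i in picks), key=_rank_key)


def single_point_crossover(
    a: Chromosome,
    b: Chromosome,
    rng: np.random.Generator,
    n_factors: int,
    prob: float = CROSSOVER_PROB,
) -> tuple[Chromosome, Chromosome]:
    """Swap tails after a uniform cut point with the configured probability."""
    if a.genes.size != b.genes.size:
        raise ValueError("parents must share chromosome size")
    if rng.random() >= prob:
        return a.copy(), b.copy()
    d = a.genes.size
    cut = int(rng.integers(1, d))
    g1 = np.concatenate([a.genes[:cut], b.genes[cut:]])
    g2 = np.concatenate([b.genes[:cut], a.genes[cut:]])
    return (
        Chromosome(_repair(g1, n_factors, rng)),
        Chromosome(_repair(g2, n_factors, rng)),
    )


def multi_mutate(
    chrom: Chromosome,
    rng: np.random.Generator,
    n_factors: int,
    prob: float = MUTATION_PROB,
    chain_prob: float = MUTATION_CHAIN_PROB,
) -> Chromosome:
    """Geometric multi-point mutation.

    With probability ``prob`` one uniform position is set to a uniform value
    in {empty} + factor ids; each further mutation then fires with
    probability ``chain_prob``, so the mutation count given at least one is
    geometric with mean 1/(1 - chain_prob).
    """
    positions = _mutation_positions(
        rng, chrom.genes.size, prob, chain_prob
    )
    if not positions:
        return chrom.copy()
    genes = chrom.genes.copy()
    for pos in positions:
        genes[pos] = int(rng.integers(0, n_factors + 1))
    return Chromosome(_repair(genes, n_factors, rng))


def _mutation_positions(
    rng: np.random.Generator, d: int, prob: float, chain_prob: float
) -> list[int]:
    """Positions hit by the geometric mutation chain (possibly repeating)."""
    if rng.random() >= prob:
        return []
    positions = [int(rng.integers(d))]
    while rng.random() < chain_prob:
        positions.append(int(rng.integers(d)))
    return positions


def run_ga(
    data: GenotypeMatrix,
    ga_config: GAConfig,
    ens_config: EnsembleConfig | None = None,
    run_seed: int = 0,
    labels: PhenotypeLabels | None = None,
    evaluator: EnsembleEvaluator | None = None,
) -> BestSubsetRecord:
    """One seeded GA run; returns the best subset of the final generation.

    With elitism the final-generation best is the best chromosome seen, so
    the per-generation best-fitness trace is non-decreasing.
    """
    if evaluator is None:
        if labels is None:
            raise ValueError("labels are required when no evaluator is given")
        evaluator = EnsembleEvaluator(data, labels, ens_config)
    n_factors = data.n_factors
    rng = np.random.default_rng(run_seed)
    population = initialize_population(ga_config, n_factors, rng)
    trace: list[float] = []
    for _ in range(ga_config.generations):
        for c in population:
            if c.fitness is None:
                c.fitness = evaluator.evaluate(c.decode())
        population.sort(key=_rank_key)
        trace.append(population[0].fitness.combined)  # type: ignore[union-attr]
        offspring = [population[i].copy() for i in range(ga_config.elitism)]
        while len(offspring) < ga_config.population_size:
            pa = tournament_select(population, ga_config.tournament_size, rng)
            pb = tournament_select(population, ga_config.tournament_size, rng)
            c1, c2 = single_point_crossover(
                pa, pb, rng, n_factors, ga_config.crossover_prob
            )
            for child in (c1, c2):
                child = multi_mutate(
                    child, rng, n_factors,
                    ga_config.mutation_prob, ga_config.mutation_chain_prob,
                )
                child.fitness = None
                if len(offspring) < ga_config.population_size:
                    offspring.append(child)
        population = offspring
    for c in population:
        if c.fitness is None:
            c.fitness = evaluator.evaluate(c.decode())
    best = min(population, key=_rank_key)
    subset = best.decode()
    trace.append(best.fitness.combined)  # type: ignore[union-attr]
    return BestSubsetRecord(
        subset=subset,
        factor_ids=tuple(data.factor_ids[i] for i in subset),
        fitness=best.fitness,  # type: ignore[arg-type]
        trace=trace,
        run_seed=run_seed,
    )


def run_restarts(
    data: GenotypeMatrix,
    labels: PhenotypeLabels,
    ga_config: GAConfig | None = None,
    ens_config: EnsembleConfig | None = None,
) -> list[BestSubsetRecord]:
    """The full n-restart protocol; restart i uses seed master_seed + i.

    All restarts share one evaluator, hence identical cross-validation folds:
    fitness values are comparable across restarts and cached subset scores
    are reused.
    """
    if ga_config is None:
        ga_config = default_ga_config(data.n_factors)
    evaluator = EnsembleEvaluator(data, labels, ens_config)
    return [
        run_ga(data, ga_config, run_seed=ga_config.master_seed + i, evaluator=evaluator)
        for i in range(ga_config.restarts)
    ]
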