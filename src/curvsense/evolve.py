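"""Genetic-algorithm design loop for curvature sensing peptides.

The loop evolves fixed-length peptide sequences toward the most negative
curvature sensing free energy ddF.  Each candidate is scored by a
pluggable :class:`FitnessBackend` that returns the raw ddF together with
the peptide's membrane insertion depths under tensionless and stretched
conditions; the raw score is multiplied by a cosine surface-constraint
window,

    c(d) = 1/2 (1 - cos(pi d / b))   for 0 <= d <= 2b, else 0,

which is 1 for a peptide sitting at the monolayer reference depth
(d = b), and 0 for soluble (d >= 2b) or transmembrane (d <= 0)
configurations.  The lower of the tensionless/stretched factors is used,
so only stably surface-bound candidates keep their full score.

Selection is truncation to the fittest parent pool, variation is
one-point crossover plus per-position point mutation, and two elitism
rules stabilize the noisy fitness signal: the single best candidate of
each generation is carried over ("fitness elite"), and any candidate
already evaluated more than ``rerun_elite_threshold`` times is retained
("rerun elite").  Elites are re-evaluated every generation and carry the
running mean of all their evaluations, so persistent candidates
accumulate sampling.

In production the backend wraps ensemble-averaged coarse-grained MD free
energy calculations; the bundled :class:`curvsense.surrogate.SurrogateBackend`
provides a deterministic desk-scale oracle with the same interface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from .peptides import Alphabet, Peptide, position_frequency_matrix, PositionFrequencyMatrix

__all__ = [
    "GAConfig",
    "Individual",
    "Population",
    "FitnessBackend",
    "EvolutionTrace",
    "scale_fitness",
    "cosine_window",
    "select_parents",
    "crossover",
    "mutate",
    "step",
    "run",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Run parameters of the design loop.

    Defaults follow the production settings: population 144, parent pool
    36, 24-residue peptides over the reduced helix-prone alphabet,
    mutation probability 1/L (one expected point mutation per child),
    monolayer depths b = 1.90 nm (tensionless) and 1.79 nm (stretched).
    """

    population_size: int = 144
    parent_pool: int = 36
    length: int = 24
    alphabet: Alphabet = Alphabet.reduced10
    restrict: str | None = None  # optional subset of the alphabet to search
    p_mut: float | None = None  # defaults to 1/length
    max_generations: int = 25
    rerun_elite_threshold: int = 3
    b_tensionless: float = 1.90
    b_stretched: float = 1.79
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.parent_pool > self.population_size:
            raise ValueError("parent_pool cannot exceed population_size")
        if self.p_mut is not None and not 0.0 <= self.p_mut <= 1.0:
            raise ValueError("p_mut must be in [0, 1]")
        if self.b_tensionless <= 0 or self.b_stretched <= 0:
            raise ValueError("monolayer depths b must be positive")
        if self.restrict is not None:
            extra = set(self.restrict) - set(self.alphabet.letters)
            if extra or len(self.restrict) < 2:
                raise ValueError(
                    "restrict must name >= 2 letters from the configured alphabet"
                )

    @property
    def letters(self) -> str:
        """Letters the search may use (restricted subset or full alphabet)."""
        return self.restrict if self.restrict is not None else self.alphabet.letters

    @property
    def mutation_rate(self) -> float:
        return 1.0 / self.length if self.p_mut is None else self.p_mut


class FitnessBackend(Protocol):
    """Fitness oracle interface: sequence -> (ddf, d_mem_t, d_mem_s).

    ``ddf`` is the curvature sensing free energy in kJ/mol and the two
    depths are the z-components of the peptide-membrane center-of-mass
    distance (nm) under tensionless and stretched conditions.  Must be
    deterministic given its own seed and return finite ddf.
    """

    def evaluate(self, sequence: str) -> tuple[float, float, float]: ...


def cosine_window(d: float, b: float) -> float:
    """Surface-constraint factor c(d) in [0, 1]; maximal at d = b."""
    d = abs(d)
    if d >= 2.0 * b:
        return 0.0
    return 0.5 * (1.0 - math.cos(math.pi * d / b))


def scale_fitness(
    ddf: float, d_mem_t: float, d_mem_s: float, config: GAConfig = GAConfig()
) -> float:
    """Scaled fitness min(c_t, c_s) * ddf (lower = fitter)."""
    c = min(
        cosine_window(d_mem_t, config.b_tensionless),
        cosine_window(d_mem_s, config.b_stretched),
    )
    return c * ddf


@dataclass
class Individual:
    """One candidate solution with its evaluation record."""

    peptide: Peptide
    fitness_history: list[float] = field(default_factory=list)
    birth_order: int = 0  # global insertion counter, used for tie-breaks

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    @property
    def n_evals(self) -> int:
        return len(self.fitness_history)

    @property
    def fitness(self) -> float:
        """Running mean of all evaluations (nan before first evaluation)."""
        if not self.fitness_history:
            return math.nan
        return float(np.mean(self.fitness_history))

    def sort_key(self) -> tuple[float, int, str]:
        return (self.fitness, self.birth_order, self.sequence)


@dataclass
class Population:
    """An evaluated (or about-to-be-evaluated) generation."""

    members: list[Individual]
    generation: int = 0
    _birth_counter: int = 0

    def __post_init__(self) -> None:
        if self._birth_counter == 0:
            self._birth_counter = max(
                (m.birth_order for m in self.members), default=-1
            ) + 1

    def __len__(self) -> int:
        return len(self.members)

    def register(self, ind: Individual) -> Individual:
        ind.birth_order = self._birth_counter
        self._birth_counter += 1
        return ind

    def best(self) -> Individual:
        if not self.members:
            raise RuntimeError("empty population")
        return min(self.members, key=Individual.sort_key)

    def mean_fitness(self) -> float:
        return float(np.mean([m.fitness for m in self.members]))


def random_population(config: GAConfig, rng: np.random.Generator) -> Population:
    letters = config.letters
    pop = Population(members=[], generation=0)
    for _ in range(config.population_size):
        seq = "".join(rng.choice(list(letters), size=config.length))
        pop.members.append(pop.register(Individual(Peptide(seq, config.alphabet))))
    return pop


def evaluate_population(
    pop: Population, backend: FitnessBackend, config: GAConfig
) -> None:
    """Evaluate every member once more; fitness becomes the running mean.

    A backend failure is logged and scored 0 (the value of any
    non-surface configuration), keeping the loop alive.
    """
    for ind in pop.members:
        try:
            ddf, d_t, d_s = backend.evaluate(ind.sequence)
            fit = scale_fitness(ddf, d_t, d_s, config)
        except Exception:  # noqa: BLE001 - backend is user code
            log.exception("fitness evaluation failed for %s; scoring 0", ind.sequence)
            fit = 0.0
        ind.fitness_history.append(fit)


def select_parents(pop: Population, k: int) -> list[Individual]:
    """The k fittest individuals (most negative running-mean fitness).

    Ties are broken by earlier evaluation (birth order), then
    lexicographic sequence, so selection is fully deterministic.
    """
    if not pop.members:
        raise RuntimeError("cannot select from an empty population")
    if k > len(pop.members):
        raise ValueError(f"k={k} exceeds population size {len(pop.members)}")
    return sorted(pop.members, key=Individual.sort_key)[:k]


def crossover(
    p1: Peptide, p2: Peptide,
    i: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Peptide, Peptide]:
    """One-point crossover: swap tails after a shared split position i."""
    if len(p1) != len(p2):
        raise ValueError("parents must have equal length")
    L = len(p1)
    if i is None:
        if rng is None:
            raise ValueError("need either a split position or an rng")
        i = int(rng.integers(1, L))
    if not 1 <= i <= L - 1:
        raise ValueError(f"split position must be in [1, {L - 1}], got {i}")
    s1, s2 = p1.sequence, p2.sequence
    return (
        Peptide(s1[:i] + s2[i:], p1.alphabet),
        Peptide(s2[:i] + s1[i:], p2.alphabet),
    )


def mutate(
    p: Peptide, p_mut: float, rng: np.random.Generator, letters: str | None = None
) -> Peptide:
    """Independent per-position point mutation with probability p_mut.

    An applied mutation always substitutes a *different* residue (drawn
    uniformly from ``letters`` -- default the peptide's alphabet -- minus
    the current one), so the expected Hamming distance is exactly
    L * p_mut.
    """
    if not 0.0 <= p_mut <= 1.0:
        raise ValueError("p_mut must be in [0, 1]")
    letters = letters or p.alphabet.letters
    chars = list(p.sequence)
    hits = rng.random(len(chars)) < p_mut
    for pos in np.flatnonzero(hits):
        options = [a for a in letters if a != chars[pos]]
        chars[pos] = options[int(rng.integers(len(options)))]
    return Peptide("".join(chars), p.alphabet)


def step(
    pop: Population,
    backend: FitnessBackend,
    config: GAConfig,
    rng: np.random.Generator,
) -> Population:
    """Produce and evaluate the next generation.

    Carries over the fitness elite and all rerun elites, fills the
    remaining slots pairwise with mutated crossover children of parents
    drawn uniformly from the parent pool, then evaluates every member
    (elites included, updating their running means).
    """
    if not pop.members or any(m.n_evals == 0 for m in pop.members):
        raise RuntimeError("step() requires a fully evaluated population")

    elite = pop.best()
    rerun_elites = [
        m for m in pop.members
        if m.n_evals > config.rerun_elite_threshold and m is not elite
    ]
    carried = [elite, *rerun_elites][: config.population_size]

    parents = select_parents(pop, min(config.parent_pool, len(pop.members)))
    nxt = Population(members=list(carried), generation=pop.generation + 1,
                     _birth_counter=pop._birth_counter)

    n_missing = config.population_size - len(nxt.members)
    children: list[Peptide] = []
    while len(children) < n_missing:
        i1, i2 = rng.integers(len(parents)), rng.integers(len(parents))
        c1, c2 = crossover(parents[int(i1)].peptide, parents[int(i2)].peptide, rng=rng)
        children.append(mutate(c1, config.mutation_rate, rng, config.letters))
        if len(children) < n_missing:  # odd last slot takes the first child only
            children.append(mutate(c2, config.mutation_rate, rng, config.letters))
    for child in children:
        nxt.members.append(nxt.register(Individual(child)))

    evaluate_population(nxt, backend, config)
    return nxt


@dataclass
class EvolutionTrace:
    """Per-generation summary of a design run."""

    best_fitness: list[float]
    mean_fitness: list[float]
    best_sequences: list[str]
    final_population: Population
    consensus_pfm: PositionFrequencyMatrix

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": range(len(self.best_fitness)),
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "best_sequence": self.best_sequences,
            }
        )


def run(
    config: GAConfig,
    backend: FitnessBackend,
    callback: Callable[[Population], None] | None = None,
) -> EvolutionTrace:
    """Run the full design loop; reproducible given ``config.seed``.

    Generation 0 is a uniform-random population.  The trace records the
    population best and mean after each evaluation round; the consensus
    position-frequency matrix is computed over the fittest
    ``parent_pool`` members of the final population.
    """
    rng = np.random.default_rng(config.seed)
    pop = random_population(config, rng)
    evaluate_population(pop, backend, config)

    best, mean, seqs = [], [], []

    def record(p: Population) -> None:
        b = p.best()
        best.append(b.fitness)
        mean.append(p.mean_fitness())
        seqs.append(b.sequence)
        if callback is not None:
            callback(p)

    record(pop)
    for _ in range(config.max_generations):
        pop = step(pop, backend, config, rng)
        record(pop)

    top = select_parents(pop, min(config.parent_pool, len(pop)))
    pfm = position_frequency_matrix(
        [m.sequence for m in top], letters=config.alphabet.letters
    )
    return EvolutionTrace(best, mean, seqs, pop, pfm)
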