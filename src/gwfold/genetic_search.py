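"""Population-based search: elitist genetic algorithm with stagnation recovery.

One generation selects a single operator from a fixed non-uniform
probability distribution and applies it (exhaustively, by default) across
the whole population; each candidate competes with its parent and survives
only on strict improvement.  The best individual ever seen (``best_global``)
is archived outside the population, so its energy trajectory is
non-increasing by construction.  After a run of non-improving generations
longer than a per-protein threshold, the population is diversified by a
random walk of successive pull moves whose length grows every time two
consecutive recoveries fail to produce a new global best.

Search is guided by one of the GW / BM / HP potentials; results are always
re-scored with the raw BM matrix for reporting, whatever the guidance.
Cost is accounted hardware-independently as the number of candidate
conformations scored (one tick per candidate, full or incremental).
"""

from __future__ import annotations

import random
import time
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

from .energy_models import (
    ContactEnergyMatrix,
    GroupScheme,
    HPClassification,
    derive_gw_matrix,
    evaluate_energy,
    hp_matrix,
    pair_energy_table,
    validate_sequence,
)
from .fcc_lattice import Conformation, Point, chain_growth_init, decode_conformation
from .move_operators import (
    OPERATORS,
    apply_random,
    exhaustive_apply,
    random_pull,
    score_full,
)

#: Operator selection probabilities (pull, crossover, diagonal a.k.a.
#: corner flip, rotation), tuned for contribution to energy minimization.
DEFAULT_OPERATOR_PROBABILITIES = {
    "pull": 0.40,
    "crossover": 0.25,
    "diagonal": 0.20,
    "rotation": 0.15,
}

#: Stagnation thresholds keyed by benchmark sequence length: the number of
#: non-improving generations tolerated before a random-walk recovery.
_THRESHOLD_TABLE = (
    (54, 50), (58, 50), (61, 50), (64, 45), (69, 45), (74, 40), (90, 35),
    (108, 30), (120, 25), (142, 20), (160, 15), (179, 15), (189, 15),
    (229, 15), (258, 15), (279, 15),
)


def threshold_for_length(n: int) -> int:
    """Stagnation threshold for a sequence of length n (step lookup)."""
    value = _THRESHOLD_TABLE[0][1]
    for length, thr in _THRESHOLD_TABLE:
        if n >= length:
            value = thr
    return value


class EvaluationCounter:
    """Counts objective-function evaluations: one per candidate scored."""

    __slots__ = ("count",)

    def __init__(self) -> None:
        self.count = 0

    def tick(self, k: int = 1) -> None:
        self.count += k


@dataclass
class Individual:
    """A conformation with its cached energy under the guidance matrix."""

    conformation: Conformation
    coords: list[Point]
    energy: float

    def clone(self) -> "Individual":
        return Individual(self.conformation, list(self.coords), self.energy)


@dataclass(frozen=True)
class GAConfig:
    """Run settings for the genetic search.

    At least one of ``time_budget`` (wall-clock seconds),
    ``max_generations`` or ``max_evaluations`` must be set; the latter two
    make runs hardware-independent and reproducible.
    """

    population_size: int = 50
    operator_probabilities: dict = field(
        default_factory=lambda: dict(DEFAULT_OPERATOR_PROBABILITIES))
    threshold_value: Optional[int] = None  # default: by sequence length
    time_budget: Optional[float] = None
    max_generations: Optional[int] = None
    max_evaluations: Optional[int] = None
    seed: int = 0
    guidance: str = "GW"
    exhaustive: bool = True
    recovery_pulls_per_unit: Optional[int] = None  # default max(1, n // 10)
    rotation_retries: int = 50

    def validated(self) -> "GAConfig":
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.threshold_value is not None and self.threshold_value < 1:
            raise ValueError("threshold_value must be >= 1")
        probs = self.operator_probabilities
        if set(probs) - set(OPERATORS):
            raise ValueError(f"unknown operators in {sorted(probs)}")
        if any(p < 0 for p in probs.values()):
            raise ValueError("operator probabilities must be non-negative")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("operator probabilities must sum to 1")
        if self.guidance not in ("GW", "BM", "HP"):
            raise ValueError("guidance must be GW, BM or HP")
        if (self.time_budget is None and self.max_generations is None
                and self.max_evaluations is None):
            raise ValueError("set a time, generation or evaluation budget")
        return self


@dataclass
class SearchState:
    """Mutable state of a running search."""

    population: list[Individual]
    best_global: Individual
    best_current: Individual
    tracking_non_improvement: int = 0
    shuffle_parameter: int = 1
    generation: int = 0
    counter: EvaluationCounter = field(default_factory=EvaluationCounter)
    improved_since_recovery: bool = True  # no failed recovery yet
    last_operator: str = "init"
    pair_energy: Optional[list[list[float]]] = None  # guidance-scale table

    @property
    def evaluation_count(self) -> int:
        return self.counter.count


class GenerationRecord(NamedTuple):
    generation: int
    operator: str
    best_energy: float  # guidance scale, global best
    best_bm_energy: float
    evaluation_count: int
    elapsed_seconds: float


@dataclass
class RunStats:
    """Outcome of a run: trajectory, final best and cost accounting."""

    trajectory: list[GenerationRecord]
    best_conformation: Conformation
    best_coords: tuple[Point, ...]
    best_energy: float  # under the guidance matrix
    best_bm_energy: float
    evaluation_count: int
    generations: int
    operator_applications: Counter
    operator_acceptances: Counter
    recoveries: int
    guidance: str
    seed: int
    initial_bm_energy: float = 0.0  # best of the random initial population


def select_operator(probs: dict, rng: random.Random) -> str:
    """Draw an operator tag from the configured distribution."""
    if abs(sum(probs.values()) - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
        raise ValueError("malformed operator distribution")
    r = rng.random()
    acc = 0.0
    tags = [t for t in OPERATORS if t in probs]
    for tag in tags:
        acc += probs[tag]
        if r < acc:
            return tag
    return tags[-1]


def elitist_replace(parent: Individual, child: Individual) -> Individual:
    """Child survives only on strictly lower energy; ties keep the parent."""
    return child if child.energy < parent.energy else parent


def evolve_generation(
    state: SearchState,
    cfg: GAConfig,
    seq: str,
    matrix: ContactEnergyMatrix,
    rng: random.Random,
    bm_matrix: Optional[ContactEnergyMatrix] = None,
    stats: Optional[RunStats] = None,
) -> SearchState:
    """One generation: select an operator, apply across the population,
    elitist replacement, best tracking."""
    op = select_operator(cfg.operator_probabilities, rng)
    state.last_operator = op
    pop = state.population
    new_pop = []
    apply_fn = exhaustive_apply if cfg.exhaustive else apply_random
    if state.pair_energy is None:
        state.pair_energy = pair_energy_table(seq, matrix)
    for idx, ind in enumerate(pop):
        mate = None
        if op == "crossover":
            mate = pop[rng.randrange(len(pop))].coords
        result = apply_fn(op, ind.coords, ind.energy, seq, matrix, rng,
                          mate_coords=mate, counter=state.counter,
                          rotation_retries=cfg.rotation_retries,
                          pair_energy=state.pair_energy)
        if stats is not None:
            stats.operator_applications[op] += 1
        if result.candidates == 0:
            new_pop.append(ind)
            continue
        child = Individual(result.conformation, list(result.coords),
                           result.energy)
        survivor = elitist_replace(ind, child)
        if survivor is child and stats is not None:
            stats.operator_acceptances[op] += 1
        new_pop.append(survivor)
    state.population = new_pop
    state.best_current = min(new_pop, key=lambda i: i.energy)
    state.generation += 1
    if state.best_current.energy < state.best_global.energy:
        state.best_global = state.best_current.clone()
        state.tracking_non_improvement = 0
        state.improved_since_recovery = True
    else:
        state.tracking_non_improvement += 1
    return state


def random_walk_recover(
    state: SearchState,
    cfg: GAConfig,
    seq: str,
    matrix: ContactEnergyMatrix,
    rng: random.Random,
) -> SearchState:
    """Diversify the population by successive random pull moves.

    Each individual receives k = shuffle_parameter x max(1, n/10) random
    feasible pulls and is re-scored once.  ``best_global`` is archived
    outside the population and is never touched.  The shuffle parameter
    grows only when the recovery *before* this one produced no new global
    best in between.
    """
    n = len(seq)
    per_unit = cfg.recovery_pulls_per_unit or max(1, n // 10)
    if not state.improved_since_recovery:
        state.shuffle_parameter += 1
    k = state.shuffle_parameter * per_unit
    if state.pair_energy is None:
        state.pair_energy = pair_energy_table(seq, matrix)
    for ind in state.population:
        coords = ind.coords
        for _ in range(k):
            new = random_pull(coords, rng)
            if new is not None:
                coords = new
        if coords is not ind.coords:
            ind.coords = coords
            ind.conformation = Conformation.from_coords(coords)
            ind.energy = score_full(coords, state.pair_energy, state.counter)
    state.best_current = min(state.population, key=lambda i: i.energy)
    state.tracking_non_improvement = 0
    state.improved_since_recovery = False
    return state


def run_search(
    seq: str,
    cfg: GAConfig,
    bm_matrix: ContactEnergyMatrix,
    scheme: Optional[GroupScheme] = None,
    hp_classification: Optional[HPClassification] = None,
) -> RunStats:
    """Full search on a sequence: Algorithm-1-style main loop.

    The population is initialized by random chain growth, evolved one
    operator per generation with elitist selection, diversified on
    stagnation, and stopped on whichever configured budget is hit first.
    The returned statistics carry both the guidance-scale and the BM-scale
    score of the best conformation found.
    """
    seq = validate_sequence(seq)
    cfg = cfg.validated()
    n = len(seq)
    rng = random.Random(cfg.seed)
    if cfg.guidance == "GW":
        matrix = derive_gw_matrix(bm_matrix, scheme or GroupScheme.default_six_group())
    elif cfg.guidance == "BM":
        matrix = bm_matrix
    else:
        matrix = hp_matrix(hp_classification)
    threshold = (cfg.threshold_value if cfg.threshold_value is not None
                 else threshold_for_length(n))

    counter = EvaluationCounter()
    table = pair_energy_table(seq, matrix)
    population = []
    for _ in range(cfg.population_size):
        conf = chain_growth_init(n, rng)
        coords = decode_conformation(conf)
        population.append(Individual(conf, coords,
                                     score_full(coords, table, counter)))
    best = min(population, key=lambda i: i.energy).clone()
    state = SearchState(population=population, best_global=best,
                        best_current=best, counter=counter,
                        pair_energy=table)

    stats = RunStats(trajectory=[], best_conformation=best.conformation,
                     best_coords=tuple(best.coords), best_energy=best.energy,
                     best_bm_energy=evaluate_energy(best.coords, seq, bm_matrix),
                     evaluation_count=counter.count, generations=0,
                     operator_applications=Counter(),
                     operator_acceptances=Counter(), recoveries=0,
                     guidance=cfg.guidance, seed=cfg.seed)
    stats.initial_bm_energy = stats.best_bm_energy
    t0 = time.monotonic()
    last_best_bm = stats.best_bm_energy
    last_best_energy = best.energy

    def budgets_left() -> bool:
        if cfg.max_generations is not None and state.generation >= cfg.max_generations:
            return False
        if cfg.max_evaluations is not None and counter.count >= cfg.max_evaluations:
            return False
        if cfg.time_budget is not None and time.monotonic() - t0 >= cfg.time_budget:
            return False
        return True

    while budgets_left():
        evolve_generation(state, cfg, seq, matrix, rng, stats=stats)
        if state.best_global.energy < last_best_energy:
            last_best_energy = state.best_global.energy
            last_best_bm = evaluate_energy(state.best_global.coords, seq,
                                           bm_matrix)
        stats.trajectory.append(GenerationRecord(
            state.generation,
            state.last_operator,
            state.best_global.energy,
            last_best_bm,
            counter.count,
            time.monotonic() - t0,
        ))
        if state.tracking_non_improvement > threshold:
            random_walk_recover(state, cfg, seq, matrix, rng)
            stats.recoveries += 1

    stats.best_conformation = state.best_global.conformation
    stats.best_coords = tuple(state.best_global.coords)
    stats.best_energy = state.best_global.energy
    stats.best_bm_energy = last_best_bm
    stats.evaluation_count = counter.count
    stats.generations = state.generation
    return stats
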