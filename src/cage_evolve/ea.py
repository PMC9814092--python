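"""The evolutionary search over (node, linker) cage compositions.

One generation: the 20-member population produces 14 crossover offspring
(7 crossovers, each swapping building blocks between a parent pair) and 10
mutants (the fittest member is always mutated; the other nine are chosen by
a fitness-thresholded accept/reject loop; each mutation swaps the node or
the linker for either its most Dice-similar alternative or a random one,
the four operators being equally likely).  From the resulting pool of 44
the next generation of 20 is drawn by roulette-wheel selection without
replacement, with the fittest pool member always surviving (elitism).
After the configured number of generations, several runs can be combined:
duplicates removed, components re-normalised over the union and the final
fitness recomputed, yielding the C1, C2, ... ranking.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diversity import mean_pairwise_dice
from .fitness import (
    EQ2_PARAMS,
    DEFAULT_LOWER_LIMIT,
    FFParams,
    FitnessRecord,
    rank_population,
    score_population,
)
from .precursors import LibraryError, Precursor, PrecursorLibrary, most_similar

logger = logging.getLogger(__name__)

__all__ = [
    "EAConfig",
    "Candidate",
    "EAResult",
    "initialize",
    "crossover",
    "mutate",
    "roulette_select",
    "evolve",
    "combine_and_rerank",
]

MUTATION_OPERATORS = ("similar_linker", "similar_node", "random_linker", "random_node")


@dataclass
class EAConfig:
    population_size: int = 20
    generations: int = 100
    crossovers_per_gen: int = 7
    mutations_per_gen: int = 10
    ff: FFParams = field(default_factory=lambda: EQ2_PARAMS)
    lower_limit: float = DEFAULT_LOWER_LIMIT  # kJ/mol validity window floor
    elitism: bool = True
    crossover_parents: str = "roulette"  # or "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population size must be at least 2")
        if self.crossovers_per_gen < 0 or self.mutations_per_gen < 0:
            raise ValueError("operator counts must be non-negative")
        if self.crossover_parents not in ("roulette", "uniform"):
            raise ValueError("crossover_parents must be 'roulette' or 'uniform'")


@dataclass
class Candidate:
    node_id: str
    linker_id: str
    record: FitnessRecord | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.node_id, self.linker_id)

    @property
    def cage_id(self) -> str:
        return f"{self.node_id}+{self.linker_id}"

    @property
    def ff(self) -> float:
        return self.record.ff if self.record is not None else 0.0


@dataclass
class EAResult:
    population: list[Candidate]
    generations: pd.DataFrame
    config: EAConfig
    pool_sizes: list[int]


class _Cache:
    """Per-run evaluation cache; hands out fresh record copies.

    Fitness scoring mutates records in place (normalised components depend
    on the population), so shared cached records must never be scored
    directly.
    """

    def __init__(self, library: PrecursorLibrary, evaluator) -> None:
        self.library = library
        self.evaluator = evaluator
        self._store: dict[tuple[str, str], FitnessRecord] = {}

    def record_for(self, candidate: Candidate) -> FitnessRecord:
        key = candidate.key
        if key not in self._store:
            node = self.library.node(candidate.node_id)
            linker = self.library.linker(candidate.linker_id)
            self._store[key] = self.evaluator.evaluate(node, linker)
        return dataclasses.replace(self._store[key])


def initialize(
    library: PrecursorLibrary, config: EAConfig, rng: np.random.Generator
) -> list[Candidate]:
    """Uniformly random initial population of distinct compositions.

    A diverse start is part of the algorithm: compositions are drawn
    without replacement from the full node x linker product.  If the
    library is too small to fill the population with distinct cages,
    duplicates are allowed with a warning.
    """
    combos = library.combinations()
    if len(combos) >= config.population_size:
        idx = rng.choice(len(combos), size=config.population_size, replace=False)
        return [Candidate(*combos[int(i)]) for i in idx]
    warnings.warn(
        "library smaller than the population size; duplicates are inevitable",
        stacklevel=2,
    )
    out = []
    for _ in range(config.population_size):
        node = library.nodes[rng.integers(len(library.nodes))]
        linker = library.linkers[rng.integers(len(library.linkers))]
        out.append(Candidate(node.id, linker.id))
    return out


def crossover(parent1: Candidate, parent2: Candidate) -> tuple[Candidate, Candidate]:
    """Exchange building blocks: (N1,L1)x(N2,L2) -> (N1,L2), (N2,L1)."""
    return (
        Candidate(parent1.node_id, parent2.linker_id),
        Candidate(parent2.node_id, parent1.linker_id),
    )


def _scaled_fitness(population: Sequence[Candidate]) -> np.ndarray:
    """Min-max scale FF to [0, 1] for the mutation accept/reject test."""
    ff = np.array([c.ff for c in population], dtype=float)
    span = ff.max() - ff.min()
    if span == 0.0:
        return np.ones_like(ff)
    return (ff - ff.min()) / span


def _apply_operator(
    candidate: Candidate,
    operator: str,
    library: PrecursorLibrary,
    rng: np.random.Generator,
) -> Candidate:
    role = "linker" if operator.endswith("linker") else "node"
    pool = library.linkers if role == "linker" else library.nodes
    current_id = candidate.linker_id if role == "linker" else candidate.node_id
    others = [p for p in pool if p.id != current_id]
    if not others:
        logger.warning("no alternative %s available; mutation is a no-op", role)
        return Candidate(candidate.node_id, candidate.linker_id)
    if operator.startswith("similar"):
        current = library.linker(current_id) if role == "linker" else library.node(current_id)
        try:
            replacement = most_similar(current, others)
        except LibraryError:
            replacement = others[rng.integers(len(others))]
            logger.warning("similar-%s pool empty; fell back to a random exchange", role)
    else:
        replacement = others[rng.integers(len(others))]
    if role == "linker":
        return Candidate(candidate.node_id, replacement.id)
    return Candidate(replacement.id, candidate.linker_id)


def mutate(
    population: Sequence[Candidate],
    library: PrecursorLibrary,
    config: EAConfig,
    rng: np.random.Generator,
) -> list[Candidate]:
    """The mutation stage: the fittest member first, then fitness-gated picks.

    Candidates are drawn uniformly and accepted when their min-max scaled
    fitness exceeds a fresh U(0,1) draw, until the configured number of
    mutants is produced; each accepted candidate undergoes one of the four
    operators with equal probability.
    """
    if config.mutations_per_gen == 0:
        return []
    scaled = _scaled_fitness(population)
    elite_idx = int(np.lexsort(([c.cage_id for c in population], [-c.ff for c in population]))[0])
    chosen = [elite_idx]
    while len(chosen) < config.mutations_per_gen:
        idx = int(rng.integers(len(population)))
        if scaled[idx] > rng.random():
            chosen.append(idx)
    mutants = []
    for idx in chosen:
        operator = MUTATION_OPERATORS[int(rng.integers(len(MUTATION_OPERATORS)))]
        mutants.append(_apply_operator(population[idx], operator, library, rng))
    return mutants


def roulette_select(
    pool: Sequence[Candidate],
    k: int,
    rng: np.random.Generator,
    elitism: bool = True,
) -> list[Candidate]:
    """Fitness-proportional selection of k members without replacement.

    The draw runs over *distinct cage compositions*: duplicates created by
    the operators collapse onto a single wheel slot, so a generation keeps
    chemically distinct members whenever the pool allows it (populations
    that degenerate into copies of one cage cannot explore).  If the pool
    holds fewer than k distinct compositions the shortfall is filled by a
    second fitness-proportional draw over the leftovers.  The fittest pool
    member always survives when ``elitism`` is on.  If every member has
    zero fitness the draw degrades to uniform (with a warning).
    """
    if k > len(pool):
        raise ValueError(f"cannot select {k} members from a pool of {len(pool)}")
    unique: dict[tuple[str, str], Candidate] = {}
    for c in sorted(pool, key=lambda c: (-c.ff, c.cage_id)):
        unique.setdefault(c.key, c)
    distinct = list(unique.values())
    ff = np.array([c.ff for c in distinct], dtype=float)
    if ff.sum() <= 0.0:
        warnings.warn("all pool members have zero fitness; selecting uniformly", stacklevel=2)

    def _draw(candidates: list[Candidate], weights: np.ndarray, n: int) -> list[int]:
        """n fitness-proportional picks without replacement (uniform if flat)."""
        probs = weights / weights.sum() if weights.sum() > 0 else None
        picked = rng.choice(len(candidates), size=n, replace=False, p=probs)
        return [int(i) for i in picked]

    selected: list[Candidate] = []
    taken: set[int] = set()
    if elitism and len(distinct) > 0:
        taken.add(0)  # distinct is sorted best-first
        selected.append(distinct[0])
    rest = [i for i in range(len(distinct)) if i not in taken]
    n_main = min(k - len(selected), len(rest))
    if n_main > 0:
        for j in _draw([distinct[i] for i in rest], ff[rest], n_main):
            selected.append(distinct[rest[j]])
    while len(selected) < k:  # pool had fewer distinct compositions than k
        leftovers = [c for c in pool if all(c is not s for s in selected)]
        weights = np.array([c.ff for c in leftovers], dtype=float)
        for j in _draw(leftovers, weights, min(k - len(selected), len(leftovers))):
            selected.append(leftovers[j])
    return selected


def _pick_parents(
    population: Sequence[Candidate], config: EAConfig, rng: np.random.Generator
) -> tuple[Candidate, Candidate]:
    ff = np.array([c.ff for c in population], dtype=float)
    if config.crossover_parents == "roulette" and ff.sum() > 0:
        probs = ff / ff.sum()
    else:
        probs = None
    i, j = rng.choice(len(population), size=2, replace=False, p=probs)
    return population[int(i)], population[int(j)]


def _score(candidates: Sequence[Candidate], cache: _Cache, config: EAConfig) -> None:
    for c in candidates:
        c.record = cache.record_for(c)
    score_population([c.record for c in candidates], params=config.ff, lower_limit=config.lower_limit)


def _generation_stats(
    gen: int, population: Sequence[Candidate], library: PrecursorLibrary
) -> dict:
    ff = np.array([c.ff for c in population], dtype=float)
    valid = [c.record for c in population if c.record.valid]
    def _mean(attr):
        vals = [getattr(r, attr) for r in valid if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else float("nan")
    return {
        "generation": gen,
        "min_ff": float(ff.min()),
        "mean_ff": float(ff.mean()),
        "max_ff": float(ff.max()),
        "mean_E_binding": _mean("E_binding"),
        "mean_A_complex": _mean("A_complex"),
        "mean_A_cage": _mean("A_cage"),
        "mean_dice": mean_pairwise_dice(population, library),
        "members": ";".join(sorted(c.cage_id for c in population)),
    }


def evolve(
    library: PrecursorLibrary,
    evaluator,
    config: EAConfig | None = None,
) -> EAResult:
    """Run the full generational loop; reproducible from ``config.seed``."""
    config = config or EAConfig()
    rng = np.random.default_rng(config.seed)
    cache = _Cache(library, evaluator)

    population = initialize(library, config, rng)
    _score(population, cache, config)
    stats = [_generation_stats(0, population, library)]
    pool_sizes: list[int] = []

    for gen in range(1, config.generations + 1):
        offspring: list[Candidate] = []
        for _ in range(config.crossovers_per_gen):
            p1, p2 = _pick_parents(population, config, rng)
            offspring.extend(crossover(p1, p2))
        mutants = mutate(population, library, config, rng)
        pool = list(population) + offspring + mutants
        pool_sizes.append(len(pool))
        _score(pool, cache, config)
        population = roulette_select(pool, config.population_size, rng, config.elitism)
        _score(population, cache, config)
        stats.append(_generation_stats(gen, population, library))
        logger.info(
            "generation %d: max FF %.4g, mean FF %.4g",
            gen, stats[-1]["max_ff"], stats[-1]["mean_ff"],
        )

    return EAResult(list(population), pd.DataFrame(stats), config, pool_sizes)


def combine_and_rerank(
    final_populations: Iterable[Sequence[Candidate]],
    lower_limit: float = DEFAULT_LOWER_LIMIT,
) -> pd.DataFrame:
    """Union the runs, drop duplicates, re-normalise and re-rank.

    Re-scoring uses the final three-component fitness over the combined
    set (per-run FF values are not comparable across runs).  Returns a
    table with code names C1, C2, ... in descending fitness order.
    """
    unique: dict[tuple[str, str], Candidate] = {}
    for population in final_populations:
        for c in population:
            if c.record is None:
                raise ValueError(f"candidate {c.cage_id} has no evaluated record")
            unique.setdefault(c.key, c)
    candidates = sorted(unique.values(), key=lambda c: c.cage_id)
    records = [dataclasses.replace(c.record) for c in candidates]
    score_population(records, params=EQ2_PARAMS, lower_limit=lower_limit)
    ranked = rank_population(records)
    rows = []
    for i, r in enumerate(ranked, start=1):
        node_id, linker_id = r.cage_id.split("+", 1)
        rows.append(
            {
                "code_name": f"C{i}",
                "cage_id": r.cage_id,
                "node_id": node_id,
                "linker_id": linker_id,
                "FF": r.ff,
                "E_binding": r.E_binding,
                "D_complex": r.D_complex,
                "A_complex": r.A_complex,
                "D_cage": r.D_cage,
                "A_cage": r.A_cage,
            }
        )
    return pd.DataFrame(rows)
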