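"""Simulated annealing over connected disease modules.

Starting from each disease's seed (the largest connected component of its
known proteins in the interactome), the optimizer simultaneously grows and
shrinks all modules — one random single-protein perturbation at a time,
always preserving connectivity and seed membership — while minimizing the
squared distance between the pairwise module Jaccard similarity and the
gold-standard phenotypic similarity.

Moves are accepted by the Metropolis rule under a geometric cooling
schedule: improvements always, worsenings with probability exp(-delta/T).
The objective is maintained incrementally and re-verified against a full
recomputation at periodic checkpoints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

from .network import (
    ProteinNetwork,
    cascade_remove,
    frontier,
    is_connected_in,
    largest_connected_component,
)
from .similarity import PhenotypeSimilarityMatrix, delta_objective, objective

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleState",
    "AnnealingConfig",
    "AnnealingTrace",
    "TraceRecord",
    "Move",
    "acceptance_probability",
    "cooling_schedule",
    "propose_move",
    "anneal",
    "initial_states",
]


@dataclass
class ModuleState:
    """One disease's immutable seed and its current connected module.

    Invariants: the seed is non-empty, contained in the module, and the
    module induces a connected subgraph; the seed never changes during
    optimization.
    """

    disease_id: str
    seed: frozenset[str]
    module: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.seed = frozenset(self.seed)
        if not self.seed:
            raise ValueError(f"disease {self.disease_id!r} has an empty seed")
        if not self.module:
            self.module = set(self.seed)
        if not self.seed <= self.module:
            raise ValueError(f"seed of {self.disease_id!r} not contained in module")

    @property
    def predicted(self) -> set[str]:
        """Novel predictions: module members outside the seed."""
        return self.module - self.seed

    def validate(self, network: ProteinNetwork) -> None:
        if not is_connected_in(self.module, network):
            raise AssertionError(f"module of {self.disease_id!r} is disconnected")
        if not self.seed <= self.module:
            raise AssertionError(f"seed of {self.disease_id!r} escaped the module")

    def copy(self) -> "ModuleState":
        return ModuleState(self.disease_id, self.seed, set(self.module))


@dataclass(frozen=True)
class AnnealingConfig:
    """Annealing parameters.

    Defaults follow the published operating point: start temperature 5,
    geometric decay by 0.995 per level down to 1e-25, 200 proposals per
    level.  ``fast()`` gives a desk-scale schedule for small benchmarks.
    """

    max_temp: float = 5.0
    min_temp: float = 1e-25
    alpha: float = 0.995
    steps_per_temp: int = 200
    rng_seed: int = 0
    report_best: bool = False
    check_every: int = 100  # full-recompute verification cadence (temp levels)
    snapshot_every: int | None = None  # record module snapshots in the trace
    validate_moves: bool = False  # debug: re-check invariants after each accept

    def __post_init__(self) -> None:
        if not (0 < self.min_temp < self.max_temp):
            raise ValueError("require 0 < min_temp < max_temp")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.steps_per_temp < 1:
            raise ValueError("steps_per_temp must be >= 1")
        if self.check_every < 1:
            raise ValueError("check_every must be >= 1")

    @classmethod
    def fast(cls, **overrides) -> "AnnealingConfig":
        """Shortened schedule for small benchmarks (min_temp=1e-4, alpha=0.95,
        100 steps per level)."""
        base = cls(min_temp=1e-4, alpha=0.95, steps_per_temp=100)
        return replace(base, **overrides)


class TraceRecord(NamedTuple):
    temperature: float
    objective: float
    best_objective: float
    accepted: int
    modules: dict[str, frozenset[str]] | None = None


@dataclass
class AnnealingTrace:
    """Per-temperature history of an annealing run."""

    records: list[TraceRecord] = field(default_factory=list)

    def append(self, record: TraceRecord) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TraceRecord]:
        return iter(self.records)

    @property
    def objectives(self) -> list[float]:
        return [r.objective for r in self.records]

    @property
    def best_objectives(self) -> list[float]:
        return [r.best_objective for r in self.records]

    def snapshots(self) -> list[TraceRecord]:
        """Records that carry a module snapshot."""
        return [r for r in self.records if r.modules is not None]


def acceptance_probability(delta: float, temp: float) -> float:
    """Metropolis acceptance: 1 for improvements, exp(-delta/temp) otherwise."""
    if temp <= 0:
        raise ValueError("temperature must be positive")
    if delta <= 0:
        return 1.0
    return math.exp(-delta / temp)


def cooling_schedule(config: AnnealingConfig) -> Iterator[float]:
    """Geometric temperature sequence: T0 = max_temp, T <- alpha * T, ending
    before the temperature would fall below min_temp."""
    t = config.max_temp
    while t >= config.min_temp:
        yield t
        t *= config.alpha


class Move(NamedTuple):
    """A proposed perturbation: ``('add', p)``, ``('remove', p)`` or
    ``('skip', None)`` when no move exists."""

    action: str
    protein: str | None


def _uniform_choice(pool: set[str], rng: np.random.Generator) -> str:
    # sorted() makes the draw independent of set iteration order
    items = sorted(pool)
    return items[rng.integers(len(items))]


def propose_move(
    state: ModuleState, network: ProteinNetwork, rng: np.random.Generator
) -> Move:
    """Propose a random single-protein perturbation for one disease.

    Chooses add or remove with equal probability; an addition draws
    uniformly from the module frontier, a removal uniformly from the
    non-seed module members.  If the chosen pool is empty the other action
    is used; if both pools are empty the move is a skip.
    """
    add_pool = frontier(state.module, network)
    remove_pool = state.module - state.seed
    want_add = bool(rng.integers(2))
    if want_add and not add_pool:
        want_add = False
    elif not want_add and not remove_pool:
        want_add = True
    if want_add:
        if not add_pool:
            return Move("skip", None)
        return Move("add", _uniform_choice(add_pool, rng))
    if not remove_pool:
        return Move("skip", None)
    return Move("remove", _uniform_choice(remove_pool, rng))


def initial_states(
    known_proteins: Mapping[str, Iterable[str]], network: ProteinNetwork
) -> tuple[list[ModuleState], list[str]]:
    """Seed every disease with the largest connected component of its known
    proteins in the network.

    Returns the seeded states plus the diseases that were dropped because
    none of their proteins is in the network; dropped diseases are logged.
    """
    states: list[ModuleState] = []
    dropped: list[str] = []
    for disease in sorted(known_proteins):
        lcc = largest_connected_component(set(known_proteins[disease]), network)
        if not lcc:
            dropped.append(disease)
            continue
        states.append(ModuleState(disease, frozenset(lcc)))
    if dropped:
        logger.info(
            "dropped %d disease(s) with no protein in the network: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    return states, dropped


def anneal(
    states: Sequence[ModuleState],
    phen: PhenotypeSimilarityMatrix,
    network: ProteinNetwork,
    config: AnnealingConfig,
) -> tuple[list[ModuleState], AnnealingTrace]:
    """Run simulated annealing over all disease modules simultaneously.

    At every temperature level ``steps_per_temp`` proposals are made; each
    proposal picks a disease uniformly at random, then a single-protein
    add/remove perturbation of its module.  Every applied move preserves
    connectivity and seed membership.  Identical inputs and ``rng_seed``
    produce identical output.

    Returns the final states (or the best-so-far states when
    ``config.report_best`` is set) and the per-temperature trace.
    """
    if len(states) < 2:
        raise ValueError("annealing needs at least two diseases")
    ids = [s.disease_id for s in states]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate disease identifiers in states")
    if set(ids) != set(phen.disease_ids):
        raise ValueError("states and phenotypic similarity cover different diseases")
    for s in states:
        if not is_connected_in(set(s.seed), network):
            raise ValueError(f"seed of {s.disease_id!r} is not connected")
        if not is_connected_in(s.module, network):
            raise ValueError(f"module of {s.disease_id!r} is not connected")

    rng = np.random.default_rng(config.rng_seed)
    work = {s.disease_id: s.copy() for s in states}
    modules = {d: work[d].module for d in ids}

    current = objective(modules, phen)
    best = current
    best_modules = {d: frozenset(m) for d, m in modules.items()}
    trace = AnnealingTrace()

    def snapshot() -> dict[str, frozenset[str]]:
        return {d: frozenset(m) for d, m in modules.items()}

    for level, temp in enumerate(cooling_schedule(config)):
        accepted = 0
        for _ in range(config.steps_per_temp):
            disease = ids[rng.integers(len(ids))]
            state = work[disease]
            move = propose_move(state, network, rng)
            if move.action == "skip":
                continue
            if move.action == "add":
                new_module = state.module | {move.protein}
            else:
                new_module = cascade_remove(
                    state.module, set(state.seed), move.protein, network
                )
                if new_module == state.module:
                    continue
            delta = delta_objective(disease, new_module, modules, phen)
            if acceptance_probability(delta, temp) >= rng.random():
                state.module = new_module
                modules[disease] = new_module
                current += delta
                accepted += 1
                if config.validate_moves:
                    state.validate(network)
                if current < best:
                    best = current
                    best_modules = snapshot()
        if (level + 1) % config.check_every == 0:
            full = objective(modules, phen)
            if abs(full - current) > 1e-6:
                raise RuntimeError(
                    f"incremental objective drifted: {current} vs {full}"
                )
            current = full
        record_snapshot = (
            snapshot()
            if config.snapshot_every is not None
            and level % config.snapshot_every == 0
            else None
        )
        trace.append(TraceRecord(temp, current, best, accepted, record_snapshot))

    if config.report_best:
        final = [
            ModuleState(d, work[d].seed, set(best_modules[d])) for d in ids
        ]
    else:
        final = [work[d] for d in ids]
    return final, trace
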