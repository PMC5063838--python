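"""Plant-growth-simulation optimiser over discrete candidate solutions.

The metaphor: a plant grows from a root R_0 toward light (the optimum).
Each candidate solution is a growth node; nodes strictly fitter than the
root receive a morphactin concentration

    C_Ti = (f(R_0) - f(R_Ti)) / sum_k (f(R_0) - f(R_Tk)),

a probability simplex over the live nodes. A uniform draw beta in [0, 1]
selects the preferential node by cumulative-interval (roulette) lookup;
that node branches — it proposes up to q new candidates, retires with
concentration zero, and concentrations are reallocated over the survivors
and any eligible newcomers with the same formula. The search stops when
the best fitness has not improved for `patience` growth cycles, the
iteration budget is exhausted, or the plant has no live node left.

The engine is objective-agnostic: candidates are opaque objects exposing
a real `fitness` and a hashable `key` (duplicate keys collapse to one
node). Lower fitness is better throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Protocol, Sequence

import numpy as np

from .config import EngineConfig

__all__ = [
    "Candidate",
    "GrowthNode",
    "PlantState",
    "EmptyPlantError",
    "InitializationError",
    "allocate_concentrations",
    "select_preferential_node",
    "branch",
    "run",
]


class Candidate(Protocol):
    fitness: float

    @property
    def key(self) -> Hashable: ...


#: A proposer maps (selected candidate, rng) to an iterable of evaluated
#: candidates (the branch's prospective nodes); an initializer maps rng to
#: the k initial trunk candidates.
Proposer = Callable[[Candidate, np.random.Generator], Iterable[Candidate]]
Initializer = Callable[[np.random.Generator], Sequence[Candidate]]


class EmptyPlantError(RuntimeError):
    """No live node remains (or none was ever eligible)."""


class InitializationError(RuntimeError):
    """The initializer produced no eligible candidate within max_restarts."""


@dataclass(eq=False)          # identity semantics: list.index must not merge equal-valued nodes
class GrowthNode:
    candidate: Candidate
    fitness: float
    origin: str                      # "trunk" | "branch"
    alive: bool = True
    concentration: float = 0.0
    created: int = 0                 # creation sequence number (tie-break)


@dataclass
class PlantState:
    root_fitness: float
    nodes: list[GrowthNode] = field(default_factory=list)
    best: GrowthNode | None = None
    iteration: int = 0
    seed: int | None = None
    keys: set = field(default_factory=set)

    @property
    def alive_nodes(self) -> list[GrowthNode]:
        return [n for n in self.nodes if n.alive]

    def add_node(self, candidate: Candidate, origin: str) -> GrowthNode | None:
        """Admit a candidate as a live node if eligible and novel.

        Eligibility is strict fitness advantage over the root; duplicate
        keys (already-seen triples) are collapsed. Returns the node, or
        None if the candidate was not admitted.
        """
        if candidate.fitness is None or not candidate.fitness < self.root_fitness:
            return None
        key = candidate.key
        if key in self.keys:
            return None
        node = GrowthNode(candidate=candidate, fitness=float(candidate.fitness),
                          origin=origin, created=len(self.nodes))
        self.nodes.append(node)
        self.keys.add(key)
        if self.best is None or node.fitness < self.best.fitness:
            self.best = node
        return node


def allocate_concentrations(state: PlantState) -> PlantState:
    """Assign morphactin concentrations to the live nodes (in place).

    Covers both the initial allocation and every post-branch reallocation:
    the retired node is simply absent from the live set, so its deficit is
    dropped from numerator and denominator alike. Raises
    :class:`EmptyPlantError` when no live node exists.
    """
    alive = state.alive_nodes
    if not alive:
        raise EmptyPlantError("no live growth node")
    deficits = np.array([state.root_fitness - n.fitness for n in alive])
    if np.any(deficits <= 0):
        raise ValueError("live node with fitness >= root fitness")
    conc = deficits / deficits.sum()
    for node, c in zip(alive, conc):
        node.concentration = float(c)
    return state


def select_preferential_node(state: PlantState, beta: float) -> int:
    """Roulette lookup: the node M whose cumulative-concentration interval
    (sum_{i<M}, sum_{i<=M}] contains beta (closed at 0 for the first node).

    Returns the index into ``state.nodes``; deterministic given beta.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    alive = state.alive_nodes
    if not alive:
        raise EmptyPlantError("no live growth node")
    cum = np.cumsum([n.concentration for n in alive])
    if abs(cum[-1] - 1.0) > 1e-9:
        raise ValueError("concentrations are not allocated (sum != 1)")
    m = int(np.searchsorted(cum, beta, side="left"))
    m = min(m, len(alive) - 1)       # guard against beta == 1.0 + fp round-off
    return state.nodes.index(alive[m])


def branch(
    state: PlantState,
    m: int,
    proposer: Proposer,
    q: int,
    rng: np.random.Generator,
) -> PlantState:
    """Grow a branch from node ``m``: retire it, admit up to q proposals,
    and reallocate concentrations over the surviving live set."""
    node = state.nodes[m]
    if not node.alive:
        raise ValueError("cannot branch a retired node")
    node.alive = False
    node.concentration = 0.0
    admitted = 0
    for cand in proposer(node.candidate, rng):
        if admitted >= q:
            break
        if state.add_node(cand, origin="branch") is not None:
            admitted += 1
    if state.alive_nodes:
        allocate_concentrations(state)
    return state


def run(
    proposer: Proposer,
    initializer: Initializer,
    config: EngineConfig | None = None,
    seed: int = 0,
) -> PlantState:
    """Full growth loop: initialise k trunk nodes, then repeat
    allocate -> roulette-select -> branch until convergence.

    Termination: `patience` consecutive cycles without best-fitness
    improvement, `max_iterations` cycles, or plant exhaustion. A fixed
    seed reproduces the trajectory bit-for-bit.
    """
    config = config or EngineConfig()
    rng = np.random.default_rng(seed)
    state = PlantState(root_fitness=config.root_fitness, seed=seed)
    for _ in range(config.max_restarts):
        for cand in initializer(rng):
            state.add_node(cand, origin="trunk")
        if state.alive_nodes:
            break
    else:
        raise InitializationError(
            f"no eligible candidate after {config.max_restarts} restarts")

    stall = 0
    while (state.iteration < config.max_iterations
           and stall < config.patience
           and state.alive_nodes):
        allocate_concentrations(state)
        beta = float(rng.uniform())
        m = select_preferential_node(state, beta)
        previous_best = state.best.fitness
        branch(state, m, proposer, config.q, rng)
        state.iteration += 1
        if state.best.fitness < previous_best:
            stall = 0
        else:
            stall += 1
    return state
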