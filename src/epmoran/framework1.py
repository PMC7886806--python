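"""Framework 1: extended phenotypes attached at birth, bonus for holders.

One cycle = ``round(renewal_rate * N)`` sequential death-birth events, then a
global EP-timer decrement.  In each event a uniformly chosen individual dies;
one of its neighbors, drawn with probability proportional to relative
fitness, reproduces into the vacancy.  A newborn of an EP-producing type
rolls for a fresh EP; a dying holder's EP is offered (timer intact) to a
random reuse-capable, EP-less neighbor, then to any such individual in the
graph, and vanishes if none exists.  Fixation is checked at cycle boundaries.

``run_sample_f1`` dispatches to a compiled kernel by default
(``engine="numba"``); ``engine="python"`` composes the granular operations
below and supports event-log auditing of EP lifetimes.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from . import _kernels
from .config import SimConfig
from .graph import PopulationGraph
from .state import (
    BehaviorState,
    NodeType,
    SampleOutcome,
    SimState,
    classify_outcome,
    init_population,
)


def _fitness_array_f1(state: SimState, config: SimConfig) -> np.ndarray:
    base = np.where(state.ntype == 0, config.base_fitness_a, config.base_fitness_b)
    alpha = np.where(state.ntype == 0, config.alpha_a, config.alpha_b)
    return base + alpha * (state.ep > 0)


def reassign_ep_f1(
    dying_node: int,
    state: SimState,
    graph: PopulationGraph,
    config: SimConfig,
    rng: np.random.Generator,
    audit_log: Union[list, None] = None,
) -> SimState:
    """Offer the dying node's EP to a new holder, or destroy it.

    Priority: (a) uniform among reuse-capable, EP-less neighbors; (b) else
    uniform among all reuse-capable, EP-less individuals in the graph; (c)
    else the token vanishes.  The lifetime counter is carried over unchanged.
    """
    assert state.ep[dying_node] > 0, "reassign_ep_f1 requires a dying EP holder"
    t_left = int(state.ep[dying_node])
    token = int(state.ep_id[dying_node])
    state.ep[dying_node] = 0
    state.ep_id[dying_node] = -1
    reuse_ok = config.can_reuse()

    def eligible(j: int) -> bool:
        return j != dying_node and reuse_ok[state.ntype[j]] and state.ep[j] == 0

    indptr, indices = graph.csr()
    neighbors = [int(j) for j in indices[indptr[dying_node]: indptr[dying_node + 1]]]
    pool = [j for j in neighbors if eligible(j)]
    if not pool:
        pool = [j for j in range(state.n) if eligible(j)]
    if pool:
        r = pool[int(rng.integers(len(pool)))]
        state.ep[r] = t_left
        state.ep_id[r] = token
        if audit_log is not None:
            audit_log.append(("transfer", state.cycle, token, dying_node, r, t_left))
    else:
        if audit_log is not None:
            audit_log.append(("vanish", state.cycle, token, dying_node, -1, t_left))
    return state


def death_birth_event_f1(
    state: SimState,
    graph: PopulationGraph,
    config: SimConfig,
    rng: np.random.Generator,
    audit_log: Union[list, None] = None,
    uniform_parent: bool = False,
) -> SimState:
    """One death-birth event: uniform death, fitness-weighted neighbor birth.

    The dying node's EP (if any) is reassigned before the newborn is placed;
    the newborn is never a candidate recipient and only rolls for its own
    fresh EP via the type's birth chance.
    """
    n = state.n
    d = int(rng.integers(n))
    indptr, indices = graph.csr()
    neighbors = indices[indptr[d]: indptr[d + 1]]
    if uniform_parent:
        parent = int(neighbors[rng.integers(len(neighbors))])
    else:
        fits = _fitness_array_f1(state, config)[neighbors]
        parent = int(neighbors[rng.choice(len(neighbors), p=fits / fits.sum())])
    new_t = int(state.ntype[parent])
    if state.ep[d] > 0:
        reassign_ep_f1(d, state, graph, config, rng, audit_log)
    state.ntype[d] = new_t
    state.residence[d] = 0
    chance = config.birth_ep_chance_a if new_t == NodeType.A else config.birth_ep_chance_b
    if rng.random() < chance:
        state.new_ep(d, config.ep_lifetime)
        state.bstate[d] = BehaviorState.USING_OWN
        if audit_log is not None:
            audit_log.append(("birth", state.cycle, int(state.ep_id[d]), d, d, config.ep_lifetime))
    else:
        state.bstate[d] = BehaviorState.SEARCHING
    return state


def run_cycle_f1(
    state: SimState,
    graph: PopulationGraph,
    config: SimConfig,
    rng: np.random.Generator,
    audit_log: Union[list, None] = None,
    uniform_parent: bool = False,
) -> SimState:
    """One full cycle: the event batch, then the EP-timer sweep."""
    for _ in range(config.events_per_cycle()):
        death_birth_event_f1(state, graph, config, rng, audit_log, uniform_parent)
    held = state.ep > 0
    state.ep[held] -= 1
    expired = held & (state.ep == 0)
    for i in np.flatnonzero(expired):
        if audit_log is not None:
            audit_log.append(("expire", state.cycle, int(state.ep_id[i]), int(i), -1, 0))
        state.ep_id[i] = -1
        state.bstate[i] = BehaviorState.SEARCHING
    state.cycle += 1
    return state


def run_sample_f1(
    graph: PopulationGraph,
    config: SimConfig,
    seed: int,
    engine: str = "numba",
    initial_types: Union[np.ndarray, None] = None,
    uniform_parent: bool = False,
    audit_log: Union[list, None] = None,
) -> SampleOutcome:
    """Run one framework-1 sample to fixation or the cycle limit.

    Fully reproducible from ``(graph, config, seed)`` for a given engine.
    ``initial_types`` (an int array, 0 = A, 1 = B) overrides the random
    initial type placement — used by the oracle cross-checks and forced-start
    tests.  ``uniform_parent`` deliberately ignores fitness in parent
    selection (a broken simulator used as a mutation-test control).
    ``audit_log`` collects (event, cycle, token, from, to, timer) tuples and
    requires the python engine.
    """
    if config.framework != 1:
        raise ValueError("run_sample_f1 requires a framework-1 config")
    rng = np.random.default_rng(seed)
    state = init_population(graph, config, rng)
    if initial_types is not None:
        state.ntype[:] = np.asarray(initial_types, dtype=np.int8)
        # EPs granted at init to nodes of a non-producing type are revoked
        produces = config.produces_at_birth()
        for i in range(state.n):
            if state.ep[i] > 0 and not produces[state.ntype[i]]:
                state.ep[i] = 0
                state.ep_id[i] = -1

    if engine == "numba":
        indptr, indices = graph.csr()
        code, cycles, count_a, ep_total, ep_a = _kernels.run_sample_f1(
            indptr,
            indices,
            state.ntype,
            state.ep,
            np.array([config.base_fitness_a, config.base_fitness_b]),
            np.array([config.alpha_a, config.alpha_b]),
            np.array([config.birth_ep_chance_a, config.birth_ep_chance_b]),
            np.array(config.can_reuse(), dtype=np.bool_),
            config.events_per_cycle(),
            config.ep_lifetime,
            config.cycle_limit,
            seed,
            uniform_parent,
        )
        state.cycle = int(cycles)
        return classify_outcome(state, config, seed=seed)
    elif engine == "python":
        while 0 < state.count_a() < state.n and state.cycle < config.cycle_limit:
            run_cycle_f1(state, graph, config, rng, audit_log, uniform_parent)
        return classify_outcome(state, config, seed=seed)
    raise ValueError(f"unknown engine {engine!r}")
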