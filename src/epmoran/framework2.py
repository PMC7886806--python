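"""Framework 2: four behavioral states with timed transitions.

Individuals cycle through searching -> producing -> using-own -> searching,
paying a production cost beta and earning an own-use bonus alpha; a searcher
that inherits an abandoned EP jumps to using-other and earns gamma until the
token's (uninterrupted) timer runs out.  Newborns always start searching with
no EP; EPs are created only by the producing->using-own transition, so the
birth-EP chance of framework 1 plays no role here.

Per cycle: the death-birth event batch first, then one global sweep that
advances residence counters, fires timed transitions, and decrements EP
timers (expired holders fall back to searching).
"""

from __future__ import annotations

from typing import Union

import numpy as np

from . import _kernels
from .config import SimConfig
from .graph import PopulationGraph
from .state import (
    BehaviorState,
    SampleOutcome,
    SimState,
    classify_outcome,
    init_population,
)

S, P, UO, UX = (
    BehaviorState.SEARCHING,
    BehaviorState.PRODUCING,
    BehaviorState.USING_OWN,
    BehaviorState.USING_OTHER,
)


def _fitness_array_f2(state: SimState, config: SimConfig) -> np.ndarray:
    base = np.where(state.ntype == 0, config.base_fitness_a, config.base_fitness_b)
    alpha = np.where(state.ntype == 0, config.alpha_a, config.alpha_b)
    beta = np.where(state.ntype == 0, config.beta_a, config.beta_b)
    gamma = np.where(state.ntype == 0, config.gamma_a, config.gamma_b)
    mod = np.select(
        [state.bstate == S, state.bstate == P, state.bstate == UO, state.bstate == UX],
        [0.0, -beta, alpha, gamma],
    )
    return base + mod


def reassign_ep_f2(
    dying_node: int,
    state: SimState,
    graph: PopulationGraph,
    config: SimConfig,
    rng: np.random.Generator,
    audit_log: Union[list, None] = None,
) -> SimState:
    """Offer the dying node's EP to a searching conspecific-capable recipient.

    Priority: uniform among searching, reuse-capable, EP-less neighbors; else
    uniform among all such individuals graph-wide; else the token vanishes.
    The recipient enters using-other with its residence reset; the token
    keeps its remaining timer.
    """
    assert state.ep[dying_node] > 0
    t_left = int(state.ep[dying_node])
    token = int(state.ep_id[dying_node])
    state.ep[dying_node] = 0
    state.ep_id[dying_node] = -1
    reuse_ok = config.can_reuse()

    def eligible(j: int) -> bool:
        return (
            j != dying_node
            and reuse_ok[state.ntype[j]]
            and state.ep[j] == 0
            and state.bstate[j] == S
        )

    indptr, indices = graph.csr()
    neighbors = [int(j) for j in indices[indptr[dying_node]: indptr[dying_node + 1]]]
    pool = [j for j in neighbors if eligible(j)]
    if not pool:
        pool = [j for j in range(state.n) if eligible(j)]
    if pool:
        r = pool[int(rng.integers(len(pool)))]
        state.ep[r] = t_left
        state.ep_id[r] = token
        state.bstate[r] = UX
        state.residence[r] = 0
        if audit_log is not None:
            audit_log.append(("transfer", state.cycle, token, dying_node, r, t_left))
    elif audit_log is not None:
        audit_log.append(("vanish", state.cycle, token, dying_node, -1, t_left))
    return state


def death_birth_event_f2(
    state: SimState,
    graph: PopulationGraph,
    config: SimConfig,
    rng: np.random.Generator,
    audit_log: Union[list, None] = None,
    uniform_parent: bool = False,
) -> SimState:
    """One death-birth event; the newborn always starts searching, EP-less."""
    n = state.n
    d = int(rng.integers(n))
    indptr, indices = graph.csr()
    neighbors = indices[indptr[d]: indptr[d + 1]]
    if uniform_parent:
        parent = int(neighbors[rng.integers(len(neighbors))])
    else:
        fits = _fitness_array_f2(state, config)[neighbors]
        parent = int(neighbors[rng.choice(len(neighbors), p=fits / fits.sum())])
    new_t = int(state.ntype[parent])
    if state.ep[d] > 0:
        reassign_ep_f2(d, state, graph, config, rng, audit_log)
    state.ntype[d] = new_t
    state.bstate[d] = S
    state.residence[d] = 0
    return state


def transition_states_f2(
    state: SimState,
    config: SimConfig,
    audit_log: Union[list, None] = None,
) -> SimState:
    """End-of-cycle sweep: residence, timed transitions, EP timers.

    Searching nodes of a producing-capable type (beta != -1) move to
    producing after ``state_time`` cycles; producers move to using-own after
    another ``state_time`` cycles and build a fresh EP.  Every EP timer then
    drops by one; holders of expired tokens fall back to searching.
    """
    produce_ok = config.can_produce()
    for i in range(state.n):
        state.residence[i] += 1
        s = state.bstate[i]
        if s == S:
            if produce_ok[state.ntype[i]] and state.residence[i] >= config.state_time:
                state.bstate[i] = P
                state.residence[i] = 0
        elif s == P:
            if state.residence[i] >= config.state_time:
                state.bstate[i] = UO
                state.residence[i] = 0
                state.new_ep(i, config.ep_lifetime)
                if audit_log is not None:
                    audit_log.append(
                        ("birth", state.cycle, int(state.ep_id[i]), i, i, config.ep_lifetime)
                    )
    held = state.ep > 0
    state.ep[held] -= 1
    expired = held & (state.ep == 0)
    for i in np.flatnonzero(expired):
        if audit_log is not None:
            audit_log.append(("expire", state.cycle, int(state.ep_id[i]), int(i), -1, 0))
        state.ep_id[i] = -1
        state.bstate[i] = S
        state.residence[i] = 0
    return state


def run_cycle_f2(
    state: SimState,
    graph: PopulationGraph,
    config: SimConfig,
    rng: np.random.Generator,
    audit_log: Union[list, None] = None,
    uniform_parent: bool = False,
) -> SimState:
    for _ in range(config.events_per_cycle()):
        death_birth_event_f2(state, graph, config, rng, audit_log, uniform_parent)
    transition_states_f2(state, config, audit_log)
    state.cycle += 1
    return state


def run_sample_f2(
    graph: PopulationGraph,
    config: SimConfig,
    seed: int,
    engine: str = "numba",
    initial_types: Union[np.ndarray, None] = None,
    uniform_parent: bool = False,
    audit_log: Union[list, None] = None,
) -> SampleOutcome:
    """Run one framework-2 sample to fixation or the cycle limit.

    Same contract as :func:`epmoran.framework1.run_sample_f1`.
    """
    if config.framework != 2:
        raise ValueError("run_sample_f2 requires a framework-2 config")
    rng = np.random.default_rng(seed)
    state = init_population(graph, config, rng)
    if initial_types is not None:
        state.ntype[:] = np.asarray(initial_types, dtype=np.int8)

    if engine == "numba":
        indptr, indices = graph.csr()
        res = _kernels.run_sample_f2(
            indptr,
            indices,
            state.ntype,
            state.bstate,
            state.ep,
            state.residence,
            np.array([config.base_fitness_a, config.base_fitness_b]),
            np.array([config.alpha_a, config.alpha_b]),
            np.array([config.beta_a, config.beta_b]),
            np.array([config.gamma_a, config.gamma_b]),
            np.array(config.can_produce(), dtype=np.bool_),
            np.array(config.can_reuse(), dtype=np.bool_),
            config.events_per_cycle(),
            config.ep_lifetime,
            config.state_time,
            config.cycle_limit,
            seed,
            uniform_parent,
        )
        state.cycle = int(res[1])
        return classify_outcome(state, config, seed=seed)
    elif engine == "python":
        while 0 < state.count_a() < state.n and state.cycle < config.cycle_limit:
            run_cycle_f2(state, graph, config, rng, audit_log, uniform_parent)
        return classify_outcome(state, config, seed=seed)
    raise ValueError(f"unknown engine {engine!r}")
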