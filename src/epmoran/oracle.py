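"""Exact validation tools for the death-birth core.

With extended phenotypes disabled, one death-birth event is a first-order
Markov chain on the 2^N type-configurations of a tiny graph, absorbing at
the two monomorphic states.  Solving the absorption linear system gives the
exact type-A fixation probability, an independent check that the simulator's
uniform-death / fitness-weighted-birth rule is implemented correctly.
Batching events into cycles does not change absorption probabilities
(events are sequential and i.i.d.), so the oracle steps one event at a time.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .config import SimConfig
from .framework1 import run_sample_f1
from .graph import PopulationGraph, generate_ba_graph
from .state import Outcome

import networkx as nx

MAX_ORACLE_NODES = 12  # 2^12 states keeps the sparse solve well under a second


def _transition_matrix(graph: PopulationGraph, fitness_by_type) -> scipy.sparse.csr_matrix:
    """Row-stochastic one-event transition matrix over all 2^N type states.

    State s encodes node i's type in bit i (set = type A).  An event: node d
    dies with probability 1/N; a neighbor reproduces into d with probability
    proportional to its fitness (``fitness_by_type[0]`` for A, ``[1]`` for B).
    """
    n = graph.n
    fa, fb = float(fitness_by_type[0]), float(fitness_by_type[1])
    if fa <= 0 or fb <= 0:
        raise ValueError("fitness values must be positive")
    indptr, indices = graph.csr()
    n_states = 1 << n
    rows, cols, vals = [], [], []
    for s in range(n_states):
        for d in range(n):
            neigh = indices[indptr[d]: indptr[d + 1]]
            fits = np.where((s >> neigh) & 1, fa, fb)
            probs = fits / fits.sum()
            for j, pj in zip(neigh, probs):
                parent_is_a = (s >> j) & 1
                s2 = (s | (1 << d)) if parent_is_a else (s & ~(1 << d))
                rows.append(s)
                cols.append(s2)
                vals.append(pj / n)
    m = scipy.sparse.coo_matrix((vals, (rows, cols)), shape=(n_states, n_states))
    return m.tocsr()


def _state_index(initial_types) -> int:
    s = 0
    for i, t in enumerate(initial_types):
        if int(t) == 0:  # type A
            s |= 1 << i
    return s


def exact_fixation_probability(
    graph: PopulationGraph,
    initial_types,
    fitness_by_type=(1.0, 1.0),
    max_nodes: int = MAX_ORACLE_NODES,
) -> float:
    """Exact probability that type A fixes from ``initial_types``.

    ``initial_types`` is a length-N sequence (0 = A, 1 = B).  Solves the
    absorption system of the one-event chain; exact up to linear-solver
    tolerance.  Graphs above ``max_nodes`` nodes are refused.
    """
    n = graph.n
    if n > max_nodes:
        raise ValueError(f"oracle limited to {max_nodes} nodes, got {n}")
    if len(initial_types) != n:
        raise ValueError("initial_types length must equal the node count")
    p_mat = _transition_matrix(graph, fitness_by_type)
    n_states = 1 << n
    all_a = n_states - 1
    s0 = _state_index(initial_types)
    if s0 == all_a:
        return 1.0
    if s0 == 0:
        return 0.0
    transient = np.array([s for s in range(n_states) if s not in (0, all_a)])
    q = p_mat[transient][:, transient]
    r_to_a = np.asarray(p_mat[transient][:, all_a].toarray()).ravel()
    ident = scipy.sparse.identity(len(transient), format="csc")
    p_abs = scipy.sparse.linalg.spsolve(ident - q.tocsc(), r_to_a)
    idx = int(np.searchsorted(transient, s0))
    return float(p_abs[idx])


def _oracle_config(n: int, fitness_by_type, cycle_limit: int = 200_000) -> SimConfig:
    """Framework-1 config with EPs off and constant per-type fitness."""
    return SimConfig(
        framework=1,
        n_nodes=n,
        ba_m=1 if n > 1 else 1,
        renewal_rate=1.0 / n,  # one event per cycle: pure Moran stepping
        birth_ep_chance_a=0.0,
        birth_ep_chance_b=0.0,
        base_fitness_a=float(fitness_by_type[0]),
        base_fitness_b=float(fitness_by_type[1]),
        cycle_limit=cycle_limit,
    )


def monte_carlo_agrees_with_oracle(
    graph: PopulationGraph,
    initial_types,
    fitness_by_type=(1.0, 1.0),
    n_samples: int = 10_000,
    seed: int = 0,
    uniform_parent: bool = False,
) -> tuple:
    """Compare simulated fixation frequency against the exact solve.

    Runs ``n_samples`` framework-1 samples with EPs disabled (one event per
    cycle) from the fixed ``initial_types`` start and returns
    ``(agrees, z_score)`` where ``agrees`` means the estimate lies within 3
    binomial standard errors of the exact probability.  With
    ``uniform_parent`` the simulator deliberately ignores fitness — a broken
    control expected to fail whenever fitness differs between types.
    """
    p_exact = exact_fixation_probability(graph, initial_types, fitness_by_type)
    config = _oracle_config(graph.n, fitness_by_type)
    types = np.asarray(initial_types, dtype=np.int8)
    n_fixed_a = 0
    n_undecided = 0
    for s in range(n_samples):
        out = run_sample_f1(
            graph, config, seed=seed + s, initial_types=types, uniform_parent=uniform_parent
        )
        if out.classification is Outcome.FIXED_A:
            n_fixed_a += 1
        elif out.classification is Outcome.UNDEFINED:
            n_undecided += 1
    if n_undecided > n_samples // 1000:
        raise RuntimeError("too many undecided runs; raise the cycle limit")
    p_hat = n_fixed_a / n_samples
    se = np.sqrt(max(p_exact * (1.0 - p_exact), 1e-12) / n_samples)
    z = (p_hat - p_exact) / se
    return bool(abs(z) <= 3.0), float(z)


def audit_ep_lifetimes(graph: PopulationGraph, config: SimConfig, seed: int) -> tuple:
    """Run one sample on the python engine with full EP event logging.

    Tracks every token from creation (at setup, at birth, or at the
    producing transition) through transfers to expiry/vanishing, and returns
    ``(max_token_age_in_cycles, n_tokens)``.  The timer law requires the max
    age never to exceed ``config.ep_lifetime``, counting across transfers.
    """
    from .framework1 import run_cycle_f1
    from .framework2 import run_cycle_f2
    from .state import init_population

    rng = np.random.default_rng(seed)
    log = []
    state = init_population(graph, config, rng)
    run_cycle = run_cycle_f1 if config.framework == 1 else run_cycle_f2
    while 0 < state.count_a() < state.n and state.cycle < config.cycle_limit:
        run_cycle(state, graph, config, rng, audit_log=log)
    end_cycle = {}
    for ev, cycle, token, _src, _dst, _t in log:
        if ev in ("expire", "vanish"):
            end_cycle[token] = cycle
    ages = [
        end_cycle.get(token, state.cycle) - birth
        for token, birth in state.ep_birth_cycle.items()
    ]
    return (max(ages) if ages else 0), len(ages)


def make_fixture(name: str) -> tuple:
    """Deterministic (graph, config) fixtures for tests and examples.

    ``tiny_path``  — 3-node path, neutral one-event config.
    ``triangle``   — 3-node complete graph, same config.
    ``ba_small``   — 20-node preferential-attachment graph (m=3), scaled-down
                     framework-1 defaults.
    ``paper_default`` — 500-node graph (m=4) with the standard framework-1
                     parameters: 4% renewal, EP lifetime 30, birth chance 0.5,
                     even type split.
    """
    if name == "tiny_path":
        g = PopulationGraph(nx.path_graph(3))
        return g, _oracle_config(3, (1.0, 1.0))
    if name == "triangle":
        g = PopulationGraph(nx.complete_graph(3))
        return g, _oracle_config(3, (1.0, 1.0))
    if name == "ba_small":
        g = generate_ba_graph(20, 3, seed=7)
        return g, SimConfig(n_nodes=20, ba_m=3, renewal_rate=0.05, cycle_limit=2000)
    if name == "paper_default":
        g = generate_ba_graph(500, 4, seed=0)
        return g, SimConfig()
    raise KeyError(f"unknown fixture {name!r}")
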