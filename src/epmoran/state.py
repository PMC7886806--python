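"""Population state shared by both simulation frameworks.

A population is a fixed set of N individuals sitting on graph nodes.  Each
carries a heritable type (A or B), a behavioral state (framework 2 only), and
at most one extended phenotype (EP) — a timed token such as a web, nest or
burrow.  An EP's lifetime counter is global to the token: it keeps running
across transfers to new holders and the token disappears when it hits zero.

Internally the state is a struct-of-arrays so that the same representation
feeds both the pure-Python reference engine and the compiled kernels:

* ``ntype[i]``     — 0 for type A, 1 for type B
* ``bstate[i]``    — behavioral state code (framework 2; framework 1 ignores it)
* ``ep[i]``        — remaining EP lifetime in cycles, 0 = no EP attached
* ``residence[i]`` — cycles spent in the current behavioral state
* ``ep_id[i]``     — token identity, -1 = none (bookkeeping for audits only)
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .config import ConfigError, SimConfig
from .graph import PopulationGraph


class NodeType(enum.IntEnum):
    A = 0
    B = 1


class BehaviorState(enum.IntEnum):
    SEARCHING = 0
    PRODUCING = 1
    USING_OWN = 2
    USING_OTHER = 3


class Outcome(enum.Enum):
    FIXED_A = "FIXED_A"
    FIXED_B = "FIXED_B"
    UNDEFINED = "UNDEFINED"


@dataclass
class SimState:
    """Mutable per-run population state (struct of arrays)."""

    ntype: np.ndarray
    bstate: np.ndarray
    ep: np.ndarray
    residence: np.ndarray
    cycle: int = 0
    ep_id: np.ndarray = None
    next_ep_id: int = 0
    ep_birth_cycle: dict = field(default_factory=dict)  # token id -> creation cycle

    @property
    def n(self) -> int:
        return self.ntype.shape[0]

    def count_a(self) -> int:
        return int(np.sum(self.ntype == NodeType.A))

    def count_b(self) -> int:
        return self.n - self.count_a()

    def ep_count(self) -> int:
        return int(np.sum(self.ep > 0))

    def ep_count_a(self) -> int:
        return int(np.sum((self.ep > 0) & (self.ntype == NodeType.A)))

    def new_ep(self, holder: int, lifetime: int) -> None:
        """Attach a freshly built token to ``holder``."""
        self.ep[holder] = lifetime
        self.ep_id[holder] = self.next_ep_id
        self.ep_birth_cycle[self.next_ep_id] = self.cycle
        self.next_ep_id += 1

    def state_counts(self) -> tuple:
        """(searching, producing, using_own, using_other) node counts."""
        return tuple(int(np.sum(self.bstate == s)) for s in range(4))


def _allocate(n: int) -> SimState:
    return SimState(
        ntype=np.zeros(n, dtype=np.int8),
        bstate=np.zeros(n, dtype=np.int8),
        ep=np.zeros(n, dtype=np.int64),
        residence=np.zeros(n, dtype=np.int64),
        ep_id=np.full(n, -1, dtype=np.int64),
    )


def _largest_remainder_counts(fractions, total: int) -> np.ndarray:
    """Integer allocation of ``total`` items to ``fractions`` (sums to total)."""
    raw = np.asarray(fractions, dtype=float) * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def init_population(
    graph: PopulationGraph, config: SimConfig, rng: np.random.Generator
) -> SimState:
    """Set up the initial population on ``graph``.

    Types: ``floor(N * initial_fraction_a)`` nodes are type A (250 of 500 at
    the defaults), placed by a uniform random permutation.

    Framework 1: each node of an EP-producing type independently starts with
    an EP with that type's birth chance (50% by default); with
    ``init_exact_half`` the same expected number is assigned exactly.

    Framework 2: behavioral states are allocated to the configured initial
    percentages (largest-remainder rounding, random placement); nodes landing
    in a using state receive a fresh EP.  A state the node's type cannot
    sustain (producing with beta = -1, using-other with gamma = -1) degrades
    to searching.
    """
    if graph.n != config.n_nodes:
        raise ConfigError(
            f"graph has {graph.n} nodes but config.n_nodes = {config.n_nodes}"
        )
    n = graph.n
    st = _allocate(n)
    n_a = int(np.floor(n * config.initial_fraction_a))
    types = np.concatenate([np.zeros(n_a, dtype=np.int8), np.ones(n - n_a, dtype=np.int8)])
    st.ntype = rng.permutation(types)

    t0 = config.initial_ep_time()
    if config.framework == 1:
        chances = (config.birth_ep_chance_a, config.birth_ep_chance_b)
        for t in (0, 1):
            idx = np.flatnonzero(st.ntype == t)
            p = chances[t]
            if p <= 0.0 or idx.size == 0:
                continue
            if config.init_exact_half:
                k = int(round(p * idx.size))
                chosen = rng.choice(idx, size=k, replace=False)
            else:
                chosen = idx[rng.random(idx.size) < p]
            for i in chosen:
                st.new_ep(int(i), t0)
        st.bstate[:] = np.where(st.ep > 0, BehaviorState.USING_OWN, BehaviorState.SEARCHING)
    else:
        counts = _largest_remainder_counts(config.state_percentages(), n)
        states = np.repeat(np.arange(4, dtype=np.int8), counts)
        st.bstate = rng.permutation(states)
        can_produce = config.can_produce()
        can_reuse = config.can_reuse()
        for i in range(n):
            t = st.ntype[i]
            s = st.bstate[i]
            if s in (BehaviorState.PRODUCING, BehaviorState.USING_OWN) and not can_produce[t]:
                st.bstate[i] = BehaviorState.SEARCHING
            elif s == BehaviorState.USING_OTHER and not can_reuse[t]:
                st.bstate[i] = BehaviorState.SEARCHING
        for i in np.flatnonzero(
            (st.bstate == BehaviorState.USING_OWN) | (st.bstate == BehaviorState.USING_OTHER)
        ):
            st.new_ep(int(i), t0)
    return st


def classify_outcome(state: SimState, config: SimConfig, seed: int = -1) -> "SampleOutcome":
    """Classify a run's terminal state.

    FIXED_A / FIXED_B when one type has taken every node; UNDEFINED when the
    cycle limit was reached with both types still present.  Pure function of
    the final state.
    """
    n_a = state.count_a()
    n_b = state.n - n_a
    if n_b == 0:
        cls = Outcome.FIXED_A
    elif n_a == 0:
        cls = Outcome.FIXED_B
    else:
        cls = Outcome.UNDEFINED
    sc = state.state_counts() if config.framework == 2 else None
    return SampleOutcome(
        classification=cls,
        cycles_elapsed=state.cycle,
        final_count_a=n_a,
        final_count_b=n_b,
        final_ep_count=state.ep_count(),
        final_ep_count_a=state.ep_count_a(),
        seed=seed,
        state_counts=sc,
    )


@dataclass(frozen=True)
class SampleOutcome:
    """Terminal record of one simulation sample."""

    classification: Outcome
    cycles_elapsed: int
    final_count_a: int
    final_count_b: int
    final_ep_count: int
    final_ep_count_a: int
    seed: int
    state_counts: Union[tuple, None] = None  # framework 2 only

    def __post_init__(self) -> None:
        assert self.final_count_a + self.final_count_b >= 0
        if self.classification is Outcome.FIXED_A:
            assert self.final_count_b == 0
        elif self.classification is Outcome.FIXED_B:
            assert self.final_count_a == 0
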