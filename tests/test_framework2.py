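"""Framework 2: behavioral-state machine, EP inheritance, full samples."""

import networkx as nx
import numpy as np
import pytest

import epmoran as em
from epmoran.framework2 import (
    death_birth_event_f2,
    reassign_ep_f2,
    run_cycle_f2,
    transition_states_f2,
)
from epmoran.state import BehaviorState, Outcome

S, P, UO, UX = (
    BehaviorState.SEARCHING,
    BehaviorState.PRODUCING,
    BehaviorState.USING_OWN,
    BehaviorState.USING_OTHER,
)


def f2_config(**overrides):
    base = dict(
        framework=2, n_nodes=4, ba_m=1, renewal_rate=0.25,
        alpha_a=0.05, alpha_b=0.05, beta_a=0.03, beta_b=0.03,
        gamma_a=0.02, gamma_b=0.02, state_time=3, ep_lifetime=4,
        pct_searching=1.0, pct_using_own=0.0,
    )
    base.update(overrides)
    return em.SimConfig(**base)


def fresh_state(graph, config, types=None):
    st = em.init_population(graph, config, np.random.default_rng(0))
    if types is not None:
        st.ntype[:] = np.asarray(types, dtype=np.int8)
    return st


class TestStateMachine:
    def test_full_lifecycle_searching_producing_using_own(self, path4):
        """search (state_time) -> produce (state_time) -> use own (ep_lifetime) -> search."""
        cfg = f2_config()
        st = fresh_state(path4, cfg)
        trajectory = []
        for _ in range(10):
            trajectory.append(int(st.bstate[0]))
            transition_states_f2(st, cfg)
        # the freshly built token is created before the same sweep's timer
        # decrement, so using-own spans ep_lifetime - 1 cycle boundaries
        assert trajectory == [S] * 3 + [P] * 3 + [UO] * 3 + [S]

    def test_sentinel_beta_never_produces(self, path4):
        cfg = f2_config(beta_b=-1.0)
        st = fresh_state(path4, cfg, types=[1, 1, 1, 1])
        for _ in range(20):
            transition_states_f2(st, cfg)
        assert np.all(st.bstate == S)

    def test_inherited_token_expires_on_its_own_clock(self, path4):
        """A using-other node with 2 cycles left searches again after 2, not state_time."""
        cfg = f2_config()
        st = fresh_state(path4, cfg)
        st.bstate[2] = UX
        st.new_ep(2, 2)
        transition_states_f2(st, cfg)
        assert st.bstate[2] == UX and st.ep[2] == 1
        transition_states_f2(st, cfg)
        assert st.bstate[2] == S and st.ep[2] == 0 and st.residence[2] == 0

    def test_producing_transition_creates_fresh_token(self, path4):
        cfg = f2_config()
        st = fresh_state(path4, cfg)
        st.bstate[:] = P
        st.residence[:] = cfg.state_time - 1
        transition_states_f2(st, cfg)
        assert np.all(st.bstate == UO)
        assert np.all(st.ep == cfg.ep_lifetime - 1)  # built, then one decrement


class TestEventsF2:
    def test_newborn_always_searching_without_ep(self, ba_small, rng):
        cfg = f2_config(n_nodes=30, ba_m=2, renewal_rate=0.1, pct_searching=0.0, pct_using_own=1.0)
        st = fresh_state(ba_small, cfg)
        # every node uses its own token; after one event exactly one newborn searches
        death_birth_event_f2(st, ba_small, cfg, rng)
        searching = np.flatnonzero(st.bstate == S)
        assert searching.size == 1
        assert st.ep[searching[0]] == 0 and st.residence[searching[0]] == 0

    def test_reassignment_prefers_searching_neighbor(self, path4, rng):
        cfg = f2_config()
        st = fresh_state(path4, cfg)
        st.bstate[:] = [UO, S, P, S]
        st.ep[:] = 0
        st.new_ep(0, 7)
        reassign_ep_f2(0, st, path4, cfg, rng)
        assert st.ep[1] == 7 and st.bstate[1] == UX and st.residence[1] == 0

    def test_graph_wide_fallback_to_distant_searcher(self, path4, rng):
        cfg = f2_config()
        st = fresh_state(path4, cfg)
        st.bstate[:] = [UO, P, UO, S]  # the only searcher is not a neighbor of 0
        st.ep[:] = 0
        st.new_ep(0, 7)
        st.new_ep(2, 3)
        reassign_ep_f2(0, st, path4, cfg, rng)
        assert st.ep[3] == 7 and st.bstate[3] == UX

    def test_sentinel_gamma_type_never_receives(self, path4, rng):
        cfg = f2_config(gamma_b=-1.0)
        st = fresh_state(path4, cfg, types=[0, 1, 1, 1])
        st.bstate[:] = [UO, S, S, S]
        st.ep[:] = 0
        st.new_ep(0, 7)
        log = []
        reassign_ep_f2(0, st, path4, cfg, rng, audit_log=log)
        assert st.ep_count() == 0
        assert log[0][0] == "vanish"


class TestSamplesF2:
    def test_state_ep_consistency_throughout(self, ba_small):
        """(state is using-own/other) <=> (a token is attached), every cycle."""
        cfg = f2_config(n_nodes=30, ba_m=2, renewal_rate=0.1, state_time=5, ep_lifetime=6)
        rng = np.random.default_rng(11)
        st = fresh_state(ba_small, cfg)
        for _ in range(60):
            run_cycle_f2(st, ba_small, cfg, rng)
            using = (st.bstate == UO) | (st.bstate == UX)
            assert np.array_equal(using, st.ep > 0)

    def test_single_type_start_fixes_immediately(self, ba500):
        cfg = em.SimConfig(framework=2, beta_a=0.03, beta_b=0.03, initial_fraction_a=0.0)
        out = em.run_sample_f2(ba500, cfg, seed=1)
        assert out.classification is Outcome.FIXED_B
        assert out.cycles_elapsed == 0

    @pytest.mark.parametrize("engine", ["numba", "python"])
    def test_determinism(self, ba_small, engine):
        cfg = f2_config(n_nodes=30, ba_m=2, renewal_rate=0.1, cycle_limit=500)
        a = em.run_sample_f2(ba_small, cfg, seed=9, engine=engine)
        assert a == em.run_sample_f2(ba_small, cfg, seed=9, engine=engine)

    def test_engines_statistically_equivalent(self, ba_small):
        cfg = f2_config(
            n_nodes=30, ba_m=2, renewal_rate=0.1, cycle_limit=400,
            alpha_a=0.02, gamma_a=0.08, alpha_b=0.08, gamma_b=0.02,
            state_time=10, ep_lifetime=10, pct_searching=0.5, pct_using_own=0.5,
        )
        wins = {}
        for engine in ("numba", "python"):
            outs = [em.run_sample_f2(ba_small, cfg, seed=s, engine=engine) for s in range(250)]
            wins[engine] = np.mean([o.classification is Outcome.FIXED_A for o in outs])
        se = np.sqrt(2 * 0.25 / 250)
        assert abs(wins["numba"] - wins["python"]) < 3 * se

    def test_higher_omega_population_wins_more(self, ba_small):
        """omega_A > omega_B (via alpha) tilts fixation toward A."""
        cfg = f2_config(
            n_nodes=30, ba_m=2, renewal_rate=0.1, cycle_limit=1000,
            alpha_a=0.15, alpha_b=0.01, state_time=10, ep_lifetime=10,
            pct_searching=0.5, pct_using_own=0.5,
        )
        outs = [em.run_sample_f2(ba_small, cfg, seed=s) for s in range(400)]
        n_a = sum(o.classification is Outcome.FIXED_A for o in outs)
        n_b = sum(o.classification is Outcome.FIXED_B for o in outs)
        assert n_a > n_b
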