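"""Framework 1: death-birth events, EP reassignment, cycles, full samples."""

import networkx as nx
import numpy as np
import pytest
import scipy.stats

import epmoran as em
from epmoran.framework1 import death_birth_event_f1, reassign_ep_f1, run_cycle_f1
from epmoran.state import Outcome


def make_state(graph, config, types, ep=None, rng=None):
    """Hand-built state: explicit types and EP timers."""
    st = em.init_population(graph, config, rng or np.random.default_rng(0))
    st.ntype[:] = np.asarray(types, dtype=np.int8)
    st.ep[:] = 0
    st.ep_id[:] = -1
    if ep:
        for node, t in ep.items():
            st.new_ep(node, t)
    return st


class TestEvents:
    def test_monomorphic_population_stays_monomorphic(self, triangle, rng):
        cfg = em.SimConfig(n_nodes=3, ba_m=1, renewal_rate=0.5)
        st = make_state(triangle, cfg, [1, 1, 1])
        for _ in range(50):
            death_birth_event_f1(st, triangle, cfg, rng)
        assert st.count_a() == 0

    def test_ep_transfer_preserves_timer(self, triangle, rng):
        """A dying holder's token moves with its remaining 10 cycles intact."""
        cfg = em.SimConfig(n_nodes=3, ba_m=1, renewal_rate=0.5)
        st = make_state(triangle, cfg, [0, 0, 0], ep={0: 10})
        reassign_ep_f1(0, st, triangle, cfg, rng)
        assert st.ep[0] == 0
        assert sorted(st.ep[1:]) == [0, 10]

    def test_single_eligible_neighbor_always_receives(self, triangle, rng):
        cfg = em.SimConfig(n_nodes=3, ba_m=1, renewal_rate=0.5)
        st = make_state(triangle, cfg, [0, 0, 0], ep={0: 10, 2: 5})
        reassign_ep_f1(0, st, triangle, cfg, rng)  # node 1 is the only EP-less one
        assert st.ep[1] == 10

    def test_reassignment_uniform_among_eligible_neighbors(self, rng):
        """Three eligible neighbors each receive the token ~1/3 of the time."""
        g = em.PopulationGraph(nx.star_graph(3))
        cfg = em.SimConfig(n_nodes=4, ba_m=1, renewal_rate=0.25)
        hits = np.zeros(3)
        for _ in range(3000):
            st = make_state(g, cfg, [0, 0, 0, 0], ep={0: 10})
            reassign_ep_f1(0, st, g, cfg, rng)
            hits[np.flatnonzero(st.ep[1:])[0]] += 1
        assert scipy.stats.chisquare(hits).pvalue > 0.01

    def test_graph_wide_fallback(self, path4, rng):
        """No eligible neighbor: a random EP-less reuser anywhere receives it."""
        cfg = em.SimConfig(n_nodes=4, ba_m=1, renewal_rate=0.25)
        st = make_state(path4, cfg, [0, 0, 0, 0], ep={0: 8, 1: 3})
        reassign_ep_f1(0, st, path4, cfg, rng)  # neighbor 1 already holds one
        assert st.ep[2] == 8 or st.ep[3] == 8

    def test_token_vanishes_without_any_eligible_reuser(self, path4, rng):
        """Type B cannot reuse (gamma=-1); an A holder dying among B loses it."""
        cfg = em.SimConfig(n_nodes=4, ba_m=1, renewal_rate=0.25, gamma_b=-1.0)
        st = make_state(path4, cfg, [0, 1, 1, 1], ep={0: 10})
        log = []
        reassign_ep_f1(0, st, path4, cfg, rng, audit_log=log)
        assert st.ep_count() == 0
        assert log[0][0] == "vanish"

    def test_newborn_is_not_a_recipient_of_the_dying_token(self, rng):
        """On a 2-node graph with reuse forbidden for B, an A holder's death
        can never hand the token to the newborn in its own slot."""
        g = em.PopulationGraph(nx.path_graph(2))
        cfg = em.SimConfig(
            n_nodes=2, ba_m=1, renewal_rate=0.5,
            birth_ep_chance_a=0.0, birth_ep_chance_b=0.0,
        )
        for _ in range(40):
            # both nodes hold a token, so the dying one's has no eligible
            # recipient and must vanish instead of landing on the newborn
            st = make_state(g, cfg, [0, 0], ep={0: 10, 1: 99})
            death_birth_event_f1(st, g, cfg, rng)
            assert sorted(st.ep) in ([0, 10], [0, 99])


class TestCycles:
    def test_default_cycle_runs_twenty_events(self):
        assert em.SimConfig().events_per_cycle() == 20

    def test_timers_decrement_once_per_cycle(self, path4, rng):
        cfg = em.SimConfig(
            n_nodes=4, ba_m=1, renewal_rate=0.25,
            birth_ep_chance_a=0.0, birth_ep_chance_b=0.0,
        )
        st = make_state(path4, cfg, [0, 0, 0, 0], ep={1: 5, 3: 1})
        run_cycle_f1(st, path4, cfg, rng)
        assert st.cycle == 1
        assert np.all(st.ep <= 4)  # every surviving timer dropped by exactly 1
        assert 1 not in st.ep  # nothing expires late

    def test_fresh_birth_ep_ends_cycle_one_short(self, ba500):
        cfg = em.SimConfig(birth_ep_chance_a=1.0, birth_ep_chance_b=1.0)
        rng = np.random.default_rng(7)
        st = em.init_population(ba500, cfg, rng)
        st.ep[:] = 0  # wipe initial tokens: only this cycle's births remain
        st.ep_id[:] = -1
        run_cycle_f1(st, ba500, cfg, rng)
        born = st.ep[st.ep > 0]
        assert born.size > 0
        assert np.all(born == cfg.ep_lifetime - 1)


class TestSamples:
    def test_all_a_start_fixes_at_cycle_zero(self, ba500):
        cfg = em.SimConfig(initial_fraction_a=1.0)
        out = em.run_sample_f1(ba500, cfg, seed=0)
        assert out.classification is Outcome.FIXED_A
        assert out.cycles_elapsed == 0

    def test_one_cycle_cannot_fix_a_balanced_start(self, ba500):
        out = em.run_sample_f1(ba500, em.SimConfig(cycle_limit=1), seed=0)
        assert out.classification is Outcome.UNDEFINED

    @pytest.mark.parametrize("engine", ["numba", "python"])
    def test_determinism(self, ba_small, engine):
        cfg = em.experiment1_config(n_nodes=30, ba_m=2, renewal_rate=0.1, cycle_limit=800)
        a = em.run_sample_f1(ba_small, cfg, seed=42, engine=engine)
        b = em.run_sample_f1(ba_small, cfg, seed=42, engine=engine)
        assert a == b
        c = em.run_sample_f1(ba_small, cfg, seed=43, engine=engine)
        assert a != c

    def test_engines_statistically_equivalent(self, ba_small):
        """The compiled kernel and the reference engine sample the same process."""
        cfg = em.experiment1_config(
            alpha_a=0.1, n_nodes=30, ba_m=2, renewal_rate=0.1, cycle_limit=600
        )
        wins = {}
        for engine in ("numba", "python"):
            outs = [em.run_sample_f1(ba_small, cfg, seed=s, engine=engine) for s in range(250)]
            wins[engine] = np.mean([o.classification is Outcome.FIXED_A for o in outs])
        se = np.sqrt(2 * 0.25 / 250)
        assert abs(wins["numba"] - wins["python"]) < 3 * se

    def test_no_ep_can_exist_after_initials_expire_without_birth(self, ba_small):
        """With birth chance 0 the process reduces to a plain Moran chain."""
        cfg = em.SimConfig(
            n_nodes=30, ba_m=2, renewal_rate=0.1,
            birth_ep_chance_a=0.0, birth_ep_chance_b=0.0, cycle_limit=40,
        )
        rng = np.random.default_rng(5)
        st = em.init_population(ba_small, cfg, rng)
        assert st.ep_count() == 0  # chance 0 means no initial tokens either
        for _ in range(40):
            run_cycle_f1(st, ba_small, cfg, rng)
        assert st.ep_count() == 0
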