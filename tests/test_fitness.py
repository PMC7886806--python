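"""Fitness algebra: relative fitness, selection weights, omega, projections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import epmoran as em
from epmoran.config import ConfigError
from epmoran.state import BehaviorState, NodeType

PAIRS = [(0.01, 0.08), (0.02, 0.07), (0.03, 0.06), (0.04, 0.05),
         (0.05, 0.04), (0.06, 0.03), (0.07, 0.02), (0.08, 0.01)]
BETAS = [0.01, 0.03, 0.05, 0.07, 0.09]


class TestRelativeFitness:
    def test_framework1_holder_earns_alpha(self):
        cfg = em.SimConfig(alpha_a=0.05)
        assert em.relative_fitness(NodeType.A, True, cfg) == pytest.approx(1.05)
        assert em.relative_fitness(NodeType.A, False, cfg) == 1.0
        assert em.relative_fitness(NodeType.B, True, cfg) == 1.0  # alpha_b = 0

    def test_framework2_state_fitnesses(self):
        cfg = em.SimConfig(
            framework=2, alpha_a=0.05, beta_a=0.03, gamma_a=0.02,
            alpha_b=0.05, beta_b=0.03, gamma_b=0.02,
        )
        f = lambda s: em.relative_fitness(NodeType.A, s, cfg)
        assert f(BehaviorState.SEARCHING) == 1.0
        assert f(BehaviorState.PRODUCING) == pytest.approx(0.97)
        assert f(BehaviorState.USING_OWN) == pytest.approx(1.05)
        assert f(BehaviorState.USING_OTHER) == pytest.approx(1.02)

    def test_sentinel_states_are_unreachable(self):
        cfg = em.SimConfig(framework=2, beta_a=-1, gamma_b=-1)
        with pytest.raises(ConfigError):
            em.relative_fitness(NodeType.A, BehaviorState.PRODUCING, cfg)
        with pytest.raises(ConfigError):
            em.relative_fitness(NodeType.B, BehaviorState.USING_OTHER, cfg)

    @pytest.mark.parametrize("framework", [1, 2])
    def test_neutral_limit_is_one_everywhere(self, framework):
        cfg = em.SimConfig(framework=framework, beta_a=0.0, beta_b=0.0)
        if framework == 1:
            states = [True, False]
        else:
            states = list(BehaviorState)
        for t in NodeType:
            for s in states:
                assert em.relative_fitness(t, s, cfg) == 1.0


class TestSelectionWeights:
    def test_examples(self):
        np.testing.assert_allclose(em.selection_weights([1.0, 1.0]), [0.5, 0.5])
        w = em.selection_weights([1.05, 1.0])
        np.testing.assert_allclose(w, [1.05 / 2.05, 1.0 / 2.05])

    def test_errors(self):
        with pytest.raises(ValueError):
            em.selection_weights([])
        with pytest.raises(ValueError):
            em.selection_weights([1.0, 0.0])

    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_normalized_and_monotone(self, fits):
        w = em.selection_weights(fits)
        assert abs(w.sum() - 1.0) < 1e-12
        order = np.argsort(fits)
        assert np.all(np.diff(w[order]) >= -1e-15)


class TestOmega:
    def test_equal_omega_table_every_cell(self):
        """The full equal-omega parameter grid: omega = alpha + gamma - beta."""
        for a, g in PAIRS:
            for b, expected in zip(BETAS, [0.08, 0.06, 0.04, 0.02, 0.00]):
                assert em.omega(a, b, g).omega == pytest.approx(expected, abs=1e-12)

    def test_fitness_table_frame(self):
        df = em.fitness_table()
        assert df.shape == (8, 5)
        assert (df["beta=0.01"] == 0.08).all()
        assert (df["beta=0.09"] == 0.00).all()

    def test_omega_is_exact_arithmetic(self):
        af = em.omega(0.01, 0.01, 0.08)
        assert af.omega == 0.08
        assert em.omega(0.08, 0.09, 0.01).omega == pytest.approx(0.0, abs=1e-15)
        assert em.omega(0, 0, 0).omega == 0


class TestSharingFavored:
    def test_examples(self):
        assert em.sharing_favored(0.04, 0.02, 0.05) is True  # ratio 2.5
        assert em.sharing_favored(0.05, 0.01, 0.01) is False  # ratio 0.25
        with pytest.raises(ZeroDivisionError):
            em.sharing_favored(0.03, 0.03, 0.05)


class TestProjectAbundance:
    @pytest.mark.parametrize(
        "n0,om,gens,expected",
        [
            (100, 1.0, 5, [100] * 6),
            (1, 2.0, 3, [1, 2, 4, 8]),
            (8, 0.5, 3, [8, 4, 2, 1]),
        ],
    )
    def test_geometric_trajectories(self, n0, om, gens, expected):
        np.testing.assert_allclose(em.project_abundance(n0, om, gens), expected)

    def test_recurrence_invariant(self):
        traj = em.project_abundance(3.0, 0.08, 10)
        np.testing.assert_allclose(traj[1:], 0.08 * traj[:-1])

    def test_negative_generations_rejected(self):
        with pytest.raises(ValueError):
            em.project_abundance(1.0, 1.0, -1)
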