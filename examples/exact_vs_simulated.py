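"""Validate the death-birth core against an exact Markov-chain solve.

With extended phenotypes disabled, the simulator is a plain death-birth
Moran process; on a tiny graph its fixation probability can be computed
exactly by solving the absorbing-chain linear system over all 2^N type
configurations.  The Monte Carlo estimate must agree within 3 sigma — and a
deliberately broken simulator that ignores fitness must not.
"""

import networkx as nx

import epmoran as em

triangle = em.PopulationGraph(nx.complete_graph(3))
types = [0, 1, 1]  # one type-A invader
fitness = (1.3, 1.0)  # A has a 30% reproductive advantage

p_exact = em.exact_fixation_probability(triangle, types, fitness)
print(f"exact P(A fixes) on the triangle: {p_exact:.6f}")

ok, z = em.monte_carlo_agrees_with_oracle(triangle, types, fitness, n_samples=10_000, seed=4)
print(f"simulator vs exact: agree={ok} (z = {z:+.2f})")

ok_bad, z_bad = em.monte_carlo_agrees_with_oracle(
    triangle, types, fitness, n_samples=10_000, seed=4, uniform_parent=True
)
print(f"fitness-ignoring mutant: agree={ok_bad} (z = {z_bad:+.2f})")
print("\nThe honest simulator sits within noise of the exact value; the")
print("mutant that picks parents uniformly is rejected decisively.")
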