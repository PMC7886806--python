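"""Grow a scale-free population graph and store it as a plain-text edge list.

The population lives on a Barabási–Albert graph: growth by preferential
attachment yields a few highly connected hubs and many low-degree nodes,
mimicking natural contact networks.
"""

import io

import epmoran as em

graph = em.generate_ba_graph(n=500, m=4, seed=1)
degrees = graph.degrees()
print(f"nodes: {graph.n}")
print(f"edges: {len(graph.edges)} (= m * (n - m) = {4 * (500 - 4)})")
print(f"degree min/median/max: {degrees.min()}/{int(sorted(degrees)[250])}/{degrees.max()}")

buf = io.StringIO()
em.write_edge_list(graph, buf)
text = buf.getvalue()
print(f"\nedge-list text, first 6 lines of {len(text.splitlines())}:")
print("\n".join(text.splitlines()[:6]))

round_tripped = em.read_edge_list(io.StringIO(text))
print(f"\nround trip preserves the graph: {round_tripped == graph}")
# The max degree dwarfs m: preferential attachment concentrates edges on hubs.
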