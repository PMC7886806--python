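# epmoran

Agent-based Moran simulations of **extended phenotypes** — webs, nests,
dams: structures a genotype builds outside its bearer's body — and of what
happens when conspecifics can *reuse* them after the builder dies.

The package is for evolutionary modelers who want to test, on structured
populations, whether the shared use of extended phenotypes raises population
fitness (the *extended fitness hypothesis*). Two populations, A and B, sit
on a Barabási–Albert scale-free graph (N = 500, m = 4 by default) and evolve
under a death-birth update: a random individual dies, a neighbor reproduces
into the vacancy with probability proportional to relative fitness. Extended
phenotypes are timed tokens that modify fitness:

- **alpha** — bonus for occupying a token you built,
- **beta** — cost while building one,
- **gamma** — bonus for occupying a token a dead conspecific left behind,

with the population-level absolute fitness **omega = alpha − beta + gamma**
and the sharing condition gamma/(alpha − beta) > 1.

Two simulation engines are provided: **framework 1** (tokens granted at
birth with fixed probability; holders earn alpha; abandoned tokens pass to
eligible neighbors with their timer intact) and **framework 2** (a
four-state behavioral machine — searching, producing, using-own,
using-other — with timed transitions and per-state fitness). An exact
absorbing-Markov-chain solver validates the death-birth core on tiny graphs,
and a batch layer runs the parameter sweeps with fully arithmetic seed
schedules.

## Worked example

Only population A produces and reuses extended phenotypes (alpha = 0.05);
B gets nothing. One sample:

```python
import epmoran as em

graph = em.generate_ba_graph(n=500, m=4, seed=1)   # 1,984 edges
config = em.experiment1_config(alpha_a=0.05)
out = em.run_sample_f1(graph, config, seed=3)
print(out.classification.value, out.cycles_elapsed, out.final_count_a)
```

prints `FIXED_A 1465 500`: the token-producing population displaced the
other entirely after 1,465 cycles (each cycle = 20 death-birth events plus a
token-aging sweep). At this bonus roughly nine in ten runs end in `FIXED_A`;
the rest hit the 5,000-cycle limit and are classified `UNDEFINED`.

Equal absolute fitness, different composition (`examples/sharing_beats_owning.py`):
both populations have omega = 0.06, but A earns it through the sharing bonus
(gamma_A = 0.08) and B through own use (alpha_B = 0.08). Over 600 samples:

```
fixation of A (high gamma): 0.368
fixation of B (high alpha): 0.278
undefined:                  0.353
```

The sharer wins — the reuse bonus matters more than the own-use bonus even
when the fitness algebra says the populations are equal.

Each script in `examples/` is a short narrative of one capability: graph
generation and edge lists, the fitness algebra and the equal-omega table,
single runs, alpha sweeps, gamma-vs-alpha competition, and the exact-oracle
cross-check.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: two cells of the equal-omega table (exact
arithmetic), the percentage of undefined runs in the two framework-1
experiments at alpha = 0.05 (only-A-produces, and both-produce/only-A-reuses),
and the percentage of undefined runs with a type-A majority at
alpha_A = 0.04 — each stochastic quantity from a fresh 20-graph × 100-sample
batch (about four minutes on one CPU). Results are written as JSON keyed by
target id.

See `docs/methods.md` for the full model description, parameter defaults,
numerical conventions, and known limitations.
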