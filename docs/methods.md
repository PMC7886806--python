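# Methods

## The model

`epmoran` simulates two populations (types A and B) competing on a fixed
contact network under a death-birth Moran update, extended to include
*extended phenotypes* (EPs): timed tokens — think webs, nests, burrows, dams —
that an individual can build, occupy, and leave behind for a conspecific to
reuse.

**Graph.** Individuals occupy the nodes of a Barabási–Albert (BA) graph grown
by preferential attachment (defaults: N = 500 nodes, attachment parameter
m = 4, hence exactly m·(N − m) = 1,984 edges). BA graphs have a power-law
degree tail, a crude but standard stand-in for natural contact structure.
Growth starts from a star on m + 1 nodes, so the original seed nodes can end
with degree < m; only incrementally attached nodes are guaranteed degree ≥ m.
Graphs round-trip through a plain-text edge list (`u v` per line, `#` headers
carrying N and m).

**Death-birth update.** Each cycle executes `round(renewal_rate · N)` events
(20 at the defaults) *sequentially*: a uniformly chosen individual dies and
one of its neighbors, drawn with probability proportional to relative
fitness, places an offspring of its own type in the vacancy. The same node
can die more than once per cycle, and a newborn can die later in the same
cycle. Fixation (one type occupying every node) is checked at cycle
boundaries only; a run that reaches `cycle_limit` with both types alive is
classified *undefined*.

**Extended phenotypes.** A token carries a remaining-lifetime counter
(default 30 cycles), decremented once per cycle and **never reset on
transfer**: a token inherited with 10 cycles left expires 10 cycles later no
matter who holds it. When a holder dies, the token is offered to (a) a
uniformly chosen eligible neighbor, else (b) a uniformly chosen eligible
individual anywhere in the graph, else (c) it vanishes. Eligibility always
requires a reuse-capable type (`gamma != -1`) and no token already attached;
framework 2 additionally requires the searching state. The newborn filling
the vacancy is never a candidate; reassignment happens before it is placed.

### Framework 1 — tokens at birth

Newborns of a producing type receive a fresh token with probability
`birth_ep_chance` (0.5 by default). Fitness is `base + alpha` while holding
a token and `base` otherwise (baseline 1). The two canonical experiments:

* **Experiment 1** (`experiment1_config`): only A produces
  (`birth_ep_chance_b = 0`) and only A reuses (`gamma_b = -1`).
* **Experiment 2** (`experiment2_config`): both produce with chance 0.5 and
  equal alpha, but only A reuses.

### Framework 2 — behavioral states

Four states with per-state fitness: searching (1), producing (1 − beta),
using-own (1 + alpha), using-other (1 + gamma). Searching lasts
`state_time` cycles (30), then the node produces for `state_time` cycles and
emerges holding a fresh token (using-own) until the token expires and it
searches again. A searcher that inherits a token jumps straight to
using-other for the token's remaining life. Newborns always start searching
with no token; `birth_ep_chance` plays no role here. Sentinels: `beta = -1`
means the type never produces, `gamma = -1` means it never reuses.

Order inside a cycle: all death-birth events first, then one global sweep
(residence +1, timed transitions fire, token timers −1, expired holders fall
back to searching). Token receipt fires immediately inside the death-birth
event, resetting the recipient's residence.

### The fitness algebra

At the population level, `omega = alpha − beta + gamma` (absolute fitness)
compares populations; sharing is predicted to be favored when
`gamma / (alpha − beta) > 1`. Both are exposed as library functions, along
with `project_abundance`, the literal geometric recurrence
`n(g+1) = omega · n(g)`. The recurrence is shipped as printed even though
omega values around 0.08 make it a shrinking map — it is a standalone
utility, never used inside the simulators, and whether a `1 + omega` growth
factor was intended is deliberately left to the caller.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_nodes`, `ba_m` | 500, 4 | graph size and attachment parameter |
| `renewal_rate` | 0.04 | fraction of nodes replaced per cycle (20 events) |
| `alpha`, `beta`, `gamma` (per type) | 0, −1, 0 | own-use bonus, production cost, shared-use bonus; −1 = behavioral switch off |
| `ep_lifetime` | 30 cycles | token lifetime, global across transfers |
| `state_time` | 30 cycles | searching/producing duration (framework 2) |
| `birth_ep_chance` (per type) | 0.5 | newborn token probability (framework 1) |
| `cycle_limit` | 5,000 | cycles before a run is declared undefined |

`cycle_limit` deserves emphasis: the undefined fraction and every quantity
conditioned on it depend strongly on this cutoff, and the source study's
exact value is not public. 5,000 is this package's documented default and
all reported undefined-fraction numbers are conditional on it.

Defaults chosen where the source is silent: initial tokens get a full fresh
lifetime; initial type placement is a uniform random permutation of
floor(N/2) A's; initial token assignment is per-individual Bernoulli with the
type's birth chance (an `init_exact_half` flag gives the deterministic
variant); framework-2 initial states are 50% searching / 50% using-own,
allocated by largest-remainder rounding, with nodes whose type cannot
sustain a state degraded to searching; initial residence counters are 0.

`base_fitness_a/b` (default 1) is a package extension: a constant per-type
baseline that lets the oracle express selective differences with tokens
disabled. Neutral defaults leave all documented behavior unchanged.

## Engines and reproducibility

Every update rule is implemented twice behind one API: numba-compiled
full-sample kernels (default; ~3–40 ms per 500-node sample) and a pure-Python
reference engine composed of the granular operations
(`death_birth_event_*`, `reassign_ep_*`, `transition_states_f2`,
`run_cycle_*`) that supports per-token event logging. A sample is fully
reproducible from `(graph, config, seed)` for a given engine; the two
engines use different random streams and are compared statistically in the
test suite. Batch seed schedules are arithmetic (`base_seed + g·S + s`), so
any sample can be re-run in isolation and aggregation is a pure fold over
the per-sample records.

Numerical choices: `renewal_rate · N` is rounded half-up; parent selection
normalizes fitness weights to machine precision; the sweep over residence
counters uses ≥ comparisons so `state_time = 1` behaves sensibly; a token
built in a sweep is decremented in that same sweep (framework 1's birth
tokens likewise end their creation cycle one short), so the using-own state
spans `ep_lifetime − 1` cycle boundaries — an off-by-one convention fixed by
the stated update order and applied identically everywhere.

## The oracle

With tokens disabled the process is a plain death-birth Moran chain, and for
graphs of ≤ 12 nodes the type-A fixation probability is solved exactly from
the absorbing-Markov-chain linear system over all 2^N configurations
(scipy sparse solve; rows of the transition matrix sum to 1 by
construction). `monte_carlo_agrees_with_oracle` runs the *actual* simulator
(one event per cycle) against this value; a `uniform_parent` switch provides
a deliberately broken simulator that must fail the gate, guarding the test
itself. Exact solves including token timers are out of reach (the state
space explodes), so token mechanics are validated instead by invariants:
state/token consistency, the timer law (no token outlives `ep_lifetime`
cycles from creation, across transfers, checked by exhaustive event-log
audit), symmetry, and monotonicity.

## What the synthetic world does and does not establish

All inputs are synthetic by design — the platform *is* the object of study.
The generator emulates: a scale-free contact structure, 1:1 initial mixtures,
and the stated bonus/cost ranges. It does not emulate: mutation between
types, cheater genotypes, search costs, token modification by new owners, or
non-BA topologies (regular lattices for biofilm-like systems are a known
extension). A green test therefore establishes internal correctness of the
stated model, not ecological realism.

Desk-scale replication (thousands of samples per parameter point, versus
millions in the full-scale study) leaves ~1–2 percentage-point Monte Carlo
noise on fixation fractions; tests size their tolerances accordingly, and
low-contrast cells of the equal-omega grid (e.g. gamma gap 0.01) are below
desk-scale resolution.

## Known limitations

* The undefined-fraction family of results is conditional on `cycle_limit`;
  with the default 5,000 the A-majority-among-undefined fraction at
  alpha = 0.04 comes out at ~81–89%, somewhat above the ~75% reported at
  full scale — consistent with a different (unknown) cycle limit there.
* The BA construction guarantees degree ≥ m only for incrementally added
  nodes; describing m as a global minimum degree is an approximation.
* Framework-2 initial state percentages for the original experiments are not
  public; the 50/50 searching/using-own default is a documented choice.
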