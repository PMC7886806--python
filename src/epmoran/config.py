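"""Run configuration: every knob of both simulation frameworks, plus the flat
``key=value`` config-file dialect.

Conventions shared by both frameworks
-------------------------------------
* ``alpha_*`` — fitness bonus for occupying an extended phenotype you built
  yourself (in framework 1, the bonus for holding one at all).
* ``beta_*``  — fitness cost while producing an extended phenotype
  (framework 2); the sentinel ``-1`` means the type never enters the
  producing state.
* ``gamma_*`` — fitness bonus for occupying an extended phenotype abandoned
  by a dead conspecific; the sentinel ``-1`` means the type never reuses one.
  In framework 1 the numeric value is unused (holders always earn alpha) but
  the sentinel still switches reuse off.

The sentinels are behavioral switches only: they never enter fitness
arithmetic.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import IO, Union

SENTINEL = -1.0  # "this type never does that"


class ConfigError(ValueError):
    """Raised for invalid or inconsistent simulation configurations."""


def _is_sentinel(x: float) -> bool:
    return x == SENTINEL


@dataclass
class SimConfig:
    """All parameters of a simulation run.

    Defaults describe a neutral, symmetric world on the standard population:
    a 500-node preferential-attachment graph (m=4), 4% of nodes replaced per
    cycle, extended phenotypes lasting 30 cycles, both types able to produce
    one at birth with probability 0.5 and to reuse abandoned ones.
    """

    framework: int = 1
    n_nodes: int = 500
    ba_m: int = 4
    renewal_rate: float = 0.04
    alpha_a: float = 0.0
    alpha_b: float = 0.0
    beta_a: float = SENTINEL
    beta_b: float = SENTINEL
    gamma_a: float = 0.0
    gamma_b: float = 0.0
    ep_lifetime: int = 30
    state_time: int = 30
    birth_ep_chance_a: float = 0.5
    birth_ep_chance_b: float = 0.5
    # initial behavioral-state mix (framework 2)
    pct_searching: float = 0.5
    pct_producing: float = 0.0
    pct_using_own: float = 0.5
    pct_using_other: float = 0.0
    cycle_limit: int = 5000
    samples: int = 100
    base_seed: int = 0
    # baseline per-type relative fitness (1.0 = neutral); lets the oracle
    # module express constant selective differences with EPs disabled
    base_fitness_a: float = 1.0
    base_fitness_b: float = 1.0
    initial_fraction_a: float = 0.5
    init_exact_half: bool = False
    initial_ep_lifetime: Union[int, None] = None  # None -> ep_lifetime

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    def events_per_cycle(self) -> int:
        """Death-birth events per cycle: renewal_rate x N, rounded half-up."""
        return int(math.floor(self.renewal_rate * self.n_nodes + 0.5))

    def produces_at_birth(self) -> tuple:
        """(type A, type B) flags: does a newborn of this type roll for an EP?"""
        return (self.birth_ep_chance_a > 0.0, self.birth_ep_chance_b > 0.0)

    def can_produce(self) -> tuple:
        """(A, B) flags: may this type enter the producing state (framework 2)?"""
        return (not _is_sentinel(self.beta_a), not _is_sentinel(self.beta_b))

    def can_reuse(self) -> tuple:
        """(A, B) flags: may this type occupy an abandoned EP?"""
        return (not _is_sentinel(self.gamma_a), not _is_sentinel(self.gamma_b))

    def initial_ep_time(self) -> int:
        return self.ep_lifetime if self.initial_ep_lifetime is None else self.initial_ep_lifetime

    def state_percentages(self) -> tuple:
        return (self.pct_searching, self.pct_producing, self.pct_using_own, self.pct_using_other)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.framework not in (1, 2):
            raise ConfigError(f"framework must be 1 or 2, got {self.framework}")
        if self.ba_m < 1 or self.n_nodes <= self.ba_m:
            raise ConfigError(f"need n_nodes > ba_m >= 1, got n_nodes={self.n_nodes}, ba_m={self.ba_m}")
        if not (0.0 < self.renewal_rate <= 1.0):
            raise ConfigError(f"renewal_rate must be in (0, 1], got {self.renewal_rate}")
        if self.renewal_rate * self.n_nodes < 1.0 - 1e-12:
            raise ConfigError("renewal_rate x n_nodes must be >= 1 (at least one event per cycle)")
        for name in ("alpha_a", "alpha_b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("beta_a", "beta_b", "gamma_a", "gamma_b"):
            v = getattr(self, name)
            if not (_is_sentinel(v) or 0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1] or the sentinel -1, got {v}")
        for name in ("birth_ep_chance_a", "birth_ep_chance_b", "initial_fraction_a"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        pcts = self.state_percentages()
        if any(p < 0.0 or p > 1.0 for p in pcts):
            raise ConfigError("initial state percentages must each lie in [0, 1]")
        if abs(sum(pcts) - 1.0) > 1e-9:
            raise ConfigError(f"initial state percentages must sum to 1, got {sum(pcts)!r}")
        for name in ("ep_lifetime", "state_time", "cycle_limit", "samples"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.initial_ep_lifetime is not None and self.initial_ep_lifetime < 1:
            raise ConfigError("initial_ep_lifetime must be >= 1 when set")
        for base, beta, label in (
            (self.base_fitness_a, self.beta_a, "A"),
            (self.base_fitness_b, self.beta_b, "B"),
        ):
            if base <= 0.0:
                raise ConfigError(f"base fitness for type {label} must be positive")
            if not _is_sentinel(beta) and base - beta <= 0.0:
                raise ConfigError(f"producing-state fitness for type {label} would be non-positive")

    def replace(self, **changes) -> "SimConfig":
        """Return a validated copy with ``changes`` applied."""
        return dataclasses.replace(self, **changes)


def experiment1_config(alpha_a: float = 0.05, **overrides) -> SimConfig:
    """Framework-1 setting where only type A produces and reuses EPs.

    Type B never receives an EP (birth chance 0) and never reuses one
    (gamma sentinel); type A holders earn ``alpha_a``.
    """
    base = dict(
        framework=1,
        alpha_a=alpha_a,
        alpha_b=0.0,
        birth_ep_chance_a=0.5,
        birth_ep_chance_b=0.0,
        gamma_a=0.0,
        gamma_b=SENTINEL,
    )
    base.update(overrides)
    return SimConfig(**base)


def experiment2_config(alpha: float = 0.05, **overrides) -> SimConfig:
    """Framework-1 setting where both types produce EPs but only A reuses.

    Both types roll for a birth EP with chance 0.5 and earn the same
    ``alpha`` while holding one; a type-B holder's EP vanishes at its death.
    """
    base = dict(
        framework=1,
        alpha_a=alpha,
        alpha_b=alpha,
        birth_ep_chance_a=0.5,
        birth_ep_chance_b=0.5,
        gamma_a=0.0,
        gamma_b=SENTINEL,
    )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# flat key=value config files
# ---------------------------------------------------------------------------

_BOOL_STRINGS = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}

# convenience keys expanding to several fields
_ALIASES = {"birth_ep_chance": ("birth_ep_chance_a", "birth_ep_chance_b")}


def parse_config(source: Union[str, IO[str]]) -> SimConfig:
    """Parse a flat ``key=value`` configuration text into a :class:`SimConfig`.

    One assignment per line; blank lines and ``#`` comments are ignored.
    Keys are the :class:`SimConfig` field names (plus ``birth_ep_chance``,
    which sets both per-type chances); unknown keys are rejected.  ``source``
    may be the text itself or an open text stream.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source
    fields = {f.name: f for f in dataclasses.fields(SimConfig)}
    values = {}

    def assign(key: str, raw: str, lineno: int) -> None:
        f = fields[key]
        try:
            if f.type in ("int", int):
                values[key] = int(raw)
            elif f.type in ("bool", bool):
                values[key] = _BOOL_STRINGS[raw.lower()]
            elif key == "initial_ep_lifetime":
                values[key] = None if raw.lower() == "none" else int(raw)
            else:
                values[key] = float(raw)
        except (ValueError, KeyError):
            raise ConfigError(f"line {lineno}: cannot parse value {raw!r} for key {key!r}") from None

    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key=value', got {raw_line!r}")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key in _ALIASES:
            for target in _ALIASES[key]:
                assign(target, raw, lineno)
        elif key in fields:
            assign(key, raw, lineno)
        else:
            raise ConfigError(f"line {lineno}: unknown configuration key {key!r}")
    return SimConfig(**values)
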