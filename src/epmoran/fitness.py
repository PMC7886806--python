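"""Fitness algebra.

Relative fitness r is the per-node reproductive weight entering the
death-birth rule: a baseline of 1 modified by the extended-phenotype bonuses
and cost (alpha for using your own, beta while producing, gamma for using an
abandoned one).  At the population level the same three parameters combine
into an absolute fitness

    omega = alpha - beta + gamma

which predicts which of two competing populations tends to win, and sharing
is expected to be favored whenever gamma / (alpha - beta) > 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .config import ConfigError, SimConfig
from .state import BehaviorState, NodeType


@dataclass(frozen=True)
class AbsoluteFitness:
    """Population-level absolute fitness omega = alpha - beta + gamma."""

    omega: float
    alpha: float
    beta: float
    gamma: float


def relative_fitness(
    node_type: NodeType,
    state: Union[BehaviorState, bool],
    config: SimConfig,
) -> float:
    """Relative fitness of a node given its type and situation.

    Framework 1 takes ``state`` as a has-EP flag: holders earn the type's
    alpha bonus on top of the type's baseline, everyone else sits at the
    baseline.  Framework 2 takes a :class:`BehaviorState`: searching is the
    baseline, producing pays beta, using your own EP earns alpha, using
    someone else's earns gamma.
    """
    t = NodeType(node_type)
    base = config.base_fitness_a if t == NodeType.A else config.base_fitness_b
    alpha = config.alpha_a if t == NodeType.A else config.alpha_b
    beta = config.beta_a if t == NodeType.A else config.beta_b
    gamma = config.gamma_a if t == NodeType.A else config.gamma_b

    if config.framework == 1:
        has_ep = bool(state)
        r = base + alpha if has_ep else base
    else:
        s = BehaviorState(state)
        if s == BehaviorState.SEARCHING:
            r = base
        elif s == BehaviorState.PRODUCING:
            if beta == -1.0:
                raise ConfigError(f"type {t.name} cannot be in the producing state (beta = -1)")
            r = base - beta
        elif s == BehaviorState.USING_OWN:
            r = base + alpha
        else:  # USING_OTHER
            if gamma == -1.0:
                raise ConfigError(f"type {t.name} cannot be in the using-other state (gamma = -1)")
            r = base + gamma
    if r <= 0.0:
        raise ConfigError(f"relative fitness must be positive, got {r}")
    return r


def selection_weights(neighbor_fitnesses: Sequence[float]) -> np.ndarray:
    """Parent-selection probabilities proportional to neighbor fitness.

    Returns an array summing to 1 (within 1e-12).  Empty input or any
    non-positive fitness is an error.
    """
    f = np.asarray(neighbor_fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one neighbor to select a parent")
    if np.any(f <= 0.0) or not np.all(np.isfinite(f)):
        raise ValueError("all fitnesses must be positive and finite")
    return f / f.sum()


def omega(alpha: float, beta: float, gamma: float) -> AbsoluteFitness:
    """Absolute fitness omega = alpha - beta + gamma.

    Sentinel values (-1) must be resolved to 0 by the caller before use:
    here they would be treated as numbers, which is never what a behavioral
    switch means.
    """
    return AbsoluteFitness(omega=alpha - beta + gamma, alpha=alpha, beta=beta, gamma=gamma)


def sharing_favored(alpha: float, beta: float, gamma: float) -> bool:
    """Is the shared use of extended phenotypes favored, i.e. gamma/(alpha - beta) > 1?

    Undefined (raises) when alpha == beta.
    """
    if alpha == beta:
        raise ZeroDivisionError("sharing condition undefined when alpha == beta")
    return gamma / (alpha - beta) > 1.0


def project_abundance(n0: float, omega_value: float, generations: int) -> np.ndarray:
    """Geometric abundance projection n(g+1) = omega * n(g).

    Returns the trajectory ``[n0, n0*omega, ..., n0*omega**generations]``
    (length ``generations + 1``).  Shipped as a standalone utility; the
    simulators never use it.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    g = np.arange(generations + 1)
    return n0 * np.power(float(omega_value), g)


def fitness_table(
    pairs: Sequence = ((0.01, 0.08), (0.02, 0.07), (0.03, 0.06), (0.04, 0.05),
                       (0.05, 0.04), (0.06, 0.03), (0.07, 0.02), (0.08, 0.01)),
    betas: Sequence[float] = (0.01, 0.03, 0.05, 0.07, 0.09),
):
    """Regenerate the equal-omega parameter table as a DataFrame.

    Rows are (alpha_A = gamma_B, alpha_B = gamma_A) pairs with constant sum;
    columns are beta values; cells are omega (identical for both populations
    by construction).
    """
    import pandas as pd

    data = {}
    for beta in betas:
        data[f"beta={beta:.2f}"] = [omega(a, beta, g).omega for a, g in pairs]
    index = [f"{a:.2f}; {g:.2f}" for a, g in pairs]
    return pd.DataFrame(data, index=index).round(10)
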