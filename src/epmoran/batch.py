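"""Batch orchestration: many graphs x many samples per parameter point.

The paper-scale design is 1,000 graphs x 5,000 samples per grid point; the
desk-scale default used throughout the tests and the acceptance script is
20 graphs x 100 samples (2,000 samples, 95% binomial half-width about 2.2
percentage points).  The seed schedule is purely arithmetic — graph ``g``
is grown with ``base_seed + g`` and sample ``s`` on graph ``g`` runs with
``base_seed + g * samples_per_graph + s`` — so any single sample can be
re-run in isolation and aggregation is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .config import SENTINEL, SimConfig
from .fitness import omega
from .framework1 import run_sample_f1
from .framework2 import run_sample_f2
from .graph import PopulationGraph, generate_ba_graph
from .state import Outcome

RECORD_COLUMNS = [
    "sample_id",
    "graph_id",
    "seed",
    "outcome",
    "cycles_elapsed",
    "final_count_a",
    "final_count_b",
    "final_ep_count",
    "final_ep_count_a",
]
F2_STATE_COLUMNS = ["count_searching", "count_producing", "count_using_own", "count_using_other"]


@dataclass(frozen=True)
class BatchSummary:
    """Aggregated outcomes for one parameter point."""

    parameter_point: dict
    n_samples: int
    frac_fixed_a: float
    frac_fixed_b: float
    frac_undefined: float
    frac_undefined_a_majority: float  # NaN when no sample was undefined
    mean_occupancy_a: float  # mean fraction of surviving A nodes holding an EP

    def __post_init__(self) -> None:
        assert abs(self.frac_fixed_a + self.frac_fixed_b + self.frac_undefined - 1.0) < 1e-12

    def __eq__(self, other) -> bool:
        if not isinstance(other, BatchSummary):
            return NotImplemented

        def same(a, b):
            if isinstance(a, float) and isinstance(b, float):
                return a == b or (np.isnan(a) and np.isnan(b))
            return a == b

        return all(
            same(getattr(self, f), getattr(other, f))
            for f in (
                "parameter_point",
                "n_samples",
                "frac_fixed_a",
                "frac_fixed_b",
                "frac_undefined",
                "frac_undefined_a_majority",
                "mean_occupancy_a",
            )
        )


def summarize(records: pd.DataFrame, parameter_point: Union[dict, None] = None) -> BatchSummary:
    """Fold per-sample records into a :class:`BatchSummary` (pure aggregation)."""
    n = len(records)
    fixed_a = (records["outcome"] == Outcome.FIXED_A.value).sum()
    fixed_b = (records["outcome"] == Outcome.FIXED_B.value).sum()
    undef = records[records["outcome"] == Outcome.UNDEFINED.value]
    if len(undef):
        a_major = float((undef["final_count_a"] > undef["final_count_b"]).mean())
    else:
        a_major = float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = records["final_ep_count_a"] / records["final_count_a"].replace(0, np.nan)
    return BatchSummary(
        parameter_point=parameter_point or {},
        n_samples=n,
        frac_fixed_a=fixed_a / n,
        frac_fixed_b=fixed_b / n,
        frac_undefined=len(undef) / n,
        frac_undefined_a_majority=a_major,
        mean_occupancy_a=float(occ.mean()) if occ.notna().any() else float("nan"),
    )


def run_batch(
    config: SimConfig,
    n_graphs: int = 20,
    samples_per_graph: int = 100,
    base_seed: int = 0,
    graphs: Union[Sequence[PopulationGraph], None] = None,
    parameter_point: Union[dict, None] = None,
) -> tuple:
    """Run ``n_graphs`` x ``samples_per_graph`` samples of ``config``.

    Returns ``(records, summary)`` where ``records`` is a DataFrame with one
    row per sample.  ``graphs`` overrides graph generation (its length must
    be ``n_graphs``); otherwise graph ``g`` is a fresh Barabási–Albert graph
    grown with seed ``base_seed + g``.
    """
    if n_graphs < 1 or samples_per_graph < 1:
        raise ValueError("need at least one graph and one sample per graph")
    run = run_sample_f1 if config.framework == 1 else run_sample_f2
    rows = []
    for g in range(n_graphs):
        if graphs is not None:
            graph = graphs[g]
        else:
            graph = generate_ba_graph(config.n_nodes, config.ba_m, seed=base_seed + g)
        for s in range(samples_per_graph):
            seed = base_seed + g * samples_per_graph + s
            out = run(graph, config, seed)
            row = {
                "sample_id": g * samples_per_graph + s,
                "graph_id": g,
                "seed": seed,
                "outcome": out.classification.value,
                "cycles_elapsed": out.cycles_elapsed,
                "final_count_a": out.final_count_a,
                "final_count_b": out.final_count_b,
                "final_ep_count": out.final_ep_count,
                "final_ep_count_a": out.final_ep_count_a,
            }
            if out.state_counts is not None:
                for col, v in zip(F2_STATE_COLUMNS, out.state_counts):
                    row[col] = v
            rows.append(row)
    records = pd.DataFrame(rows)
    return records, summarize(records, parameter_point)


def _resolved(x: float) -> float:
    """Sentinel bonuses resolve to 0 in fitness arithmetic."""
    return 0.0 if x == SENTINEL else x


def sweep_alpha(
    config_template: SimConfig,
    alpha_values: Sequence[float],
    n_graphs: int = 20,
    samples_per_graph: int = 100,
    base_seed: int = 0,
    vary_both: bool = False,
) -> list:
    """One batch per alpha value (framework-1 alpha sweeps).

    ``vary_both`` sets alpha for both types (the both-types-produce
    experiment); otherwise only type A's bonus moves and type B keeps the
    template's value.
    """
    stride = n_graphs * samples_per_graph + n_graphs
    summaries = []
    for i, a in enumerate(alpha_values):
        changes = {"alpha_a": a, "alpha_b": a} if vary_both else {"alpha_a": a}
        cfg = config_template.replace(**changes)
        _, summ = run_batch(
            cfg,
            n_graphs,
            samples_per_graph,
            base_seed + i * stride,
            parameter_point={"alpha_a": cfg.alpha_a, "alpha_b": cfg.alpha_b},
        )
        summaries.append(summ)
    return summaries


def sweep_omega_ratio(
    config_template: SimConfig,
    ratio_values: Sequence[float],
    n_graphs: int = 20,
    samples_per_graph: int = 100,
    base_seed: int = 0,
) -> list:
    """Framework-2 sweep of omega_A / omega_B, moving alpha_A only.

    The template fixes alpha_B, beta and gamma; for each target ratio,
    alpha_A is back-computed from ``omega_A = ratio * omega_B``.  A ratio
    requiring alpha_A outside [0, 1] is an error.
    """
    cfg0 = config_template
    omega_b = omega(
        _resolved(cfg0.alpha_b), _resolved(cfg0.beta_b), _resolved(cfg0.gamma_b)
    ).omega
    stride = n_graphs * samples_per_graph + n_graphs
    summaries = []
    for i, ratio in enumerate(ratio_values):
        alpha_a = ratio * omega_b + _resolved(cfg0.beta_a) - _resolved(cfg0.gamma_a)
        if not (0.0 <= alpha_a <= 1.0):
            raise ValueError(
                f"omega ratio {ratio} needs alpha_a = {alpha_a:.4f}, outside [0, 1]"
            )
        cfg = cfg0.replace(alpha_a=alpha_a)
        omega_a = omega(_resolved(cfg.alpha_a), _resolved(cfg.beta_a), _resolved(cfg.gamma_a)).omega
        _, summ = run_batch(
            cfg,
            n_graphs,
            samples_per_graph,
            base_seed + i * stride,
            parameter_point={"ratio": ratio, "alpha_a": alpha_a, "omega_a": omega_a, "omega_b": omega_b},
        )
        summaries.append(summ)
    return summaries


def sweep_equal_omega(
    config_template: SimConfig,
    alpha_gamma_pairs: Sequence = ((0.01, 0.08), (0.02, 0.07), (0.03, 0.06), (0.04, 0.05),
                                   (0.05, 0.04), (0.06, 0.03), (0.07, 0.02), (0.08, 0.01)),
    beta_values: Sequence[float] = (0.01, 0.03, 0.05, 0.07, 0.09),
    n_graphs: int = 20,
    samples_per_graph: int = 100,
    base_seed: int = 0,
) -> list:
    """Framework-2 grid with omega_A = omega_B enforced by construction.

    Each pair ``(p, q)`` sets alpha_A = gamma_B = p and alpha_B = gamma_A = q,
    so both populations share omega = p + q - beta for every beta.  One
    summary per (pair, beta) cell.
    """
    stride = n_graphs * samples_per_graph + n_graphs
    summaries = []
    i = 0
    for p, q in alpha_gamma_pairs:
        for beta in beta_values:
            cfg = config_template.replace(
                alpha_a=p, gamma_b=p, alpha_b=q, gamma_a=q, beta_a=beta, beta_b=beta
            )
            om_a = omega(cfg.alpha_a, cfg.beta_a, cfg.gamma_a).omega
            om_b = omega(cfg.alpha_b, cfg.beta_b, cfg.gamma_b).omega
            if abs(om_a - om_b) > 1e-12:
                raise ValueError(f"grid cell ({p}, {q}, beta={beta}) breaks omega_A = omega_B")
            _, summ = run_batch(
                cfg,
                n_graphs,
                samples_per_graph,
                base_seed + i * stride,
                parameter_point={
                    "alpha_a": p, "gamma_a": q, "alpha_b": q, "gamma_b": p,
                    "beta": beta, "omega": om_a,
                },
            )
            summaries.append(summ)
            i += 1
    return summaries


def summaries_to_frame(summaries: Sequence[BatchSummary]) -> pd.DataFrame:
    """Tabulate sweep summaries: one row per grid point."""
    rows = []
    for s in summaries:
        row = dict(s.parameter_point)
        row.update(
            n_samples=s.n_samples,
            frac_fixed_a=s.frac_fixed_a,
            frac_fixed_b=s.frac_fixed_b,
            frac_undefined=s.frac_undefined,
            frac_undefined_a_majority=s.frac_undefined_a_majority,
            mean_occupancy_a=s.mean_occupancy_a,
        )
        rows.append(row)
    return pd.DataFrame(rows)
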