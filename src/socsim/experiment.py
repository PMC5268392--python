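"""Replicated IR vs no-IR experiments.

For each condition x replicate the full pipeline runs: simulation ->
per-snapshot DBSCAN group metrics -> lineage lifespans -> final signed
network -> Louvain modularity on the positive subgraph.  Metrics are
averaged over replicates; conditions are compared with the Kruskal-Wallis
rank test and Dunn's multiple-comparison post hoc.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import (
    ClusterSnapshot,
    DbscanParams,
    cluster_metrics,
    cluster_series,
    max_cluster_size,
)
from .config import Condition, ConfigError, ExperimentConfig, SimulationConfig
from .network import build_network, louvain
from .sim import SimulationResult, run_simulation
from .tracking import compute_lifespans, mean_lifespan

__all__ = [
    "replicate_seed",
    "run_replicate",
    "run_experiment",
    "ExperimentResult",
    "summarize",
    "compare_conditions",
    "dunn_test",
    "ComparisonResult",
]


def replicate_seed(master_seed: int, condition_index: int, replicate_index: int) -> int:
    """Deterministic per-replicate seed, derived by spawning a numpy
    SeedSequence at (condition, replicate); always < 2**31."""
    ss = np.random.SeedSequence(
        int(master_seed), spawn_key=(int(condition_index), int(replicate_index))
    )
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


@dataclass
class ReplicateSummary:
    """All pipeline metrics for a single simulation run."""

    per_round: pd.DataFrame  # round, n_clusters, mean_cluster_size, max_cluster_size
    mean_lifespan: float
    modularity: float
    final_n_clusters: int
    final_mean_cluster_size: float
    max_cluster_size: int


def run_replicate(
    config: SimulationConfig,
    dbscan_params: DbscanParams = DbscanParams(),
    tau: float = 0.5,
    tau_split: float = 0.25,
    with_lifespans: bool = True,
    with_network: bool = True,
) -> ReplicateSummary:
    """One simulation through the full measurement pipeline."""
    result = run_simulation(config)
    snaps = cluster_series(result, dbscan_params)
    rows = []
    for s in snaps:
        n_c, mean_sz = cluster_metrics(s)
        rows.append((s.round, n_c, mean_sz, max_cluster_size(s)))
    per_round = pd.DataFrame(
        rows, columns=["round", "n_clusters", "mean_cluster_size", "max_cluster_size"]
    )
    life = (
        mean_lifespan(compute_lifespans(snaps, tau=tau, tau_split=tau_split))
        if with_lifespans
        else float("nan")
    )
    q = float("nan")
    if with_network:
        net = build_network(result.events, n_agents=config.n_agents)
        q = louvain(net, seed=config.seed).q
    return ReplicateSummary(
        per_round=per_round,
        mean_lifespan=life,
        modularity=q,
        final_n_clusters=int(per_round.n_clusters.iloc[-1]),
        final_mean_cluster_size=float(per_round.mean_cluster_size.iloc[-1]),
        max_cluster_size=int(per_round.max_cluster_size.max()),
    )


@dataclass
class ExperimentResult:
    """Aggregated pipeline metrics over conditions x replicates."""

    config: ExperimentConfig
    per_round: pd.DataFrame  # condition, replicate, round, n_clusters, ...
    per_replicate: pd.DataFrame  # condition, replicate, seed, metrics


def run_experiment(
    exp: ExperimentConfig,
    dbscan_params: DbscanParams = DbscanParams(),
    tau: float = 0.5,
    tau_split: float = 0.25,
    with_lifespans: bool = True,
    with_network: bool = True,
) -> ExperimentResult:
    """Run every condition x replicate; reproducible from ``master_seed``."""
    per_round_parts = []
    rep_rows = []
    for ci, cond in enumerate(exp.conditions):
        for rep in range(exp.replicates):
            seed = replicate_seed(exp.master_seed, ci, rep)
            cfg = cond.apply(exp.base).replace(seed=seed)
            summary = run_replicate(
                cfg, dbscan_params, tau, tau_split, with_lifespans, with_network
            )
            pr = summary.per_round.copy()
            pr.insert(0, "replicate", rep)
            pr.insert(0, "condition", cond.label)
            per_round_parts.append(pr)
            rep_rows.append(
                {
                    "condition": cond.label,
                    "replicate": rep,
                    "seed": seed,
                    "mean_lifespan": summary.mean_lifespan,
                    "modularity": summary.modularity,
                    "final_n_clusters": summary.final_n_clusters,
                    "final_mean_cluster_size": summary.final_mean_cluster_size,
                    "max_cluster_size": summary.max_cluster_size,
                }
            )
    return ExperimentResult(
        config=exp,
        per_round=pd.concat(per_round_parts, ignore_index=True),
        per_replicate=pd.DataFrame(rep_rows),
    )


_SUMMARY_METRICS = (
    "final_n_clusters",
    "final_mean_cluster_size",
    "mean_lifespan",
    "modularity",
    "max_cluster_size",
)


def summarize(result: ExperimentResult) -> pd.DataFrame:
    """Per-condition mean and sd of the endpoint metrics.

    The sd of a single replicate is reported as 0.
    """
    g = result.per_replicate.groupby("condition", sort=False)
    out = {}
    for m in _SUMMARY_METRICS:
        out[f"{m}_mean"] = g[m].mean()
        out[f"{m}_sd"] = g[m].std(ddof=1).fillna(0.0)
    df = pd.DataFrame(out).reset_index()
    df.insert(1, "replicates", g.size().to_numpy())
    return df


@dataclass
class ComparisonResult:
    """Kruskal-Wallis across conditions plus Dunn pairwise post hoc."""

    h: float
    p: float
    dunn: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj
    degenerate: bool = False


def dunn_test(
    samples: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's z statistics on pooled ranks, with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided p values,
    Bonferroni-adjusted by default (``adjust=None`` for raw only).
    """
    names = list(samples)
    values = [np.asarray(samples[k], float) for k in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[start : start + len(v)].mean()
        sizes[name] = len(v)
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    pairs = list(itertools.combinations(names, 2))
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p_raw})
    df = pd.DataFrame(rows)
    if adjust == "bonferroni":
        df["p_adj"] = np.minimum(df["p_raw"] * len(pairs), 1.0)
    elif adjust is None:
        df["p_adj"] = df["p_raw"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def compare_conditions(samples: Mapping[str, Sequence[float]]) -> ComparisonResult:
    """Kruskal-Wallis H test across >= 2 conditions plus Dunn post hoc.

    When every value in every sample is identical the comparison is
    degenerate and reported as no evidence of a difference (H=0, p=1).
    """
    if len(samples) < 2:
        raise ValueError("need at least two conditions to compare")
    values = [np.asarray(v, float) for v in samples.values()]
    if any(len(v) < 3 for v in values):
        raise ValueError("need at least three replicates per condition")
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        dunn = dunn_test(samples)
        return ComparisonResult(h=0.0, p=1.0, dunn=dunn, degenerate=True)
    h, p = stats.kruskal(*values)
    return ComparisonResult(h=float(h), p=float(p), dunn=dunn_test(samples))
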