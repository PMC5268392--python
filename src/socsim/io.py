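"""CSV / GraphML writers and readers, plus run metadata.

All writers are deterministic: stable row order and %.9g float formatting,
so identical runs produce byte-identical files.  Readers validate schemas
and report the offending line on failure.
"""
from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .network import InteractionNetwork, Partition
from .sim import BEHAVIOR_NAMES, InteractionType

__all__ = [
    "FormatError",
    "FLOAT_FORMAT",
    "write_trajectory",
    "read_trajectory",
    "write_events",
    "read_events",
    "write_labels",
    "read_labels",
    "write_transitions",
    "write_lifespans",
    "write_edges",
    "read_edges",
    "write_graphml",
    "RunMetadata",
    "write_metadata",
    "read_metadata",
]

FLOAT_FORMAT = "%.9g"


class FormatError(ValueError):
    """Raised for malformed tabular input files."""


def _check_columns(df: pd.DataFrame, expected: tuple[str, ...], path: Any) -> None:
    if tuple(df.columns) != expected:
        raise FormatError(
            f"{path}: expected columns {list(expected)}, found {list(df.columns)}"
        )


def write_trajectory(df: pd.DataFrame, path: str | Path) -> None:
    """(round, agent_id, x, y) snapshots to CSV."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT,
              columns=["round", "agent_id", "x", "y"])


def read_trajectory(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ("round", "agent_id", "x", "y"), path)
    for col in ("x", "y"):
        bad = df.index[~np.isfinite(df[col].to_numpy(float))]
        if len(bad):
            raise FormatError(f"{path}: non-finite {col} at line {bad[0] + 2}")
    return df


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    """(round, actor, partner, behavior) log to CSV; behavior by name."""
    out = df.copy()
    if out["behavior"].dtype != object:
        out["behavior"] = out["behavior"].map(lambda c: BEHAVIOR_NAMES[int(c)])
    out.to_csv(path, index=False, columns=["round", "actor", "partner", "behavior"])


def read_events(path: str | Path, as_codes: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ("round", "actor", "partner", "behavior"), path)
    valid = set(BEHAVIOR_NAMES)
    if len(df):
        bad = df.index[~df["behavior"].isin(valid)]
        if len(bad):
            raise FormatError(
                f"{path}: invalid behavior {df['behavior'].iloc[bad[0]]!r} "
                f"at line {bad[0] + 2} (expected one of {sorted(valid)})"
            )
        if (df["actor"] == df["partner"]).any():
            i = int(df.index[df["actor"] == df["partner"]][0])
            raise FormatError(f"{path}: actor == partner at line {i + 2}")
    if as_codes:
        df["behavior"] = df["behavior"].map(
            lambda s: int(InteractionType.from_name(s))
        )
    return df


def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    """(round, agent_id, cluster_id) cluster labels to CSV (noise = -1)."""
    df.to_csv(path, index=False, columns=["round", "agent_id", "cluster_id"])


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ("round", "agent_id", "cluster_id"), path)
    return df


def write_transitions(transitions, path: str | Path) -> None:
    """Flatten TransitionRecords to CSV (targets/overlaps ;-separated)."""
    rows = []
    for step in transitions:
        for r in step:
            rows.append(
                {
                    "round_from": r.round_from,
                    "round_to": r.round_to,
                    "source": -1 if r.source is None else r.source,
                    "outcome": r.outcome,
                    "targets": ";".join(str(t) for t in r.targets),
                    "overlaps": ";".join(FLOAT_FORMAT % v for v in r.overlaps),
                }
            )
    pd.DataFrame(
        rows,
        columns=["round_from", "round_to", "source", "outcome", "targets", "overlaps"],
    ).to_csv(path, index=False)


def write_lifespans(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=["lineage_id", "birth", "death", "lifespan"])


def write_edges(network: InteractionNetwork, path: str | Path) -> None:
    """(node_a, node_b, weight) edge list to CSV, sorted by node pair."""
    network.edges.sort_values(["node_a", "node_b"]).to_csv(
        path, index=False, columns=["node_a", "node_b", "weight"]
    )


def read_edges(path: str | Path) -> InteractionNetwork:
    df = pd.read_csv(path)
    _check_columns(df, ("node_a", "node_b", "weight"), path)
    nodes = (
        np.unique(df[["node_a", "node_b"]].to_numpy().ravel())
        if len(df)
        else np.empty(0, np.int64)
    )
    return InteractionNetwork(nodes=nodes, edges=df)


def write_graphml(
    network: InteractionNetwork,
    path: str | Path,
    partition: Partition | None = None,
) -> None:
    """GraphML export with weight (and optional community) attributes."""
    import networkx as nx

    g = network.to_networkx()
    if partition is not None:
        nx.set_node_attributes(g, partition.membership, "community")
    nx.write_graphml(g, path)


@dataclass
class RunMetadata:
    """Everything needed to exactly reproduce an output directory."""

    config: dict[str, Any]
    seeds: list[int]
    software: str = ""
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def __post_init__(self) -> None:
        if not self.software:
            from . import __version__

            self.software = f"socsim {__version__}"


def write_metadata(meta: RunMetadata, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "software": meta.software,
                "created": meta.created,
                "seeds": meta.seeds,
                "config": meta.config,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def read_metadata(path: str | Path) -> RunMetadata:
    with open(path) as fh:
        d = json.load(fh)
    return RunMetadata(
        config=d["config"], seeds=d["seeds"], software=d["software"],
        created=d["created"],
    )
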