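"""Spatial group detection.

A *group* is purely spatial: a DBSCAN cluster of agents whose chained
eps-neighborhoods contain at least ``min_pts`` points.  By default the
clustering treats coordinates as plain Euclidean, matching the reference
analysis convention (a group straddling the world seam counts as two);
pass ``periodic=True`` to use the toroidal metric of the world instead
(each axis difference wrapped to <= L/2).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .sim import SimulationResult

__all__ = [
    "DbscanParams",
    "ClusterSnapshot",
    "toroidal_distance",
    "pairwise_toroidal_distances",
    "dbscan",
    "cluster_metrics",
    "max_cluster_size",
    "cluster_series",
]

NOISE = -1


@dataclass(frozen=True)
class DbscanParams:
    """eps = 3, min_pts = 4: the standard recommendation for 2-d data.

    ``min_pts`` counts the point itself (original DBSCAN convention), so the
    smallest detectable group has 4 members.
    """

    eps: float = 3.0
    min_pts: int = 4

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.min_pts < 1:
            raise ValueError(f"min_pts must be >= 1, got {self.min_pts}")


def toroidal_distance(p, q, L: float):
    """Euclidean distance on the L-periodic torus; broadcasts over arrays."""
    d = np.abs(np.asarray(p, float) - np.asarray(q, float))
    d = np.minimum(d, L - d)
    return np.sqrt((d * d).sum(axis=-1))


def pairwise_toroidal_distances(points: np.ndarray, L: float) -> np.ndarray:
    """Full (n, n) toroidal distance matrix (used by tests and small inputs)."""
    pts = np.asarray(points, float)
    d = np.abs(pts[:, None, :] - pts[None, :, :])
    d = np.minimum(d, L - d)
    return np.sqrt((d * d).sum(axis=-1))


@dataclass
class ClusterSnapshot:
    """Per-round cluster labels over all agents (noise = -1)."""

    round: int
    labels: np.ndarray

    @cached_property
    def members(self) -> dict[int, frozenset]:
        """Mapping cluster id -> frozenset of agent ids (noise excluded)."""
        out: dict[int, set] = {}
        for agent, lab in enumerate(self.labels):
            if lab != NOISE:
                out.setdefault(int(lab), set()).add(agent)
        return {k: frozenset(v) for k, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": np.full(len(self.labels), self.round, np.int64),
                "agent_id": np.arange(len(self.labels)),
                "cluster_id": np.asarray(self.labels, np.int64),
            }
        )


def dbscan(
    points: np.ndarray,
    L: float,
    params: DbscanParams = DbscanParams(),
    periodic: bool = False,
) -> np.ndarray:
    """Label points with DBSCAN; returns an int array with noise = -1.

    Neighbor queries are grid-bucketed (cell size >= eps) in periodic mode
    when the torus is wide enough, otherwise brute force.  Labels are
    deterministic given the input order; the induced partition is
    order-invariant.
    """
    pts = np.ascontiguousarray(points, np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) == 0:
        return np.empty(0, np.int64)
    return _kernels.dbscan_kernel(
        pts, float(params.eps), int(params.min_pts), float(L), bool(periodic)
    )


def cluster_metrics(snapshot: ClusterSnapshot) -> tuple[int, float]:
    """(number of clusters, mean cluster size); (0, 0.0) when all noise."""
    sizes = np.bincount(snapshot.labels[snapshot.labels != NOISE])
    sizes = sizes[sizes > 0]
    if sizes.size == 0:
        return 0, 0.0
    return int(sizes.size), float(sizes.mean())


def max_cluster_size(snapshot: ClusterSnapshot) -> int:
    """Member count of the largest cluster (0 when all noise)."""
    labs = snapshot.labels[snapshot.labels != NOISE]
    if labs.size == 0:
        return 0
    return int(np.bincount(labs).max())


def cluster_series(
    result: SimulationResult,
    params: DbscanParams = DbscanParams(),
    periodic: bool = False,
) -> list[ClusterSnapshot]:
    """DBSCAN every snapshot of a simulation result."""
    L = result.config.world_size
    return [
        ClusterSnapshot(round=int(r), labels=dbscan(pos, L, params, periodic))
        for r, pos in zip(result.snapshot_rounds, result.snapshots)
    ]
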