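"""Signed interaction networks and modularity.

Every interacting pair gets one undirected edge whose weight is the signed
sum of its events (-1 agonistic, 0 neutral, +1 affiliative), so the weight
describes the prevailing relationship.  Community structure is read from the
positive subgraph only — modules are built from primarily affiliative
relationships — with the Louvain algorithm, and quantified by Newman's
weighted modularity

    Q = (1 / 2W) * sum_ij [w_ij - k_i k_j / (2W)] * delta(c_i, c_j)

with W the total edge weight and k the weighted degrees.
"""
from __future__ import annotations

import random as _random
from dataclasses import dataclass
from typing import Mapping

import igraph as ig
import numpy as np
import pandas as pd

from .sim import InteractionType

__all__ = [
    "InteractionNetwork",
    "Partition",
    "build_network",
    "positive_subgraph",
    "modularity",
    "louvain",
]

_WEIGHTS = np.array([-1, 0, 1], np.int64)  # agonistic, neutral, affiliative


@dataclass
class InteractionNetwork:
    """Undirected weighted graph: nodes are agent ids, one edge per
    interacting pair, integer weight = (#affiliative - #agonistic) events."""

    nodes: np.ndarray
    edges: pd.DataFrame  # columns node_a < node_b, weight

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_weight(self, a: int, b: int) -> int:
        if a > b:
            a, b = b, a
        m = self.edges[(self.edges.node_a == a) & (self.edges.node_b == b)]
        if len(m) == 0:
            raise KeyError(f"no edge between {a} and {b}")
        return int(m.weight.iloc[0])

    def to_networkx(self):
        """As a networkx Graph with a ``weight`` edge attribute."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(int(v) for v in self.nodes)
        g.add_weighted_edges_from(
            (int(a), int(b), int(w))
            for a, b, w in self.edges[["node_a", "node_b", "weight"]].itertuples(
                index=False
            )
        )
        return g


def build_network(
    events: pd.DataFrame, n_agents: int | None = None
) -> InteractionNetwork:
    """Accumulate an event log into a signed network.

    ``events`` needs columns actor, partner, behavior (codes 0/1/2 or the
    names agonistic/neutral/affiliative).  Pairs whose events cancel (or are
    all neutral) keep a weight-0 edge: the pair did interact.
    """
    actor = events["actor"].to_numpy(np.int64)
    partner = events["partner"].to_numpy(np.int64)
    beh = events["behavior"]
    if beh.dtype == object or str(beh.dtype).startswith("str"):
        codes = beh.map(lambda s: int(InteractionType.from_name(s))).to_numpy(np.int64)
    else:
        codes = beh.to_numpy(np.int64)
    if codes.size and (codes.min() < 0 or codes.max() > 2):
        raise ValueError("behavior codes must be 0 (agonistic), 1 (neutral) or 2 (affiliative)")
    a = np.minimum(actor, partner)
    b = np.maximum(actor, partner)
    if np.any(a == b):
        raise ValueError("self-interactions are not allowed")
    df = pd.DataFrame({"node_a": a, "node_b": b, "weight": _WEIGHTS[codes]})
    edges = (
        df.groupby(["node_a", "node_b"], as_index=False, sort=True)["weight"].sum()
    )
    if n_agents is None:
        nodes = np.unique(np.concatenate([a, b])) if a.size else np.empty(0, np.int64)
    else:
        nodes = np.arange(n_agents)
    return InteractionNetwork(nodes=nodes, edges=edges)


def positive_subgraph(network: InteractionNetwork) -> InteractionNetwork:
    """Drop edges with weight <= 0; the node set is preserved (isolates ok)."""
    edges = network.edges[network.edges.weight > 0].reset_index(drop=True)
    return InteractionNetwork(nodes=network.nodes.copy(), edges=edges)


def modularity(network: InteractionNetwork, membership: Mapping[int, int]) -> float:
    """Newman weighted modularity of a node -> community assignment."""
    w = network.edges["weight"].to_numpy(float)
    tot = w.sum()
    if tot == 0:
        raise ValueError("modularity is undefined for zero total edge weight")
    comm = np.array([membership[int(v)] for v in network.nodes])
    _, comm = np.unique(comm, return_inverse=True)  # contiguous community ids
    idx = {int(v): k for k, v in enumerate(network.nodes)}
    a = np.array([idx[int(x)] for x in network.edges.node_a], np.int64)
    b = np.array([idx[int(x)] for x in network.edges.node_b], np.int64)
    within = w[comm[a] == comm[b]].sum()
    k = np.zeros(network.n_nodes)
    np.add.at(k, a, w)
    np.add.at(k, b, w)
    n_comm = int(comm.max()) + 1 if len(comm) else 0
    s = np.zeros(n_comm)
    np.add.at(s, comm, k)
    return float(within / tot - ((s / (2.0 * tot)) ** 2).sum())


@dataclass
class Partition:
    """A node -> community assignment with its modularity Q."""

    membership: dict[int, int]
    q: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


def louvain(network: InteractionNetwork, seed: int = 0) -> Partition:
    """Louvain (multilevel) modularity maximization on positive weights.

    Edges with weight <= 0 are excluded from the optimization.  On an
    edgeless (after filtering) network every node is its own community and
    Q is reported as nan (undefined).  Deterministic given ``seed``.
    """
    pos = positive_subgraph(network)
    nodes = [int(v) for v in pos.nodes]
    if pos.n_edges == 0:
        return Partition({v: i for i, v in enumerate(nodes)}, float("nan"))
    idx = {v: i for i, v in enumerate(nodes)}
    pairs = list(
        zip(
            (idx[int(x)] for x in pos.edges.node_a),
            (idx[int(x)] for x in pos.edges.node_b),
        )
    )
    g = ig.Graph(n=len(nodes), edges=pairs)
    ig.set_random_number_generator(_random.Random(seed))
    clustering = g.community_multilevel(weights=pos.edges["weight"].to_list())
    membership = {v: int(c) for v, c in zip(nodes, clustering.membership)}
    # relabel communities by smallest member id for stable output
    remap: dict[int, int] = {}
    for v in nodes:
        c = membership[v]
        if c not in remap:
            remap[c] = len(remap)
    membership = {v: remap[c] for v, c in membership.items()}
    return Partition(membership, modularity(pos, membership))
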