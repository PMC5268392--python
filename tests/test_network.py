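"""Signed-network construction, modularity and Louvain community recovery."""
import itertools

import numpy as np
import pandas as pd
import pytest

from socsim import InteractionType
from socsim.network import (
    InteractionNetwork,
    build_network,
    louvain,
    modularity,
    positive_subgraph,
)

from oracles import modularity_oracle

AGO, NEU, AFF = 0, 1, 2


def events(*rows):
    return pd.DataFrame(rows, columns=["actor", "partner", "behavior"])


def net_from_edges(edge_list):
    nodes = sorted({u for u, _, _ in edge_list} | {v for _, v, _ in edge_list})
    df = pd.DataFrame(
        [(min(u, v), max(u, v), w) for u, v, w in edge_list],
        columns=["node_a", "node_b", "weight"],
    )
    return InteractionNetwork(nodes=np.array(nodes), edges=df)


class TestBuildNetwork:
    def test_empty_log(self):
        net = build_network(events(), n_agents=5)
        assert net.n_edges == 0 and net.n_nodes == 5

    def test_signed_sum(self):
        net = build_network(
            events((1, 2, AFF), (2, 1, AFF), (1, 2, AFF), (1, 2, AGO))
        )
        assert net.edge_weight(1, 2) == 2

    def test_cancellation_keeps_edge(self):
        net = build_network(events((0, 1, AFF), (1, 0, AGO), (0, 1, NEU)))
        assert net.n_edges == 1 and net.edge_weight(0, 1) == 0

    def test_behavior_names_accepted(self):
        net = build_network(
            events((0, 1, "affiliative"), (0, 1, "agonistic"), (0, 2, "neutral"))
        )
        assert net.edge_weight(0, 1) == 0 and net.edge_weight(0, 2) == 0

    def test_self_interaction_rejected(self):
        with pytest.raises(ValueError):
            build_network(events((3, 3, AFF)))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_weights_match_bruteforce_recount(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        ev = events(*[
            (a, b, rng.integers(0, 3))
            for a, b in zip(rng.integers(0, n, 300), rng.integers(0, n, 300))
            if a != b
        ])
        net = build_network(ev, n_agents=n)
        brute = {}
        for row in ev.itertuples(index=False):
            key = tuple(sorted((row.actor, row.partner)))
            brute[key] = brute.get(key, 0) + [-1, 0, 1][row.behavior]
        assert net.n_edges == len(brute)
        for (a, b), w in brute.items():
            assert net.edge_weight(a, b) == w


class TestPositiveSubgraph:
    def test_all_positive_unchanged(self):
        net = net_from_edges([(0, 1, 2), (1, 2, 1)])
        pos = positive_subgraph(net)
        assert pos.n_edges == 2 and list(pos.nodes) == [0, 1, 2]

    def test_all_nonpositive_empties(self):
        pos = positive_subgraph(net_from_edges([(0, 1, -2), (1, 2, 0)]))
        assert pos.n_edges == 0 and list(pos.nodes) == [0, 1, 2]

    def test_mixed_filters(self):
        pos = positive_subgraph(net_from_edges([(0, 1, 2), (1, 2, 0), (2, 3, -1)]))
        assert pos.n_edges == 1 and pos.edge_weight(0, 1) == 2


class TestModularity:
    def test_single_community_is_zero(self):
        net = net_from_edges([(0, 1, 1), (1, 2, 1), (2, 0, 1)])
        assert modularity(net, {0: 0, 1: 0, 2: 0}) == pytest.approx(0.0, abs=1e-15)

    def test_two_disconnected_edges(self):
        net = net_from_edges([(0, 1, 1), (2, 3, 1)])
        assert modularity(net, {0: 0, 1: 0, 2: 1, 3: 1}) == pytest.approx(0.5)

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError):
            modularity(net_from_edges([(0, 1, 0)]), {0: 0, 1: 0})

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        edge_list = [
            (u, v, int(rng.integers(1, 5)))
            for u, v in itertools.combinations(range(n), 2)
            if rng.random() < 0.6
        ]
        if not edge_list:
            edge_list = [(0, 1, 1)]
        membership = {v: int(rng.integers(0, 3)) for v in range(n)}
        net = net_from_edges(edge_list)
        ours = modularity(net, membership)
        ref = modularity_oracle(edge_list, membership)
        assert ours == pytest.approx(ref, abs=1e-12)


class TestLouvain:
    def k4_pair(self):
        edges = []
        for base in (0, 4):
            edges += [
                (a + base, b + base, 1)
                for a, b in itertools.combinations(range(4), 2)
            ]
        return net_from_edges(edges)

    def test_recovers_disconnected_cliques(self):
        part = louvain(self.k4_pair(), seed=1)
        groups = {}
        for v, c in part.membership.items():
            groups.setdefault(c, set()).add(v)
        assert sorted(map(sorted, groups.values())) == [[0, 1, 2, 3], [4, 5, 6, 7]]
        assert part.q == pytest.approx(0.5)
        assert part.q == pytest.approx(modularity(self.k4_pair(), part.membership))

    def test_single_clique_single_community(self):
        net = net_from_edges(
            [(a, b, 1) for a, b in itertools.combinations(range(5), 2)]
        )
        assert louvain(net).n_communities == 1

    def test_not_worse_than_singletons(self):
        rng = np.random.default_rng(8)
        edge_list = [
            (u, v, int(rng.integers(1, 4)))
            for u, v in itertools.combinations(range(10), 2)
            if rng.random() < 0.3
        ]
        net = net_from_edges(edge_list)
        part = louvain(net, seed=0)
        singletons = {int(v): i for i, v in enumerate(net.nodes)}
        assert part.q >= modularity(net, singletons) - 1e-12

    def test_negative_edges_excluded(self):
        net = net_from_edges([(0, 1, 1), (1, 2, -5), (2, 3, 1)])
        part = louvain(net)
        assert part.membership[0] == part.membership[1]
        assert part.membership[2] == part.membership[3]
        assert part.membership[1] != part.membership[2]

    def test_edgeless_gives_singletons_and_nan_q(self):
        part = louvain(net_from_edges([(0, 1, -1)]))
        assert part.n_communities == 2 and np.isnan(part.q)

    def test_deterministic_given_seed(self):
        net = self.k4_pair()
        assert louvain(net, seed=3).membership == louvain(net, seed=3).membership
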