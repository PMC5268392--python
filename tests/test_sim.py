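"""Engine unit and property tests: memory, movement, encounters, rounds."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import socsim
from socsim import (
    InteractionType,
    PairMemory,
    SimulationConfig,
    World,
    apply_behavior,
    behavior_probabilities,
    find_partner,
    random_walk_step,
    run_simulation,
    seed_stream,
)
from socsim.clustering import toroidal_distance

AGO, NEU, AFF = (
    InteractionType.AGONISTIC,
    InteractionType.NEUTRAL,
    InteractionType.AFFILIATIVE,
)


class TestBehaviorProbabilities:
    @pytest.mark.parametrize(
        "history,m,expected",
        [
            ([], 0.5, (1 / 3, 1 / 3, 1 / 3)),  # strangers: equiprobable
            ([AFF, AGO, AGO], 0.0, (1 / 3, 1 / 3, 1 / 3)),  # zero modifier
            ([AFF], 0.05, (0.31746, 0.31746, 0.36508)),  # hand-renormalized
        ],
    )
    def test_examples(self, history, m, expected):
        p = behavior_probabilities(history, m)
        assert p == pytest.approx(expected, abs=5e-6)

    @given(
        history=st.lists(st.sampled_from([AGO, NEU, AFF]), max_size=30),
        m=st.floats(0.0, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_is_distribution(self, history, m):
        p = behavior_probabilities(history, m)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p > 0) and np.all(p < 1)

    def test_remembered_type_gains_probability(self):
        base = behavior_probabilities([], 0.1)
        biased = behavior_probabilities([AFF, AFF, AFF], 0.1)
        assert biased[2] > base[2] > biased[0]


class TestPairMemory:
    def test_zero_length_stays_empty(self):
        mem = PairMemory(0)
        mem.record(1, 2, AFF)
        assert mem.history(1, 2) == ()

    def test_fifo_eviction(self):
        mem = PairMemory(2)
        for b in (AFF, AGO, NEU):
            mem.record(3, 5, b)
        assert mem.history(3, 5) == (AGO, NEU)

    def test_unordered_pair_key(self):
        mem = PairMemory(4)
        mem.record(9, 2, AFF)
        assert mem.history(2, 9) == mem.history(9, 2) == (AFF,)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            PairMemory(4).record(1, 1, AFF)

    @given(st.lists(st.sampled_from([AGO, NEU, AFF]), max_size=100))
    @settings(max_examples=100, deadline=None)
    def test_window_never_exceeds_max(self, behaviors):
        mem = PairMemory(5)
        for b in behaviors:
            mem.record(0, 1, b)
        hist = mem.history(0, 1)
        assert len(hist) <= 5
        assert hist == tuple(behaviors[-5:])


class TestRandomWalkStep:
    def test_zero_step_is_identity(self):
        assert np.allclose(random_walk_step((4.0, 5.0), 0.0, 10.0, angle=1.3), (4, 5))

    def test_wraps_across_the_seam(self):
        new = random_walk_step((78.5, 0.0), 1.0, 79.0, angle=0.0)
        assert new == pytest.approx((0.5, 0.0))

    def test_displacement_equals_step_and_is_isotropic(self):
        seed_stream(42)
        L, step = 20.0, 1.0
        start = np.array([3.0, 3.0])
        deltas = []
        for _ in range(10_000):
            new = random_walk_step(start, step, L)
            assert toroidal_distance(start, new, L) == pytest.approx(step)
            dx = (new - start + L / 2) % L - L / 2
            deltas.append(dx)
        mean = np.mean(deltas, axis=0)
        assert np.abs(mean).max() < 0.05  # ~5 sigma for 1e4 unit steps


class TestInitWorld:
    def test_empty_world(self):
        cfg = SimulationConfig(world_size=10, n_agents=0, n_rounds=3)
        res = run_simulation(cfg)
        assert res.events.empty and res.snapshots.shape[1] == 0

    def test_seeded_positions_bitwise_reproducible(self):
        cfg = SimulationConfig(world_size=79, n_agents=1000, n_rounds=0, seed=5)
        a, b = World(cfg).positions, World(cfg).positions
        assert np.array_equal(a, b)
        assert a.min() >= 0 and a.max() < 79

    def test_uniform_placement_nearest_neighbor_distance(self):
        # Poisson expectation 1/(2 sqrt(rho)) for rho = n / L^2
        cfg = SimulationConfig(world_size=79, n_agents=1000, n_rounds=0, seed=17)
        pos = World(cfg).positions
        d = np.abs(pos[:, None, :] - pos[None, :, :])
        d = np.minimum(d, 79 - d)
        dm = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(dm, np.inf)
        expected = 0.5 / np.sqrt(1000 / 79.0**2)
        assert dm.min(1).mean() == pytest.approx(expected, abs=0.08)


class TestFindPartner:
    def test_lonely_agent_has_none(self, placed_world):
        w = placed_world([(5.0, 5.0)])
        assert find_partner(w, 0) is None

    def test_mutual_within_radius(self, placed_world):
        w = placed_world([(5.0, 5.0), (5.5, 5.0)])
        assert find_partner(w, 0) == 1 and find_partner(w, 1) == 0

    def test_nearest_wins(self, placed_world):
        w = placed_world([(5.0, 5.0), (5.3, 5.0), (5.8, 5.0)])
        assert find_partner(w, 0) == 1

    def test_out_of_range_ignored(self, placed_world):
        w = placed_world([(5.0, 5.0), (8.0, 5.0)])
        assert find_partner(w, 0) is None

    def test_tie_breaks_to_smaller_id(self, placed_world):
        w = placed_world([(5.0, 5.0), (5.5, 5.0), (4.5, 5.0)])
        assert find_partner(w, 0) == 1  # ids 1 and 2 equidistant

    def test_sees_across_the_seam(self, placed_world):
        w = placed_world([(0.2, 5.0), (29.8, 5.0)])
        assert find_partner(w, 0) == 1


class TestApplyBehavior:
    def test_affiliative_step_toward(self, placed_world):
        w = placed_world([(10.0, 10.0), (12.0, 10.0)], radius=3.0)
        assert apply_behavior(w, 0, 1, AFF) == pytest.approx((11.0, 10.0))

    def test_agonistic_step_away(self, placed_world):
        w = placed_world([(10.0, 10.0), (12.0, 10.0)], radius=3.0)
        assert apply_behavior(w, 0, 1, AGO) == pytest.approx((9.0, 10.0))

    def test_affiliative_stops_at_partner(self, placed_world):
        w = placed_world([(10.0, 10.0), (10.4, 10.0)])
        assert apply_behavior(w, 0, 1, AFF) == pytest.approx((10.4, 10.0))

    def test_collinear_distance_shrinks_by_step(self, placed_world):
        w = placed_world([(10.0, 10.0), (12.5, 10.0)], radius=3.0)
        d0 = toroidal_distance(w.positions[0], w.positions[1], 30.0)
        apply_behavior(w, 0, 1, AFF)
        d1 = toroidal_distance(w.positions[0], w.positions[1], 30.0)
        assert d1 == pytest.approx(d0 - 1.0)

    def test_self_interaction_rejected(self, placed_world):
        w = placed_world([(1.0, 1.0), (2.0, 2.0)])
        with pytest.raises(ValueError):
            apply_behavior(w, 0, 0, AFF)


class TestRunRound:
    def test_single_agent_walks_without_events(self):
        cfg = SimulationConfig(world_size=10, n_agents=1, n_rounds=0, seed=3)
        w = World(cfg)
        before = w.positions.copy()
        w.run_round()
        assert w.event_log().empty
        assert toroidal_distance(before[0], w.positions[0], 10.0) == pytest.approx(1.0)

    def test_distant_agents_only_walk(self, placed_world):
        w = placed_world([(2.0, 2.0), (20.0, 20.0)])
        w.run_round()
        assert w.event_log().empty

    def test_round_conserves_agents_and_bounds(self, tiny_config):
        w = World(tiny_config)
        for _ in range(tiny_config.n_rounds):
            w.run_round()
            assert w.positions.shape == (30, 2)
            assert w.positions.min() >= 0
            assert w.positions.max() < tiny_config.world_size


class TestRunSimulation:
    def test_no_rounds_yields_initial_snapshot_only(self):
        cfg = SimulationConfig(world_size=10, n_agents=5, n_rounds=0)
        res = run_simulation(cfg)
        assert list(res.snapshot_rounds) == [0]
        assert res.events.empty

    def test_snapshot_cadence(self):
        cfg = SimulationConfig(
            world_size=15, n_agents=10, n_rounds=25, snapshot_interval=10
        )
        res = run_simulation(cfg)
        assert list(res.snapshot_rounds) == [0, 10, 20]

    def test_deterministic_given_seed(self, tiny_config):
        a, b = run_simulation(tiny_config), run_simulation(tiny_config)
        assert np.array_equal(a.snapshots, b.snapshots)
        assert a.events.equals(b.events)

    def test_recognition_off_equivalences(self):
        """IR disabled, M=0 and m=0 give identical trajectories and logs."""
        base = dict(world_size=12, n_agents=40, n_rounds=60, seed=9)
        variants = [
            SimulationConfig(**base, ir_enabled=False, memory_length=20,
                             memory_modifier=0.05),
            SimulationConfig(**base, ir_enabled=True, memory_length=0,
                             memory_modifier=0.05),
            SimulationConfig(**base, ir_enabled=True, memory_length=20,
                             memory_modifier=0.0),
        ]
        results = [run_simulation(c) for c in variants]
        for other in results[1:]:
            assert np.array_equal(results[0].snapshots, other.snapshots)
            assert results[0].events.equals(other.events)

    def test_recognition_biases_toward_repeats(self):
        """With memory, a persistent pair repeats its last behavior more than
        the 1/3 chance strangers would."""
        cfg = SimulationConfig(
            world_size=4.5, n_agents=2, n_rounds=20_000,
            memory_length=10, memory_modifier=0.1, seed=21,
            snapshot_interval=20_000,
        )
        ev = run_simulation(cfg).events
        assert len(ev) > 5_000
        b = ev["behavior"].to_numpy()
        repeat_rate = (b[1:] == b[:-1]).mean()
        assert repeat_rate > 0.35

    def test_world_memory_matches_event_log_replay(self):
        """The engine's ring-buffer memory equals a literal FIFO replay of its
        own event log, pair by pair."""
        cfg = SimulationConfig(
            world_size=8, n_agents=20, n_rounds=80,
            memory_length=5, memory_modifier=0.2, seed=13,
        )
        w = World(cfg)
        for _ in range(cfg.n_rounds):
            w.run_round()
        ev = w.event_log()
        replay = PairMemory(cfg.memory_length)
        for row in ev.itertuples(index=False):
            replay.record(row.actor, row.partner, InteractionType(row.behavior))
        assert len(replay) > 0
        for a, b in replay.pairs():
            assert w.pair_memory(a, b) == replay.history(a, b)
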