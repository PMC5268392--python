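"""The agent-based engine.

Agents live on a square torus of side L.  Each round every agent, in a fresh
seeded random order, looks for its nearest neighbor within the interaction
radius.  If one exists the pair has an encounter: one of three behaviors —
agonistic, neutral or affiliative — is drawn with probabilities biased by
the pair's shared memory of past encounters, and both members express it as
movement (away from / random relative to / toward the other; the initiator
moves first, the partner responds).  When individual recognition is enabled
the encounter is appended to the pair's bounded FIFO memory.  Agents with no
neighbor in range take a random-walk step.

With an empty memory the three behaviors are equiprobable; each remembered
interaction of a type adds ``memory_modifier`` to that type's probability
weight (weights renormalized), so established pairs tend to repeat their
past behaviors — the individual-recognition feedback at the heart of the
model.  Disabling recognition (``ir_enabled=False``), a zero-length memory
(``memory_length=0``) and a zero modifier (``memory_modifier=0``) are all
behaviorally identical.
"""
from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .config import SimulationConfig

__all__ = [
    "InteractionType",
    "PairMemory",
    "World",
    "SimulationResult",
    "init_world",
    "seed_stream",
    "behavior_probabilities",
    "random_walk_step",
    "find_partner",
    "apply_behavior",
    "record_interaction",
    "run_round",
    "run_simulation",
]


class InteractionType(enum.IntEnum):
    """The three encounter outcomes; ``weight`` is the signed network weight."""

    AGONISTIC = 0
    NEUTRAL = 1
    AFFILIATIVE = 2

    @property
    def weight(self) -> int:
        return (-1, 0, 1)[int(self)]

    @classmethod
    def from_name(cls, name: str) -> "InteractionType":
        try:
            return cls[name.upper()]
        except KeyError:
            raise ValueError(f"unknown interaction type {name!r}") from None


#: behavior code -> CSV name
BEHAVIOR_NAMES = ("agonistic", "neutral", "affiliative")


class PairMemory:
    """Bounded FIFO memory of the last ``max_length`` interactions per pair.

    Keys are unordered: ``memory(a, b)`` is ``memory(b, a)``.  With
    ``max_length == 0`` the memory stays empty (no recognition).
    """

    def __init__(self, max_length: int):
        if max_length < 0:
            raise ValueError("max_length must be >= 0")
        self.max_length = int(max_length)
        self._store: dict[tuple[int, int], deque] = {}

    @staticmethod
    def _key(a: int, b: int) -> tuple[int, int]:
        if a == b:
            raise ValueError("an agent has no memory of itself")
        return (a, b) if a < b else (b, a)

    def record(self, a: int, b: int, behavior: InteractionType) -> None:
        if self.max_length == 0:
            return
        key = self._key(a, b)
        if key not in self._store:
            self._store[key] = deque(maxlen=self.max_length)
        self._store[key].append(InteractionType(behavior))

    def history(self, a: int, b: int) -> tuple[InteractionType, ...]:
        return tuple(self._store.get(self._key(a, b), ()))

    def counts(self, a: int, b: int) -> np.ndarray:
        c = np.zeros(3, dtype=np.int64)
        for it in self.history(a, b):
            c[int(it)] += 1
        return c

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self._store)

    def __len__(self) -> int:
        return len(self._store)


def record_interaction(
    memory: PairMemory, a: int, b: int, behavior: InteractionType
) -> PairMemory:
    """Append one interaction to the pair's FIFO window (oldest evicted at M)."""
    memory.record(a, b, behavior)
    return memory


def behavior_probabilities(
    history: Iterable[InteractionType], m: float
) -> np.ndarray:
    """Probabilities (agonistic, neutral, affiliative) given a pair's history.

    Each behavior starts with weight 1/3; every remembered interaction of a
    type adds ``m`` to its weight; weights are renormalized.  An empty
    history (strangers) gives (1/3, 1/3, 1/3).
    """
    counts = np.zeros(3)
    for it in history:
        counts[int(it)] += 1
    w = 1.0 / 3.0 + m * counts
    return w / w.sum()


def seed_stream(seed: int) -> None:
    """Seed the global simulation RNG stream directly.

    Normally :class:`World` construction does this; call it yourself before
    using the drawing operations (:func:`random_walk_step` without a forced
    angle, neutral :func:`apply_behavior`) standalone.
    """
    _kernels.seed_rng(int(seed))


class World:
    """Mutable simulation state: agent positions, pair memory, event log.

    Construction seeds the global RNG stream; a sequence of ``run_round``
    calls is deterministic given the config.  Interleaving rounds of two
    worlds shares the stream and breaks per-world reproducibility.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        n = config.n_agents
        L = float(config.world_size)
        _kernels.seed_rng(int(config.seed))
        if n > 0:
            self.positions = _kernels.init_positions(n, L)
        else:
            self.positions = np.empty((0, 2), np.float64)
        self.round = 0
        M = int(config.memory_length)
        n_pairs = n * (n - 1) // 2
        self._buf = np.zeros((max(n_pairs, 1), max(M, 1)), np.uint8)
        self._blen = np.zeros(max(n_pairs, 1), np.int64)
        self._bhead = np.zeros(max(n_pairs, 1), np.int64)
        self._counts = np.zeros((max(n_pairs, 1), 3), np.int64)
        # neighbor grid: cell size >= interaction radius
        ncell = int(L // config.interaction_radius)
        self._use_grid = bool(n > 0 and ncell >= 3)
        self._ncell = ncell if self._use_grid else 1
        self._cell_size = L / self._ncell
        self._head = np.full(self._ncell * self._ncell, -1, np.int64)
        self._nxt = np.full(max(n, 1), -1, np.int64)
        self._prv = np.full(max(n, 1), -1, np.int64)
        self._cellof = np.zeros(max(n, 1), np.int64)
        if self._use_grid:
            _kernels.grid_build(
                self.positions, self._cell_size, self._ncell,
                self._head, self._nxt, self._prv, self._cellof,
            )
        self._ev_actor = np.empty(max(n, 1), np.int64)
        self._ev_partner = np.empty(max(n, 1), np.int64)
        self._ev_behavior = np.empty(max(n, 1), np.int64)
        self._events: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []

    # ------------------------------------------------------------ properties

    @property
    def n_agents(self) -> int:
        return self.config.n_agents

    @property
    def agent_ids(self) -> np.ndarray:
        return np.arange(self.config.n_agents)

    def pair_memory(self, a: int, b: int) -> tuple[InteractionType, ...]:
        """The remembered window for pair {a, b}, oldest first."""
        if a == b:
            raise ValueError("an agent has no memory of itself")
        M = int(self.config.memory_length)
        if M == 0:
            return ()
        p = _kernels.pair_index(a, b, self.config.n_agents)
        out = []
        for k in range(self._blen[p]):
            out.append(InteractionType(int(self._buf[p, (self._bhead[p] + k) % M])))
        return tuple(out)

    def set_positions(self, positions) -> None:
        """Overwrite all agent positions (replay/testing); rebuilds the grid."""
        arr = np.ascontiguousarray(positions, np.float64)
        if arr.shape != (self.config.n_agents, 2):
            raise ValueError(
                f"expected shape {(self.config.n_agents, 2)}, got {arr.shape}"
            )
        L = self.config.world_size
        if arr.size and (arr.min() < 0 or arr.max() >= L):
            raise ValueError(f"positions must lie in [0, {L})")
        self.positions[:] = arr
        if self._use_grid:
            _kernels.grid_build(
                self.positions, self._cell_size, self._ncell,
                self._head, self._nxt, self._prv, self._cellof,
            )

    # ------------------------------------------------------------ dynamics

    def run_round(self) -> "World":
        cfg = self.config
        nev = _kernels.run_round_kernel(
            self.positions,
            float(cfg.interaction_radius),
            float(cfg.step_length),
            float(cfg.world_size),
            float(cfg.memory_modifier),
            int(cfg.memory_length),
            bool(cfg.ir_enabled),
            self._buf,
            self._blen,
            self._bhead,
            self._counts,
            self._use_grid,
            self._head,
            self._nxt,
            self._prv,
            self._cellof,
            self._cell_size,
            self._ncell,
            self._ev_actor,
            self._ev_partner,
            self._ev_behavior,
        )
        if nev:
            self._events.append(
                (
                    self.round,
                    self._ev_actor[:nev].copy(),
                    self._ev_partner[:nev].copy(),
                    self._ev_behavior[:nev].copy(),
                )
            )
        self.round += 1
        return self

    def event_log(self) -> pd.DataFrame:
        """All logged interactions as a (round, actor, partner, behavior) frame."""
        if not self._events:
            return pd.DataFrame(
                {
                    "round": np.array([], np.int64),
                    "actor": np.array([], np.int64),
                    "partner": np.array([], np.int64),
                    "behavior": np.array([], np.int64),
                }
            )
        rounds = np.concatenate(
            [np.full(a.size, r, np.int64) for r, a, _, _ in self._events]
        )
        return pd.DataFrame(
            {
                "round": rounds,
                "actor": np.concatenate([a for _, a, _, _ in self._events]),
                "partner": np.concatenate([p for _, _, p, _ in self._events]),
                "behavior": np.concatenate([b for _, _, _, b in self._events]),
            }
        )


def init_world(config: SimulationConfig) -> World:
    """Seed the RNG and place ``n_agents`` uniformly at random in [0, L)^2."""
    return World(config)


def run_round(world: World) -> World:
    """Advance the world by one round (see :meth:`World.run_round`)."""
    return world.run_round()


# ------------------------------------------------------------ unit operations


def random_walk_step(
    position: Sequence[float],
    step_length: float,
    L: float,
    angle: Optional[float] = None,
) -> np.ndarray:
    """One random-walk step of fixed length in a uniform direction, wrapped.

    Pass ``angle`` to force the direction (radians, measured from +x);
    otherwise it is drawn from the seeded stream.
    """
    x, y = float(position[0]), float(position[1])
    if angle is None:
        nx, ny = _kernels.random_step(x, y, float(step_length), float(L))
    else:
        nx, ny = _kernels.step_in_direction(
            x, y, float(angle), float(step_length), float(L)
        )
    return np.array([nx, ny])


def find_partner(world: World, agent_id: int) -> Optional[int]:
    """Nearest other agent within the interaction radius, or None.

    Distance is toroidal; exact ties go to the smaller agent id.
    """
    j = _kernels.nearest_partner(
        world.positions,
        int(agent_id),
        float(world.config.interaction_radius),
        float(world.config.world_size),
        world._use_grid,
        world._head,
        world._nxt,
        world._cellof,
        world._cell_size,
        world._ncell,
    )
    return None if j < 0 else int(j)


def apply_behavior(
    world: World, actor: int, partner: int, behavior: InteractionType
) -> np.ndarray:
    """Express a behavior as movement and return the actor's new position.

    Affiliative: one step along the shortest toroidal direction toward the
    partner, stopping at the partner if closer than one step.  Agonistic:
    one step directly away (random direction if co-located).  Neutral: a
    random-walk step.
    """
    if actor == partner:
        raise ValueError("actor and partner must differ")
    L = float(world.config.world_size)
    step = float(world.config.step_length)
    ax, ay = world.positions[actor]
    px, py = world.positions[partner]
    b = InteractionType(behavior)
    if b is InteractionType.AFFILIATIVE:
        nx, ny = _kernels.move_toward(ax, ay, px, py, step, L)
    elif b is InteractionType.AGONISTIC:
        nx, ny = _kernels.move_away(ax, ay, px, py, step, L)
    else:
        nx, ny = _kernels.random_step(ax, ay, step, L)
    world.positions[actor, 0] = nx
    world.positions[actor, 1] = ny
    if world._use_grid:
        _kernels.grid_move(
            int(actor),
            _kernels.cell_index(nx, ny, world._cell_size, world._ncell),
            world._head,
            world._nxt,
            world._prv,
            world._cellof,
        )
    return np.array([nx, ny])


# ------------------------------------------------------------ full runs


@dataclass
class SimulationResult:
    """Output of :func:`run_simulation`.

    ``snapshots[k]`` holds all agent positions at round ``snapshot_rounds[k]``
    (round 0 always included).  ``events`` is the full interaction log.
    """

    config: SimulationConfig
    snapshot_rounds: np.ndarray
    snapshots: np.ndarray  # (n_snapshots, n_agents, 2)
    events: pd.DataFrame

    @property
    def final_positions(self) -> np.ndarray:
        return self.snapshots[-1]

    def trajectory_frame(self) -> pd.DataFrame:
        """Long-format (round, agent_id, x, y) table of all snapshots."""
        n = self.config.n_agents
        s = len(self.snapshot_rounds)
        return pd.DataFrame(
            {
                "round": np.repeat(self.snapshot_rounds, n),
                "agent_id": np.tile(np.arange(n), s),
                "x": self.snapshots[:, :, 0].ravel(),
                "y": self.snapshots[:, :, 1].ravel(),
            }
        )


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run ``n_rounds`` rounds from a fresh world; fully seed-deterministic."""
    world = World(config)
    rounds = [0]
    snaps = [world.positions.copy()]
    for _ in range(config.n_rounds):
        world.run_round()
        if world.round % config.snapshot_interval == 0:
            rounds.append(world.round)
            snaps.append(world.positions.copy())
    return SimulationResult(
        config=config,
        snapshot_rounds=np.asarray(rounds, np.int64),
        snapshots=np.stack(snaps) if config.n_agents > 0 else np.empty(
            (len(snaps), 0, 2)
        ),
        events=world.event_log(),
    )
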