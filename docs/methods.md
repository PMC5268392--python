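# Methods

## Model

`socsim` simulates a fixed population of `n` point agents on a square torus
of side `L` (length units are arbitrary; one unit equals one movement step
at the defaults).  The model deliberately contains **nothing but movement,
encounters and memory** — no resources, fitness, reproduction or mortality —
so that any difference between runs with and without individual recognition
(IR) is attributable to recognition alone.  It is a null model in the
ecological sense: a baseline against which externally induced grouping
(density constraints, predation pressure) can be compared.

### Round structure

Each round processes every agent once, in a fresh seeded random permutation,
updating positions in place (asynchronous updates: agents acting later in a
round see the moves of earlier actors).  On its turn an agent

1. finds its nearest neighbour within `interaction_radius` under the
   toroidal metric (ties broken toward the smaller agent id);
2. if none exists, takes one random-walk step: a fixed `step_length` in a
   uniformly random direction, wrapped torus-style;
3. otherwise the pair has an **encounter**: a behaviour is drawn from the
   pair's memory-biased distribution (below) and **both members enact it** —
   the initiator moves first, then the partner responds relative to the
   initiator's new position.
   - *affiliative*: move `step_length` along the shortest toroidal
     direction toward the other, stopping at their position if nearer than
     one step;
   - *agonistic*: move `step_length` directly away (a uniform random
     direction in the degenerate co-located case, where "away" is
     undefined);
   - *neutral*: a random-walk step.

One encounter is logged as one event `(round, initiator, partner,
behaviour)` and — when IR is enabled — appended once to the pair's memory.
An agent initiates at most one encounter per round but may additionally be
the responding partner of others.

The encounter is modelled as a mutual, pair-level outcome rather than a
one-sided act: a behavioural interaction between two animals affects both
participants, and the pair's shared memory counts *encounters*, which is
also what makes the memory window commensurable with the encounter-based
window definition used throughout.

### Memory and behaviour choice

Each unordered pair shares a FIFO window of its last `M = memory_length`
encounters.  Behaviour probabilities are an additive-weight rule: type `X`
with count `c_X` in the window has weight `1/3 + m·c_X`
(`m = memory_modifier`), and the three weights are renormalised.  Strangers
(empty window) draw uniformly.  The rule keeps a proper distribution for
every window content, reduces exactly to uniform when `m = 0` or the window
is empty, and makes repetition self-reinforcing in both directions:
friendships (affiliative runs) and feuds (agonistic runs) are both sticky.

Three parameterisations are exactly equivalent and are tested to produce
bit-identical trajectories from a shared seed: `ir_enabled=False`,
`memory_length=0`, and `memory_modifier=0`.

### Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `world_size` L | — | length | study configuration uses 79 with 1000 agents |
| `n_agents` | — | count | 1000 in the study configuration |
| `n_rounds` | — | rounds | 1000 in the study configuration |
| `memory_length` M | 20 | encounters/pair | middle of the studied 0–30 range |
| `memory_modifier` m | 0.05 | probability weight | middle of the studied 0.005–0.5 range |
| `interaction_radius` | 1.0 | length | encounters are local relative to the clustering scale (eps = 3) |
| `step_length` | 1.0 | length | one unit per round; radius = step keeps encounter and movement scales equal |
| `snapshot_interval` | 1 | rounds | cluster metrics at every round |

`interaction_radius` must be below `L/2` (otherwise "nearest within radius"
degenerates on the torus).

### Randomness

All simulation draws come from one global seeded MT19937 stream (numba's),
with a fixed draw order: initial positions (x, y per agent), then per round
one Fisher–Yates permutation followed by per-agent decisions (one behaviour
uniform per encounter; one angle per random step).  `run_simulation` is a
bit-reproducible function of its config.  Replicate seeds in experiments are
spawned from the master seed via `numpy.random.SeedSequence(master,
spawn_key=(condition, replicate))`, truncated below 2^31.

## Measurement pipeline

**Spatial groups** are DBSCAN clusters of the agent positions with
`eps = 3`, `MinPts = 4` (the standard 2-d recommendation), `MinPts`
counting the point itself, so the smallest detectable group is 4 agents.
Neighbour queries are grid-bucketed (cell size ≥ eps), making a full
1000-round × 1000-agent cluster series a ~1 s computation.  The metric is
**plain Euclidean by default** even though the world is periodic: the
reference analysis convention this package reproduces treats coordinates as
plain points (its reported initial cluster count, ≈30 for uniform random
placement at the study density, matches the Euclidean count ≈27–31 and not
the toroidal one ≈19).  `periodic=True` switches to the toroidal metric;
translation invariance on the torus is property-tested.  Border points are
adopted by the first cluster that reaches them (deterministic scan order by
agent id); as in any sequential DBSCAN this can leave a later cluster with
fewer than `MinPts` labelled members when clusters share borders.

**Group persistence** compares the member sets of consecutive snapshots.
For source cluster A and target B, the directed overlap is `|A∩B| / |A|`.
A *survives* into its best-overlapping target if that overlap strictly
exceeds `tau` (default 0.5 — majority criterion) and A is the target's
dominant contributor; it is *absorbed* if the dominant contributor is
another source; it *splits* if at least two targets each receive
`tau_split` (default 0.25) of it; otherwise it *disappears*.  Unclaimed
targets *emerge*.  A lineage extends only through survivals; its lifespan
is the number of snapshots from birth to last survival (a frozen
configuration replayed k times yields lifespan k exactly).  Both thresholds
are configurable and echoed in run metadata; internal transitions (size or
compactness change) are out of scope.

**Networks.**  Every interacting pair carries one undirected edge weighted
by the signed event sum (−1 agonistic, 0 neutral, +1 affiliative); pairs
with cancelling or purely neutral interactions keep a weight-0 edge (they
did interact).  Community structure is computed on the **positive subgraph
only** (weight > 0; weight-0 edges are excluded from the null model) with
the Louvain multilevel algorithm (python-igraph's C implementation, RNG
seeded per call for determinism), and scored by Newman's weighted
modularity, implemented directly from the double-sum formula and verified
against an exhaustive oracle.  An edgeless positive subgraph yields the
all-singletons partition with Q reported as NaN (undefined).

**Statistics.**  Conditions are compared with the Kruskal–Wallis rank test
(scipy) and Dunn's multiple-comparison z tests on pooled ranks with tie
correction and Bonferroni adjustment (implemented in
`socsim.experiment.dunn_test`; no post-hoc library is used).  Samples that
are identical across all conditions short-circuit to "no evidence of
difference" (H = 0, p = 1).

## Problem sizes

The bundled experiment driver defaults to 10 replicates per condition; the
package's own ensemble checks and `scripts/acceptance.py` run the full
spatial scale (1000 agents, 79-unit world, 1000 rounds) at that reduced
replication, which gives stable means for the spatial metrics in a few
minutes on one CPU.  The 100-replicate design of the original study is a
single config value (`replicates: 100`).

## What the simulation does and does not show

The generator *is* the study system: there is no external data.  Passing
tests demonstrate internal correctness (engine invariants, oracle-verified
clustering/modularity, seeded reproducibility) and reproduce ensemble
patterns of the modelled system — they say nothing about any real animal
population.  Real systems have heterogeneous space, varying group sizes,
birth/death, and recognition that is graded and error-prone rather than a
binary flag; none of that is modelled.

## Known limitations and open points

- With the one-sided, initiator-only encounter rule (each agent acts on its
  nearest neighbour, partner passive) the population reaches a statistical
  steady state with no IR contrast; the mutual-encounter rule described
  above is required for the coarsening/fragmentation contrast and is this
  package's model definition.
- At the default parameters the no-IR endpoint coarsens from ≈30 toward
  ≈20 clusters over 1000 rounds with transient giant clusters (>600 of
  1000 agents), and recognition holds the count near or above its initial
  value; stronger modifiers (m = 0.5) fragment further.  Full collapse to
  fewer than 10 clusters, and the IR endpoint near 50, are not reached at
  these parameter values — see the ensemble checks for the measured
  values.  The modularity contrast (higher Q with IR, increasing weakly
  with m) is an ensemble effect small relative to replicate noise.
- Exact co-location of agents (produced by the affiliative stop-at-contact
  rule) makes nearest-neighbour ties; they are broken deterministically by
  agent id.
- The event log counts one event per encounter; a round can contain up to
  `n` encounters, and an agent can appear in several as a responder.
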