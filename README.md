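# socsim

Agent-based simulation of **individual recognition (IR)** and its effect on
animal group formation and social structure, with the full measurement
pipeline used to analyse it: density-based spatial clustering (DBSCAN),
group-lifetime tracking by membership overlap, and signed interaction
networks with Louvain modularity.

## The model

`n` agents live on a square torus of side `L` with no resources, fitness or
mortality — the model isolates the effect of social memory.  Each round,
every agent (in a fresh random order) looks for its nearest neighbour within
the interaction radius:

- **no neighbour** — the agent takes one random-walk step of fixed length;
- **neighbour in range** — the pair has an *encounter*.  One of three
  behaviours is drawn — *agonistic*, *neutral* or *affiliative* — and both
  members express it as movement: away from each other, a random step, or
  toward each other (stopping at contact).

Strangers draw the three behaviours with equal probability 1/3.  When
individual recognition is enabled, each unordered pair shares a FIFO memory
of its last `M` encounters, and each remembered encounter of a type adds `m`
to that type's probability weight:

    P(X | history) = (1/3 + m·c_X) / (1 + m·(c_ago + c_neu + c_aff))

where `c_X` counts type `X` in the window.  Pairs therefore tend to repeat
their past behaviours — friendships and feuds reinforce themselves.
Disabling recognition, setting `M = 0` and setting `m = 0` are provably
identical (same seeded trajectory, event for event).

**Measurement.**  Groups are purely spatial: DBSCAN clusters (`eps = 3`,
`MinPts = 4`) of the agent positions.  Group persistence is tracked by
membership overlap between consecutive snapshots (survival / split /
absorption / disappearance / emergence), yielding lineage lifespans.  The
interaction log becomes a weighted signed network (−1 agonistic, 0 neutral,
+1 affiliative, summed per pair); community structure is computed with the
Louvain algorithm on the positive subgraph and quantified by Newman's
weighted modularity Q.

## Worked example

```python
from socsim import (SimulationConfig, run_simulation, cluster_series,
                    cluster_metrics, build_network, louvain)

cfg = SimulationConfig(world_size=79, n_agents=1000, n_rounds=1000,
                       memory_length=20, memory_modifier=0.05, seed=11)
res = run_simulation(cfg)
snaps = cluster_series(res)
print("round 0:", cluster_metrics(snaps[0]))
print("round 1000:", cluster_metrics(snaps[-1]))
net = build_network(res.events, n_agents=cfg.n_agents)
print("modularity Q =", round(louvain(net, seed=11).q, 3))
```

prints (exactly, given the seed):

```
round 0: (26, 36.03846153846154)
round 1000: (31, 30.258064516129032)
modularity Q = 0.334
```

i.e. this recognition-enabled replicate starts with 26 spatial groups of
mean size ~36, ends with 31 groups of mean size ~30, and its affiliative
network partitions into communities with modularity 0.334.  The same seed
with `ir_enabled=False` ends with 23 larger groups (mean size ~41): without
recognition the groups coarsen, with it they stay numerous and small.
Modularity fluctuates strongly between replicates, so the IR/no-IR contrast
in Q is an ensemble statement — compare condition means over replicates
with `socsim.experiment.run_experiment`, not single runs.

The same pipeline is scriptable from the shell:

```bash
socsim simulate --config config.yaml --out run/
socsim analyze --trajectory run/trajectory.csv --events run/events.csv \
               --world-size 79 --out analysis/
socsim experiment --config experiment.yaml --out exp/
```

## Layout

| module | contents |
| --- | --- |
| `socsim.sim` | the engine: world, movement, encounters, pair memory |
| `socsim.clustering` | DBSCAN (grid-bucketed, toroidal or Euclidean metric), group metrics |
| `socsim.tracking` | overlap-based transition classification, lifespans |
| `socsim.network` | signed networks, positive subgraph, modularity, Louvain |
| `socsim.experiment` | replicated condition grids, Kruskal–Wallis + Dunn |
| `socsim.io`, `socsim.cli` | CSV/GraphML/metadata writers, `socsim` command |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
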