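"""Group persistence: MONIC-style transitions between successive snapshots.

Cluster identity is defined by member agent ids, never by label values, so
label permutation across rounds is harmless.  For a source cluster A at time
t and candidate targets B at time t+1 the directed overlap is
|A ∩ B| / |A|.  A survives into its best-overlapping target when that
overlap strictly exceeds the survival threshold tau AND A is that target's
dominant contributor; a source that clears tau into a target dominated by
another source is absorbed; a source spreading at least tau_split of itself
into two or more targets (none exceeding tau) splits; anything else
disappears.
Targets claimed by no source emerge.  Lifespan of a lineage is the number
of consecutive snapshots it persists through survival links.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterSnapshot

__all__ = [
    "SURVIVED",
    "SPLIT",
    "ABSORBED",
    "DISAPPEARED",
    "EMERGED",
    "TransitionRecord",
    "overlap",
    "match_snapshots",
    "track",
    "compute_lifespans",
    "mean_lifespan",
]

SURVIVED = "survived"
SPLIT = "split"
ABSORBED = "absorbed"
DISAPPEARED = "disappeared"
EMERGED = "emerged"


@dataclass(frozen=True)
class TransitionRecord:
    """Outcome of one source cluster (or an emerged target) across one step."""

    round_from: int
    round_to: int
    source: Optional[int]  # None for emerged targets
    outcome: str
    targets: tuple[int, ...]
    overlaps: tuple[float, ...]


def overlap(a: frozenset | set, b: frozenset | set) -> float:
    """Directed membership overlap |A ∩ B| / |A|; A must be nonempty."""
    if len(a) == 0:
        raise ValueError("overlap is undefined for an empty source cluster")
    return len(a & b) / len(a)


def match_snapshots(
    s_t: ClusterSnapshot,
    s_t1: ClusterSnapshot,
    tau: float = 0.5,
    tau_split: float = 0.25,
) -> list[TransitionRecord]:
    """Classify every source cluster of ``s_t`` against ``s_t1``.

    Ties (equal overlap, equal contribution) break toward the smaller id so
    results are deterministic.
    """
    src = s_t.members
    tgt = s_t1.members
    r0, r1 = s_t.round, s_t1.round
    records: list[TransitionRecord] = []

    # dominant contributor of each target: source with the largest |A ∩ B|
    dominant: dict[int, int] = {}
    for b_id in sorted(tgt):
        best_src, best_n = None, 0
        for a_id in sorted(src):
            n = len(src[a_id] & tgt[b_id])
            if n > best_n:
                best_src, best_n = a_id, n
        if best_src is not None:
            dominant[b_id] = best_src

    claimed: set[int] = set()
    for a_id in sorted(src):
        a = src[a_id]
        ovs = {b_id: overlap(a, b) for b_id, b in tgt.items()}
        best_b = min(
            (b for b, ov in ovs.items() if ov > 0),
            key=lambda b: (-ovs[b], b),
            default=None,
        )
        if best_b is not None and ovs[best_b] > tau:
            out = SURVIVED if dominant.get(best_b) == a_id else ABSORBED
            records.append(
                TransitionRecord(r0, r1, a_id, out, (best_b,), (ovs[best_b],))
            )
            claimed.add(best_b)
            continue
        parts = sorted(b for b, ov in ovs.items() if ov >= tau_split)
        if len(parts) >= 2:
            records.append(
                TransitionRecord(
                    r0, r1, a_id, SPLIT, tuple(parts),
                    tuple(ovs[b] for b in parts),
                )
            )
            claimed.update(parts)
            continue
        records.append(TransitionRecord(r0, r1, a_id, DISAPPEARED, (), ()))

    for b_id in sorted(set(tgt) - claimed):
        records.append(TransitionRecord(r0, r1, None, EMERGED, (b_id,), ()))
    return records


def track(
    snapshots: Sequence[ClusterSnapshot],
    tau: float = 0.5,
    tau_split: float = 0.25,
) -> list[list[TransitionRecord]]:
    """Transitions for every consecutive snapshot pair of a run."""
    return [
        match_snapshots(snapshots[k], snapshots[k + 1], tau, tau_split)
        for k in range(len(snapshots) - 1)
    ]


def compute_lifespans(
    snapshots: Sequence[ClusterSnapshot],
    transitions: Optional[Sequence[Sequence[TransitionRecord]]] = None,
    tau: float = 0.5,
    tau_split: float = 0.25,
) -> pd.DataFrame:
    """Lineage table with columns lineage_id, birth, death, lifespan.

    ``birth``/``death`` are snapshot indices; a lineage extends across a step
    only through a *survived* outcome, and ``lifespan = death - birth + 1``
    (a cluster seen in a single snapshot has lifespan 1).
    """
    if len(snapshots) == 0:
        return pd.DataFrame(columns=["lineage_id", "birth", "death", "lifespan"])
    if transitions is None:
        transitions = track(snapshots, tau, tau_split)
    rows: list[tuple[int, int, int]] = []  # (birth, death) filled on close
    # active: cluster id at current snapshot -> birth snapshot index
    active = {c: 0 for c in snapshots[0].members}
    for k, recs in enumerate(transitions):
        survived_into = {
            r.source: r.targets[0] for r in recs if r.outcome == SURVIVED
        }
        nxt: dict[int, int] = {}
        for c, birth in active.items():
            if c in survived_into:
                nxt[survived_into[c]] = birth
            else:
                rows.append((birth, k))
        for c in snapshots[k + 1].members:
            if c not in nxt:
                nxt[c] = k + 1
        active = nxt
    last = len(snapshots) - 1
    for birth in active.values():
        rows.append((birth, last))
    rows.sort()
    return pd.DataFrame(
        {
            "lineage_id": np.arange(len(rows)),
            "birth": [b for b, _ in rows],
            "death": [d for _, d in rows],
            "lifespan": [d - b + 1 for b, d in rows],
        }
    )


def mean_lifespan(lifespans: pd.DataFrame) -> float:
    """Mean lifespan over lineages (0.0 when no cluster ever formed)."""
    if len(lifespans) == 0:
        return 0.0
    return float(lifespans["lifespan"].mean())
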