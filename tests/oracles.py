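"""Independent brute-force oracles used by the test suite.

Deliberately naive O(n^2)/O(n^2 k) implementations, kept free of any code
from the package's own kernels.
"""
from __future__ import annotations

import numpy as np


def torus_dist_matrix(points: np.ndarray, L: float) -> np.ndarray:
    pts = np.asarray(points, float)
    d = np.abs(pts[:, None, :] - pts[None, :, :])
    d = np.minimum(d, L - d)
    return np.sqrt((d**2).sum(-1))


def euclid_dist_matrix(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, float)
    d = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((d**2).sum(-1))


def dbscan_oracle(
    points: np.ndarray, eps: float, min_pts: int, L: float, periodic: bool
) -> np.ndarray:
    """Density-connectivity DBSCAN by exhaustive distance matrix.

    Core points have >= min_pts points within eps (self included); clusters
    are connected components of the core-core eps-graph; a border point
    joins the earliest-discovered cluster owning a core within eps
    (discovery order = order of each cluster's lowest-index core), matching
    the first-come border rule of sequential DBSCAN scans.  Noise = -1.
    """
    n = len(points)
    if n == 0:
        return np.empty(0, np.int64)
    dm = torus_dist_matrix(points, L) if periodic else euclid_dist_matrix(points)
    within = dm <= eps
    core = within.sum(1) >= min_pts
    labels = np.full(n, -1, np.int64)
    # union-find over cores
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        if not core[i]:
            continue
        for j in range(i + 1, n):
            if core[j] and within[i, j]:
                parent[find(i)] = find(j)
    comp_label: dict[int, int] = {}
    next_label = 0
    for i in range(n):  # label components in lowest-core-index order
        if core[i]:
            r = find(i)
            if r not in comp_label:
                comp_label[r] = next_label
                next_label += 1
            labels[i] = comp_label[r]
    for i in range(n):  # border points
        if core[i]:
            continue
        owning = [labels[j] for j in range(n) if core[j] and within[i, j]]
        if owning:
            labels[i] = min(owning)
    return labels


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Same grouping up to label permutation, with noise (-1) matched exactly."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping: dict[int, int] = {}
    back: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(int(x), int(y)) != y:
            return False
        if back.setdefault(int(y), int(x)) != x:
            return False
    return True


def modularity_oracle(edges, membership) -> float:
    """Newman weighted modularity by the literal double sum over node pairs.

    ``edges``: iterable of (u, v, w) undirected edges, no self loops.
    """
    nodes = sorted({u for u, _, _ in edges} | {v for _, v, _ in edges})
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, wt in edges:
        w[idx[u], idx[v]] += wt
        w[idx[v], idx[u]] += wt
    two_w = w.sum()
    k = w.sum(1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[nodes[i]] == membership[nodes[j]]:
                q += w[i, j] - k[i] * k[j] / two_w
    return q / two_w


def dunn_z_oracle(x, y):
    """Dunn z for two groups by direct rank arithmetic (no ties assumed)."""
    import scipy.stats as st

    pooled = np.concatenate([x, y])
    ranks = st.rankdata(pooled)
    n = len(pooled)
    rx = ranks[: len(x)].mean()
    ry = ranks[len(x):].mean()
    se = np.sqrt(n * (n + 1) / 12.0 * (1 / len(x) + 1 / len(y)))
    return (rx - ry) / se
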