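"""Numba kernels for the simulation engine and DBSCAN.

All randomness uses numba's global per-thread MT19937 stream, seeded via
:func:`seed_rng`.  Draw order is fixed and documented: world initialization
draws agent positions (x then y, agent 0..n-1); each round draws one
Fisher–Yates permutation, then per acting agent one behavior uniform
(encounter) and, for neutral moves / lone random walks / zero-distance
agonistic moves, one direction angle.  This makes every run bit-reproducible
from its seed.

Neighbor searches use uniform grid bucketing with cell size >= the search
radius, maintained as doubly-linked lists so the asynchronous in-place
position updates are visible to agents acting later in the same round.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# behavior codes (network weights -1, 0, +1 respectively)
AGONISTIC = 0
NEUTRAL = 1
AFFILIATIVE = 2


@njit(cache=False)
def seed_rng(seed):
    np.random.seed(seed)


@njit(inline="always")
def wrap(x, L):
    x = x % L
    if x >= L:  # guard against float rounding of tiny negatives
        x -= L
    if x < 0.0:
        x += L
    return x


@njit(inline="always")
def torus_delta(a, b, L):
    """Signed shortest displacement from a to b on a circle of length L."""
    d = b - a
    half = 0.5 * L
    if d > half:
        d -= L
    elif d < -half:
        d += L
    return d


@njit(inline="always")
def torus_dist2(ax, ay, bx, by, L):
    dx = torus_delta(ax, bx, L)
    dy = torus_delta(ay, by, L)
    return dx * dx + dy * dy


@njit(inline="always")
def pair_index(i, j, n):
    """Index of unordered pair {i, j} among the n*(n-1)/2 pairs (i < j)."""
    if i > j:
        i, j = j, i
    return i * (2 * n - i - 1) // 2 + (j - i - 1)


@njit
def init_positions(n, L):
    pos = np.empty((n, 2), np.float64)
    for i in range(n):
        pos[i, 0] = np.random.uniform(0.0, L)
        pos[i, 1] = np.random.uniform(0.0, L)
    return pos


@njit
def rand_permutation(n):
    p = np.arange(n)
    for i in range(n - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        t = p[i]
        p[i] = p[j]
        p[j] = t
    return p


# ---------------------------------------------------------------- grid


@njit(inline="always")
def cell_index(x, y, cell_size, ncell):
    cx = int(x / cell_size)
    if cx >= ncell:
        cx = ncell - 1
    cy = int(y / cell_size)
    if cy >= ncell:
        cy = ncell - 1
    return cx * ncell + cy


@njit
def grid_build(pos, cell_size, ncell, head, nxt, prv, cellof):
    for c in range(ncell * ncell):
        head[c] = -1
    for i in range(pos.shape[0]):
        c = cell_index(pos[i, 0], pos[i, 1], cell_size, ncell)
        cellof[i] = c
        prv[i] = -1
        nxt[i] = head[c]
        if head[c] >= 0:
            prv[head[c]] = i
        head[c] = i


@njit
def grid_move(i, newc, head, nxt, prv, cellof):
    oldc = cellof[i]
    if oldc == newc:
        return
    if prv[i] >= 0:
        nxt[prv[i]] = nxt[i]
    else:
        head[oldc] = nxt[i]
    if nxt[i] >= 0:
        prv[nxt[i]] = prv[i]
    nxt[i] = head[newc]
    prv[i] = -1
    if head[newc] >= 0:
        prv[head[newc]] = i
    head[newc] = i
    cellof[i] = newc


@njit
def nearest_partner(pos, i, radius, L, use_grid, head, nxt, cellof, cell_size, ncell):
    """Nearest other agent within `radius` (inclusive), ties to smaller id.

    Returns -1 when no agent is in range.
    """
    best = -1
    best_d2 = radius * radius
    if use_grid:
        cx = cellof[i] // ncell
        cy = cellof[i] % ncell
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                c = ((cx + dx) % ncell) * ncell + ((cy + dy) % ncell)
                j = head[c]
                while j >= 0:
                    if j != i:
                        d2 = torus_dist2(
                            pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1], L
                        )
                        if d2 < best_d2 or (
                            d2 == best_d2 and (best == -1 or j < best)
                        ):
                            best = j
                            best_d2 = d2
                    j = nxt[j]
    else:
        for j in range(pos.shape[0]):
            if j == i:
                continue
            d2 = torus_dist2(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1], L)
            if d2 < best_d2 or (d2 == best_d2 and (best == -1 or j < best)):
                best = j
                best_d2 = d2
    return best


# ---------------------------------------------------------------- behavior


@njit(inline="always")
def behavior_probs(c_ago, c_neu, c_aff, m):
    """Additive rule: weight 1/3 + m * (count of that type in the window)."""
    w0 = 1.0 / 3.0 + m * c_ago
    w1 = 1.0 / 3.0 + m * c_neu
    w2 = 1.0 / 3.0 + m * c_aff
    s = w0 + w1 + w2
    return w0 / s, w1 / s, w2 / s


@njit
def draw_behavior(p_ago, p_neu):
    u = np.random.random()
    if u < p_ago:
        return AGONISTIC
    elif u < p_ago + p_neu:
        return NEUTRAL
    return AFFILIATIVE


@njit
def record_pair(buf, blen, bhead, counts, p, behavior, M):
    """Append to the pair's FIFO ring buffer, evicting the oldest at M."""
    if M == 0:
        return
    if blen[p] < M:
        buf[p, (bhead[p] + blen[p]) % M] = behavior
        blen[p] += 1
    else:
        old = buf[p, bhead[p]]
        counts[p, old] -= 1
        buf[p, bhead[p]] = behavior
        bhead[p] = (bhead[p] + 1) % M
    counts[p, behavior] += 1


# ---------------------------------------------------------------- movement


@njit
def random_step(x, y, step, L):
    theta = np.random.uniform(0.0, 2.0 * np.pi)
    return wrap(x + step * np.cos(theta), L), wrap(y + step * np.sin(theta), L)


@njit
def step_in_direction(x, y, theta, step, L):
    return wrap(x + step * np.cos(theta), L), wrap(y + step * np.sin(theta), L)


@njit
def move_toward(ax, ay, px, py, step, L):
    """Move step toward (px, py) along the shortest toroidal direction,
    stopping at the partner's position when closer than one step."""
    dx = torus_delta(ax, px, L)
    dy = torus_delta(ay, py, L)
    d = np.sqrt(dx * dx + dy * dy)
    if d <= step:
        return px, py
    return wrap(ax + step * dx / d, L), wrap(ay + step * dy / d, L)


@njit
def move_away(ax, ay, px, py, step, L):
    """Move step directly away from (px, py); random direction if co-located."""
    dx = torus_delta(ax, px, L)
    dy = torus_delta(ay, py, L)
    d = np.sqrt(dx * dx + dy * dy)
    if d == 0.0:
        return random_step(ax, ay, step, L)
    return wrap(ax - step * dx / d, L), wrap(ay - step * dy / d, L)


# ---------------------------------------------------------------- round


@njit
def run_round_kernel(
    pos,
    radius,
    step,
    L,
    m,
    M,
    ir_enabled,
    buf,
    blen,
    bhead,
    counts,
    use_grid,
    head,
    nxt,
    prv,
    cellof,
    cell_size,
    ncell,
    ev_actor,
    ev_partner,
    ev_behavior,
):
    """One round: each agent, in a fresh random order, initiates at most one
    encounter with its nearest in-range neighbor, or random-walks.

    An encounter is mutual: one behavior is drawn from the pair's shared
    memory and both members enact it — the initiator moves first, then the
    partner responds relative to the initiator's new position (affiliative:
    toward; agonistic: away; neutral: a random step).  One event and, with
    recognition enabled, one memory entry are recorded per encounter.
    Positions update in place (asynchronous), so agents acting later in the
    round see earlier moves.  Returns the number of events written to the
    ev_* buffers."""
    n = pos.shape[0]
    order = rand_permutation(n)
    nev = 0
    for k in range(n):
        i = order[k]
        j = nearest_partner(
            pos, i, radius, L, use_grid, head, nxt, cellof, cell_size, ncell
        )
        if j >= 0:
            p = pair_index(i, j, n)
            p0, p1, _ = behavior_probs(counts[p, 0], counts[p, 1], counts[p, 2], m)
            b = draw_behavior(p0, p1)
            if b == AFFILIATIVE:
                x, y = move_toward(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1], step, L)
            elif b == AGONISTIC:
                x, y = move_away(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1], step, L)
            else:
                x, y = random_step(pos[i, 0], pos[i, 1], step, L)
            pos[i, 0] = x
            pos[i, 1] = y
            if use_grid:
                grid_move(i, cell_index(x, y, cell_size, ncell), head, nxt, prv, cellof)
            # partner responds with the same encounter behavior
            if b == AFFILIATIVE:
                x, y = move_toward(pos[j, 0], pos[j, 1], pos[i, 0], pos[i, 1], step, L)
            elif b == AGONISTIC:
                x, y = move_away(pos[j, 0], pos[j, 1], pos[i, 0], pos[i, 1], step, L)
            else:
                x, y = random_step(pos[j, 0], pos[j, 1], step, L)
            pos[j, 0] = x
            pos[j, 1] = y
            if use_grid:
                grid_move(j, cell_index(x, y, cell_size, ncell), head, nxt, prv, cellof)
            ev_actor[nev] = i
            ev_partner[nev] = j
            ev_behavior[nev] = b
            nev += 1
            if ir_enabled:
                record_pair(buf, blen, bhead, counts, p, b, M)
        else:
            x, y = random_step(pos[i, 0], pos[i, 1], step, L)
            pos[i, 0] = x
            pos[i, 1] = y
            if use_grid:
                grid_move(i, cell_index(x, y, cell_size, ncell), head, nxt, prv, cellof)
    return nev


# ---------------------------------------------------------------- DBSCAN


@njit(inline="always")
def _plain_dist2(ax, ay, bx, by):
    dx = bx - ax
    dy = by - ay
    return dx * dx + dy * dy


@njit
def _region_query(
    pos, i, eps2, L, periodic, use_grid, head, nxt, cellidx, cell_size, ncell, neigh
):
    cnt = 0
    if use_grid:
        cx = cellidx[i] // ncell
        cy = cellidx[i] % ncell
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                gx = cx + dx
                gy = cy + dy
                if periodic:
                    gx = gx % ncell
                    gy = gy % ncell
                elif gx < 0 or gx >= ncell or gy < 0 or gy >= ncell:
                    continue
                j = head[gx * ncell + gy]
                while j >= 0:
                    if periodic:
                        d2 = torus_dist2(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1], L)
                    else:
                        d2 = _plain_dist2(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1])
                    if d2 <= eps2:
                        neigh[cnt] = j
                        cnt += 1
                    j = nxt[j]
    else:
        for j in range(pos.shape[0]):
            if periodic:
                d2 = torus_dist2(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1], L)
            else:
                d2 = _plain_dist2(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1])
            if d2 <= eps2:
                neigh[cnt] = j
                cnt += 1
    return cnt


@njit
def dbscan_kernel(pos, eps, min_pts, L, periodic):
    """DBSCAN with grid-bucketed neighbor queries.

    Core points have >= min_pts points (self included) within eps; clusters
    are density-connected components of cores plus border points, which join
    the first core cluster that reaches them (scan order by point index).
    Labels: 0..k-1 in discovery order, noise = -1.
    """
    n = pos.shape[0]
    labels = np.full(n, -2, np.int64)
    use_grid = False
    ncell = 1
    cell_size = L
    nc = int(L // eps)
    # periodic wrap needs >= 3 distinct cells per axis; plain mode just >= 2
    if (periodic and nc >= 3) or (not periodic and nc >= 2):
        use_grid = True
        ncell = nc
        cell_size = L / nc
    head = np.full(ncell * ncell, -1, np.int64)
    nxt = np.full(n, -1, np.int64)
    cellidx = np.zeros(n, np.int64)
    if use_grid:
        for i in range(n):
            c = cell_index(pos[i, 0], pos[i, 1], cell_size, ncell)
            cellidx[i] = c
            nxt[i] = head[c]
            head[c] = i
    neigh = np.empty(n, np.int64)
    queue = np.empty(n, np.int64)
    eps2 = eps * eps
    cluster = 0
    for i in range(n):
        if labels[i] != -2:
            continue
        cnt = _region_query(
            pos, i, eps2, L, periodic, use_grid, head, nxt, cellidx, cell_size, ncell, neigh
        )
        if cnt < min_pts:
            labels[i] = -1
            continue
        labels[i] = cluster
        qh = 0
        qt = 0
        for t in range(cnt):
            j = neigh[t]
            if labels[j] == -2:
                labels[j] = cluster
                queue[qt] = j
                qt += 1
            elif labels[j] == -1:
                labels[j] = cluster
        while qh < qt:
            j = queue[qh]
            qh += 1
            cntj = _region_query(
                pos, j, eps2, L, periodic, use_grid, head, nxt, cellidx, cell_size,
                ncell, neigh,
            )
            if cntj >= min_pts:
                for t in range(cntj):
                    k = neigh[t]
                    if labels[k] == -2:
                        labels[k] = cluster
                        queue[qt] = k
                        qt += 1
                    elif labels[k] == -1:
                        labels[k] = cluster
        cluster += 1
    return labels
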