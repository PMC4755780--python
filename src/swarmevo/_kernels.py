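"""Numba kernels for the per-step hot loop.

These are performance twins of the pure-numpy reference implementations in
:mod:`swarmevo.dynamics`; the test suite checks them against brute force on
seeded configurations.  All distances use the minimum-image convention on a
square torus of edge ``L``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

EPS_SPEED = 1e-8  # below this the heading v/|v| is treated as undefined
EPS_COINCIDENT = 1e-12  # coincident agents exert no social force on each other


@njit(cache=True, inline="always")
def _mi(d: float, L: float) -> float:
    # minimum image for |d| < 1.5 L
    if d > 0.5 * L:
        return d - L
    if d < -0.5 * L:
        return d + L
    return d


@njit(cache=True, inline="always")
def _consider(hd, hj, c, k, d2, j):
    """Offer candidate (d2, j) to an agent's k-best list, kept sorted
    ascending by (distance^2, index); returns the new count.

    The lexicographic order makes the selection canonical (independent of
    the order candidates are scanned in), which is what guarantees the
    cell-list path returns exactly the brute-force result."""
    if c >= k:
        if d2 > hd[k - 1] or (d2 == hd[k - 1] and j > hj[k - 1]):
            return c
        c = k - 1
    p = c
    while p > 0 and (hd[p - 1] > d2 or (hd[p - 1] == d2 and hj[p - 1] > j)):
        hd[p] = hd[p - 1]
        hj[p] = hj[p - 1]
        p -= 1
    hd[p] = d2
    hj[p] = j
    return c + 1


@njit(cache=True)
def knn_neighbors(pos, L, lmax, k):
    """k nearest neighbours within per-agent radius ``lmax``.

    Returns (nbr, counts): ``nbr[i, :counts[i]]`` holds neighbour indices of
    agent ``i`` sorted by distance ascending, ties broken by index ascending.
    Uses a cell list when the domain is wide enough relative to the largest
    interaction range; the result is scan-order independent (canonical
    (distance, index) selection), hence identical to brute force.
    """
    n = pos.shape[0]
    nbr = np.full((n, k), -1, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    if n == 0 or k == 0:
        return nbr, counts
    hd = np.empty(k, dtype=np.float64)
    hj = np.empty(k, dtype=np.int64)
    rc = 0.0
    for i in range(n):
        if lmax[i] > rc:
            rc = lmax[i]
    ncell = int(L / rc) if rc > 0 else 0

    if ncell >= 3:
        # --- cell-list path (cell edge >= rc, so 3x3 neighbourhood suffices)
        cell_edge = L / ncell
        ncells = ncell * ncell
        cell_of = np.empty(n, dtype=np.int64)
        ccount = np.zeros(ncells + 1, dtype=np.int64)
        for i in range(n):
            cx = int(pos[i, 0] / cell_edge)
            cy = int(pos[i, 1] / cell_edge)
            if cx >= ncell:
                cx = ncell - 1
            if cy >= ncell:
                cy = ncell - 1
            cid = cx * ncell + cy
            cell_of[i] = cid
            ccount[cid + 1] += 1
        for c in range(ncells):
            ccount[c + 1] += ccount[c]
        order = np.empty(n, dtype=np.int64)
        fill = ccount[:-1].copy()
        for i in range(n):
            cid = cell_of[i]
            order[fill[cid]] = i
            fill[cid] += 1
        for i in range(n):
            xi = pos[i, 0]
            yi = pos[i, 1]
            r2max = lmax[i] * lmax[i]
            cx = cell_of[i] // ncell
            cy = cell_of[i] % ncell
            c = 0
            for ox in range(-1, 2):
                gx = (cx + ox) % ncell
                for oy in range(-1, 2):
                    gy = (cy + oy) % ncell
                    cid = gx * ncell + gy
                    for q in range(ccount[cid], ccount[cid + 1]):
                        j = order[q]
                        if j == i:
                            continue
                        dx = _mi(xi - pos[j, 0], L)
                        dy = _mi(yi - pos[j, 1], L)
                        d2 = dx * dx + dy * dy
                        if d2 <= r2max:
                            c = _consider(hd, hj, c, k, d2, j)
            counts[i] = c
            _heap_to_sorted(hd, hj, c, nbr, i)
    else:
        # --- all-pairs path
        for i in range(n):
            xi = pos[i, 0]
            yi = pos[i, 1]
            r2max = lmax[i] * lmax[i]
            c = 0
            for j in range(n):
                if j == i:
                    continue
                dx = _mi(xi - pos[j, 0], L)
                dy = _mi(yi - pos[j, 1], L)
                d2 = dx * dx + dy * dy
                if d2 <= r2max:
                    c = _consider(hd, hj, c, k, d2, j)
            counts[i] = c
            _heap_to_sorted(hd, hj, c, nbr, i)
    return nbr, counts


@njit(cache=True, inline="always")
def _heap_to_sorted(hd, hj, c, nbr, i):
    # the k-best list is already sorted ascending by (d2, j)
    for q in range(c):
        nbr[i, q] = hj[q]


@njit(cache=True)
def social_forces(pos, nbr, counts, Cr, Ca, lr, la, L):
    """Pairwise attraction-repulsion force on every agent.

    Force from neighbour j on focal i is
    ``[(Cr/lr) e^{-d/lr} - (Ca/la) e^{-d/la}] * rhat`` with ``rhat`` pointing
    from j toward i (positive coefficient = repulsion).
    """
    n = pos.shape[0]
    out = np.zeros((n, 2), dtype=np.float64)
    for i in range(n):
        fx = 0.0
        fy = 0.0
        for q in range(counts[i]):
            j = nbr[i, q]
            dx = _mi(pos[i, 0] - pos[j, 0], L)
            dy = _mi(pos[i, 1] - pos[j, 1], L)
            d = math.sqrt(dx * dx + dy * dy)
            if d < EPS_COINCIDENT:
                continue
            coeff = (Cr / lr) * math.exp(-d / lr) - (Ca / la) * math.exp(-d / la)
            fx += coeff * dx / d
            fy += coeff * dy / d
        out[i, 0] = fx
        out[i, 1] = fy
    return out


@njit(cache=True)
def integrate(pos, vel, psi, fs, m, eta, tau, n_sub, gamma, headings, L):
    """Advance one time step in place with frozen social force and psi.

    Semi-implicit Euler with ``n_sub`` sub-steps: the velocity is updated
    first (the self-propulsion term is re-evaluated at the current velocity),
    then the position.  The self-propulsion term changes the speed along the
    current heading and is clamped so deceleration stops at v = 0 within a
    sub-step instead of reversing the heading: in the continuous dynamics the
    speed reaches zero in finite time for Psi < 0 and v = 0 is absorbing (the
    force acts along +-v/|v| and vanishes there), so overshooting through
    zero would be an integration artifact.  A noise kick of exact magnitude
    ``gamma`` and heading ``headings[i]`` is added to each velocity at the
    end of the step, and positions are wrapped onto the torus.
    """
    n = pos.shape[0]
    dt = tau / n_sub
    for i in range(n):
        x = pos[i, 0]
        y = pos[i, 1]
        vx = vel[i, 0]
        vy = vel[i, 1]
        fsx = fs[i, 0]
        fsy = fs[i, 1]
        p = psi[i]
        for _ in range(n_sub):
            speed = math.sqrt(vx * vx + vy * vy)
            if speed >= EPS_SPEED:
                s_new = speed + dt * (p - eta * speed * speed) / m
                if s_new < 0.0:
                    s_new = 0.0
                scale = s_new / speed
                vx *= scale
                vy *= scale
            vx += dt * fsx / m
            vy += dt * fsy / m
            x += dt * vx
            y += dt * vy
        if gamma > 0.0:
            vx += gamma * math.cos(headings[i])
            vy += gamma * math.sin(headings[i])
        pos[i, 0] = x % L
        pos[i, 1] = y % L
        vel[i, 0] = vx
        vel[i, 1] = vy


@njit(cache=True)
def advance(pos, vel, psi, lmax, Cr, Ca, lr, la, k, m, eta, tau, n_sub, gamma, headings, L):
    """Full synchronous step: neighbours and forces from the pre-step state,
    then integration of every agent."""
    nbr, counts = knn_neighbors(pos, L, lmax, k)
    fs = social_forces(pos, nbr, counts, Cr, Ca, lr, la, L)
    integrate(pos, vel, psi, fs, m, eta, tau, n_sub, gamma, headings, L)
    return fs


@njit(cache=True)
def group_labels(nbr, counts):
    """Connected components of the social interaction graph.

    Edge {i, j} exists if either agent counts the other among its
    neighbours.  Returns a label array (labels are component roots).
    """
    n = nbr.shape[0]
    parent = np.arange(n)
    for i in range(n):
        for q in range(counts[i]):
            j = nbr[i, q]
            # union(i, j) with path halving
            ri = i
            while parent[ri] != ri:
                parent[ri] = parent[parent[ri]]
                ri = parent[ri]
            rj = j
            while parent[rj] != rj:
                parent[rj] = parent[parent[rj]]
                rj = parent[rj]
            if ri < rj:
                parent[rj] = ri
            else:
                parent[ri] = rj
    labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        r = i
        while parent[r] != r:
            r = parent[r]
        labels[i] = r
    return labels


@njit(cache=True)
def mean_knn_distance(pos, L, n_neighbors):
    """Mean distance to the ``n_neighbors`` nearest others, averaged over all
    agents (no interaction-range cutoff)."""
    n = pos.shape[0]
    total = 0.0
    best = np.empty(n_neighbors, dtype=np.float64)
    for i in range(n):
        c = 0
        for j in range(n):
            if j == i:
                continue
            dx = _mi(pos[i, 0] - pos[j, 0], L)
            dy = _mi(pos[i, 1] - pos[j, 1], L)
            d2 = dx * dx + dy * dy
            if c < n_neighbors:
                p = c
                while p > 0 and best[p - 1] > d2:
                    best[p] = best[p - 1]
                    p -= 1
                best[p] = d2
                c += 1
            elif d2 < best[n_neighbors - 1]:
                p = n_neighbors - 1
                while p > 0 and best[p - 1] > d2:
                    best[p] = best[p - 1]
                    p -= 1
                best[p] = d2
        acc = 0.0
        for q in range(n_neighbors):
            acc += math.sqrt(best[q])
        total += acc / n_neighbors
    return total / n
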