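"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the collision
oracle advances a body along its ray in 1 mm steps, the clustering oracle
is a plain union-find over pairwise follow checks, and the product-limit
oracle is a hand computation.
"""

from __future__ import annotations

import numpy as np


def stepping_collision_distance(positions, velocities, v0, radii, i, alpha,
                                r_inner, r_outer, d_max, step=0.001):
    """Advance pedestrian ``i`` along ``alpha`` in 1 mm increments until its
    body touches a wall or a (linearly extrapolated) neighbour."""
    e = np.array([np.cos(alpha), np.sin(alpha)])
    n_steps = int(d_max / step)
    s = np.arange(n_steps + 1) * step                 # travel distances
    t = s / v0[i]
    xi = positions[i] + s[:, None] * e                # (S, 2)
    r = np.linalg.norm(xi, axis=1)
    hit = (r > r_outer - radii[i]) | (r < r_inner + radii[i])
    for j in range(len(positions)):
        if j == i:
            continue
        xj = positions[j] + t[:, None] * velocities[j]
        hit |= np.linalg.norm(xj - xi, axis=1) <= radii[i] + radii[j]
    hits = np.flatnonzero(hit)
    return float(s[hits[0]]) if hits.size else float(d_max)


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def unionfind_clusters(traj, t, delta, window, same_direction_only=True):
    """Connected components of the follow relation via explicit union-find."""
    fi = int(np.argmin(np.abs(traj.times - t)))
    w = int(round(window / traj.dt))
    assert fi + w < traj.n_frames
    ids = traj.ids
    uf = UnionFind(ids.tolist())
    for a in range(len(ids)):
        for b in range(len(ids)):
            if a == b:
                continue
            if same_direction_only and traj.directions[a] != traj.directions[b]:
                continue
            seg = traj.positions[fi:fi + w + 1, a]     # a's forward trajectory
            ref = traj.positions[fi, b]                # b's position now
            if np.linalg.norm(seg - ref, axis=1).min() < delta:
                uf.union(int(ids[a]), int(ids[b]))
    groups = {}
    for x in ids.tolist():
        groups.setdefault(uf.find(int(x)), set()).add(int(x))
    return {frozenset(g) for g in groups.values()}


def product_limit(durations, events):
    """Hand-rolled Kaplan-Meier: returns (times, survival) at event times."""
    order = np.argsort(durations)
    durations = np.asarray(durations, float)[order]
    events = np.asarray(events, int)[order]
    times, surv = [], []
    s = 1.0
    uniq = np.unique(durations[events == 1])
    for t in uniq:
        at_risk = np.sum(durations >= t)
        d = np.sum((durations == t) & (events == 1))
        s *= 1.0 - d / at_risk
        times.append(t)
        surv.append(s)
    return np.array(times), np.array(surv)


def euler_relaxation_speed(v0, tau, dt, t):
    """Discrete symplectic-Euler solution of dv/dt = (v0 - v)/tau from rest."""
    n = int(round(t / dt))
    return v0 * (1.0 - (1.0 - dt / tau) ** n)
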