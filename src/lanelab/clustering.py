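"""Follow-relation clustering of trajectories into lanes.

Pedestrian ``j`` follows pedestrian ``i`` at time ``t`` when j's trajectory
over the look-ahead window ``[t, t + window]`` passes within ``delta`` of
i's position at time ``t`` (defaults delta = 0.6 m, window = 1 s).
Clusters are the connected components of the symmetrised follow relation;
by default edges are restricted to pedestrians sharing a circulation
direction, so a lane is a group walking the same way.  A cluster's identity
is its exact membership set: any change of composition is the death of the
old cluster and the birth of new ones, which yields the lifetime
distribution analysed by :mod:`lanelab.relaxation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .trajectory import TrajectorySet

__all__ = [
    "ClusteringParams",
    "ClusterTimeline",
    "SurvivalCurve",
    "is_following",
    "clusters_at",
    "cluster_count_series",
    "classify_phase",
    "track_lifetimes",
    "survival_curve",
    "sensitivity_scan",
]


@dataclass(frozen=True)
class ClusteringParams:
    """Clustering thresholds: follow distance delta (m), look-ahead window
    (s), cluster evaluation rate (Hz), and whether follow edges are
    restricted to same-direction pairs (the default; see module docs)."""

    delta: float = 0.6
    window: float = 1.0
    eval_rate: float = 10.0
    same_direction_only: bool = True

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.window <= 0 or self.eval_rate <= 0:
            raise ValueError("delta, window and eval_rate must be positive")


@dataclass
class ClusterTimeline:
    """Per-evaluation-time partitions plus cluster birth/death bookkeeping.

    ``lifetimes`` are completed cluster lifetimes (death minus birth, s);
    ``censored`` the ages of clusters still alive at the last evaluation.
    """

    eval_times: np.ndarray
    partitions: list
    lifetimes: np.ndarray
    censored: np.ndarray


@dataclass
class SurvivalCurve:
    """Sampled Kaplan-Meier survival p(t) with at-risk counts."""

    times: np.ndarray
    probabilities: np.ndarray
    at_risk: np.ndarray


class OutOfWindowError(ValueError):
    """Query time too close to the recording end for the look-ahead window."""


def _window_frames(traj: TrajectorySet, t: float, params: ClusteringParams):
    i0 = traj.frame_index(t)
    n_ahead = int(round(params.window / traj.dt))
    if i0 + n_ahead >= traj.n_frames:
        raise OutOfWindowError(
            f"t={t}: needs {params.window}s of forward trajectory beyond the recording"
        )
    return i0, i0 + n_ahead


def _min_dist_matrix(traj: TrajectorySet, i0: int, i1: int) -> np.ndarray:
    """M[j, i] = min over frames s in [i0, i1] of |x_j(s) - x_i(t0)|."""
    ref = traj.positions[i0]                       # (N, 2)
    seg = traj.positions[i0:i1 + 1]                # (W, N, 2)
    d = np.linalg.norm(seg[:, :, None, :] - ref[None, None, :, :], axis=-1)
    return d.min(axis=0)


def is_following(traj: TrajectorySet, j, i, t: float,
                 params: ClusteringParams = ClusteringParams()) -> bool:
    """True iff pedestrian ``j`` follows ``i`` at time ``t``."""
    if i == j:
        raise ValueError("self-following is undefined")
    i0, i1 = _window_frames(traj, t, params)
    ji = int(np.flatnonzero(traj.ids == j)[0])
    ii = int(np.flatnonzero(traj.ids == i)[0])
    seg = traj.positions[i0:i1 + 1, ji]
    ref = traj.positions[i0, ii]
    return bool(np.linalg.norm(seg - ref, axis=-1).min() < params.delta)


def _adjacency(traj: TrajectorySet, i0: int, i1: int,
               params: ClusteringParams) -> np.ndarray:
    m = _min_dist_matrix(traj, i0, i1) < params.delta
    adj = m | m.T
    np.fill_diagonal(adj, False)
    if params.same_direction_only:
        same = traj.directions[:, None] == traj.directions[None, :]
        adj &= same
    return adj


def clusters_at(traj: TrajectorySet, t: float,
                params: ClusteringParams = ClusteringParams()) -> list[frozenset]:
    """Partition of pedestrian ids into clusters at time ``t``.

    Singletons are clusters of one; the result is always a partition of the
    full roster.
    """
    i0, i1 = _window_frames(traj, t, params)
    adj = _adjacency(traj, i0, i1, params)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    return [frozenset(traj.ids[labels == c].tolist()) for c in range(n_comp)]


def _eval_frame_indices(traj: TrajectorySet, params: ClusteringParams):
    stride = max(1, int(round((1.0 / params.eval_rate) / traj.dt)))
    n_ahead = int(round(params.window / traj.dt))
    return np.arange(0, traj.n_frames - n_ahead, stride), n_ahead


def cluster_count_series(traj: TrajectorySet,
                         params: ClusteringParams = ClusteringParams()):
    """(eval_times, counts) of clusters over all admissible times."""
    frames, n_ahead = _eval_frame_indices(traj, params)
    if frames.size == 0:
        raise OutOfWindowError("recording shorter than the look-ahead window")
    counts = np.empty(frames.size, dtype=int)
    for k, fi in enumerate(frames):
        adj = _adjacency(traj, fi, fi + n_ahead, params)
        counts[k] = connected_components(csr_matrix(adj), directed=False)[0]
    return traj.times[frames], counts


def classify_phase(count: int) -> str:
    """Order (<= 5 clusters), disorder (>= 10) or intermediate."""
    if count < 1:
        raise ValueError("cluster count must be >= 1")
    if count <= 5:
        return "order"
    if count >= 10:
        return "disorder"
    return "intermediate"


def track_lifetimes(traj: TrajectorySet,
                    params: ClusteringParams = ClusteringParams()) -> ClusterTimeline:
    """Cluster birth/death tracking over the whole recording.

    A membership set is born at the first evaluation where it appears and
    dies at the first evaluation where it is no longer a cluster of the
    partition; sets alive at the last evaluation are right-censored at
    their current age.
    """
    frames, n_ahead = _eval_frame_indices(traj, params)
    if frames.size == 0:
        raise OutOfWindowError("recording shorter than the look-ahead window")
    eval_times = traj.times[frames]
    partitions = []
    alive: dict[frozenset, float] = {}
    lifetimes, censored = [], []
    for k, fi in enumerate(frames):
        adj = _adjacency(traj, fi, fi + n_ahead, params)
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        part = [frozenset(traj.ids[labels == c].tolist()) for c in range(n_comp)]
        partitions.append(part)
        t = eval_times[k]
        current = set(part)
        for members in list(alive):
            if members not in current:
                lifetimes.append(t - alive.pop(members))
        for members in current:
            if members not in alive:
                alive[members] = t
    t_end = eval_times[-1]
    censored = [t_end - birth for birth in alive.values()]
    return ClusterTimeline(eval_times=eval_times, partitions=partitions,
                           lifetimes=np.sort(np.asarray(lifetimes)),
                           censored=np.sort(np.asarray(censored)))


def survival_curve(timeline: ClusterTimeline) -> SurvivalCurve:
    """Kaplan-Meier estimator of cluster survival p(t).

    Censored clusters contribute to the risk sets without forcing a death,
    which avoids the downward lifetime bias of discarding them on short
    recordings.
    """
    from lifelines import KaplanMeierFitter

    durations = np.concatenate([timeline.lifetimes, timeline.censored])
    if durations.size == 0:
        raise ValueError("no clusters observed")
    events = np.concatenate([np.ones_like(timeline.lifetimes),
                             np.zeros_like(timeline.censored)])
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    times = np.asarray(sf.index, dtype=float)
    probs = sf.iloc[:, 0].to_numpy()
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return SurvivalCurve(times=times, probabilities=probs, at_risk=at_risk)


def sensitivity_scan(traj: TrajectorySet, delta_grid, window_grid,
                     eval_rate: float = 10.0,
                     same_direction_only: bool = True) -> pd.DataFrame:
    """Time-averaged cluster count for every (delta, window) pair.

    Returns a DataFrame indexed by delta with window columns, supporting
    the robustness check that the clustering outcome is flat over a
    reasonable parameter region.
    """
    out = np.empty((len(delta_grid), len(window_grid)))
    for a, delta in enumerate(delta_grid):
        for b, window in enumerate(window_grid):
            params = ClusteringParams(delta=float(delta), window=float(window),
                                      eval_rate=eval_rate,
                                      same_direction_only=same_direction_only)
            _, counts = cluster_count_series(traj, params)
            out[a, b] = counts.mean()
    return pd.DataFrame(out, index=np.asarray(delta_grid, dtype=float),
                        columns=np.asarray(window_grid, dtype=float))
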