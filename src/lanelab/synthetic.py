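"""Synthetic trajectory generators.

The experimental recordings behind this analysis pipeline were never
deposited, so every analysis stage is exercised against constructed inputs
with known ground truth: perfectly circular lane fixtures for the
clustering, a switching fixture with exactly known cluster lifetimes, a
disordered random-walk end-member, and the truncated-Gaussian comfortable
walking-speed sampler used by the simulator (mean 1.2 m/s, standard
deviation 0 to 0.3 m/s, floored at 0.3 m/s).

Fixtures are intentionally idealised — realism is the simulator's job; the
fixtures exist so that analysis answers are provable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CorridorGeometry, from_polar
from .trajectory import TrajectorySet

__all__ = [
    "SpeedDistribution",
    "FixtureSpec",
    "sample_comfortable_speeds",
    "make_lane_fixture",
    "make_disordered_fixture",
    "make_switching_fixture",
    "add_tracking_noise",
]


@dataclass(frozen=True)
class SpeedDistribution:
    """Truncated Gaussian of comfortable walking speeds (m/s)."""

    mu: float = 1.2
    sigma: float = 0.16
    floor: float = 0.3

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (self.mu > self.floor >= 0):
            raise ValueError("require mu > floor >= 0")


def sample_comfortable_speeds(n: int, dist: SpeedDistribution = SpeedDistribution(),
                              seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. comfortable speeds, resampling draws below the floor.

    ``seed`` may be an int, a Generator, or None.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if dist.sigma == 0.0:
        return np.full(n, dist.mu)
    out = rng.normal(dist.mu, dist.sigma, size=n)
    bad = out < dist.floor
    while np.any(bad):
        out[bad] = rng.normal(dist.mu, dist.sigma, size=int(bad.sum()))
        bad = out < dist.floor
    return out


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry of a concentric-lane fixture.

    Lanes are perfect circles; lane ``l`` carries ``peds_per_lane``
    pedestrians in single file with an arc spacing of ``gap_along_lane``
    metres, all moving at constant angular speed, with circulation signs
    alternating by lane (+1, -1, +1, ...).
    """

    n_lanes: int = 2
    peds_per_lane: int = 5
    lane_radii: tuple = (2.75, 3.75)
    gap_along_lane: float = 0.8
    speed: float = 1.2
    duration: float = 30.0
    sample_rate: float = 10.0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lane_radii) != self.n_lanes:
            raise ValueError("one radius per lane required")
        if self.gap_along_lane <= 0:
            raise ValueError("gap_along_lane must be positive")


def make_lane_fixture(spec: FixtureSpec,
                      geometry: CorridorGeometry = CorridorGeometry()) -> TrajectorySet:
    """Concentric single-file lanes at constant angular speed."""
    body_margin = 0.25
    for r in spec.lane_radii:
        if not (geometry.r_inner + body_margin < r < geometry.r_outer - body_margin):
            raise ValueError(f"lane radius {r} outside the corridor")
        arc_needed = spec.peds_per_lane * spec.gap_along_lane
        if arc_needed > 2 * np.pi * r:
            raise ValueError("lane over-full: pedestrians would wrap onto each other")
    times = np.arange(0.0, spec.duration + 0.5 / spec.sample_rate, 1.0 / spec.sample_rate)
    n = spec.n_lanes * spec.peds_per_lane
    positions = np.empty((times.size, n, 2))
    directions = np.empty(n, dtype=int)
    ped = 0
    for lane, r in enumerate(spec.lane_radii):
        sign = 1 if lane % 2 == 0 else -1
        omega = sign * spec.speed / r
        dtheta = spec.gap_along_lane / r
        for k in range(spec.peds_per_lane):
            theta = -sign * k * dtheta + omega * times
            positions[:, ped, :] = from_polar(np.full_like(times, r), theta)
            directions[ped] = sign
            ped += 1
    traj = TrajectorySet(times=times, positions=positions, directions=directions,
                         geometry=geometry, v0=np.full(n, spec.speed))
    if spec.jitter > 0:
        traj = add_tracking_noise(traj, spec.jitter, seed=spec.seed)
    return traj


def make_disordered_fixture(n: int, duration: float, seed: int,
                            geometry: CorridorGeometry = CorridorGeometry(),
                            sample_rate: float = 10.0,
                            step_std: float = 0.12) -> TrajectorySet:
    """Independent random walks with reflecting walls: the disorder end-member.

    Headings are uncorrelated frame to frame, so no pedestrian coherently
    follows another; circulation labels alternate but carry no kinematic
    meaning here.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + 0.5 / sample_rate, 1.0 / sample_rate)
    margin = 0.2
    start = _rejection_place(n, 2 * margin, geometry, rng)
    positions = np.empty((times.size, n, 2))
    positions[0] = start
    lo, hi = geometry.r_inner + margin, geometry.r_outer - margin
    for f in range(1, times.size):
        nxt = positions[f - 1] + rng.normal(0.0, step_std, size=(n, 2))
        r = np.linalg.norm(nxt, axis=-1)
        # radial reflection off both walls
        r_ref = np.clip(r, lo, hi) - (r - np.clip(r, lo, hi))
        r_ref = np.clip(r_ref, lo, hi)
        nxt *= (r_ref / r)[:, None]
        positions[f] = nxt
    directions = np.where(np.arange(n) % 2 == 0, 1, -1)
    return TrajectorySet(times=times, positions=positions, directions=directions,
                         geometry=geometry)


def make_switching_fixture(partition_a, partition_b, period: float, duration: float,
                           geometry: CorridorGeometry = CorridorGeometry(),
                           sample_rate: float = 10.0) -> TrajectorySet:
    """Trajectory alternating between two static configurations.

    Each partition (an iterable of iterables of pedestrian ids over the same
    id set) is realised as tight single-file groups (0.3 m spacing, within
    any follow threshold >= 0.35 m) on its own circle, groups separated by
    wide arcs; the two configurations sit on circles 1.0 m apart so no
    cross-configuration pair ever comes within a typical follow threshold.
    The exact cluster partition therefore equals ``partition_a`` during even
    phases and ``partition_b`` during odd phases, and every completed
    cluster lifetime equals ``period``.
    """
    parts_a = [tuple(sorted(g)) for g in partition_a]
    parts_b = [tuple(sorted(g)) for g in partition_b]
    ids_a = sorted(i for g in parts_a for i in g)
    ids_b = sorted(i for g in parts_b for i in g)
    if ids_a != ids_b or len(set(ids_a)) != len(ids_a):
        raise ValueError("partitions must partition the same id set")
    ids = ids_a
    dt = 1.0 / sample_rate
    if abs(period / dt - round(period / dt)) > 1e-9:
        raise ValueError("period must be a multiple of the sampling step")

    def layout(parts, radius):
        spacing, group_gap = 0.3, 2.0
        arc = sum((len(g) - 1) * spacing for g in parts) + len(parts) * group_gap
        if arc > 2 * np.pi * radius:
            raise ValueError("partition not realizable on one circle")
        pos = {}
        theta = 0.0
        for g in parts:
            for member in g:
                pos[member] = from_polar(radius, theta)
                theta += spacing / radius
            theta += (group_gap - spacing) / radius
        return pos

    r_a = geometry.mid_radius() - 0.5
    r_b = geometry.mid_radius() + 0.5
    pos_a = layout(parts_a, r_a)
    pos_b = layout(parts_b, r_b)

    times = np.arange(0.0, duration + 0.5 * dt, dt)
    n = len(ids)
    positions = np.empty((times.size, n, 2))
    for f, t in enumerate(times):
        phase = int(t / period + 1e-9) % 2
        cfg = pos_a if phase == 0 else pos_b
        for col, i in enumerate(ids):
            positions[f, col] = cfg[i]
    return TrajectorySet(times=times, positions=positions,
                         directions=np.ones(n, dtype=int), geometry=geometry,
                         ids=np.array(ids))


def add_tracking_noise(traj: TrajectorySet, amplitude: float, seed=None) -> TrajectorySet:
    """Add i.i.d. zero-mean Gaussian position jitter (tracking error)."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    out = traj.copy()
    if amplitude > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        out.positions = out.positions + rng.normal(0.0, amplitude, size=out.positions.shape)
    return out


def _rejection_place(n: int, min_sep: float, geometry: CorridorGeometry,
                     rng: np.random.Generator, margin: float = 0.2,
                     max_attempts_per: int = 5000) -> np.ndarray:
    """Area-uniform non-overlapping placement in the annulus."""
    placed = np.empty((n, 2))
    lo2 = (geometry.r_inner + margin) ** 2
    hi2 = (geometry.r_outer - margin) ** 2
    count = 0
    attempts = 0
    while count < n:
        attempts += 1
        if attempts > max_attempts_per * n:
            raise RuntimeError(f"could not place {n} pedestrians without overlap")
        r = np.sqrt(rng.uniform(lo2, hi2))
        theta = rng.uniform(0.0, 2 * np.pi)
        cand = from_polar(r, theta)
        if count and np.min(np.linalg.norm(placed[:count] - cand, axis=-1)) < min_sep:
            continue
        placed[count] = cand
        count += 1
    return placed
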