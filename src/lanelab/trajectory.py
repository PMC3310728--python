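"""Time-indexed pedestrian trajectories.

:class:`TrajectorySet` is the interchange object between the simulator, the
synthetic fixtures and every analysis stage.  It stores uniformly sampled
positions for a fixed roster of pedestrians together with each pedestrian's
attributed circulation direction, and refuses irregular sampling or
non-finite data at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CorridorGeometry

__all__ = ["TrajectorySet"]

_DT_RTOL = 1e-6


@dataclass
class TrajectorySet:
    """Uniformly sampled positions of N labelled pedestrians.

    Parameters
    ----------
    times : (T,) strictly increasing sampling instants, s, uniform spacing.
    positions : (T, N, 2) Cartesian positions, m.
    directions : (N,) attributed circulation signs, +1 anti-clockwise / -1
        clockwise.
    geometry : the corridor the trajectories live in.
    v0 : optional (N,) comfortable walking speeds, m/s.
    ids : optional (N,) integer pedestrian labels; defaults to 0..N-1.
    """

    times: np.ndarray
    positions: np.ndarray
    directions: np.ndarray
    geometry: CorridorGeometry
    v0: np.ndarray | None = None
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.directions = np.asarray(self.directions, dtype=int)
        if self.v0 is not None:
            self.v0 = np.asarray(self.v0, dtype=float)
        if self.times.ndim != 1 or self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("times must be (T,), positions (T, N, 2)")
        T, N = self.positions.shape[:2]
        if self.times.shape[0] != T:
            raise ValueError(f"times has {self.times.shape[0]} frames, positions {T}")
        if self.directions.shape != (N,):
            raise ValueError("directions must have one entry per pedestrian")
        if not np.all(np.isin(self.directions, (-1, 1))):
            raise ValueError("directions must be +1 or -1")
        if self.v0 is not None and self.v0.shape != (N,):
            raise ValueError("v0 must have one entry per pedestrian")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if T >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(steps - steps[0]) > _DT_RTOL * max(steps[0], 1.0)):
                raise ValueError("non-uniform sampling interval; resample explicitly")
        if self.ids is None:
            self.ids = np.arange(N)
        else:
            self.ids = np.asarray(self.ids, dtype=int)
            if self.ids.shape != (N,) or len(np.unique(self.ids)) != N:
                raise ValueError("ids must be N unique integers")

    # -- basic views -----------------------------------------------------

    @property
    def n_pedestrians(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise ValueError("single-frame trajectory has no sampling interval")
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def frame_index(self, t: float) -> int:
        """Index of the sampled instant closest to ``t`` (within half a step)."""
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 0.5 * self.dt + 1e-9:
            raise ValueError(f"t={t} outside the sampled range")
        return idx

    def velocities(self) -> np.ndarray:
        """(T, N, 2) finite-difference velocities (central, one-sided at ends)."""
        if self.n_frames < 2:
            raise ValueError("cannot differentiate a single-frame trajectory")
        return np.gradient(self.positions, self.times, axis=0)

    def radii(self) -> np.ndarray:
        """(T, N) radial positions |x|."""
        return np.linalg.norm(self.positions, axis=-1)

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(
            times=self.times.copy(),
            positions=self.positions.copy(),
            directions=self.directions.copy(),
            geometry=self.geometry,
            v0=None if self.v0 is None else self.v0.copy(),
            ids=self.ids.copy(),
        )
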