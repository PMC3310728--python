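"""Driving the walking model: seeded end-to-end simulations on the ring.

A run places N pedestrians uniformly at random (without body overlap) in the
annulus, attributes half of them to each circulation direction, draws
comfortable speeds from the truncated Gaussian, integrates the heuristic
model, and records positions at a fixed output rate into a
:class:`~lanelab.trajectory.TrajectorySet`.  Everything is a pure function
of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CorridorGeometry
from .model import CrowdState, ModelParams, step
from .synthetic import SpeedDistribution, _rejection_place, sample_comfortable_speeds
from .trajectory import TrajectorySet

__all__ = ["SimulationConfig", "run_simulation"]


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one simulation run."""

    n: int = 60
    sigma: float = 0.16
    duration: float = 60.0
    seed: int = 0
    params: ModelParams = field(default_factory=ModelParams)
    geometry: CorridorGeometry = field(default_factory=CorridorGeometry)
    unidirectional: bool = False
    output_rate: float = 10.0
    mean_speed: float = 1.2
    speed_floor: float = 0.3

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one pedestrian")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.output_rate <= 0:
            raise ValueError("output_rate must be positive")

    def speed_distribution(self) -> SpeedDistribution:
        return SpeedDistribution(mu=self.mean_speed, sigma=self.sigma,
                                 floor=self.speed_floor)


def _initial_state(config: SimulationConfig, rng: np.random.Generator) -> CrowdState:
    p = config.params
    positions = _rejection_place(config.n, 2 * p.body_radius, config.geometry, rng,
                                 margin=p.body_radius)
    if config.unidirectional:
        directions = np.ones(config.n, dtype=int)
    else:
        half = config.n // 2
        directions = np.array([1] * half + [-1] * (config.n - half))
        rng.shuffle(directions)
    v0 = sample_comfortable_speeds(config.n, config.speed_distribution(), seed=rng)
    return CrowdState(
        positions=positions,
        velocities=np.zeros((config.n, 2)),
        v0=v0,
        directions=directions,
        radii=np.full(config.n, p.body_radius),
    )


def run_simulation(config: SimulationConfig) -> TrajectorySet:
    """Run one seeded simulation and record trajectories at the output rate."""
    p = config.params
    rng = np.random.default_rng(config.seed)
    state = _initial_state(config, rng)

    record_every = max(1, round(1.0 / (config.output_rate * p.dt)))
    n_steps = round(config.duration / p.dt)
    frames = [state.positions.copy()]
    times = [0.0]
    for s in range(1, n_steps + 1):
        state = step(state, p, config.geometry, rng)
        if s % record_every == 0:
            frames.append(state.positions.copy())
            times.append(s * p.dt)
    return TrajectorySet(
        times=np.asarray(times),
        positions=np.asarray(frames),
        directions=state.directions,
        geometry=config.geometry,
        v0=state.v0,
    )
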