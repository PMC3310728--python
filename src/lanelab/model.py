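"""Heuristics-based pedestrian walking model on the ring corridor.

Each pedestrian steers by evaluating candidate headings within its vision
field.  For a heading ``alpha`` the anticipated free path ``f(alpha)`` is the
distance the pedestrian could travel at its comfortable speed before first
body contact with another pedestrian (extrapolated linearly at that
pedestrian's current velocity) or with a wall circle, capped at the horizon
``d_max``.  The chosen heading minimises the anticipated distance to the
destination

    d(alpha)^2 = d_max^2 + f(alpha)^2 - 2 d_max f(alpha) cos(alpha0 - alpha),

where ``alpha0`` points toward the destination.  The desired speed is
``min(v0, d_h / tau)`` with ``d_h`` the free path to the first obstacle
along the chosen heading (``d_max`` on a free ray), so pedestrians slow
down and stop as their anticipated path shortens.
Velocities relax toward the desired velocity on a timescale ``tau``, and
linear-spring repulsion between overlapping bodies (and against walls) is
added to the acceleration, so the full equation of motion is

    dv_i/dt = (v_des e_des - v_i) / tau + sum_j f_ij + sum_W f_iW.

``contact_mode='substitute'`` instead suppresses the steering term during
any body overlap, an alternative reading of the model kept for sensitivity
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _fast
from .geometry import CorridorGeometry, tangent_direction

__all__ = [
    "ModelParams",
    "Pedestrian",
    "AgentState",
    "CrowdState",
    "SteeringDecision",
    "collision_distance",
    "desired_direction",
    "desired_speed",
    "contact_forces",
    "update_destination",
    "step",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Behavioural-model constants.

    tau : velocity relaxation time, s (0.5).
    vision_half_angle : half-width of the vision field, degrees (45).
    d_max : horizon distance for collision anticipation, m (10).
    k_contact : contact-spring stiffness, acceleration per metre of overlap (1e3).
    body_radius : disc radius of a pedestrian body, m (0.2).
    d_dest : look-ahead distance of the moving destination point, m (5).
    dt : integration step, s (0.025; implementation parameter).  The contact
        spring gives a pair oscillation frequency sqrt(2 k_contact) ~ 45
        rad/s, so the step must keep sqrt(2 k_contact) * dt < 2; at the
        default stiffness any dt above ~0.045 s is numerically unstable in
        dense crowds.
    n_directions : candidate headings sampled across the vision field (61;
        implementation parameter).
    contact_mode : 'add' (default) sums steering and contact accelerations;
        'substitute' replaces the steering term by the contact force during
        any body overlap.
    """

    tau: float = 0.5
    vision_half_angle: float = 45.0
    d_max: float = 10.0
    k_contact: float = 1.0e3
    body_radius: float = 0.2
    d_dest: float = 5.0
    dt: float = 0.025
    n_directions: int = 61
    contact_mode: str = "add"

    def __post_init__(self) -> None:
        for name in ("tau", "vision_half_angle", "d_max", "k_contact",
                     "body_radius", "d_dest", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.vision_half_angle > 90.0:
            raise ValueError("vision_half_angle must be <= 90 degrees")
        if self.dt > self.tau / 2:
            raise ValueError("dt must satisfy dt <= tau/2 for a stable relaxation")
        if self.n_directions < 3:
            raise ValueError("need at least 3 candidate headings")
        if self.contact_mode not in ("substitute", "add"):
            raise ValueError("contact_mode must be 'substitute' or 'add'")

    @property
    def vision_half_angle_rad(self) -> float:
        return float(np.deg2rad(self.vision_half_angle))

    def heading_offsets(self) -> np.ndarray:
        """Uniform grid of candidate heading offsets around alpha0, radians."""
        a = self.vision_half_angle_rad
        return np.linspace(-a, a, self.n_directions)


@dataclass(frozen=True)
class Pedestrian:
    """Static attributes of one pedestrian."""

    id: int
    v0: float
    direction: int
    body_radius: float = 0.2

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError("comfortable speed must be positive")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class AgentState:
    """Kinematic state of one pedestrian."""

    position: np.ndarray
    velocity: np.ndarray
    destination: np.ndarray


@dataclass
class CrowdState:
    """Array-of-structs state of the whole crowd at one instant.

    positions / velocities : (N, 2) m, m/s
    v0 : (N,) comfortable speeds, m/s
    directions : (N,) circulation signs
    radii : (N,) body radii, m
    """

    positions: np.ndarray
    velocities: np.ndarray
    v0: np.ndarray
    directions: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        self.v0 = np.atleast_1d(np.asarray(self.v0, dtype=float))
        self.directions = np.atleast_1d(np.asarray(self.directions, dtype=int))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        n = self.positions.shape[0]
        if not (self.velocities.shape == (n, 2) and self.v0.shape == (n,)
                and self.directions.shape == (n,) and self.radii.shape == (n,)):
            raise ValueError("inconsistent crowd-state array shapes")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class SteeringDecision:
    """Outcome of one pedestrian's heading/speed choice."""

    alpha_des: float
    f_samples: np.ndarray
    d_h: float          # free path to the first obstacle along alpha_des
    v_des: float
    alpha0: float


def update_destination(position: np.ndarray, direction, d_dest: float) -> np.ndarray:
    """Destination point ``d_dest`` metres away along the circulation tangent.

    Refreshed every integration step, so the destination keeps sliding along
    the ring ahead of the pedestrian.
    """
    position = np.asarray(position, dtype=float)
    return position + d_dest * tangent_direction(position, direction)


def desired_speed(v0: float, d_h: float, tau: float) -> float:
    """min(v0, d_h / tau): slow down when the free path shortens."""
    if min(v0, d_h, tau) < 0:
        raise ValueError("arguments must be non-negative")
    return min(v0, d_h / tau)


# ---------------------------------------------------------------------------
# vectorised collision anticipation
# ---------------------------------------------------------------------------

def _free_paths(positions, velocities, v0, radii, alphas, params, geometry):
    """Anticipated free paths for every agent and candidate heading.

    positions, velocities : (N, 2); v0, radii : (N,); alphas : (N, K)
    absolute candidate headings.  Returns (N, K) travel distances until
    first surface contact, in [0, d_max].

    Neighbour collisions solve |dx + w t| = r_i + r_j for the earliest t > 0
    with dx the centre offset and w the relative velocity under heading
    alpha; walls are circles of radius r_outer - r_i (outer) and
    r_inner + r_i (inner) intersected with the ray of travel.

    Bodies (or walls) already in contact are excluded from the anticipation:
    physical contact is governed by the repulsive contact force, which takes
    over from the heuristic, so only collisions that have not yet happened
    constrain the free path.  Without this exclusion a touching neighbour
    blocks the entire vision field (a disc at contact distance subtends
    ~90 degrees) and every contact becomes an absorbing deadlock.
    """
    N, K = alphas.shape
    e = np.stack([np.cos(alphas), np.sin(alphas)], axis=-1)          # (N,K,2)

    f_ped = np.full((N, K), np.inf)
    if N > 1:
        dx = positions[None, :, :] - positions[:, None, :]           # (i,j,2)
        rsum = radii[:, None] + radii[None, :]
        c = (dx**2).sum(-1) - rsum**2                                 # (i,j)
        w = velocities[None, None, :, :] - v0[:, None, None, None] * e[:, :, None, :]
        a = (w**2).sum(-1)                                            # (i,k,j)
        b = 2.0 * (dx[:, None, :, :] * w).sum(-1)
        cc = c[:, None, :]
        disc = b * b - 4.0 * a * cc
        ok = (disc >= 0.0) & (a > _EPS)
        t = np.where(ok, (-b - np.sqrt(np.where(ok, disc, 0.0)))
                     / np.where(a > _EPS, 2.0 * a, 1.0), np.inf)
        t = np.where(t > 0.0, t, np.inf)
        dist = v0[:, None, None] * t
        # already-touching neighbours belong to the contact force, not f
        dist = np.where(cc <= 0.0, np.inf, dist)
        idx = np.arange(N)
        dist[idx, :, idx] = np.inf
        f_ped = dist.min(axis=2)

    # walls: travel s along e until |x + s e| hits a wall-contact circle
    xe = (positions[:, None, :] * e).sum(-1)                          # (N,K)
    xx = (positions**2).sum(-1)[:, None]
    c_out = xx - (geometry.r_outer - radii[:, None]) ** 2
    s_out = np.where(c_out <= 0.0,
                     -xe + np.sqrt(np.maximum(xe**2 - c_out, 0.0)), np.inf)
    s_out = np.where(s_out > 1e-9, s_out, np.inf)
    r_in_c = geometry.r_inner + radii[:, None]
    c_in = xx - r_in_c**2
    disc_in = xe**2 - c_in
    s_in = np.where((c_in > 0.0) & (disc_in > 0.0),
                    -xe - np.sqrt(np.maximum(disc_in, 0.0)), np.inf)
    s_in = np.where(s_in > 1e-9, s_in, np.inf)   # tangential grazing is no collision

    f = np.minimum(f_ped, np.minimum(s_out, s_in))
    return np.clip(f, 0.0, params.d_max)


def collision_distance(state: CrowdState, i: int, alpha: float,
                       params: ModelParams, geometry: CorridorGeometry) -> float:
    """Free path of pedestrian ``i`` along heading ``alpha`` (m, <= d_max)."""
    alphas = np.full((len(state), 1), float(alpha))
    f = _free_paths(state.positions, state.velocities, state.v0, state.radii,
                    alphas, params, geometry)
    return float(f[i, 0])


def _looking_directions(state: CrowdState, params: ModelParams) -> np.ndarray:
    """alpha0 for every agent: direction toward the moving destination."""
    dest = update_destination(state.positions, state.directions, params.d_dest)
    rel = dest - state.positions
    return np.arctan2(rel[:, 1], rel[:, 0])


def _steer_all(state: CrowdState, params: ModelParams, geometry: CorridorGeometry,
               rng: np.random.Generator | None = None):
    """Heading and speed choice for every agent.

    Returns (alpha_des (N,), v_des (N,), f (N,K), alpha0 (N,), d_h (N,)).
    Exact symmetric ties between a left and a right candidate are broken by
    a coin flip from ``rng`` to avoid a systematic chirality.
    """
    offsets = params.heading_offsets()
    alpha0 = _looking_directions(state, params)
    alphas = alpha0[:, None] + offsets[None, :]
    if _fast.HAVE_NUMBA:
        f = _fast.free_paths_kernel(
            np.ascontiguousarray(state.positions), np.ascontiguousarray(state.velocities),
            state.v0, state.radii, np.ascontiguousarray(alphas),
            params.d_max, geometry.r_inner, geometry.r_outer)
    else:
        f = _free_paths(state.positions, state.velocities, state.v0,
                        state.radii, alphas, params, geometry)
    cos_off = np.cos(offsets)
    d2 = params.d_max**2 + f**2 - 2.0 * params.d_max * f * cos_off[None, :]
    d = np.sqrt(np.maximum(d2, 0.0))

    dmin = d.min(axis=1, keepdims=True)
    tie = d <= dmin + 1e-12
    if rng is None:
        coin = np.ones(len(state))
    else:
        coin = rng.integers(0, 2, size=len(state)) * 2.0 - 1.0
    # prefer smallest |offset|; exact +/- ties nudged toward the coin's side
    score = np.where(
        tie,
        np.abs(offsets)[None, :] - 1e-9 * coin[:, None] * np.sign(offsets)[None, :],
        np.inf,
    )
    k_best = score.argmin(axis=1)
    rows = np.arange(len(state))
    alpha_des = alphas[rows, k_best]
    d_h = f[rows, k_best]
    v_des = np.minimum(state.v0, d_h / params.tau)
    return alpha_des, v_des, f, alpha0, d_h


def desired_direction(state: CrowdState, i: int, params: ModelParams,
                      geometry: CorridorGeometry,
                      rng: np.random.Generator | None = None) -> SteeringDecision:
    """Steering decision of pedestrian ``i`` in the current crowd state."""
    dest = update_destination(state.positions[i], int(state.directions[i]), params.d_dest)
    if np.allclose(dest, state.positions[i]):
        raise ValueError("destination coincides with the current position")
    alpha_des, v_des, f, alpha0, d_h = _steer_all(state, params, geometry, rng)
    return SteeringDecision(
        alpha_des=float(alpha_des[i]),
        f_samples=f[i].copy(),
        d_h=float(d_h[i]),
        v_des=float(v_des[i]),
        alpha0=float(alpha0[i]),
    )


# ---------------------------------------------------------------------------
# contact forces
# ---------------------------------------------------------------------------

def _contact_forces_all(state: CrowdState, params: ModelParams,
                        geometry: CorridorGeometry):
    """Linear-spring repulsion k * g(overlap) for bodies and walls.

    Returns (forces (N, 2), in_contact (N,) bool).  g(x) = max(x, 0), so the
    force vanishes without touching.  Raises on coincident centres, where
    the push direction is undefined.
    """
    N = len(state)
    F = np.zeros((N, 2))
    in_contact = np.zeros(N, dtype=bool)
    if N > 1:
        dx = state.positions[:, None, :] - state.positions[None, :, :]   # j -> i
        dist = np.linalg.norm(dx, axis=-1)
        rsum = state.radii[:, None] + state.radii[None, :]
        np.fill_diagonal(dist, np.inf)
        overlap = np.clip(rsum - dist, 0.0, None)
        if np.any((dist == 0.0) & np.isfinite(rsum) & (overlap > 0)):
            raise ValueError("coincident pedestrian centres: degenerate state")
        touching = overlap > 0.0
        if np.any(dist[touching] == 0.0):
            raise ValueError("coincident pedestrian centres: degenerate state")
        n_ij = np.where(touching[..., None], dx / np.where(dist[..., None] > 0, dist[..., None], 1.0), 0.0)
        F += params.k_contact * (overlap[..., None] * n_ij).sum(axis=1)
        in_contact |= touching.any(axis=1)

    r = np.linalg.norm(state.positions, axis=-1)
    radial = state.positions / np.where(r[:, None] > 0, r[:, None], 1.0)
    g_out = np.clip(state.radii - (geometry.r_outer - r), 0.0, None)
    g_in = np.clip(state.radii - (r - geometry.r_inner), 0.0, None)
    F += params.k_contact * (g_in[:, None] - g_out[:, None]) * radial
    in_contact |= (g_out > 0) | (g_in > 0)
    return F, in_contact


def contact_forces(state: CrowdState, i: int, params: ModelParams,
                   geometry: CorridorGeometry) -> np.ndarray:
    """Net contact force (acceleration, m/s^2) on pedestrian ``i``."""
    F, _ = _contact_forces_all(state, params, geometry)
    return F[i]


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def step(state: CrowdState, params: ModelParams, geometry: CorridorGeometry,
         rng: np.random.Generator | None = None) -> CrowdState:
    """One symplectic-Euler step: velocity update, then position update.

    The acceleration is the steering relaxation (v_des e_des - v)/tau plus
    the contact forces; with ``contact_mode='substitute'`` agents with any
    body or wall overlap are driven by the contact force alone.
    """
    alpha_des, v_des, _, _, _ = _steer_all(state, params, geometry, rng)
    e_des = np.stack([np.cos(alpha_des), np.sin(alpha_des)], axis=-1)
    acc_heur = (v_des[:, None] * e_des - state.velocities) / params.tau
    F, in_contact = _contact_forces_all(state, params, geometry)
    if params.contact_mode == "substitute":
        acc = np.where(in_contact[:, None], F, acc_heur)
    else:
        acc = acc_heur + F
    v_new = state.velocities + params.dt * acc
    x_new = state.positions + params.dt * v_new
    if not (np.all(np.isfinite(v_new)) and np.all(np.isfinite(x_new))):
        raise FloatingPointError("non-finite state after update; reduce dt")
    return replace(state, positions=x_new, velocities=v_new)
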