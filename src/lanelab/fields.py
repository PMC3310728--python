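"""Local density and radial-speed fields over the ring.

The local density at a point x is a Gaussian-kernel-weighted count,

    rho(x) = sum_j (1 / (pi R^2)) exp(-d_jx^2 / R^2),      R = 0.7 m,

whose plane integral per pedestrian is one, so integrating rho over the
whole plane returns N.  The directional profile rho(theta, t) averages
rho over points of the corridor along direction theta; the radial speed
v_r(theta, t) averages |d r_j / d t| over the pedestrians inside the
angular sector at theta and is the signature of lane-leaving (overtaking)
manoeuvres.  Sectors without pedestrians carry NaN, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import CorridorGeometry, from_polar
from .trajectory import TrajectorySet

__all__ = [
    "FieldParams",
    "FieldMaps",
    "local_density_at_point",
    "density_profile",
    "radial_speed_profile",
    "build_field_maps",
    "density_speed_correlation",
]


@dataclass(frozen=True)
class FieldParams:
    """Field-measure resolution parameters.

    kernel_R : Gaussian weight scale, m (0.7).
    n_theta : angular bins over [0, 2*pi); 72 bins = 5 degree sectors.
    n_radial_samples : points per direction for the radial average.
    time_step : map sampling interval, s.
    t_skip : initial transient discarded by the correlation, s (10).
    """

    kernel_R: float = 0.7
    n_theta: int = 72
    n_radial_samples: int = 20
    time_step: float = 0.5
    t_skip: float = 10.0

    def __post_init__(self) -> None:
        if self.kernel_R <= 0 or self.n_theta < 1 or self.n_radial_samples < 1:
            raise ValueError("kernel_R, n_theta, n_radial_samples must be positive")

    @property
    def sector_width(self) -> float:
        return 2.0 * np.pi / self.n_theta

    def theta_bins(self) -> np.ndarray:
        """Bin-centre angles, radians."""
        return (np.arange(self.n_theta) + 0.5) * self.sector_width


@dataclass
class FieldMaps:
    """rho(theta, t) and v_r(theta, t) on a polar-angle x time grid.

    density : (T, n_theta) per m^2; radial_speed : (T, n_theta) m/s with
    NaN marking empty sectors.
    """

    theta: np.ndarray
    times: np.ndarray
    density: np.ndarray
    radial_speed: np.ndarray


def local_density_at_point(positions: np.ndarray, x: np.ndarray,
                           kernel_R: float = 0.7) -> float:
    """Gaussian-kernel density (per m^2) of one frame at point ``x``."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] == 0:
        return 0.0
    d2 = ((positions - np.asarray(x, dtype=float)) ** 2).sum(axis=1)
    return float(np.exp(-d2 / kernel_R**2).sum() / (np.pi * kernel_R**2))


def density_profile(positions: np.ndarray, geometry: CorridorGeometry,
                    params: FieldParams = FieldParams()) -> np.ndarray:
    """rho(theta): radial mean of the local density along each direction."""
    theta = params.theta_bins()
    radii = np.linspace(geometry.r_inner, geometry.r_outer, params.n_radial_samples)
    pts = from_polar(radii[None, :], theta[:, None])          # (n_theta, n_rad, 2)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] == 0:
        return np.zeros(params.n_theta)
    d2 = ((pts[:, :, None, :] - positions[None, None, :, :]) ** 2).sum(-1)
    rho = np.exp(-d2 / params.kernel_R**2).sum(-1) / (np.pi * params.kernel_R**2)
    return rho.mean(axis=1)


def _sector_indices(positions: np.ndarray, params: FieldParams) -> np.ndarray:
    theta = np.mod(np.arctan2(positions[:, 1], positions[:, 0]), 2 * np.pi)
    return np.minimum((theta / params.sector_width).astype(int), params.n_theta - 1)


def radial_speed_profile(traj: TrajectorySet, t: float,
                         params: FieldParams = FieldParams()) -> np.ndarray:
    """v_r(theta) at time ``t``: sector means of |dr/dt|, NaN when empty."""
    if traj.n_frames < 2:
        raise ValueError("radial speeds need at least two frames")
    fi = traj.frame_index(t)
    vr = np.abs(np.gradient(traj.radii(), traj.times, axis=0))[fi]
    return _sector_mean(traj.positions[fi], vr, params)


def _sector_mean(positions: np.ndarray, values: np.ndarray,
                 params: FieldParams) -> np.ndarray:
    idx = _sector_indices(positions, params)
    out = np.full(params.n_theta, np.nan)
    sums = np.bincount(idx, weights=values, minlength=params.n_theta)
    counts = np.bincount(idx, minlength=params.n_theta)
    occupied = counts > 0
    out[occupied] = sums[occupied] / counts[occupied]
    return out


def build_field_maps(traj: TrajectorySet,
                     params: FieldParams = FieldParams()) -> FieldMaps:
    """rho and v_r on the (time, theta) grid at ``time_step`` spacing."""
    stride = max(1, int(round(params.time_step / traj.dt)))
    frames = np.arange(0, traj.n_frames, stride)
    vr_all = np.abs(np.gradient(traj.radii(), traj.times, axis=0))
    density = np.empty((frames.size, params.n_theta))
    radial = np.empty((frames.size, params.n_theta))
    for k, fi in enumerate(frames):
        density[k] = density_profile(traj.positions[fi], traj.geometry, params)
        radial[k] = _sector_mean(traj.positions[fi], vr_all[fi], params)
    return FieldMaps(theta=params.theta_bins(), times=traj.times[frames],
                     density=density, radial_speed=radial)


def density_speed_correlation(maps: FieldMaps, t_skip: float = 10.0):
    """Pearson correlation between rho and v_r over defined cells after t_skip.

    Returns ``(coefficient, p_value)`` from a two-sided test; empty-sector
    cells are excluded, never imputed.
    """
    sel = maps.times > t_skip
    rho = maps.density[sel].ravel()
    vr = maps.radial_speed[sel].ravel()
    ok = np.isfinite(vr) & np.isfinite(rho)
    if ok.sum() < 10:
        raise ValueError("fewer than 10 valid (rho, v_r) cells after t_skip")
    r, p = stats.pearsonr(rho[ok], vr[ok])
    return float(r), float(p)
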