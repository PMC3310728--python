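"""Ring-corridor geometry and polar-coordinate conventions.

The experimental arena is an annulus centred at the origin.  All angles are
radians internally, measured counter-clockwise from the +x axis; a
circulation sign of +1 means anti-clockwise (increasing theta), -1 clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CorridorGeometry", "area", "to_polar", "from_polar", "tangent_direction"]


@dataclass(frozen=True)
class CorridorGeometry:
    """Annular corridor with inner radius ``r_inner`` and outer ``r_outer`` (m).

    Defaults reproduce the experimental ring (2 m / 4.5 m).
    """

    r_inner: float = 2.0
    r_outer: float = 4.5

    def __post_init__(self) -> None:
        if not (0.0 < self.r_inner < self.r_outer):
            raise ValueError(
                f"require 0 < r_inner < r_outer, got ({self.r_inner}, {self.r_outer})"
            )

    def area(self) -> float:
        """Walkable surface pi * (r_outer^2 - r_inner^2) in m^2."""
        return float(np.pi * (self.r_outer**2 - self.r_inner**2))

    def mid_radius(self) -> float:
        return 0.5 * (self.r_inner + self.r_outer)

    def contains(self, xy: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True where points lie inside the annulus shrunk by ``margin``."""
        r = np.linalg.norm(np.asarray(xy, dtype=float), axis=-1)
        return (r >= self.r_inner + margin) & (r <= self.r_outer - margin)


def area(geometry: CorridorGeometry) -> float:
    """Surface of the annular corridor in m^2."""
    return geometry.area()


def to_polar(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian ``(..., 2)`` -> ``(r, theta)`` with theta in [0, 2*pi).

    Raises ``ValueError`` for points at the origin, where the angle is
    undefined.
    """
    xy = np.asarray(xy, dtype=float)
    r = np.linalg.norm(xy, axis=-1)
    if np.any(r == 0.0):
        raise ValueError("polar angle undefined at the origin")
    theta = np.mod(np.arctan2(xy[..., 1], xy[..., 0]), 2.0 * np.pi)
    return r, theta


def from_polar(r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_polar`; returns ``(..., 2)`` Cartesian points."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return np.stack([r * np.cos(theta), r * np.sin(theta)], axis=-1)


def tangent_direction(xy: np.ndarray, direction) -> np.ndarray:
    """Unit vector tangent to the ring at ``xy``, oriented by circulation sign.

    ``direction`` is +1 for anti-clockwise (theta increasing) or -1 for
    clockwise; it may be a scalar or an array broadcastable against the
    leading shape of ``xy``.
    """
    xy = np.asarray(xy, dtype=float)
    r = np.linalg.norm(xy, axis=-1, keepdims=True)
    if np.any(r == 0.0):
        raise ValueError("tangent undefined at the origin")
    d = np.asarray(direction, dtype=float)[..., None] if np.ndim(direction) else float(direction)
    radial = xy / r
    # rotate the radial unit vector by +90 deg, then flip by the sign
    tangent = np.stack([-radial[..., 1], radial[..., 0]], axis=-1)
    return tangent * d
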