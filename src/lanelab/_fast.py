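"""Numba-compiled inner kernel for collision anticipation.

Mirrors :func:`lanelab.model._free_paths` exactly; the numpy version remains
the readable reference implementation and the two are cross-checked in the
test suite.  Falls back silently when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def free_paths_kernel(pos, vel, v0, radii, alphas, d_max, r_inner, r_outer):
    """(N, K) anticipated free paths; see the numpy reference for the maths."""
    N, K = alphas.shape
    f = np.empty((N, K))
    for i in range(N):
        xi0 = pos[i, 0]
        xi1 = pos[i, 1]
        xx = xi0 * xi0 + xi1 * xi1
        ro = r_outer - radii[i]
        ri = r_inner + radii[i]
        c_out = xx - ro * ro
        c_in = xx - ri * ri
        vi = v0[i]
        for k in range(K):
            e0 = math.cos(alphas[i, k])
            e1 = math.sin(alphas[i, k])
            best = d_max
            xe = xi0 * e0 + xi1 * e1
            if c_out <= 0.0:
                s = -xe + math.sqrt(max(xe * xe - c_out, 0.0))
                if 1e-9 < s < best:
                    best = s
            if c_in > 0.0:
                disc = xe * xe - c_in
                if disc > 0.0:
                    s = -xe - math.sqrt(disc)
                    if 1e-9 < s < best:
                        best = s
            for j in range(N):
                if j == i:
                    continue
                dx0 = pos[j, 0] - xi0
                dx1 = pos[j, 1] - xi1
                rs = radii[i] + radii[j]
                c = dx0 * dx0 + dx1 * dx1 - rs * rs
                if c <= 0.0:
                    # already touching: the contact force owns this pair
                    continue
                w0 = vel[j, 0] - vi * e0
                w1 = vel[j, 1] - vi * e1
                b = 2.0 * (dx0 * w0 + dx1 * w1)
                a = w0 * w0 + w1 * w1
                if a <= 1e-12:
                    continue
                disc = b * b - 4.0 * a * c
                if disc < 0.0:
                    continue
                t = (-b - math.sqrt(disc)) / (2.0 * a)
                if t > 0.0 and vi * t < best:
                    best = vi * t
            if best < 0.0:
                best = 0.0
            f[i, k] = best
    return f
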