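"""Analytic radial surfaces with exact plane sectioning.

A :class:`RadialSurface` is a star-shaped surface ``p(u) = c + r(u) * u``
over unit directions ``u`` restricted to a domain (a spherical cap, an
elliptical patch, or the full sphere), optionally carried by a rigid pose.
Both phantom bone surfaces (sphere radius plus a small fixed asphericity)
and cartilage outer surfaces (bone radius offset by a thickness field)
have this form, which makes plane sections computable to solver precision:
for each azimuth about the section plane's normal the polar angle solves a
scalar equation handled by vectorized bisection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

_BISECT_ITERS = 80


def orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``axis`` to a right-handed frame."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    helper = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(helper, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


@dataclass
class RadialSurface:
    """Star-shaped surface about ``center`` in its local frame, plus a pose.

    Parameters
    ----------
    center : (3,) local-frame center of the radial parameterization.
    radius_fn : maps unit directions ``(n, 3)`` to radii ``(n,)`` in mm.
    domain_fn : boolean mask of directions belonging to the surface.
    r_bounds : (r_min, r_max) bracket for the radius function.
    pose_rotation, pose_translation : rigid pose mapping local to world,
        ``x_world = R @ x_local + t``.
    """

    center: np.ndarray
    radius_fn: Callable[[np.ndarray], np.ndarray]
    domain_fn: Callable[[np.ndarray], np.ndarray]
    r_bounds: tuple[float, float]
    pose_rotation: np.ndarray = None
    pose_translation: np.ndarray = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.pose_rotation is None:
            self.pose_rotation = np.eye(3)
        if self.pose_translation is None:
            self.pose_translation = np.zeros(3)
        self.pose_rotation = np.asarray(self.pose_rotation, dtype=float)
        self.pose_translation = np.asarray(self.pose_translation, dtype=float)

    # ------------------------------------------------------------------ basics
    def with_pose(self, rotation: np.ndarray, translation: np.ndarray) -> "RadialSurface":
        """Return a copy with a new pose composed on top of the current one."""
        R = np.asarray(rotation, float) @ self.pose_rotation
        t = np.asarray(rotation, float) @ self.pose_translation + np.asarray(translation, float)
        return RadialSurface(self.center, self.radius_fn, self.domain_fn, self.r_bounds, R, t)

    def points_from_directions(self, u: np.ndarray) -> np.ndarray:
        """World-frame surface points for local unit directions ``u``."""
        u = np.asarray(u, dtype=float)
        local = self.center + self.radius_fn(u)[:, None] * u
        return local @ self.pose_rotation.T + self.pose_translation

    def sample_directions(self, n: int = 4096, seed: int = 0) -> np.ndarray:
        """Quasi-uniform in-domain unit directions (Fibonacci sphere)."""
        i = np.arange(n, dtype=float) + 0.5
        phi = np.pi * (3.0 - np.sqrt(5.0)) * i
        z = 1.0 - 2.0 * i / n
        s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        u = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
        return u[self.domain_fn(u)]

    def z_range(self, n_sample: int = 8192) -> tuple[float, float]:
        u = self.sample_directions(n_sample)
        if len(u) == 0:
            raise ValueError("surface domain is empty")
        z = self.points_from_directions(u)[:, 2]
        margin = 2.0 * (self.r_bounds[1] - self.r_bounds[0]) + 0.5
        return float(z.min()) - margin, float(z.max()) + margin

    # ---------------------------------------------------------------- slicing
    def section_z(self, z0: float, point_spacing: float) -> list[tuple[np.ndarray, bool]]:
        """Intersect with the world plane ``z = z0``.

        Returns a list of ``(points, closed)`` with points (n, 3) in world
        coordinates ordered along the curve, spaced approximately
        ``point_spacing`` apart, every point lying on the surface to solver
        precision.
        """
        R, t = self.pose_rotation, self.pose_translation
        m = R.T @ np.array([0.0, 0.0, 1.0])  # plane normal in local frame
        d = z0 - t[2]                         # plane offset: m . x_local = d
        h = d - float(self.center @ m)        # height of plane above center
        r_min, r_max = self.r_bounds
        if abs(h) >= r_max:
            return []
        e1, e2 = orthonormal_basis(m)

        r_mid = 0.5 * (r_min + r_max)
        rho_est = np.sqrt(max(r_mid**2 - min(h**2, r_mid**2 * 0.999), 1e-6))
        n_phi = max(16, int(np.ceil(2.0 * np.pi * rho_est / point_spacing)))
        phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
        cph, sph = np.cos(phi), np.sin(phi)

        def directions(theta):
            st, ct = np.sin(theta), np.cos(theta)
            return (st * cph)[:, None] * e1 + (st * sph)[:, None] * e2 + ct[:, None] * m

        def f(theta):
            u = directions(theta)
            return self.radius_fn(u) * np.cos(theta) - h

        lo_val = np.clip(h / r_min if r_min > 0 else -1.0, -1.0, 1.0)
        hi_val = np.clip(h / r_max, -1.0, 1.0)
        a = np.minimum(np.arccos(lo_val), np.arccos(hi_val))
        b = np.maximum(np.arccos(lo_val), np.arccos(hi_val))
        # widen the bracket slightly against radius-bound slack
        a = np.maximum(a - 0.05, 0.0)
        b = np.minimum(b + 0.05, np.pi)
        ta = np.full(n_phi, a)
        tb = np.full(n_phi, b)
        fa, fb = f(ta), f(tb)
        ok = np.sign(fa) != np.sign(fb)
        if not np.any(ok):
            return []
        for _ in range(_BISECT_ITERS):
            tm = 0.5 * (ta + tb)
            fm = f(tm)
            take_hi = np.sign(fm) == np.sign(fa)
            ta = np.where(take_hi, tm, ta)
            fa = np.where(take_hi, fm, fa)
            tb = np.where(take_hi, tb, tm)
        theta = 0.5 * (ta + tb)
        u = directions(theta)
        in_dom = ok & self.domain_fn(u)
        if not np.any(in_dom):
            return []
        pts_world = self.points_from_directions(u)

        contours: list[tuple[np.ndarray, bool]] = []
        if np.all(in_dom):
            contours.append((pts_world, True))
        else:
            # contiguous in-domain runs, cyclic in phi
            idx = np.flatnonzero(in_dom)
            breaks = np.flatnonzero(np.diff(idx) > 1)
            runs = np.split(idx, breaks + 1)
            if len(runs) > 1 and idx[0] == 0 and idx[-1] == n_phi - 1:
                runs[0] = np.concatenate([runs[-1], runs[0]])
                runs = runs[:-1]
            for run in runs:
                if len(run) >= 2:
                    contours.append((pts_world[run], False))
        return contours
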