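"""Rigid registration of pre- and post-exercise bone surfaces.

Point-to-point iterative closest point (ICP): nearest-neighbour matching
through a KD-tree, closed-form Kabsch (SVD) pose update per iteration.
Initialization aligns centroids and, when the shape is sufficiently
anisotropic, principal axes (the sign combination with the lowest starting
residual wins); near-isotropic shapes start from the identity rotation.
Each bone is registered independently so the cartilage comparison is
site-specific on that bone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .geometry import SurfaceMesh


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3))
        if err > 1e-9:
            raise ValueError(f"rotation is not orthonormal (||R^T R - I|| = {err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        a = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({"matrix": self.to_matrix().tolist()}, indent=1))

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls.from_matrix(json.loads(Path(path).read_text())["matrix"])


@dataclass
class ICPConfig:
    max_iterations: int = 100
    tolerance: float = 1e-4       # mm change in rms residual
    max_points: int = 20000       # deterministic stride subsampling
    use_pca_init: bool = True
    pca_isotropy_threshold: float = 0.05  # relative eigenvalue spread below which PCA init is skipped


@dataclass
class RegistrationReport:
    transform: RigidTransform
    rms_residual: float
    iterations: int
    converged: bool
    rms_trace: list = dc_field(default_factory=list)


def apply_transform(mesh: SurfaceMesh, t: RigidTransform) -> SurfaceMesh:
    return SurfaceMesh(t.apply(mesh.vertices), mesh.faces.copy(), mesh.label)


def _subsample(points: np.ndarray, max_points: int) -> np.ndarray:
    if len(points) <= max_points:
        return points
    stride = int(np.ceil(len(points) / max_points))
    return points[::stride]


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid motion mapping src onto dst."""
    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    H = (src - c_src).T @ (dst - c_dst)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, c_dst - R @ c_src)


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def _initial_transform(moving: np.ndarray, fixed: np.ndarray, tree: cKDTree,
                       config: ICPConfig) -> RigidTransform:
    c_mov = moving.mean(axis=0)
    c_fix = fixed.mean(axis=0)
    candidates = [RigidTransform(np.eye(3), c_fix - c_mov)]
    if config.use_pca_init:
        w_m, v_m = _principal_axes(moving)
        w_f, v_f = _principal_axes(fixed)
        spread = (w_m[0] - w_m[2]) / max(w_m[0], 1e-300)
        if spread > config.pca_isotropy_threshold:
            for s1 in (1.0, -1.0):
                for s2 in (1.0, -1.0):
                    A = v_f @ np.diag([s1, s2, s1 * s2]) @ v_m.T
                    if np.linalg.det(A) < 0:
                        A = v_f @ np.diag([s1, s2, -s1 * s2]) @ v_m.T
                    candidates.append(RigidTransform(A, c_fix - A @ c_mov))
    best, best_rms = None, np.inf
    probe = _subsample(moving, 2000)
    for cand in candidates:
        d, _ = tree.query(cand.apply(probe), workers=-1)
        rms = float(np.sqrt(np.mean(d**2)))
        if rms < best_rms:
            best, best_rms = cand, rms
    return best


def icp_align(moving: SurfaceMesh, fixed: SurfaceMesh, config: ICPConfig | None = None) -> RegistrationReport:
    """Align ``moving`` into the frame of ``fixed``.

    Returns a report whose transform maps moving-frame coordinates into the
    fixed frame; the stored per-iteration rms trace is non-increasing.
    """
    config = config or ICPConfig()
    if moving.is_empty or fixed.is_empty:
        raise ValueError("cannot register an empty mesh")
    mov = _subsample(np.asarray(moving.vertices, dtype=float), config.max_points)
    fix = _subsample(np.asarray(fixed.vertices, dtype=float), config.max_points)
    tree = cKDTree(fix)

    current = _initial_transform(mov, fix, tree, config)
    pts = current.apply(mov)
    trace: list[float] = []
    prev_rms = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        d, idx = tree.query(pts, workers=-1)
        step = _kabsch(pts, fix[idx])
        pts = step.apply(pts)
        current = step.compose(current)
        rms = float(np.sqrt(np.mean(np.sum((pts - fix[idx]) ** 2, axis=1))))
        trace.append(rms)
        if abs(prev_rms - rms) < config.tolerance:
            converged = True
            break
        prev_rms = rms
    return RegistrationReport(
        transform=current,
        rms_residual=trace[-1],
        iterations=iterations,
        converged=converged,
        rms_trace=trace,
    )
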