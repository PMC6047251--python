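"""Synthetic shoulder phantom with exact ground truth.

The humeral head is a spherical cap (default radius 24 mm, half-angle 60
degrees) and the glenoid a shallow spherical-patch socket (default radius
of curvature 30 mm, elliptical footprint ~35 mm superoinferior x 25 mm
anteroposterior).  Both bone surfaces carry a fixed ~2% low-order radial
asphericity so that rigid registration is fully determined (a perfect
sphere leaves rotation about its centre unconstrained, which no real bone
does).  Cartilage outer surfaces are radial offsets of the bone by a
thickness field; the post-exercise session scales thickness by
``1 - strain`` pointwise and moves the whole scene by a rigid offset.

Coordinates: right-handed, mm, +z superior, +x lateral; +y is anterior
for a right shoulder and posterior for a left one (the anteroposterior
axis mirrors with laterality).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable

import numpy as np

from .fields import ConstantField, RadialField, ScalarField, field_from_spec
from .geometry import ALLOWED_LABELS, Contour, ContourStack, SurfaceMesh, reconstruct_surface
from .registration import RigidTransform
from .surfaces import RadialSurface

_ASPHERICITY_AMPLITUDE = 0.02
_HUMERAL_CAP_HALF_ANGLE_DEG = 60.0


def _asphericity(u: np.ndarray) -> np.ndarray:
    """Fixed smooth radial perturbation breaking all rotational symmetries."""
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    return 0.9 * x * y + 0.7 * y * z + 0.5 * z * x + 0.8 * x * y * z


@dataclass
class PhantomSpec:
    """Geometry, fields, noise and pose of one synthetic subject."""

    humeral_head_radius: float = 24.0
    glenoid_radius_of_curvature: float = 30.0
    glenoid_extent_si: float = 35.0
    glenoid_extent_ap: float = 25.0
    laterality: str = "right"
    humeral_thickness_field: object = 1.0
    glenoid_thickness_field: object = None  # default: 1.2 mm center -> 1.5 mm anteroinferior rim
    humeral_strain_field: object = 0.0
    glenoid_strain_field: object = 0.0
    rigid_offset: RigidTransform = None
    contour_slice_spacing: float = 0.5
    in_plane_point_spacing: float = 0.3
    noise_sd: float = 0.04
    seed: int = 0
    compartments: tuple = ("humeral", "glenoid")

    def __post_init__(self):
        for name in ("humeral_head_radius", "glenoid_radius_of_curvature",
                     "glenoid_extent_si", "glenoid_extent_ap",
                     "contour_slice_spacing", "in_plane_point_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")
        bad = set(self.compartments) - {"humeral", "glenoid"}
        if bad:
            raise ValueError(f"compartments contains unknown entries {sorted(bad)}")
        if self.glenoid_thickness_field is None:
            # anterior (+ap) and inferior (-si) biased periphery, thickest anteroinferior
            self.glenoid_thickness_field = RadialField(
                center=1.2, edge=1.5,
                bias_ap=1.0 / np.sqrt(2), bias_si=-1.0 / np.sqrt(2),
                iso_weight=0.6,
            )
        if self.rigid_offset is None:
            self.rigid_offset = RigidTransform.identity()


@dataclass
class GroundTruth:
    """Per-compartment true thickness and strain on the pre bone vertices."""

    compartments: dict  # name -> dict(points, t_pre, t_post, strain)
    true_rigid_offset: RigidTransform

    def _cat(self, key: str) -> np.ndarray:
        return np.concatenate([c[key] for c in self.compartments.values()])

    @property
    def true_thickness_pre(self) -> np.ndarray:
        return self._cat("t_pre")

    @property
    def true_thickness_post(self) -> np.ndarray:
        return self._cat("t_post")

    @property
    def true_strain(self) -> np.ndarray:
        return self._cat("strain")


@dataclass
class Scene:
    """One session of a phantom subject: meshes plus their analytic sources."""

    session: str
    laterality: str
    meshes: dict        # label -> SurfaceMesh
    surfaces: dict      # label -> RadialSurface
    axis_ap: np.ndarray = None
    axis_si: np.ndarray = None
    axis_ml: np.ndarray = None


def _anatomical_axes(laterality: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sign = 1.0 if laterality == "right" else -1.0
    e_ap = np.array([0.0, sign, 0.0])
    e_si = np.array([0.0, 0.0, 1.0])
    e_ml = np.array([1.0, 0.0, 0.0])  # +x lateral
    return e_ap, e_si, e_ml


def _build_surfaces(spec: PhantomSpec, strain_on: bool):
    """Analytic surfaces (local frame, identity pose) for one session."""
    e_ap, e_si, _ = _anatomical_axes(spec.laterality)
    axis_medial = np.array([-1.0, 0.0, 0.0])
    out: dict[str, RadialSurface] = {}
    samples: dict[str, tuple] = {}

    def bounds(fn, domain):
        u = _fibonacci_sphere(20000)
        u = u[domain(u)]
        r = fn(u)
        return float(r.min()) - 0.3, float(r.max()) + 0.3

    if "humeral" in spec.compartments:
        R_h = spec.humeral_head_radius
        cosc = np.cos(np.deg2rad(_HUMERAL_CAP_HALF_ANGLE_DEG))
        sinc = np.sin(np.deg2rad(_HUMERAL_CAP_HALF_ANGLE_DEG))
        center_h = np.array([-3.5, 0.0, 0.0])

        def dom_h(u):
            return u @ axis_medial >= cosc

        def coords_h(u):
            return (u @ e_ap) / sinc, (u @ e_si) / sinc

        t_field = field_from_spec(spec.humeral_thickness_field)
        s_field = field_from_spec(spec.humeral_strain_field)
        u_s = _fibonacci_sphere(20000)
        u_s = u_s[dom_h(u_s)]
        ap_s, si_s = coords_h(u_s)
        t_field.bind(ap_s, si_s)
        s_field.bind(ap_s, si_s)
        _check_strain(s_field, ap_s, si_s, "humeral_strain_field")

        def r_bone_h(u):
            return R_h * (1.0 + _ASPHERICITY_AMPLITUDE * _asphericity(u))

        def r_cart_h(u, t_field=t_field, s_field=s_field, strain_on=strain_on):
            ap, si = coords_h(u)
            t = t_field(ap, si)
            if strain_on:
                t = t * (1.0 - s_field(ap, si))
            return r_bone_h(u) + t

        out["humeral_bone"] = RadialSurface(center_h, r_bone_h, dom_h, bounds(r_bone_h, dom_h))
        out["humeral_cartilage"] = RadialSurface(center_h, r_cart_h, dom_h, bounds(r_cart_h, dom_h))
        samples["humeral"] = (center_h, dom_h, coords_h, r_bone_h, t_field, s_field)

    if "glenoid" in spec.compartments:
        R_g = spec.glenoid_radius_of_curvature
        a_ap = spec.glenoid_extent_ap / 2.0
        a_si = spec.glenoid_extent_si / 2.0
        center_g = np.zeros(3)

        def dom_g(u):
            uap = u @ e_ap
            usi = u @ e_si
            return (u @ axis_medial > 0) & (
                (R_g * uap / a_ap) ** 2 + (R_g * usi / a_si) ** 2 <= 1.0
            )

        def coords_g(u):
            return R_g * (u @ e_ap) / a_ap, R_g * (u @ e_si) / a_si

        t_field = field_from_spec(spec.glenoid_thickness_field)
        s_field = field_from_spec(spec.glenoid_strain_field)
        u_s = _fibonacci_sphere(40000)
        u_s = u_s[dom_g(u_s)]
        ap_s, si_s = coords_g(u_s)
        t_field.bind(ap_s, si_s)
        s_field.bind(ap_s, si_s)
        _check_strain(s_field, ap_s, si_s, "glenoid_strain_field")

        def r_bone_g(u):
            return R_g * (1.0 + _ASPHERICITY_AMPLITUDE * _asphericity(u))

        def r_cart_g(u, t_field=t_field, s_field=s_field, strain_on=strain_on):
            ap, si = coords_g(u)
            t = t_field(ap, si)
            if strain_on:
                t = t * (1.0 - s_field(ap, si))
            return r_bone_g(u) - t  # socket: cartilage sits on the concave side

        out["glenoid_bone"] = RadialSurface(center_g, r_bone_g, dom_g, bounds(r_bone_g, dom_g))
        out["glenoid_cartilage"] = RadialSurface(center_g, r_cart_g, dom_g, bounds(r_cart_g, dom_g))
        samples["glenoid"] = (center_g, dom_g, coords_g, r_bone_g, t_field, s_field)

    return out, samples


def _check_strain(s_field: ScalarField, ap, si, name: str) -> None:
    vals = s_field(ap, si)
    if np.any(vals < 0.0) or np.any(vals >= 1.0):
        raise ValueError(f"{name} values must lie in [0, 1); got range "
                         f"[{vals.min():.3f}, {vals.max():.3f}]")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _mesh_from_surface(surface: RadialSurface, label: str, spacing: float,
                       point_spacing: float) -> SurfaceMesh:
    """Noise-free exact slicing followed by lofting."""
    z_lo, z_hi = surface.z_range()
    ks = np.arange(np.ceil(z_lo / spacing), np.floor(z_hi / spacing) + 1)
    contours = []
    for k in ks:
        z = float(k * spacing)
        for pts, closed in surface.section_z(z, point_spacing):
            if len(pts) < (3 if closed else 2):
                continue
            try:
                contours.append(Contour(z=z, label=label, points=pts[:, :2], closed=closed))
            except ValueError:
                continue  # degenerate near-tangent section
    stack = ContourStack(subject="phantom", session="pre", laterality="right",
                         slice_spacing=spacing, contours=contours)
    return reconstruct_surface(stack, label)


def generate_phantom(spec: PhantomSpec):
    """Build pre and post scenes plus exact ground truth.

    Returns ``(pre, post, truth)``.  The post-session cartilage thickness
    equals the pre thickness scaled by ``1 - strain`` at each surface
    point, and the whole post scene is rigidly moved by
    ``spec.rigid_offset``.  Ground truth fields live on the pre bone mesh
    vertices of each compartment's cartilage footprint.
    """
    e_ap, e_si, e_ml = _anatomical_axes(spec.laterality)
    pre_surfaces, samples = _build_surfaces(spec, strain_on=False)
    post_surfaces, _ = _build_surfaces(spec, strain_on=True)
    off = spec.rigid_offset
    post_surfaces = {k: s.with_pose(off.rotation, off.translation) for k, s in post_surfaces.items()}

    def make_meshes(surfaces):
        return {
            label: _mesh_from_surface(surf, label, spec.contour_slice_spacing,
                                      spec.in_plane_point_spacing)
            for label, surf in surfaces.items()
        }

    pre = Scene("pre", spec.laterality, make_meshes(pre_surfaces), pre_surfaces,
                axis_ap=e_ap, axis_si=e_si, axis_ml=e_ml)
    post = Scene("post", spec.laterality, make_meshes(post_surfaces), post_surfaces,
                 axis_ap=e_ap, axis_si=e_si, axis_ml=e_ml)

    truth_comp = {}
    for name, (center, dom, coords, r_bone, t_field, s_field) in samples.items():
        bone_mesh = pre.meshes[f"{name}_bone"]
        v = bone_mesh.vertices
        d = v - center
        u = d / np.linalg.norm(d, axis=1, keepdims=True)
        mask = dom(u)
        ap, si = coords(u[mask])
        t_pre = t_field(ap, si)
        s = s_field(ap, si)
        t_post = t_pre * (1.0 - s)
        truth_comp[name] = {
            "points": v[mask],
            "vertex_index": np.flatnonzero(mask),
            "t_pre": t_pre,
            "t_post": t_post,
            "strain": s,
        }
    truth = GroundTruth(truth_comp, off)
    return pre, post, truth


def slice_to_contours(scene, spacing: float, point_spacing: float, noise_sd: float,
                      seed: int, labels: Iterable[str] | None = None,
                      subject: str = "phantom", session: str = "pre",
                      laterality: str | None = None) -> ContourStack:
    """Section a scene (or dict of surfaces/meshes) into a noisy contour stack.

    Each surface is intersected with the parallel axial planes
    ``z = k * spacing``; each intersection is an ordered polyline with
    ~``point_spacing`` arc-length steps; an independent zero-mean Gaussian
    displacement of SD ``noise_sd`` is applied per point along the in-plane
    contour normal.  Identical seed and inputs give identical stacks.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if isinstance(scene, Scene):
        sources = scene.surfaces
        laterality = laterality if laterality is not None else scene.laterality
        session = scene.session
    else:
        sources = dict(scene)
        laterality = laterality or "right"
    if labels is not None:
        sources = {k: v for k, v in sources.items() if k in set(labels)}
    unknown = set(sources) - set(ALLOWED_LABELS)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}; allowed: {list(ALLOWED_LABELS)}")

    rng = np.random.default_rng(seed)
    contours: list[Contour] = []
    z_lims = []
    for surf in sources.values():
        if isinstance(surf, RadialSurface):
            pts = surf.points_from_directions(surf.sample_directions(8192))
            z_lims.append((float(pts[:, 2].min()), float(pts[:, 2].max())))
        else:
            v = np.asarray(surf.vertices)
            z_lims.append((float(v[:, 2].min()), float(v[:, 2].max())))
    z_lo = min(a for a, _ in z_lims) - 0.5
    z_hi = max(b for _, b in z_lims) + 0.5
    if spacing > (z_hi - z_lo):
        raise ValueError("no slices produced: spacing larger than object extent")
    ks = np.arange(np.ceil(z_lo / spacing), np.floor(z_hi / spacing) + 1)

    for label in sorted(sources):
        surf = sources[label]
        for k in ks:
            z = float(k * spacing)
            for pts, closed in _section_source(surf, z, point_spacing):
                if len(pts) < (3 if closed else 2):
                    continue
                xy = pts[:, :2].copy()
                if noise_sd > 0:
                    normals = _inplane_normals(xy, closed)
                    xy = xy + rng.normal(0.0, noise_sd, size=len(xy))[:, None] * normals
                try:
                    contours.append(Contour(z=z, label=label, points=xy, closed=closed))
                except ValueError:
                    continue  # degenerate near-tangent section

    if not contours:
        raise ValueError("no slices produced: spacing larger than object extent?")
    return ContourStack(subject=subject, session=session, laterality=laterality,
                        slice_spacing=spacing, contours=contours)


def _section_source(surf, z: float, point_spacing: float):
    if isinstance(surf, RadialSurface):
        return surf.section_z(z, point_spacing)
    tm = surf.to_trimesh() if isinstance(surf, SurfaceMesh) else surf
    path = tm.section(plane_origin=[0.0, 0.0, z], plane_normal=[0.0, 0.0, 1.0])
    if path is None:
        return []
    out = []
    for pts in path.discrete:
        pts = np.asarray(pts, dtype=float)
        closed = bool(np.allclose(pts[0], pts[-1]))
        if closed:
            pts = pts[:-1]
        n = max(3 if closed else 2, int(np.ceil(_arc_length(pts, closed) / point_spacing)))
        out.append((_resample3d(pts, closed, n), closed))
    return out


def _arc_length(pts: np.ndarray, closed: bool) -> float:
    p = np.vstack([pts, pts[:1]]) if closed else pts
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def _resample3d(pts: np.ndarray, closed: bool, n: int) -> np.ndarray:
    from .geometry import _resample
    return _resample(pts, closed, n)


def _inplane_normals(xy: np.ndarray, closed: bool) -> np.ndarray:
    if closed:
        tang = np.roll(xy, -1, axis=0) - np.roll(xy, 1, axis=0)
    else:
        tang = np.empty_like(xy)
        tang[1:-1] = xy[2:] - xy[:-2]
        tang[0] = xy[1] - xy[0]
        tang[-1] = xy[-1] - xy[-2]
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])
    lens = np.linalg.norm(norm, axis=1, keepdims=True)
    return norm / np.maximum(lens, 1e-300)
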