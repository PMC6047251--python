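"""Cartilage thickness maps on the bone surface and segmentation repeatability.

Thickness at a bone vertex is the Euclidean distance to the nearest vertex
of the cartilage articular (outer) surface — the same nearest-vertex
definition used to build the study's thickness maps.  The cartilage
footprint is the set of bone vertices whose nearest cartilage vertex lies
within a cutoff (default 5 mm, comfortably above any plausible thickness)
and in front of the bone surface (outward normal toward the match).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import ContourStack, SurfaceMesh, reconstruct_surface


@dataclass
class ThicknessConfig:
    footprint_cutoff: float = 5.0   # mm
    use_point_to_triangle: bool = False  # refinement: distance to cartilage triangles


@dataclass
class ThicknessMap:
    """Per-bone-vertex thickness scalar field (NaN outside the footprint)."""

    bone: SurfaceMesh
    thickness: np.ndarray  # (n_vertices,), NaN where unmasked
    mask: np.ndarray       # (n_vertices,) bool

    @property
    def mean_thickness(self) -> float:
        return float(np.mean(self.thickness[self.mask]))

    def masked_vertices(self) -> np.ndarray:
        return self.bone.vertices[self.mask]


def _oriented_normals(bone: SurfaceMesh, cartilage_tree: cKDTree,
                      dist: np.ndarray, direction: np.ndarray,
                      cutoff: float) -> np.ndarray:
    """Vertex normals with a consistent outward (cartilage-facing) sign.

    For watertight meshes trimesh yields outward normals directly.  Open
    sheets have consistent winding from lofting but an ambiguous global
    sign; the sign producing the larger cartilage footprint is the one
    facing the joint.
    """
    tm = bone.to_trimesh()
    normals = np.asarray(tm.vertex_normals, dtype=float)
    if tm.is_watertight:
        if tm.volume < 0:
            normals = -normals
        return normals
    near = dist < cutoff
    dots = np.einsum("ij,ij->i", normals, direction)
    plus = np.count_nonzero(near & (dots > 0))
    minus = np.count_nonzero(near & (dots < 0))
    return normals if plus >= minus else -normals


def compute_thickness_map(bone: SurfaceMesh, cartilage: SurfaceMesh,
                          config: ThicknessConfig | None = None) -> ThicknessMap:
    """Nearest-cartilage-vertex distance at every bone vertex, with footprint mask."""
    config = config or ThicknessConfig()
    if cartilage.is_empty:
        raise ValueError("cartilage mesh is empty")
    if bone.is_empty:
        raise ValueError("bone mesh is empty")
    tree = cKDTree(cartilage.vertices)
    dist, idx = tree.query(bone.vertices, workers=-1)
    direction = cartilage.vertices[idx] - bone.vertices
    normals = _oriented_normals(bone, tree, dist, direction, config.footprint_cutoff)
    dots = np.einsum("ij,ij->i", normals, direction)
    mask = (dist < config.footprint_cutoff) & ((dots > 0) | (dist <= 1e-12))
    if not np.any(mask):
        raise ValueError("no cartilage footprint: no bone vertex faces cartilage within cutoff")
    thickness = np.full(len(bone.vertices), np.nan)
    if config.use_point_to_triangle:
        thickness[mask] = _point_to_surface_distance(bone.vertices[mask], cartilage)
    else:
        thickness[mask] = dist[mask]
    return ThicknessMap(bone=bone, thickness=thickness, mask=mask)


def _closest_point_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                                c: np.ndarray) -> np.ndarray:
    """Vectorized closest point on triangles (a, b, c) to points p (all (n, 3))."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(cond, value):
        nonlocal done
        sel = cond & ~done
        out[sel] = value[sel]
        done |= sel

    assign((d1 <= 0) & (d2 <= 0), a)                               # vertex a
    assign((d3 >= 0) & (d4 <= d3), b)                              # vertex b
    assign((d6 >= 0) & (d5 <= d6), c)                              # vertex c
    vc = d1 * d4 - d3 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)   # edge ab
    vb = d5 * d2 - d1 * d6
    with np.errstate(invalid="ignore", divide="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)   # edge ac
    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + w_bc[:, None] * (c - b))                                 # edge bc
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    assign(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)  # interior
    return out


def _point_to_surface_distance(points: np.ndarray, surface: SurfaceMesh,
                               n_candidates: int = 12) -> np.ndarray:
    """Exact distance to the triangulated surface via nearby-triangle search."""
    tri = surface.vertices[surface.faces]
    centroids = tri.mean(axis=1)
    k = min(n_candidates, len(tri))
    _, cand = cKDTree(centroids).query(points, k=k, workers=-1)
    cand = np.atleast_2d(cand.T).T.reshape(len(points), k)
    p_rep = np.repeat(points, k, axis=0)
    tris = tri[cand.ravel()]
    closest = _closest_point_on_triangles(p_rep, tris[:, 0], tris[:, 1], tris[:, 2])
    d = np.linalg.norm(p_rep - closest, axis=1).reshape(len(points), k)
    return d.min(axis=1)


def compute_repeatability(repeated_stacks: list[ContourStack], bone_label: str,
                          cartilage_label: str,
                          config: ThicknessConfig | None = None) -> tuple[float, float]:
    """Segmentation repeatability from repeated contour stacks of one anatomy.

    Each repetition is reconstructed and thickness-mapped; the result is
    ``(sd_mm, strain_equivalent_percent)`` where ``sd_mm`` is the standard
    deviation of the mean masked thickness across repetitions and the
    strain equivalent expresses it as a percentage of the pooled mean
    thickness.
    """
    if len(repeated_stacks) < 2:
        raise ValueError("need >= 2 repeated segmentations")
    means = []
    for stack in repeated_stacks:
        bone = reconstruct_surface(stack, bone_label)
        cart = reconstruct_surface(stack, cartilage_label)
        means.append(compute_thickness_map(bone, cart, config).mean_thickness)
    means = np.asarray(means)
    sd_mm = float(np.std(means, ddof=1))
    pooled = float(np.mean(means))
    return sd_mm, 100.0 * sd_mm / pooled


def strain_equivalent(sd_mm: float, pooled_mean_thickness_mm: float) -> float:
    """Express a thickness repeatability SD as percent strain of the pooled mean."""
    if pooled_mean_thickness_mm <= 0:
        raise ValueError("pooled mean thickness must be > 0")
    return 100.0 * sd_mm / pooled_mean_thickness_mm
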