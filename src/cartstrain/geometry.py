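"""Contour stacks, surface meshes, their file formats, and reconstruction.

The raw input of the pipeline is a labeled contour stack: for each axial
slice (``z = const``, 0.5 mm apart) an ordered point list per tissue
(humeral bone, humeral cartilage, glenoid bone, glenoid cartilage), as a
manual MRI segmentation would produce.  Bone contours are closed rings,
cartilage contours may be open arcs.  Reconstruction lofts adjacent
contours into a triangulated surface: each contour is resampled by arc
length, corresponded to its neighbour (cyclic-shift alignment for rings,
endpoint alignment for arcs), optionally refined with interpolated
intermediate rings, and stitched with triangle strips.  Vertices of the
reconstructed surface lie on the input contours, so no systematic offset
enters downstream thickness maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

ALLOWED_LABELS = ("humeral_bone", "humeral_cartilage", "glenoid_bone", "glenoid_cartilage")
SESSIONS = ("pre", "post")
LATERALITIES = ("left", "right")

_DUP_TOL = 1e-9


# --------------------------------------------------------------------- types
@dataclass
class Contour:
    """One ordered in-plane point list at height ``z`` (mm)."""

    z: float
    label: str
    points: np.ndarray  # (n, 2) mm
    closed: bool

    def __post_init__(self):
        if self.label not in ALLOWED_LABELS:
            raise ValueError(f"unknown label {self.label!r}; allowed: {list(ALLOWED_LABELS)}")
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        n_min = 3 if self.closed else 2
        if len(self.points) < n_min:
            raise ValueError(
                f"contour at z={self.z} needs >= {n_min} points ({'closed' if self.closed else 'open'}), "
                f"got {len(self.points)}"
            )
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= _DUP_TOL):
            raise ValueError(f"contour at z={self.z} has consecutive duplicate points")

    def points3d(self) -> np.ndarray:
        return np.column_stack([self.points, np.full(len(self.points), self.z)])


@dataclass
class ContourStack:
    """Labeled contour geometry for one subject and session."""

    subject: str
    session: str
    laterality: str
    slice_spacing: float
    contours: list = field(default_factory=list)

    def __post_init__(self):
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}, got {self.laterality!r}")
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be > 0")
        self.contours = sorted(self.contours, key=lambda c: (c.z, c.label))
        zs = self.z_values()
        if len(zs) >= 2:
            gaps = np.diff(zs)
            steps = np.round(gaps / self.slice_spacing)
            if np.any(np.abs(gaps - steps * self.slice_spacing) > 1e-6):
                raise ValueError("slice z values are not uniform multiples of slice_spacing")

    def z_values(self) -> np.ndarray:
        return np.unique(np.round([c.z for c in self.contours], 9))

    def contours_for(self, label: str) -> list:
        if label not in ALLOWED_LABELS:
            raise ValueError(f"unknown label {label!r}; allowed: {list(ALLOWED_LABELS)}")
        return [c for c in self.contours if c.label == label]


@dataclass
class SurfaceMesh:
    """Triangulated surface in mm."""

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray     # (m, 3) int
    label: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.to_trimesh().vertex_normals, dtype=float)

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0 or len(self.faces) == 0

    def drop_degenerate(self) -> "SurfaceMesh":
        """Remove zero-area faces and unreferenced vertices."""
        v, f = self.vertices, self.faces
        a = v[f[:, 1]] - v[f[:, 0]]
        b = v[f[:, 2]] - v[f[:, 0]]
        area2 = np.linalg.norm(np.cross(a, b), axis=1)
        f = f[area2 > 2e-12]
        used = np.unique(f)
        remap = -np.ones(len(v), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return SurfaceMesh(v[used], remap[f], self.label)


# ----------------------------------------------------------------- stack I/O
def write_contour_stack(stack: ContourStack, path) -> None:
    by_z: dict[float, list] = {}
    for c in stack.contours:
        by_z.setdefault(float(c.z), []).append(c)
    doc = {
        "subject": stack.subject,
        "session": stack.session,
        "laterality": stack.laterality,
        "slice_spacing_mm": stack.slice_spacing,
        "slices": [
            {
                "z_mm": z,
                "contours": [
                    {"label": c.label, "closed": bool(c.closed), "points_mm": c.points.tolist()}
                    for c in cs
                ],
            }
            for z, cs in sorted(by_z.items())
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_contour_stack(path) -> ContourStack:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed contour stack JSON in {path}: {e}") from e
    try:
        contours = [
            Contour(
                z=float(sl["z_mm"]),
                label=c["label"],
                points=np.asarray(c["points_mm"], dtype=float),
                closed=bool(c["closed"]),
            )
            for sl in doc["slices"]
            for c in sl["contours"]
        ]
        return ContourStack(
            subject=doc["subject"],
            session=doc["session"],
            laterality=doc["laterality"],
            slice_spacing=float(doc["slice_spacing_mm"]),
            contours=contours,
        )
    except KeyError as e:
        raise ValueError(f"contour stack JSON in {path} is missing field {e}") from e


# ------------------------------------------------------------------ mesh I/O
def write_mesh(mesh: SurfaceMesh, path, scalars: np.ndarray | None = None) -> None:
    """Write PLY/OBJ/STL.  A per-vertex scalar channel is supported on PLY only."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        _write_ply(mesh, path, scalars)
    elif ext in (".obj", ".stl"):
        if scalars is not None:
            raise ValueError("per-vertex scalars are only supported on PLY")
        mesh.to_trimesh().export(str(path))
    else:
        raise ValueError(f"unsupported mesh extension {ext!r}; supported: .ply .obj .stl")


def read_mesh(path, label: str = "") -> tuple[SurfaceMesh, np.ndarray | None]:
    """Read PLY/OBJ/STL; returns (mesh, scalar channel or None).

    STL stores triangle soup; its vertices are merged within 1e-6 mm.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        return _read_ply(path, label)
    if ext in (".obj", ".stl"):
        tm = trimesh.load(str(path), process=False, force="mesh")
        if ext == ".stl":
            tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), label), None
    raise ValueError(f"unsupported mesh extension {ext!r}; supported: .ply .obj .stl")


def _write_ply(mesh: SurfaceMesh, path: Path, scalars: np.ndarray | None) -> None:
    n, m = len(mesh.vertices), len(mesh.faces)
    lines = ["ply", "format ascii 1.0", f"element vertex {n}"]
    lines += ["property double x", "property double y", "property double z"]
    if scalars is not None:
        scalars = np.asarray(scalars, dtype=float)
        if len(scalars) != n:
            raise ValueError("scalar channel length must match vertex count")
        lines.append("property double thickness_mm")
    lines += [f"element face {m}", "property list uchar int vertex_indices", "end_header"]
    body = []
    for i in range(n):
        row = " ".join(repr(float(x)) for x in mesh.vertices[i])
        if scalars is not None:
            row += f" {float(scalars[i])!r}"
        body.append(row)
    for f in mesh.faces:
        body.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines + body) + "\n")


def _read_ply(path: Path, label: str) -> tuple[SurfaceMesh, np.ndarray | None]:
    text = path.read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise ValueError(f"{path} is not a PLY file")
    i, n_v, n_f, props, in_vertex = 1, 0, 0, [], False
    fmt = None
    while i < len(text):
        tok = text[i].split()
        i += 1
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if tok[1] == "vertex":
                n_v = int(tok[2])
            elif tok[1] == "face":
                n_f = int(tok[2])
        elif tok[0] == "property" and in_vertex and tok[1] != "list":
            props.append(tok[2])
        elif tok[0] == "end_header":
            break
    if fmt != "ascii":
        tm = trimesh.load(str(path), process=False, force="mesh")
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), label), None
    vdata = np.array([[float(x) for x in text[i + k].split()] for k in range(n_v)])
    faces = []
    for k in range(n_f):
        tok = text[i + n_v + k].split()
        if int(tok[0]) != 3:
            raise ValueError("only triangular faces are supported")
        faces.append([int(tok[1]), int(tok[2]), int(tok[3])])
    cols = {p: vdata[:, j] for j, p in enumerate(props)}
    verts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    scal = cols.get("thickness_mm")
    return SurfaceMesh(verts, np.asarray(faces, dtype=np.int64), label), scal


# ------------------------------------------------------------ reconstruction
def _polyline_lengths(pts: np.ndarray, closed: bool) -> np.ndarray:
    p = np.vstack([pts, pts[:1]]) if closed else pts
    return np.linalg.norm(np.diff(p, axis=0), axis=1)


def _resample(pts: np.ndarray, closed: bool, n: int) -> np.ndarray:
    """Resample a polyline at n points uniformly by arc length."""
    seg = _polyline_lengths(pts, closed)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if closed:
        t = np.linspace(0.0, total, n, endpoint=False)
        ref = np.vstack([pts, pts[:1]])
    else:
        t = np.linspace(0.0, total, n)
        ref = pts
    idx = np.clip(np.searchsorted(s, t, side="right") - 1, 0, len(seg) - 1)
    frac = (t - s[idx]) / np.maximum(seg[idx], 1e-300)
    return ref[idx] + frac[:, None] * (ref[idx + 1] - ref[idx])


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _align_rings(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cyclically shift ring b (same length as a) to minimize sum|a-b|^2."""
    n = len(a)
    best_shift, best_cost = 0, np.inf
    costs = np.empty(n)
    for s in range(n):
        costs[s] = np.sum((a - np.roll(b, -s, axis=0)) ** 2)
    best_shift = int(np.argmin(costs))
    return np.roll(b, -best_shift, axis=0)


def _cap_apex(ring: np.ndarray, neighbor: np.ndarray) -> np.ndarray:
    """Apex point closing an end ring.

    Fits the circle through the mean radii of the end ring and its
    neighbour in the (radius, z) plane and places the apex where that
    circle meets the axis — exact for a sphere sectioned short of its
    pole.  Falls back to the planar ring centroid when the rings do not
    shrink toward the end or the extrapolation is unstable.
    """
    c_xy = ring[:, :2].mean(axis=0)
    z1, z2 = float(neighbor[0, 2]), float(ring[0, 2])
    rho1 = float(np.mean(np.linalg.norm(neighbor[:, :2] - neighbor[:, :2].mean(axis=0), axis=1)))
    rho2 = float(np.mean(np.linalg.norm(ring[:, :2] - c_xy, axis=1)))
    flat = np.array([c_xy[0], c_xy[1], z2])
    if rho2 >= rho1 or abs(z2 - z1) < 1e-12:
        return flat
    c = (rho2**2 + z2**2 - rho1**2 - z1**2) / (2.0 * (z2 - z1))
    r2 = rho2**2 + (z2 - c) ** 2
    if r2 <= 0:
        return flat
    apex_z = c + np.sign(z2 - z1) * np.sqrt(r2)
    if not np.isfinite(apex_z) or abs(apex_z - z2) > rho2:
        return flat
    return np.array([c_xy[0], c_xy[1], apex_z])


def reconstruct_surface(stack: ContourStack, label: str, z_subdivisions: int = 1) -> SurfaceMesh:
    """Loft the contours of one tissue label into a triangulated surface.

    ``z_subdivisions`` intermediate rings are interpolated between adjacent
    slices so vertex spacing along z (0.5 mm slices -> 0.25 mm with the
    default of 1) is commensurate with the ~0.3 mm in-plane point spacing;
    nearest-vertex thickness bias scales with the square of the largest
    vertex gap.
    """
    contours = stack.contours_for(label)
    by_z: dict[float, list] = {}
    for c in contours:
        by_z.setdefault(float(np.round(c.z, 9)), []).append(c)
    zs = sorted(by_z)
    if len(zs) < 2:
        raise ValueError(f"insufficient contours: label {label!r} present on {len(zs)} slice(s), need >= 2")
    planes = []
    for z in zs:
        cs = by_z[z]
        if len(cs) > 1:
            raise ValueError(f"multiple {label!r} contours on slice z={z}; branching is not supported")
        planes.append(cs[0])

    closed = planes[0].closed
    if any(c.closed != closed for c in planes):
        raise ValueError(f"label {label!r} mixes open and closed contours across slices")

    # resample all contours to a common ring size
    n_ring = max(len(c.points) for c in planes)
    if closed:
        n_ring = max(n_ring, 3)
    rings2d = []
    for c in planes:
        pts = c.points
        if closed and _signed_area(pts) < 0:
            pts = pts[::-1]  # consistent CCW winding
        rings2d.append(_resample(pts, closed, n_ring))

    # correspondence propagates down the stack
    for i in range(1, len(rings2d)):
        prev, cur = rings2d[i - 1], rings2d[i]
        c_prev = prev.mean(axis=0)
        c_cur = cur.mean(axis=0)
        ext_prev = np.ptp(prev, axis=0)
        ext_cur = np.ptp(cur, axis=0)
        if np.linalg.norm(c_cur - c_prev) > 0.75 * (np.max(ext_prev) + np.max(ext_cur)):
            raise ValueError(
                f"non-overlapping adjacent contours for {label!r} between z={zs[i-1]} and z={zs[i]}"
            )
        if closed:
            rings2d[i] = _align_rings(prev, cur)
        else:
            fwd = np.sum((cur[[0, -1]] - prev[[0, -1]]) ** 2)
            rev = np.sum((cur[[-1, 0]] - prev[[0, -1]]) ** 2)
            if rev < fwd:
                rings2d[i] = cur[::-1]

    # build 3d rings with optional interpolated intermediates
    rings3d = []
    for i, z in enumerate(zs):
        ring_i = np.column_stack([rings2d[i], np.full(n_ring, z)])
        rings3d.append(ring_i)
        if i + 1 < len(zs):
            ring_n = np.column_stack([rings2d[i + 1], np.full(n_ring, zs[i + 1])])
            for k in range(1, z_subdivisions + 1):
                f = k / (z_subdivisions + 1)
                rings3d.append((1 - f) * ring_i + f * ring_n)

    verts = np.vstack(rings3d)
    n_levels = len(rings3d)
    faces = []
    for lev in range(n_levels - 1):
        base0 = lev * n_ring
        base1 = (lev + 1) * n_ring
        rng = np.arange(n_ring) if closed else np.arange(n_ring - 1)
        j = rng
        jn = (rng + 1) % n_ring if closed else rng + 1
        faces.append(np.column_stack([base0 + j, base1 + jn, base1 + j]))
        faces.append(np.column_stack([base0 + j, base0 + jn, base1 + jn]))
    faces = np.vstack(faces)

    if closed:
        # cap both ends with a fan; the apex extrapolates the osculating
        # sphere of the last two rings (exact for spherical ends, planar
        # fallback for cylinder-like ends)
        caps_v = []
        caps_f = []
        nv = len(verts)
        for lev, flip in ((0, True), (n_levels - 1, False)):
            nb = 1 if lev == 0 else n_levels - 2
            ring = verts[lev * n_ring:(lev + 1) * n_ring]
            neighbor = verts[nb * n_ring:(nb + 1) * n_ring]
            centroid = _cap_apex(ring, neighbor)
            ci = nv + len(caps_v)
            caps_v.append(centroid)
            j = np.arange(n_ring)
            jn = (j + 1) % n_ring
            tri = np.column_stack([np.full(n_ring, ci), lev * n_ring + j, lev * n_ring + jn])
            if flip:
                tri = tri[:, [0, 2, 1]]
            caps_f.append(tri)
        verts = np.vstack([verts, np.vstack(caps_v)])
        faces = np.vstack([faces, np.vstack(caps_f)])

    return SurfaceMesh(verts, faces, label).drop_degenerate()
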