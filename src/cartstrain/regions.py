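"""Anatomical sampling-region grids and regional strain statistics.

Regional thickness is averaged inside 2-mm-radius sampling regions laid
out on the cartilage footprint of the bone surface: a 3x3 grid on the
glenoid and a 2-band x (3x3) grid (18 regions) on the humeral head.
Region centres sit at the 20/50/80% quantiles of the footprint's
anteroposterior and superoinferior coordinates, snapped to the nearest
footprint vertex.  Strain in a region is the post-exercise thickness
change normalized to the pre-exercise thickness, positive in compression;
compartmental strain is the mean over that compartment's regions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import SurfaceMesh
from .thickness import ThicknessMap

REGION_RADIUS_MM = 2.0
AP_LABELS = ("anterior", "central", "posterior")
SI_LABELS = ("superior", "central", "inferior")
BAND_LABELS = ("superior", "inferior")
_QUANTILES = (0.8, 0.5, 0.2)  # anterior/superior first


@dataclass
class AnatomicalFrame:
    """Orthonormal anatomical axes fitted to the articular surface."""

    origin: np.ndarray
    axis_ap: np.ndarray
    axis_si: np.ndarray
    axis_ml: np.ndarray
    laterality: str

    def __post_init__(self):
        for name in ("axis_ap", "axis_si", "axis_ml"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v / np.linalg.norm(v))
        self.origin = np.asarray(self.origin, dtype=float)
        M = np.column_stack([self.axis_ap, self.axis_si, self.axis_ml])
        if np.linalg.norm(M.T @ M - np.eye(3)) > 1e-9:
            raise ValueError("anatomical axes are not orthonormal")
        if abs(abs(np.linalg.det(M)) - 1.0) > 1e-9:
            raise ValueError("anatomical axes are degenerate")

    def coords(self, points: np.ndarray) -> np.ndarray:
        """(ap, si, ml) coordinates of points, mm."""
        d = np.asarray(points, dtype=float) - self.origin
        return np.column_stack([d @ self.axis_ap, d @ self.axis_si, d @ self.axis_ml])


@dataclass
class Region:
    id: int
    center: np.ndarray
    radius: float
    ap_label: str
    si_label: str
    band: str | None = None


@dataclass
class RegionGrid:
    compartment: str  # "humeral" | "glenoid"
    regions: list

    def __post_init__(self):
        expected = 18 if self.compartment == "humeral" else 9
        if len(self.regions) != expected:
            raise ValueError(f"{self.compartment} grid must have {expected} regions, "
                             f"got {len(self.regions)}")


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Linear least-squares sphere fit; returns (center, radius)."""
    p = np.asarray(points, dtype=float)
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = np.einsum("ij,ij->i", p, p)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def fit_anatomical_frame(bone: SurfaceMesh, laterality: str,
                         compartment: str = "glenoid") -> AnatomicalFrame:
    """Anatomical axes from the articular surface geometry.

    The mediolateral axis is the mean surface normal of the articular face,
    obtained from a least-squares sphere fit: for the concave glenoid the
    curvature centre lies on the lateral (joint) side of the patch, and
    for the convex humeral head it lies medial to it, so
    ``normalize(centre - centroid)`` points laterally in both cases.  The
    superoinferior axis is the footprint's principal axis orthogonalized
    against mediolateral (superior toward +z), and anteroposterior
    completes the frame with the anterior sign set by laterality.
    """
    if bone.is_empty:
        raise ValueError("cannot fit a frame to an empty mesh")
    v = bone.vertices
    centroid = v.mean(axis=0)
    sphere_c, _ = _fit_sphere(v)
    ml = sphere_c - centroid
    n = np.linalg.norm(ml)
    if n < 1e-9:
        raise ValueError("ambiguous orientation: surface has no preferred normal")
    ml /= n

    d = v - centroid
    tang = d - np.outer(d @ ml, ml)
    cov = np.cov(tang.T)
    w, vecs = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, vecs = w[order], vecs[:, order]
    if (w[0] - w[1]) / max(w[0], 1e-300) < 0.01:
        raise ValueError("ambiguous orientation: footprint principal axes are isotropic within 1%")
    si = vecs[:, 0] - (vecs[:, 0] @ ml) * ml
    si /= np.linalg.norm(si)
    if si[2] < 0:
        si = -si
    ap = np.cross(si, ml)
    if laterality == "left":
        ap = -ap
    return AnatomicalFrame(origin=centroid, axis_ap=ap, axis_si=si, axis_ml=ml,
                           laterality=laterality)


def build_region_grid(footprint_points: np.ndarray, frame: AnatomicalFrame,
                      compartment: str, layout: list | None = None) -> RegionGrid:
    """Place the 2-mm sampling regions on the cartilage footprint.

    Glenoid: 3x3 tensor grid at the {20, 50, 80}% quantiles of the
    footprint's AP and SI coordinates.  Humeral head: 2 SI bands split at
    the median, each with its own 3 (AP) x 3 (within-band SI) quantile
    grid, 18 regions total.  Centres are snapped to the nearest footprint
    vertex.  ``layout`` optionally overrides the humeral default with an
    explicit list of (ap_quantile, si_quantile, ap_label, si_label, band)
    tuples evaluated on the whole footprint.
    """
    pts = np.asarray(footprint_points, dtype=float)
    if len(pts) == 0:
        raise ValueError("footprint is empty")
    co = frame.coords(pts)
    ap, si = co[:, 0], co[:, 1]

    def snap(ap0, si0):
        d2 = (ap - ap0) ** 2 + (si - si0) ** 2
        return pts[int(np.argmin(d2))]

    regions: list[Region] = []
    if compartment == "glenoid":
        ap_centers = np.quantile(ap, _QUANTILES)
        si_centers = np.quantile(si, _QUANTILES)
        rid = 1
        for i, (si_c, si_lab) in enumerate(zip(si_centers, SI_LABELS)):
            for j, (ap_c, ap_lab) in enumerate(zip(ap_centers, AP_LABELS)):
                regions.append(Region(rid, snap(ap_c, si_c), REGION_RADIUS_MM, ap_lab, si_lab))
                rid += 1
    elif compartment == "humeral":
        if layout is not None:
            for rid, (ap_q, si_q, ap_lab, si_lab, band) in enumerate(layout, start=1):
                regions.append(Region(rid, snap(np.quantile(ap, ap_q), np.quantile(si, si_q)),
                                      REGION_RADIUS_MM, ap_lab, si_lab, band))
        else:
            si_median = np.median(si)
            rid = 1
            for band, band_mask in zip(BAND_LABELS, (si >= si_median, si < si_median)):
                ap_b, si_b = ap[band_mask], si[band_mask]
                ap_centers = np.quantile(ap_b, _QUANTILES)
                si_centers = np.quantile(si_b, _QUANTILES)
                for si_c, si_lab in zip(si_centers, SI_LABELS):
                    for ap_c, ap_lab in zip(ap_centers, AP_LABELS):
                        regions.append(Region(rid, snap(ap_c, si_c), REGION_RADIUS_MM,
                                              ap_lab, band, band))
                        rid += 1
    else:
        raise ValueError(f"unknown compartment {compartment!r}")

    centers = np.array([r.center for r in regions])
    if len(centers) > 1:
        from scipy.spatial.distance import pdist
        if np.min(pdist(centers)) < 2.0 * REGION_RADIUS_MM:
            warnings.warn(f"{compartment} footprint is small: 2-mm sampling regions overlap",
                          stacklevel=2)
    return RegionGrid(compartment=compartment, regions=regions)


def region_mean_thickness(tmap: ThicknessMap, grid: RegionGrid) -> pd.DataFrame:
    """Mean masked thickness within 2 mm of each region centre.

    Returns a frame with one row per region; regions containing no masked
    vertex are flagged missing (NaN mean).
    """
    pts = tmap.bone.vertices[tmap.mask]
    vals = tmap.thickness[tmap.mask]
    rows = []
    for r in grid.regions:
        d2 = np.sum((pts - r.center) ** 2, axis=1)
        sel = d2 <= r.radius**2
        rows.append({
            "region_id": r.id,
            "ap_label": r.ap_label,
            "si_label": r.si_label,
            "band": r.band or "",
            "n_vertices": int(np.count_nonzero(sel)),
            "mean_thickness_mm": float(np.mean(vals[sel])) if np.any(sel) else np.nan,
            "missing": not bool(np.any(sel)),
        })
    df = pd.DataFrame(rows)
    if df["missing"].all():
        raise ValueError("all sampling regions are empty")
    return df


@dataclass
class StrainTable:
    """Per-subject regional strains plus compartment summaries."""

    rows: pd.DataFrame  # subject, compartment, region_id, ap_label, si_label, band, t_pre, t_post, strain
    summaries: dict = dc_field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def save_summary(self, path) -> None:
        Path(path).write_text(json.dumps(self.summaries, indent=1))


def _t_ci_half_width(values: np.ndarray, confidence: float = 0.95) -> float:
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        return float("nan")
    sem = np.std(values, ddof=1) / np.sqrt(n)
    return float(sps.t.ppf(0.5 + confidence / 2.0, n - 1) * sem)


def compute_strain_table(pre_maps: dict, post_maps: dict, grids: dict,
                         subjects: list[str]) -> StrainTable:
    """Regional and compartmental strain across subjects.

    ``pre_maps[subject][compartment]`` and ``post_maps`` are region-mean
    thickness frames (both computed on the registered pre-session bone
    mesh); ``grids[subject][compartment]`` the matching grids.  Strain is
    ``(t_pre - t_post) / t_pre`` per region, positive in compression.
    Compartment summaries report the across-subject mean of per-subject
    regional means with a t-distribution 95% CI, both for the mean of
    regional strains (the study's definition) and, separately labeled, for
    the strain of compartment-mean thicknesses.
    """
    rows = []
    for subj in subjects:
        for comp, pre_df in pre_maps[subj].items():
            post_df = post_maps[subj][comp]
            merged = pre_df.merge(post_df, on=["region_id", "ap_label", "si_label", "band"],
                                  suffixes=("_pre", "_post"))
            for _, r in merged.iterrows():
                t_pre = r["mean_thickness_mm_pre"]
                t_post = r["mean_thickness_mm_post"]
                if np.isfinite(t_pre) and t_pre <= 0:
                    raise ValueError(f"non-positive pre-exercise thickness in subject {subj}, "
                                     f"{comp} region {int(r['region_id'])}")
                rows.append({
                    "subject": subj,
                    "compartment": comp,
                    "region_id": int(r["region_id"]),
                    "ap_label": r["ap_label"],
                    "si_label": r["si_label"],
                    "band": r["band"],
                    "t_pre": t_pre,
                    "t_post": t_post,
                    "strain": (t_pre - t_post) / t_pre,
                })
    df = pd.DataFrame(rows)
    summaries = {}
    for comp, g in df.groupby("compartment"):
        per_subject = g.groupby("subject")["strain"].mean()
        mean_of_means = g.groupby("subject").apply(
            lambda s: (s["t_pre"].mean() - s["t_post"].mean()) / s["t_pre"].mean(),
            include_groups=False)
        summaries[comp] = {
            "mean_strain": float(per_subject.mean()),
            "ci95_half_width": _t_ci_half_width(per_subject.values),
            "mean_strain_of_mean_thickness": float(mean_of_means.mean()),
            "mean_t_pre_mm": float(g.groupby("subject")["t_pre"].mean().mean()),
            "mean_t_post_mm": float(g.groupby("subject")["t_post"].mean().mean()),
            "n_subjects": int(per_subject.size),
        }
    return StrainTable(rows=df, summaries=summaries)
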