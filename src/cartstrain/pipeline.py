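"""End-to-end orchestration: contours -> surfaces -> registration -> strain -> stats.

A subject run reconstructs the labeled surfaces of both sessions, aligns
each post-exercise bone to its pre-exercise counterpart with ICP, carries
the post cartilage through the recovered transform, computes both
thickness maps on the pre bone vertices, and aggregates them on the
anatomical region grids.  A cohort run repeats this per subject (collecting
failures rather than aborting), concatenates the regional strain table and
runs the repeated-measures statistics.  Every stage is deterministic given
the configuration and seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .geometry import ContourStack, reconstruct_surface, write_mesh
from .phantom import PhantomSpec, generate_phantom, slice_to_contours
from .registration import ICPConfig, apply_transform, icp_align
from .regions import (
    build_region_grid,
    compute_strain_table,
    fit_anatomical_frame,
    region_mean_thickness,
)
from .stats import pearson_corr, rm_anova, tukey_posthoc
from .thickness import ThicknessConfig, compute_thickness_map

log = logging.getLogger("cartstrain")

_LABELS = {
    "humeral": ("humeral_bone", "humeral_cartilage"),
    "glenoid": ("glenoid_bone", "glenoid_cartilage"),
}


@dataclass
class RunConfig:
    compartments: tuple = ("humeral", "glenoid")
    icp: ICPConfig = dc_field(default_factory=ICPConfig)
    thickness: ThicknessConfig = dc_field(default_factory=ThicknessConfig)
    z_subdivisions: int = 1
    humeral_layout: list | None = None
    seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["output_dir"] = str(d["output_dir"]) if d["output_dir"] else None
        return d


@dataclass
class SubjectResult:
    subject: str
    pre_region_means: dict   # compartment -> DataFrame
    post_region_means: dict
    grids: dict
    registrations: dict      # compartment -> RegistrationReport
    frame: object


def run_subject(pre: ContourStack, post: ContourStack, config: RunConfig | None = None) -> SubjectResult:
    """Full single-subject pipeline from two contour stacks.

    The post-session thickness map is evaluated at the pre-session bone
    vertices after the post cartilage has been moved by the bone ICP
    transform, so regional pre/post comparisons are site-specific.
    """
    config = config or RunConfig()
    if pre.subject != post.subject:
        raise ValueError(f"session stacks belong to different subjects: "
                         f"{pre.subject!r} vs {post.subject!r}")
    subject = pre.subject
    available = [c for c in config.compartments
                 if pre.contours_for(_LABELS[c][0]) and post.contours_for(_LABELS[c][0])]
    if not available:
        raise ValueError(f"subject {subject}: no requested compartment present in both stacks")

    outdir = Path(config.output_dir) / subject if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    pre_maps, post_maps, grids, registrations = {}, {}, {}, {}
    pre_bones = {}
    try:
        for comp in available:
            bone_label, cart_label = _LABELS[comp]
            t0 = time.perf_counter()
            pre_bone = reconstruct_surface(pre, bone_label, config.z_subdivisions)
            pre_cart = reconstruct_surface(pre, cart_label, config.z_subdivisions)
            post_bone = reconstruct_surface(post, bone_label, config.z_subdivisions)
            post_cart = reconstruct_surface(post, cart_label, config.z_subdivisions)
            pre_bones[comp] = pre_bone

            report = icp_align(post_bone, pre_bone, config.icp)
            registrations[comp] = report
            post_cart_aligned = apply_transform(post_cart, report.transform)

            tmap_pre = compute_thickness_map(pre_bone, pre_cart, config.thickness)
            tmap_post = compute_thickness_map(pre_bone, post_cart_aligned, config.thickness)
            pre_maps[comp] = (tmap_pre, tmap_post)
            log.info("subject %s %s: icp rms %.4f mm in %d it, %.1fs", subject, comp,
                     report.rms_residual, report.iterations, time.perf_counter() - t0)

            if outdir:
                write_mesh(pre_bone, outdir / f"{comp}_bone_pre.ply")
                write_mesh(post_cart_aligned, outdir / f"{comp}_cartilage_post_aligned.ply")
                write_mesh(pre_bone, outdir / f"{comp}_thickness_pre.ply", tmap_pre.thickness)
                write_mesh(pre_bone, outdir / f"{comp}_thickness_post.ply", tmap_post.thickness)
                report.transform.save(outdir / f"{comp}_transform.json")

        frame_comp = "glenoid" if "glenoid" in available else "humeral"
        frame = fit_anatomical_frame(pre_bones[frame_comp], pre.laterality, frame_comp)

        region_pre, region_post = {}, {}
        for comp in available:
            tmap_pre, tmap_post = pre_maps[comp]
            layout = config.humeral_layout if comp == "humeral" else None
            grid = build_region_grid(tmap_pre.masked_vertices(), frame, comp, layout)
            grids[comp] = grid
            region_pre[comp] = region_mean_thickness(tmap_pre, grid)
            region_post[comp] = region_mean_thickness(tmap_post, grid)
            if outdir:
                region_pre[comp].to_csv(outdir / f"{comp}_regions_pre.csv", index=False)
                region_post[comp].to_csv(outdir / f"{comp}_regions_post.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"subject {subject}: {e}") from e

    return SubjectResult(subject=subject, pre_region_means=region_pre,
                         post_region_means=region_post, grids=grids,
                         registrations=registrations, frame=frame)


@dataclass
class CohortResult:
    strain_table: object      # StrainTable
    stats: dict
    failures: list
    subjects: list


def run_cohort(subject_stacks: list, config: RunConfig | None = None,
               covariates: dict | None = None) -> CohortResult:
    """Cohort pipeline over ``[(subject_id, pre_stack, post_stack), ...]``.

    Per-subject failures are collected (the run continues) and listed in
    the result.  ``covariates`` maps a name (e.g. ``"bmi"``) to a
    per-subject value dict for Pearson correlations against compartment
    strain.
    """
    config = config or RunConfig()
    if len(subject_stacks) < 3:
        raise ValueError(">= 3 subjects required for statistics")
    results, failures = {}, []
    for subject, pre, post in subject_stacks:
        try:
            results[subject] = run_subject(pre, post, config)
        except Exception as e:  # noqa: BLE001 - robustness contract
            log.warning("%s", e)
            failures.append({"subject": subject, "error": str(e)})
    if len(results) < 3:
        raise ValueError(f">= 3 successful subjects required; got {len(results)} "
                         f"({len(failures)} failed)")

    subjects = sorted(results)
    pre_maps = {s: results[s].pre_region_means for s in subjects}
    post_maps = {s: results[s].post_region_means for s in subjects}
    grids = {s: results[s].grids for s in subjects}
    table = compute_strain_table(pre_maps, post_maps, grids, subjects)

    stats: dict = {"compartments": table.summaries, "anova": {}, "tukey": {}, "pearson": {}}
    df = table.rows
    for comp, factor, name in (("glenoid", "ap_label", "glenoid_ap"),
                               ("glenoid", "si_label", "glenoid_si"),
                               ("humeral", "ap_label", "humeral_ap"),
                               ("humeral", "band", "humeral_si")):
        sub = df[df["compartment"] == comp]
        if sub.empty or sub[factor].nunique() < 2:
            continue
        res = rm_anova(sub, factor)
        stats["anova"][name] = {"F": res.F, "df": [res.df_num, res.df_den],
                                "p": res.p, "p_gg": res.p_gg, "eps_gg": res.eps_gg}
        if res.p < 0.05:
            stats["tukey"][name] = tukey_posthoc(sub, factor).to_dict("records")
        # regional means for reporting
        stats["anova"][name]["level_means"] = (
            sub.groupby([ "subject", factor], observed=True)["strain"].mean()
            .groupby(factor, observed=True).mean().to_dict())

    if covariates:
        for cov_name, values in covariates.items():
            for comp in df["compartment"].unique():
                per_subj = df[df["compartment"] == comp].groupby("subject")["strain"].mean()
                x = [values[s] for s in per_subj.index]
                r, p = pearson_corr(x, per_subj.values)
                stats["pearson"][f"{cov_name}_{comp}"] = {"r": r, "p": p}

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "strain_table.csv")
        (out / "stats.json").write_text(json.dumps(stats, indent=1, default=float))
        (out / "run_config.json").write_text(json.dumps(config.to_dict(), indent=1, default=str))
        (out / "manifest.json").write_text(json.dumps(
            {"subjects": subjects, "failures": failures}, indent=1))
    return CohortResult(strain_table=table, stats=stats, failures=failures, subjects=subjects)


# ------------------------------------------------------------------ phantoms
def phantom_subject_stacks(spec: PhantomSpec, subject: str = "phantom",
                           seed: int | None = None):
    """Generate one phantom subject's pre and post contour stacks.

    Independent noise streams for the two sessions are derived from the
    seed; the returned tuple also carries the ground truth.
    """
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_pre, s_post = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    pre_scene, post_scene, truth = generate_phantom(spec)
    pre = slice_to_contours(pre_scene, spec.contour_slice_spacing,
                            spec.in_plane_point_spacing, spec.noise_sd, s_pre,
                            subject=subject)
    post = slice_to_contours(post_scene, spec.contour_slice_spacing,
                             spec.in_plane_point_spacing, spec.noise_sd, s_post,
                             subject=subject)
    return pre, post, truth
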