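"""Anatomical frames, region grids, and strain-table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cartstrain.geometry import SurfaceMesh
from cartstrain.regions import (
    AnatomicalFrame,
    RegionGrid,
    build_region_grid,
    compute_strain_table,
    fit_anatomical_frame,
    region_mean_thickness,
)
from cartstrain.registration import RigidTransform, apply_transform
from cartstrain.thickness import ThicknessMap, compute_thickness_map


def _angle_deg(a, b):
    return np.degrees(np.arccos(np.clip(abs(np.dot(a, b)), -1, 1)))


@pytest.fixture(scope="module")
def glenoid_maps(glenoid_scene):
    pre, _, _ = glenoid_scene
    bone = pre.meshes["glenoid_bone"]
    tmap = compute_thickness_map(bone, pre.meshes["glenoid_cartilage"])
    frame = fit_anatomical_frame(bone, "right")
    return bone, tmap, frame


class TestAnatomicalFrame:
    def test_axes_match_generator_within_2_degrees(self, glenoid_scene, glenoid_maps):
        pre, _, _ = glenoid_scene
        _, _, frame = glenoid_maps
        assert _angle_deg(frame.axis_ml, pre.axis_ml) < 2.0
        assert _angle_deg(frame.axis_si, pre.axis_si) < 2.0
        assert _angle_deg(frame.axis_ap, pre.axis_ap) < 2.0

    def test_equivariance_under_rotation(self, glenoid_maps):
        bone, _, frame = glenoid_maps
        T = RigidTransform.from_axis_angle([0, 0, 1], 30.0, [5.0, 2.0, -1.0])
        frame2 = fit_anatomical_frame(apply_transform(bone, T), "right")
        for ax in ("axis_ml", "axis_si", "axis_ap"):
            assert _angle_deg(getattr(frame2, ax), T.rotation @ getattr(frame, ax)) < 2.0

    def test_left_flips_ap_only(self, glenoid_maps):
        bone, _, right = glenoid_maps
        left = fit_anatomical_frame(bone, "left")
        assert np.allclose(left.axis_ap, -right.axis_ap, atol=1e-12)
        assert np.allclose(left.axis_si, right.axis_si, atol=1e-12)
        assert np.allclose(left.axis_ml, right.axis_ml, atol=1e-12)

    def test_isotropic_footprint_rejected(self):
        # circularly symmetric spherical cap: no in-plane anisotropy
        theta = np.linspace(0.0, 2 * np.pi, 60, endpoint=False)
        rings = []
        for rho in (3.0, 6.0, 9.0, 12.0):
            x = -np.sqrt(900.0 - rho**2)
            rings.append(np.column_stack([
                np.full_like(theta, x), rho * np.cos(theta), rho * np.sin(theta)]))
        verts = np.vstack(rings)
        mesh = SurfaceMesh(verts, np.array([[0, 1, 2]]), "glenoid_bone")
        with pytest.raises(ValueError, match="ambiguous orientation"):
            fit_anatomical_frame(mesh, "right")


class TestRegionGrid:
    def test_glenoid_grid_has_nine_regions(self, glenoid_maps):
        _, tmap, frame = glenoid_maps
        grid = build_region_grid(tmap.masked_vertices(), frame, "glenoid")
        assert len(grid.regions) == 9
        assert all(r.radius == 2.0 for r in grid.regions)
        labels = {(r.ap_label, r.si_label) for r in grid.regions}
        assert len(labels) == 9

    def test_grid_count_contract_enforced(self):
        with pytest.raises(ValueError, match="9 regions"):
            RegionGrid("glenoid", [])

    def test_centers_lie_on_footprint(self, glenoid_maps):
        _, tmap, frame = glenoid_maps
        grid = build_region_grid(tmap.masked_vertices(), frame, "glenoid")
        fp = tmap.masked_vertices()
        for r in grid.regions:
            d = np.min(np.linalg.norm(fp - r.center, axis=1))
            assert d == 0.0

    def test_grid_equivariance(self, glenoid_maps):
        _, tmap, frame = glenoid_maps
        T = RigidTransform.from_axis_angle([0.3, 1.0, 0.2], 25.0, [8.0, -3.0, 4.0])
        fp = tmap.masked_vertices()
        grid = build_region_grid(fp, frame, "glenoid")
        frame_t = AnatomicalFrame(T.apply(frame.origin[None])[0],
                                  T.rotation @ frame.axis_ap,
                                  T.rotation @ frame.axis_si,
                                  T.rotation @ frame.axis_ml, "right")
        grid_t = build_region_grid(T.apply(fp), frame_t, "glenoid")
        for a, b in zip(grid.regions, grid_t.regions):
            assert np.allclose(T.apply(a.center[None])[0], b.center, atol=1e-6)
            assert (a.ap_label, a.si_label) == (b.ap_label, b.si_label)

    def test_humeral_grid_has_eighteen_regions(self, default_phantom):
        pre, _, _ = default_phantom
        bone = pre.meshes["humeral_bone"]
        tmap = compute_thickness_map(bone, pre.meshes["humeral_cartilage"])
        frame = fit_anatomical_frame(pre.meshes["glenoid_bone"], "right")
        grid = build_region_grid(tmap.masked_vertices(), frame, "humeral")
        assert len(grid.regions) == 18
        bands = [r.band for r in grid.regions]
        assert bands.count("superior") == 9 and bands.count("inferior") == 9


class TestRegionMeanThickness:
    def test_uniform_map_gives_uniform_means(self, glenoid_maps):
        bone, tmap, frame = glenoid_maps
        uniform = ThicknessMap(bone, np.where(tmap.mask, 1.0, np.nan), tmap.mask)
        grid = build_region_grid(uniform.masked_vertices(), frame, "glenoid")
        df = region_mean_thickness(uniform, grid)
        assert np.allclose(df.mean_thickness_mm, 1.0, atol=1e-12)
        assert not df.missing.any()

    def test_step_field_region_mean_is_weighted_average(self):
        # planar grid mesh, thickness 1.0 for y<0 and 1.4 for y>0, region at origin
        xs = np.arange(-3.0, 3.01, 0.25)
        ys = np.arange(-3.0, 3.01, 0.25) + 0.125  # offset: no vertex at y=0
        X, Y = np.meshgrid(xs, ys)
        verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        mesh = SurfaceMesh(verts, np.array([[0, 1, 2]]), "glenoid_bone")
        thickness = np.where(verts[:, 1] > 0, 1.4, 1.0)
        tmap = ThicknessMap(mesh, thickness, np.ones(len(verts), dtype=bool))
        frame = AnatomicalFrame(np.zeros(3), [1, 0, 0], [0, 1, 0], [0, 0, 1], "right")
        from cartstrain.regions import Region
        grid = RegionGrid("glenoid", [
            Region(i + 1, np.array([0.0, 0.0, 0.0]), 2.0, "central", "central")
            for i in range(9)])
        df = region_mean_thickness(tmap, grid)
        assert df.mean_thickness_mm.iloc[0] == pytest.approx(1.2, abs=0.02)

    def test_default_pattern_center_region(self, glenoid_maps):
        _, tmap, frame = glenoid_maps
        grid = build_region_grid(tmap.masked_vertices(), frame, "glenoid")
        df = region_mean_thickness(tmap, grid)
        center = df[(df.ap_label == "central") & (df.si_label == "central")]
        assert center.mean_thickness_mm.iloc[0] == pytest.approx(1.2, abs=0.08)


class TestStrainTable:
    @staticmethod
    def _region_df(values):
        return pd.DataFrame([
            {"region_id": i + 1, "ap_label": "central", "si_label": "central",
             "band": "", "n_vertices": 10, "mean_thickness_mm": v, "missing": False}
            for i, v in enumerate(values)])

    def _table(self, t_pre, t_post, subjects=("s1", "s2", "s3")):
        pre = {s: {"glenoid": self._region_df(t_pre)} for s in subjects}
        post = {s: {"glenoid": self._region_df(t_post)} for s in subjects}
        return compute_strain_table(pre, post, {}, list(subjects))

    def test_printed_compartment_thicknesses_give_15_percent(self):
        table = self._table([1.3] * 9, [1.1] * 9)
        strain = table.summaries["glenoid"]["mean_strain"]
        assert round(100.0 * strain) == 15

    def test_no_change_gives_zero_strain(self):
        table = self._table([1.2] * 9, [1.2] * 9)
        assert table.rows.strain.abs().max() == 0.0

    def test_swelling_gives_negative_strain_without_error(self):
        table = self._table([1.0] * 9, [1.1] * 9)
        assert (table.rows.strain < 0).all()

    def test_nonpositive_pre_thickness_raises(self):
        with pytest.raises(ValueError, match="region 1"):
            self._table([0.0] * 9, [1.0] * 9)

    def test_ci_matches_closed_form(self):
        from scipy import stats as sps
        strains = [0.10, 0.12, 0.17, 0.15, 0.13, 0.19, 0.11, 0.16]
        subjects = [f"s{i}" for i in range(8)]
        pre = {s: {"glenoid": self._region_df([1.0] * 9)} for s in subjects}
        post = {s: {"glenoid": self._region_df([1.0 - e] * 9)}
                for s, e in zip(subjects, strains)}
        table = compute_strain_table(pre, post, {}, subjects)
        g = table.summaries["glenoid"]
        assert g["mean_strain"] == pytest.approx(np.mean(strains), abs=1e-12)
        expected_hw = sps.t.ppf(0.975, 7) * np.std(strains, ddof=1) / np.sqrt(8)
        assert g["ci95_half_width"] == pytest.approx(expected_hw, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.5, 3.0), st.floats(-0.5, 0.9))
    def test_strain_identity_property(self, t_pre, strain):
        t_post = t_pre * (1.0 - strain)
        table = self._table([t_pre] * 9, [t_post] * 9)
        assert np.allclose(table.rows.strain, strain, atol=1e-12)
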