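"""Contour/mesh I/O and loft reconstruction against analytic oracles."""

import json

import numpy as np
import pytest

from cartstrain.geometry import (
    Contour,
    ContourStack,
    SurfaceMesh,
    read_contour_stack,
    read_mesh,
    reconstruct_surface,
    write_contour_stack,
    write_mesh,
)
from cartstrain.phantom import slice_to_contours

from conftest import make_sphere_surface


def sphere_stack(radius=10.0, spacing=0.5, point_spacing=0.3):
    return slice_to_contours({"humeral_bone": make_sphere_surface(radius)},
                             spacing, point_spacing, 0.0, seed=0)


class TestTypes:
    def test_contour_rejects_bad_label(self):
        with pytest.raises(ValueError, match="humeral_bone"):
            Contour(z=0.0, label="femur", points=np.zeros((3, 2)) + np.arange(3)[:, None],
                    closed=False)

    def test_contour_rejects_duplicates_and_short(self):
        with pytest.raises(ValueError, match="duplicate"):
            Contour(z=0.0, label="humeral_bone",
                    points=np.array([[0, 0], [0, 0], [1, 1]]), closed=True)
        with pytest.raises(ValueError, match=">= 3"):
            Contour(z=0.0, label="humeral_bone",
                    points=np.array([[0, 0], [1, 1]]), closed=True)

    def test_stack_rejects_nonuniform_spacing(self):
        mk = lambda z: Contour(z=z, label="humeral_bone",
                               points=np.array([[0, 0], [1, 0], [1, 1]]), closed=True)
        with pytest.raises(ValueError, match="uniform"):
            ContourStack("s", "pre", "right", 0.5, [mk(0.0), mk(0.5), mk(0.8)])


class TestStackIO:
    def test_round_trip_identity(self, tmp_path):
        stack = sphere_stack()
        p = tmp_path / "stack.json"
        write_contour_stack(stack, p)
        back = read_contour_stack(p)
        assert back.subject == stack.subject
        assert back.slice_spacing == stack.slice_spacing
        assert len(back.contours) == len(stack.contours)
        for a, b in zip(stack.contours, back.contours):
            assert a.z == b.z and a.label == b.label and a.closed == b.closed
            assert np.array_equal(a.points, b.points)

    def test_shuffled_slices_returned_sorted(self, tmp_path):
        stack = sphere_stack(spacing=1.0, point_spacing=0.6)
        p = tmp_path / "stack.json"
        write_contour_stack(stack, p)
        doc = json.loads(p.read_text())
        doc["slices"] = doc["slices"][::-1]
        p.write_text(json.dumps(doc))
        back = read_contour_stack(p)
        zs = [c.z for c in back.contours]
        assert zs == sorted(zs)

    def test_unknown_label_error_lists_allowed(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({
            "subject": "s", "session": "pre", "laterality": "right",
            "slice_spacing_mm": 0.5,
            "slices": [{"z_mm": 0.0, "contours": [
                {"label": "femur", "closed": True,
                 "points_mm": [[0, 0], [1, 0], [1, 1]]}]}],
        }))
        with pytest.raises(ValueError, match="glenoid_cartilage"):
            read_contour_stack(p)

    def test_malformed_json(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            read_contour_stack(p)


class TestMeshIO:
    tet = SurfaceMesh(
        np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
        np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]),
        "humeral_bone",
    )

    def test_ply_round_trip_exact(self, tmp_path):
        p = tmp_path / "tet.ply"
        write_mesh(self.tet, p)
        back, scal = read_mesh(p)
        assert np.array_equal(back.vertices, self.tet.vertices)
        assert np.array_equal(back.faces, self.tet.faces)
        assert scal is None

    def test_ply_thickness_channel_preserved(self, tmp_path):
        p = tmp_path / "tet.ply"
        vals = np.array([0.1, 0.2, np.nan, 1.75])
        write_mesh(self.tet, p, scalars=vals)
        _, scal = read_mesh(p)
        assert np.allclose(scal[[0, 1, 3]], vals[[0, 1, 3]])
        assert np.isnan(scal[2])

    def test_obj_round_trip(self, tmp_path):
        p = tmp_path / "tet.obj"
        write_mesh(self.tet, p)
        back, _ = read_mesh(p)
        assert np.allclose(back.vertices, self.tet.vertices, atol=1e-6)

    def test_stl_round_trip_after_dedup(self, tmp_path):
        p = tmp_path / "tet.stl"
        write_mesh(self.tet, p)
        back, _ = read_mesh(p)
        a = np.array(sorted(map(tuple, np.round(back.vertices, 6))))
        b = np.array(sorted(map(tuple, np.round(self.tet.vertices, 6))))
        assert np.allclose(a, b, atol=1e-6)

    def test_unsupported_extension(self, tmp_path):
        with pytest.raises(ValueError, match="ply"):
            write_mesh(self.tet, tmp_path / "tet.vtk")


class TestReconstruction:
    def test_sliced_sphere_reconstruction_accuracy(self):
        mesh = reconstruct_surface(sphere_stack(), "humeral_bone")
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert np.max(np.abs(r - 10.0)) < 0.3
        area = mesh.to_trimesh().area
        assert abs(area - 4 * np.pi * 100.0) / (4 * np.pi * 100.0) < 0.03
        n_pts = sum(len(c.points) for c in sphere_stack().contours)
        assert len(mesh.vertices) >= n_pts / 2

    def test_two_squares_loft_to_prism_shell(self):
        sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        stack = ContourStack("s", "pre", "right", 1.0, [
            Contour(z=0.0, label="humeral_bone", points=sq, closed=True),
            Contour(z=1.0, label="humeral_bone", points=sq, closed=True),
        ])
        mesh = reconstruct_surface(stack, "humeral_bone", z_subdivisions=0)
        assert len(mesh.vertices) >= 8
        assert mesh.to_trimesh().is_winding_consistent

    def test_insufficient_contours(self):
        sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        stack = ContourStack("s", "pre", "right", 1.0, [
            Contour(z=0.0, label="humeral_bone", points=sq, closed=True)])
        with pytest.raises(ValueError, match="insufficient"):
            reconstruct_surface(stack, "humeral_bone")

    def test_non_overlapping_contours_error_names_slices(self):
        sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        stack = ContourStack("s", "pre", "right", 1.0, [
            Contour(z=0.0, label="humeral_bone", points=sq, closed=True),
            Contour(z=1.0, label="humeral_bone", points=sq + 50.0, closed=True),
        ])
        with pytest.raises(ValueError, match="z=0.0 and z=1.0"):
            reconstruct_surface(stack, "humeral_bone")

    def test_phantom_glenoid_vertices_on_generating_surface(self, glenoid_scene):
        pre_scene, _, _ = glenoid_scene
        stack = slice_to_contours(pre_scene, 0.5, 0.3, 0.0, seed=0)
        mesh = reconstruct_surface(stack, "glenoid_bone")
        surf = pre_scene.surfaces["glenoid_bone"]
        d = mesh.vertices - surf.center
        u = d / np.linalg.norm(d, axis=1, keepdims=True)
        r_expected = surf.radius_fn(u)
        err = np.abs(np.linalg.norm(d, axis=1) - r_expected)
        assert np.max(err) < 0.3

    def test_error_decreases_with_resolution(self):
        errs = []
        for spacing, pt in ((0.5, 0.3), (0.25, 0.15)):
            mesh = reconstruct_surface(sphere_stack(10.0, spacing, pt), "humeral_bone")
            tm = mesh.to_trimesh()
            fc = np.vstack([mesh.vertices, tm.triangles_center])
            errs.append(np.max(np.abs(np.linalg.norm(fc, axis=1) - 10.0)))
        assert errs[1] < errs[0]

    def test_rigid_equivariance(self):
        from cartstrain.registration import RigidTransform
        stack = sphere_stack(spacing=1.0, point_spacing=0.5)
        T = RigidTransform.from_axis_angle([0, 0, 1], 33.0, [5.0, -2.0, 0.0])
        moved = ContourStack("s", "pre", "right", 1.0, [
            Contour(z=c.z + 0.0, label=c.label,
                    points=(np.column_stack([c.points, np.full(len(c.points), c.z)])
                            @ T.rotation.T + T.translation)[:, :2],
                    closed=c.closed)
            for c in stack.contours
        ])
        m1 = reconstruct_surface(moved, "humeral_bone")
        m0 = reconstruct_surface(stack, "humeral_bone")
        assert np.allclose(m1.vertices, T.apply(m0.vertices), atol=1e-6)
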