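import numpy as np
import pytest

from limbmorph import (
    Plane,
    RigidTransform,
    TriangleMesh,
    anatomical_trim_plane,
    apply_transform,
    extreme_point,
    generate_multibone_hard_tissue,
    merge_meshes,
    trim_by_plane,
    validate_mesh,
    vertex_normals,
)
from limbmorph.exceptions import MeshValidationError

from conftest import fan_cube, open_cylinder


def _rigid(angle_deg, axis, translation):
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, float)
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / np.linalg.norm(axis))
    return RigidTransform(R.as_matrix(), translation)


class TestValidate:
    def test_valid_triangle_unchanged(self):
        m = TriangleMesh(np.eye(3), [[0, 1, 2]])
        rep = validate_mesh(m)
        assert rep.n_vertices_removed == 0 and rep.n_faces_removed == 0
        np.testing.assert_array_equal(rep.mesh.vertices, m.vertices)

    def test_prune_unreferenced_vertex(self):
        m = TriangleMesh(np.vstack([np.eye(3), [5, 5, 5]]), [[0, 1, 2]])
        rep = validate_mesh(m, prune=True)
        assert rep.mesh.n_vertices == 3
        assert rep.n_vertices_removed == 1
        np.testing.assert_array_equal(rep.mesh.faces, [[0, 1, 2]])

    def test_out_of_range_face_named(self):
        m = TriangleMesh(np.vstack([np.eye(3), [1, 1, 1]]), [[0, 1, 5]])
        with pytest.raises(MeshValidationError, match="face 0"):
            validate_mesh(m)

    def test_nonfinite_vertex_rejected(self):
        m = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, np.nan, 0]], [[0, 1, 2]])
        with pytest.raises(MeshValidationError, match="vertex 2"):
            validate_mesh(m, prune=True)

    def test_degenerate_face_pruned(self):
        m = TriangleMesh(np.eye(3), [[0, 1, 2], [1, 1, 2]])
        with pytest.raises(MeshValidationError):
            validate_mesh(m)
        rep = validate_mesh(m, prune=True)
        assert rep.mesh.n_faces == 1 and rep.n_faces_removed == 1


class TestMerge:
    def test_concatenation_offsets(self):
        a = open_cylinder(1, 1, 8, 1)  # 16 vertices
        b = TriangleMesh(np.eye(3), [[0, 1, 2]])
        merged = merge_meshes([a, b])
        assert merged.n_vertices == a.n_vertices + 3
        assert merged.n_faces == a.n_faces + 1
        np.testing.assert_array_equal(merged.faces[-1], [16, 17, 18])

    def test_single_mesh_identity(self):
        a = fan_cube()
        m = merge_meshes([a])
        np.testing.assert_array_equal(m.vertices, a.vertices)
        np.testing.assert_array_equal(m.faces, a.faces)

    def test_multibone_compile_counting_oracle(self):
        parts = generate_multibone_hard_tissue()
        merged = merge_meshes(parts, name="hard_tissue")
        assert merged.n_vertices == sum(p.n_vertices for p in parts)
        assert merged.n_faces == sum(p.n_faces for p in parts)
        # merge then validate never changes face count
        assert validate_mesh(merged).mesh.n_faces == merged.n_faces

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            merge_meshes([])


class TestVertexNormals:
    def test_fan_cube_corner_symmetry(self):
        cube = fan_cube()
        normals, undef = vertex_normals(cube)
        assert not undef[:8].any()
        for i in range(8):
            expected = (cube.vertices[i] - 0.5) * 2 / np.sqrt(3)
            np.testing.assert_allclose(normals[i], expected, atol=1e-12)

    def test_sphere_normals_radial(self):
        import trimesh

        s = trimesh.creation.icosphere(subdivisions=4)
        m = TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))
        normals, _ = vertex_normals(m)
        radial = m.vertices / np.linalg.norm(m.vertices, axis=1, keepdims=True)
        assert np.abs(normals - radial).max() < 0.01

    def test_isolated_vertex_flagged(self):
        m = TriangleMesh(np.vstack([np.eye(3), [9, 9, 9]]), [[0, 1, 2]])
        normals, undef = vertex_normals(m)
        assert undef[3] and not undef[:3].any()
        np.testing.assert_array_equal(normals[3], 0)


class TestApplyTransform:
    def test_identity(self, phantom_small):
        bone, _, _ = phantom_small
        out = apply_transform(bone, RigidTransform.identity())
        np.testing.assert_array_equal(out.vertices, bone.vertices)

    def test_translation_moves_centroid(self):
        m = fan_cube()
        t = RigidTransform(np.eye(3), [5, -3, 2])
        out = apply_transform(m, t)
        np.testing.assert_allclose(
            out.vertices.mean(0) - m.vertices.mean(0), [5, -3, 2], atol=1e-12
        )

    def test_rotation_inverse_roundtrip(self, phantom_small):
        bone, _, _ = phantom_small
        t = _rigid(30, [0, 0, 1], [1, 2, 3])
        back = apply_transform(apply_transform(bone, t), t.inverse())
        assert np.abs(back.vertices - bone.vertices).max() < 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigidity_preserves_distances_and_areas(self, seed, phantom_small):
        bone, _, _ = phantom_small
        rng = np.random.default_rng(seed)
        t = _rigid(rng.uniform(0, 180), rng.normal(size=3), rng.normal(size=3) * 40)
        out = apply_transform(bone, t)
        idx = rng.choice(bone.n_vertices, size=(60, 2))
        d0 = np.linalg.norm(bone.vertices[idx[:, 0]] - bone.vertices[idx[:, 1]], axis=1)
        d1 = np.linalg.norm(out.vertices[idx[:, 0]] - out.vertices[idx[:, 1]], axis=1)
        np.testing.assert_allclose(d1, d0, rtol=1e-9)

        def areas(m):
            v, f = m.vertices, m.faces
            return 0.5 * np.linalg.norm(
                np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1
            )

        np.testing.assert_allclose(areas(out), areas(bone), rtol=1e-9)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestExtremePoint:
    def test_matches_exhaustive_scan(self, phantom_small):
        bone, skin, _ = phantom_small
        rng = np.random.default_rng(0)
        for mesh in (bone, skin):
            for _ in range(5):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                pt, idx = extreme_point(mesh, d)
                proj = mesh.vertices @ d
                assert idx == int(np.argmax(proj))
                np.testing.assert_array_equal(pt, mesh.vertices[idx])

    def test_tie_breaks_to_lowest_index(self):
        cube = fan_cube()
        _, idx = extreme_point(cube, (0, 0, -1))
        candidates = np.flatnonzero(cube.vertices[:, 2] == 0)
        assert idx == candidates.min()

    def test_single_vertex(self):
        m = TriangleMesh([[1, 2, 3]], np.empty((0, 3), int))
        pt, idx = extreme_point(m, (1, 0, 0))
        assert idx == 0 and tuple(pt) == (1, 2, 3)

    def test_empty_mesh_rejected(self):
        m = TriangleMesh(np.empty((0, 3)), np.empty((0, 3), int))
        with pytest.raises(ValueError):
            extreme_point(m, (0, 0, 1))


class TestTrimPlane:
    def test_anatomical_plane_geometry(self, phantom_default):
        bone, _, _ = phantom_default
        plane = anatomical_trim_plane(bone, (0, 0, -1), 50.0)
        distal_z = bone.vertices[:, 2].min()
        assert plane.point[2] == pytest.approx(distal_z + 50.0)
        np.testing.assert_array_equal(plane.normal, [0, 0, -1])

    def test_zero_offset_rejected(self, phantom_small):
        bone, _, _ = phantom_small
        with pytest.raises(ValueError):
            anatomical_trim_plane(bone, (0, 0, -1), 0.0)

    def test_degenerate_direction_rejected(self, phantom_small):
        bone, _, _ = phantom_small
        with pytest.raises(ValueError):
            anatomical_trim_plane(bone, (0, 0, 0), 50.0)

    def test_cylinder_lateral_area_halves(self):
        cyl = open_cylinder(10, 100, 64, 40)
        plane = Plane(point=(0, 0, 50), normal=(0, 0, -1.0))
        cut = trim_by_plane(cyl, plane)
        area = cut.to_trimesh().area
        assert area == pytest.approx(cyl.to_trimesh().area / 2, rel=0.005)

    def test_noop_when_mesh_on_kept_side(self):
        cyl = open_cylinder(5, 10, 16, 4)
        plane = Plane(point=(0, 0, 20), normal=(0, 0, -1.0))
        cut = trim_by_plane(cyl, plane)
        assert cut.n_faces == cyl.n_faces
        assert np.abs(np.sort(cut.vertices, 0) - np.sort(cyl.vertices, 0)).max() < 1e-12

    def test_single_triangle_split_to_quad(self):
        tri = TriangleMesh([[0, 0, 0], [2, 0, 0], [0, 0, 2]], [[0, 1, 2]])
        plane = Plane(point=(0, 0, 1), normal=(0, 0, -1.0))  # discard z > 1
        cut = trim_by_plane(tri, plane)
        assert cut.n_faces == 2  # retained quad region as two triangles
        assert plane.signed_distance(cut.vertices).min() >= -1e-9

    def test_idempotent(self, phantom_default):
        _, skin, _ = phantom_default
        plane = Plane(point=(0, 0, 45.0), normal=(0, 0, -1.0))
        once = trim_by_plane(skin, plane)
        twice = trim_by_plane(once, plane)
        a = np.sort(once.vertices.round(9), axis=0)
        b = np.sort(twice.vertices.round(9), axis=0)
        assert a.shape == b.shape and np.abs(a - b).max() < 1e-9

    def test_all_output_vertices_on_kept_side(self, phantom_default):
        bone, skin, _ = phantom_default
        plane = anatomical_trim_plane(bone, (0, 0, -1), 50.0)
        for mesh in (bone, skin):
            cut = trim_by_plane(mesh, plane)
            assert plane.signed_distance(cut.vertices).min() >= -1e-9

    def test_fully_discarded_warns_and_empties(self):
        cyl = open_cylinder(5, 10, 16, 4)
        plane = Plane(point=(0, 0, -5), normal=(0, 0, -1.0))
        with pytest.warns(UserWarning, match="discarded side"):
            cut = trim_by_plane(cyl, plane)
        assert cut.n_vertices == 0
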