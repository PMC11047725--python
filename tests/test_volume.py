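import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cloudvol as cv
from cloudvol.geometry import PointCloud, TriangleMesh
from cloudvol.volume import (
    SlicingConfig,
    mesh_volume,
    min_point_spacing,
    orient_faces,
    signed_tet_volume,
    slicing_volume,
)

from .oracles import closed_cylinder_mesh, icosphere, unit_cube_mesh


def _det_expansion(a, b, c):
    """The printed determinant expansion for the origin tetrahedron."""
    (x1, y1, z1), (x2, y2, z2), (x3, y3, z3) = a, b, c
    return (-x3 * y2 * z1 + x2 * y3 * z1 + x3 * y1 * z2
            - x1 * y3 * z2 - x2 * y1 * z3 + x1 * y2 * z3) / 6.0


class TestSignedTetVolume:
    def test_unit_right_tetrahedron(self):
        assert signed_tet_volume([1, 0, 0], [0, 1, 0], [0, 0, 1]) == pytest.approx(1 / 6)

    def test_antisymmetry(self):
        assert signed_tet_volume([1, 0, 0], [0, 0, 1], [0, 1, 0]) == pytest.approx(-1 / 6)

    def test_degenerate_triangle_zero(self):
        assert signed_tet_volume([1, 1, 1], [2, 2, 2], [3, 3, 3]) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-50, 50, allow_nan=False, width=32), min_size=9, max_size=9),
        st.lists(st.floats(-50, 50, allow_nan=False, width=32), min_size=3, max_size=3),
    )
    def test_translation_of_all_vertices_with_origin(self, flat, origin):
        # moving vertices and origin together leaves the volume unchanged
        a, b, c = np.asarray(flat, dtype=np.float64).reshape(3, 3)
        o = np.asarray(origin, dtype=np.float64)
        v0 = signed_tet_volume(a, b, c, origin=(0.0, 0.0, 0.0))
        v1 = signed_tet_volume(a + o, b + o, c + o, origin=o)
        assert v1 == pytest.approx(v0, abs=1e-6 + 1e-9 * abs(v0))

    def test_matches_determinant_expansion(self, rng):
        for _ in range(100):
            a, b, c = rng.standard_normal((3, 3))
            v = signed_tet_volume(a, b, c)
            assert abs(abs(v) - abs(_det_expansion(a, b, c))) < 1e-12


class TestMeshVolume:
    def test_unit_cube_is_one(self):
        assert mesh_volume(unit_cube_mesh()).volume == pytest.approx(1.0, abs=1e-12)

    def test_translated_cube_unchanged(self):
        mesh = unit_cube_mesh()
        moved = TriangleMesh(mesh.vertices + [100.0, -50.0, 3.0], mesh.faces)
        assert mesh_volume(moved).volume == pytest.approx(1.0, abs=1e-9)

    def test_icosphere_analytic_and_voxel_oracle(self):
        from .oracles import voxel_volume_oracle

        mesh = icosphere(4)
        vol = mesh_volume(mesh).volume
        analytic = 4 * np.pi / 3
        assert abs(vol - analytic) / analytic < 0.005
        voxel = voxel_volume_oracle(mesh, 256)
        assert abs(vol - voxel) / vol < 0.005

    def test_origin_invariance(self):
        mesh = icosphere(2)
        v0 = mesh_volume(mesh, origin=(0, 0, 0)).volume
        v1 = mesh_volume(mesh, origin=tuple(mesh.vertices.mean(axis=0))).volume
        v2 = mesh_volume(mesh, origin=(250.0, -80.0, 1000.0)).volume
        assert v1 == pytest.approx(v0, rel=1e-10)
        assert v2 == pytest.approx(v0, rel=1e-10)

    def test_winding_flip_invariance(self):
        mesh = icosphere(2)
        flipped = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1].copy())
        assert mesh_volume(flipped).volume == pytest.approx(mesh_volume(mesh).volume, rel=1e-12)

    def test_signed_raw_recorded(self):
        res = mesh_volume(unit_cube_mesh())
        assert res.volume == abs(res.signed_raw)
        assert res.facet_count == 12

    def test_non_watertight_reports_open_edges(self):
        mesh = unit_cube_mesh()
        with pytest.raises(ValueError, match="watertight"):
            mesh_volume(TriangleMesh(mesh.vertices, mesh.faces[:-1]))


class TestOrientFaces:
    def test_repairs_single_flipped_face(self):
        mesh = unit_cube_mesh()
        faces = mesh.faces.copy()
        faces[3] = faces[3][::-1]
        repaired = orient_faces(TriangleMesh(mesh.vertices, faces))
        assert mesh_volume(repaired).signed_raw == pytest.approx(1.0, abs=1e-12)

    def test_consistent_mesh_fixed_point(self):
        mesh = icosphere(1)
        out = orient_faces(mesh)
        np.testing.assert_array_equal(out.faces, mesh.faces)

    def test_reference_cloud_selects_inward(self):
        mesh = unit_cube_mesh()
        centers = mesh.vertices[mesh.faces].mean(axis=1)
        inward = np.array([0.5, 0.5, 0.5]) - centers
        inward /= np.linalg.norm(inward, axis=1)[:, None]
        ref = PointCloud(centers, inward)
        out = orient_faces(mesh, reference=ref)
        # inward facets give negative signed volume; magnitude unchanged
        assert mesh_volume(out).signed_raw == pytest.approx(-1.0, abs=1e-12)
        assert mesh_volume(out).volume == pytest.approx(1.0, abs=1e-12)

    def test_non_watertight_rejected(self):
        mesh = unit_cube_mesh()
        with pytest.raises(ValueError):
            orient_faces(TriangleMesh(mesh.vertices, mesh.faces[:-1]))


class TestSlicing:
    def test_dense_cube_within_one_percent(self, rng):
        # surface + interior sampling of the unit cube
        surface, _ = cv.sample_shape(cv.ShapeSpec(kind="cube", density=4000, seed=1))
        interior = rng.random((20000, 3))
        cloud = PointCloud(np.vstack([surface.points, interior]))
        res = slicing_volume(cloud, SlicingConfig(axis="z", interval=0.02))
        assert abs(res.volume - 1.0) < 0.01

    def test_cylinder_within_one_percent(self):
        cloud, truth = cv.sample_shape(cv.ShapeSpec(kind="cylinder", density=4000, seed=2))
        res = slicing_volume(cloud, SlicingConfig(axis="z", interval=0.01))
        assert abs(res.volume - truth) / truth < 0.01

    def test_concave_l_prism_overestimates(self):
        cloud, truth = cv.sample_shape(cv.ShapeSpec(kind="l_prism", density=4000, seed=3))
        # slabs along z project to the L contour; its hull fills the notch
        res = slicing_volume(cloud, SlicingConfig(axis="z", interval=0.01))
        # convex-hull contours fill the notch: strict overestimate
        assert res.volume > truth * 1.05

    def test_degenerate_slices_rejected(self):
        cloud = PointCloud(np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)]))
        with pytest.raises(ValueError):
            slicing_volume(cloud, SlicingConfig(axis="z", interval=0.5))

    def test_bad_config(self):
        with pytest.raises(ValueError):
            SlicingConfig(axis="w")
        with pytest.raises(ValueError):
            SlicingConfig(interval=-1.0)


class TestMinPointSpacing:
    def test_regular_grid(self):
        ax = np.arange(0, 0.1, 0.01)
        x, y = np.meshgrid(ax, ax, indexing="ij")
        cloud = PointCloud(np.column_stack([x.ravel(), y.ravel(), np.zeros(x.size)]))
        assert min_point_spacing(cloud) == pytest.approx(0.01)

    def test_two_points(self):
        assert min_point_spacing(PointCloud(np.array([[0, 0, 0], [3, 4, 0.0]]))) == 5.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            min_point_spacing(PointCloud(np.zeros((1, 3))))

    def test_matches_brute_force(self, rng):
        pts = rng.standard_normal((1000, 3))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert min_point_spacing(PointCloud(pts)) == pytest.approx(d.min(), rel=1e-12)


class TestVoxelOracleFixtures:
    """Mesh volume vs the 256^3 voxelization oracle on the four fixtures."""

    @pytest.mark.parametrize(
        "mesh_fn",
        [
            unit_cube_mesh,
            lambda: icosphere(3),
            lambda: closed_cylinder_mesh(segments=256, caps="rings"),
        ],
        ids=["cube", "icosphere", "cylinder"],
    )
    def test_primitive_fixtures(self, mesh_fn):
        from .oracles import voxel_volume_oracle

        mesh = mesh_fn()
        vol = mesh_volume(mesh).volume
        voxel = voxel_volume_oracle(mesh, 256)
        assert abs(vol - voxel) / vol < 0.005

    def test_piglet_fixture(self):
        from .oracles import voxel_volume_oracle
        from cloudvol.synthetic import piglet_mesh

        mesh = piglet_mesh(resolution=96)  # coarser build keeps the test fast
        vol = mesh_volume(mesh).volume
        voxel = voxel_volume_oracle(mesh, 256)
        assert abs(vol - voxel) / vol < 0.005
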