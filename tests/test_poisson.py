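import numpy as np
import pytest

import cloudvol as cv
from cloudvol.geometry import PointCloud
from cloudvol.poisson import (
    IndicatorField,
    ScreenedConfig,
    build_octree,
    compute_sample_weights,
    extract_isosurface,
    reconstruct,
    solve_poisson,
    solve_screened_poisson,
    splat_vector_field,
)
from cloudvol.volume import mesh_volume


@pytest.fixture(scope="module")
def sphere_setup(request):
    """Oriented sphere cloud with octree, tau and splatted field at D=6."""
    cloud, truth = cv.sample_shape(cv.ShapeSpec(kind="sphere", density=800, seed=7))
    work = PointCloud(cloud.points.copy(), cloud.normals.copy())
    tree = build_octree(work, 6)
    tau = compute_sample_weights(work, 10)
    field = splat_vector_field(tree, work)
    return work, tree, tau, field, truth


class TestOctree:
    def test_single_point_one_path(self):
        tree = build_octree(PointCloud(np.array([[0.3, 0.4, 0.5]])), 2)
        assert [len(c) for c in tree.level_coords] == [1, 1, 1]
        assert tree.n_leaves == 1
        assert tree.sample_leaf[0] == 0

    def test_cube_corners_octant_partition(self):
        pts = np.array(
            [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
        )
        tree = build_octree(PointCloud(pts), 1)
        assert len(tree.level_coords[1]) == 8
        assert len(np.unique(tree.sample_leaf)) == 8

    def test_leaf_count_matches_voxel_hash(self, rng):
        cloud, _ = cv.sample_shape(cv.ShapeSpec(kind="cube", density=1600, seed=4))
        depth = 6
        tree = build_octree(cloud, depth)
        # brute-force voxel hashing at depth-D resolution
        res = 1 << depth
        ijk = np.floor((cloud.points - tree.root_min) / tree.cell_width).astype(int)
        np.clip(ijk, 0, res - 1, out=ijk)
        occupied = len(np.unique(ijk, axis=0))
        assert tree.n_leaves <= 8 * occupied
        assert tree.n_leaves == occupied  # exact for this construction

    def test_padding_and_containment(self, rng):
        pts = rng.random((500, 3)) * [2.0, 1.0, 0.5]
        tree = build_octree(PointCloud(pts), 5)
        extent = (pts.max(axis=0) - pts.min(axis=0)).max()
        assert tree.root_width == pytest.approx(extent * 1.1, rel=1e-9)
        assert np.all(pts >= tree.root_min - 1e-12)
        assert np.all(pts <= tree.root_min + tree.root_width + 1e-12)

    def test_child_width_halves(self, sphere_setup):
        _, tree, _, _, _ = sphere_setup
        for level in range(1, tree.depth + 1):
            assert tree.node_width(level) == pytest.approx(tree.node_width(level - 1) / 2)

    def test_depth_out_of_range(self):
        with pytest.raises(ValueError):
            build_octree(PointCloud(np.zeros((1, 3))), 0)
        with pytest.raises(ValueError):
            build_octree(PointCloud(np.zeros((1, 3))), 13)


class TestSplat:
    def test_single_sample_mass_conservation(self):
        cloud = PointCloud(np.array([[0.5, 0.5, 0.5], [0.51, 0.5, 0.5]]),
                           np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]]))
        tree = build_octree(cloud, 4)
        field = splat_vector_field(tree, cloud, weights=np.array([1.0, 0.0]))
        np.testing.assert_allclose(field.total(), [0, 0, 1], atol=1e-12)

    def test_antipodal_cancellation(self):
        cloud = PointCloud(np.array([[1.0, 0, 0], [-1.0, 0, 0]]),
                           np.array([[-1.0, 0, 0], [1.0, 0, 0]]))  # inward
        tree = build_octree(cloud, 4)
        field = splat_vector_field(tree, cloud)
        assert np.linalg.norm(field.total()) < 1e-8

    def test_weighted_mass_equals_weighted_normal_sum(self, sphere_setup):
        work, tree, tau, _, _ = sphere_setup
        field = splat_vector_field(tree, work, weights=tau)
        expected = (work.normals * tau[:, None]).sum(axis=0)
        np.testing.assert_allclose(field.total(), expected, atol=1e-8)

    def test_field_aligns_with_normals_on_sphere(self, sphere_setup):
        work, _, _, field, _ = sphere_setup
        vals = field.evaluate(work.points)
        inner = np.einsum("ij,ij->i", vals, work.normals)
        assert (inner > 0).mean() >= 0.99

    def test_requires_normals(self, rng):
        cloud = PointCloud(rng.random((50, 3)))
        tree = build_octree(cloud, 4)
        with pytest.raises(ValueError):
            splat_vector_field(tree, cloud)


class TestSampleWeights:
    def _cloud(self, normals):
        # query point at origin, n=2 neighbors at unit distance
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
        return PointCloud(pts, np.asarray(normals, dtype=float))

    def test_identical_normals_tau_one(self):
        cloud = self._cloud([[0, 0, 1], [0, 0, 1], [0, 0, 1]])
        tau = compute_sample_weights(cloud, 2)
        assert tau[0] == pytest.approx(1.0)

    def test_obtuse_normals_tau_zero(self):
        cloud = self._cloud([[0, 0, 1], [0, 0, -1], [np.sin(2.0), 0, np.cos(2.0)]])
        tau = compute_sample_weights(cloud, 2)
        assert tau[0] == pytest.approx(0.0)

    def test_half_aligned_half_orthogonal_tau_half(self):
        cloud = self._cloud([[0, 0, 1], [0, 0, 1], [1, 0, 0]])
        tau = compute_sample_weights(cloud, 2)
        assert tau[0] == pytest.approx(0.5)

    def test_range_and_storage(self, sphere_setup):
        work, _, tau, _, _ = sphere_setup
        assert np.all((tau >= 0) & (tau <= 1))
        assert work.confidence is tau


class TestSolvePoisson:
    def test_zero_field_zero_solution(self, sphere_setup):
        work, tree, _, _, _ = sphere_setup
        field = splat_vector_field(tree, work, weights=np.zeros(len(work)))
        out = solve_poisson(tree, field)
        assert np.abs(out.chi).max() < 1e-12

    def test_inside_outside_separation(self, sphere_setup):
        work, tree, _, field, _ = sphere_setup
        out = solve_poisson(tree, field)
        center = out.evaluate(np.array([[0.0, 0.0, 0.0]]))[0]
        outside = out.evaluate(np.array([[0.0, 0.0, 1.05 * tree.root_width / 2]]))[0]
        assert (center - out.mu_iso) * (outside - out.mu_iso) < 0

    def test_linearity_in_field(self, sphere_setup):
        work, tree, _, field, _ = sphere_setup
        base = solve_poisson(tree, field)
        doubled = splat_vector_field(tree, work, weights=np.full(len(work), 2.0))
        out = solve_poisson(tree, doubled)
        np.testing.assert_allclose(out.chi, 2.0 * base.chi, atol=1e-10)

    def test_mu_iso_is_sample_mean(self, sphere_setup):
        work, tree, _, field, _ = sphere_setup
        out = solve_poisson(tree, field)
        assert out.mu_iso == out.evaluate(work.points).mean()


class TestScreenedSolve:
    def test_lambda_zero_equals_plain(self, sphere_setup):
        work, tree, _, field, _ = sphere_setup
        plain = solve_poisson(tree, field)
        scr = solve_screened_poisson(tree, field, work, ScreenedConfig(lam=0.0, depth=6))
        np.testing.assert_allclose(scr.chi, plain.chi, atol=1e-8)

    def test_zero_tau_equals_plain(self, sphere_setup):
        work, tree, _, field, _ = sphere_setup
        zero_tau = PointCloud(work.points, work.normals, np.zeros(len(work)))
        plain = solve_poisson(tree, field)
        scr = solve_screened_poisson(tree, field, zero_tau, ScreenedConfig(lam=4.0, depth=6))
        np.testing.assert_allclose(scr.chi, plain.chi, atol=1e-8)

    def test_screening_pulls_samples_toward_iso(self, sphere_setup):
        work, tree, _, field, _ = sphere_setup
        plain = solve_poisson(tree, field)
        r_plain = np.abs(plain.evaluate(work.points) - plain.mu_iso).mean()
        scr = solve_screened_poisson(tree, field, work, ScreenedConfig(lam=4.0, depth=6))
        r_scr = np.abs(scr.evaluate(work.points) - scr.mu_iso).mean()
        assert r_scr <= r_plain

    def test_requires_tau(self, sphere_setup):
        work, tree, _, field, _ = sphere_setup
        bare = PointCloud(work.points, work.normals)
        with pytest.raises(ValueError):
            solve_screened_poisson(tree, field, bare, ScreenedConfig(lam=4.0, depth=6))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ScreenedConfig(lam=-1.0)


class TestIsosurface:
    def test_sphere_radius_within_two_percent(self):
        cloud, _ = cv.sample_shape(cv.ShapeSpec(kind="sphere", density=800, seed=7))
        work = PointCloud(cloud.points.copy(), cloud.normals.copy())
        tree = build_octree(work, 7)
        compute_sample_weights(work, 10)
        field = splat_vector_field(tree, work)
        ind = solve_screened_poisson(tree, field, work, ScreenedConfig(lam=4.0, depth=7))
        mesh = extract_isosurface(ind, work)
        assert mesh.is_watertight()
        radii = np.linalg.norm(mesh.vertices, axis=1)
        assert abs(radii.mean() - 1.0) < 0.02

    def test_every_edge_shared_by_two_faces(self, sphere_setup):
        work, tree, _, field, _ = sphere_setup
        mesh = extract_isosurface(solve_poisson(tree, field), work)
        e = np.sort(mesh.edges(), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        assert np.all(counts == 2)

    def test_degenerate_solve_rejected(self, sphere_setup):
        work, tree, _, _, _ = sphere_setup
        flat = IndicatorField(octree=tree, chi=np.zeros((64, 64, 64)))
        with pytest.raises(ValueError, match="degenerate"):
            extract_isosurface(flat, work)


class TestReconstruct:
    def test_cube_improved_d6(self, small_cube_cloud):
        cloud, truth = small_cube_cloud
        mesh = reconstruct(PointCloud(cloud.points), depth=6, method="improved", smooth=False)
        assert mesh.is_watertight()
        vol = mesh_volume(mesh).volume
        assert abs(vol - truth) / truth < 0.01

    def test_facet_count_grows_with_depth(self, small_cube_cloud):
        cloud, _ = small_cube_cloud
        m5 = reconstruct(PointCloud(cloud.points), depth=5, method="improved", smooth=False)
        m6 = reconstruct(PointCloud(cloud.points), depth=6, method="improved", smooth=False)
        assert m6.n_faces > m5.n_faces

    def test_similarity_equivariance(self, small_cube_cloud):
        cloud, truth = small_cube_cloud
        base = mesh_volume(
            reconstruct(PointCloud(cloud.points), depth=6, method="poisson", smooth=False)
        ).volume
        s = 2.5
        moved = PointCloud(cloud.points * s + [10.0, -5.0, 2.0])
        vol = mesh_volume(reconstruct(moved, depth=6, method="poisson", smooth=False)).volume
        assert abs(vol - base * s**3) / (base * s**3) < 0.005

    def test_depth_validation_first(self, small_cube_cloud):
        cloud, _ = small_cube_cloud
        with pytest.raises(ValueError):
            reconstruct(PointCloud(cloud.points), depth=3)
        with pytest.raises(ValueError):
            reconstruct(PointCloud(cloud.points), depth=13)

    def test_bad_method(self, small_cube_cloud):
        cloud, _ = small_cube_cloud
        with pytest.raises(ValueError):
            reconstruct(PointCloud(cloud.points), depth=5, method="delaunay")

    def test_report_populated(self, small_cube_cloud):
        cloud, _ = small_cube_cloud
        report = {}
        reconstruct(PointCloud(cloud.points), depth=5, method="improved",
                    smooth=False, report=report)
        assert set(report) >= {"stage_seconds", "facet_count", "depth", "method"}
        assert report["depth"] == 5
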