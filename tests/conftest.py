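import numpy as np
import pytest

import cloudvol as cv


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def sphere_cloud():
    """10k-point unit sphere sampling with analytic inward normals."""
    cloud, truth = cv.sample_shape(cv.ShapeSpec(kind="sphere", density=800, seed=7))
    return cloud, truth


@pytest.fixture(scope="session")
def small_cube_cloud():
    """Modest cube sampling for fast reconstruction tests."""
    cloud, truth = cv.sample_shape(cv.ShapeSpec(kind="cube", density=2500, seed=3))
    return cloud, truth


@pytest.fixture(scope="session")
def oriented_sphere(sphere_cloud):
    """Sphere cloud with PCA-estimated, MST-oriented normals."""
    cloud, truth = sphere_cloud
    est = cv.estimate_normals_pca(cv.PointCloud(cloud.points), 20)
    return cv.orient_normals_mst(est, 10, "tangency"), truth
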