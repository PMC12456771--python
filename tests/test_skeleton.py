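import numpy as np
import pytest
from scipy.spatial import cKDTree

from skelphen import (
    PointCloud,
    SyntheticPlantSpec,
    generate_plant,
    partition_voxels,
    skeletonize_iterative,
    weighted_centroids,
)
from skelphen.skeleton import sub_cube_centroid


def test_single_point_occupies_one_sub_cube():
    part = partition_voxels(np.array([[0.2, 0.3, 0.4]]), L=0.01)
    assert len(np.unique(part.sub_index, axis=0)) == 1
    assert len(np.unique(part.parent_index, axis=0)) == 1


def test_distant_points_fall_in_distinct_parent_cubes():
    pts = np.array([[0.001, 0.001, 0.001], [0.015, 0.001, 0.001]])
    part = partition_voxels(pts, L=0.01)
    assert not np.array_equal(part.parent_index[0], part.parent_index[1])


def test_partition_matches_floor_division_oracle(rng):
    pts = rng.uniform(0, 0.3, (1000, 3))
    L = 0.01
    part = partition_voxels(pts, L)
    origin = pts.min(axis=0)
    expected_sub = np.floor((pts - origin) / (L / 2)).astype(np.int64)
    np.testing.assert_array_equal(part.sub_index, expected_sub)
    np.testing.assert_array_equal(part.parent_index, expected_sub // 2)


def test_sub_cube_centroid_identity_symmetry_and_mean(rng):
    p = np.array([[0.1, 0.2, 0.3]])
    np.testing.assert_allclose(sub_cube_centroid(p), p[0])
    sym = np.array([[1.0, 2, 3], [-1.0, -2, -3]])
    np.testing.assert_allclose(sub_cube_centroid(sym), 0.0, atol=1e-15)
    pts = rng.normal(size=(50, 3))
    np.testing.assert_allclose(sub_cube_centroid(pts), pts.mean(axis=0), atol=1e-12)
    with pytest.raises(ValueError):
        sub_cube_centroid(np.empty((0, 3)))


def test_weighted_centroid_symmetric_sub_cubes_hit_parent_center():
    # 8 points at the 8 sub-cube centers of one parent cube of edge 0.01
    c = 0.0025
    offs = [0.0, 0.005]
    pts = np.array([[c + dx, c + dy, c + dz] for dx in offs for dy in offs for dz in offs])
    part = partition_voxels(pts, L=0.01)
    sk = weighted_centroids(part, theta=0)
    assert len(sk) == 1
    np.testing.assert_allclose(sk.points[0], pts.mean(axis=0), atol=1e-12)


def test_theta_above_all_counts_empties_skeleton(rng):
    pts = rng.uniform(0, 0.05, (200, 3))
    part = partition_voxels(pts, L=0.01)
    sk = weighted_centroids(part, theta=10_000)
    assert len(sk) == 0


def test_weighted_centroid_equals_mean_of_retained_union(rng):
    """C_w must equal the plain mean of the retained sub-cubes' points."""
    for trial in range(10):
        pts = rng.uniform(0, 0.08, (500, 3))
        part = partition_voxels(pts, L=0.01)
        sk = weighted_centroids(part, theta=2)
        # brute force per parent cube
        origin = pts.min(axis=0)
        sub = np.floor((pts - origin) / 0.005).astype(np.int64)
        parent = sub // 2
        counts = {}
        for s in map(tuple, sub):
            counts[s] = counts.get(s, 0) + 1
        expected = {}
        for ptup in set(map(tuple, parent)):
            members = [
                i
                for i in range(len(pts))
                if tuple(parent[i]) == ptup and counts[tuple(sub[i])] > 2
            ]
            if members:
                expected[ptup] = pts[members].mean(axis=0)
        got = {tuple(np.round(p, 12)) for p in sk.points}
        want = {tuple(np.round(v, 12)) for v in expected.values()}
        assert got == want


def test_translation_equivariance(rng):
    pts = rng.uniform(0, 0.1, (800, 3))
    shift = np.array([1.23, -4.56, 7.89])
    sk1 = skeletonize_iterative(pts, L0=0.01, theta=2, n_iter=2)
    sk2 = skeletonize_iterative(pts + shift, L0=0.01, theta=2, n_iter=2)
    order1 = np.lexsort(sk1.points.T)
    order2 = np.lexsort(sk2.points.T)
    np.testing.assert_allclose(sk2.points[order2] - shift, sk1.points[order1], atol=1e-9)


def test_point_count_non_increasing_across_iterations(rng):
    pts = rng.uniform(0, 0.2, (3000, 3))
    prev = len(pts)
    for n_iter in (1, 2, 3):
        sk = skeletonize_iterative(pts, L0=0.01, theta=0, n_iter=n_iter)
        assert len(sk) <= prev
        prev = len(sk)


def test_cylinder_skeleton_tracks_axis():
    spec = SyntheticPlantSpec(
        n_leaves=0, stem_curvature=0.0, noise_sigma=0.0, outlier_count=0, seed=0
    )
    cloud, truth = generate_plant(spec)
    sk = skeletonize_iterative(cloud)
    d, _ = cKDTree(truth.stem_axis_samples).query(sk.points, k=1)
    assert np.all(d <= 0.005)


def test_annihilating_pass_returns_previous_set(rng):
    pts = rng.uniform(0, 0.2, (5000, 3)) * [1, 1, 0.001]  # a sheet
    with pytest.warns(UserWarning, match="returning the previous"):
        sk = skeletonize_iterative(pts, L0=0.01, theta=6, n_iter=3)
    assert len(sk) >= 2


def test_empty_cloud_rejected():
    with pytest.raises(ValueError):
        partition_voxels(np.empty((0, 3)), 0.01)
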