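import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skelphen import (
    KMeansConfig,
    LCCPConfig,
    PointCloud,
    VCCSConfig,
    adaptive_k,
    kmeanspp_split,
    lccp_merge,
    segment_leaves,
    vccs_supervoxels,
)
from skelphen.leafseg import Supervoxel, similarity_distance


def make_sv(i, centroid, normal, pts_idx=None, adjacency=()):
    return Supervoxel(
        id=i,
        point_indices=np.asarray(pts_idx if pts_idx is not None else [i]),
        centroid=np.asarray(centroid, float),
        normal=np.asarray(normal, float) / np.linalg.norm(normal),
        curvature=0.0,
        fpfh=np.zeros(33),
        adjacency=set(adjacency),
    )


def test_similarity_distance_zero_for_identical_features():
    cfg = VCCSConfig()
    assert similarity_distance(0.0, 0.0, 0.0, cfg, c_max=0.2) == 0.0


def test_similarity_distance_hand_evaluated_case():
    cfg = VCCSConfig(R_voxel=0.008, R_seed=0.01, w_c=0.2, w_s=0.4, w_n=1.0)
    d = similarity_distance(0.1, 0.01, 0.25, cfg, c_max=0.2)
    # 0.2*0.25 + 0.4*(1/3) + 1*0.0625 = 0.24583̄
    assert d == pytest.approx(0.05 + 0.4 / 3 + 0.0625, rel=1e-12)
    assert d == pytest.approx(0.2458333333333, rel=1e-9)


def _planar_patch(center, n=400, half=0.02, seed=0):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(-half, half, (n, 2))
    return np.column_stack([xy[:, 0] + center[0], np.full(n, center[1]), xy[:, 1] + center[2]])


def test_supervoxels_partition_all_points():
    pts = _planar_patch((0, 0.1, 0), n=1500)
    svs = vccs_supervoxels(pts, VCCSConfig())
    covered = np.concatenate([sv.point_indices for sv in svs])
    assert sorted(covered) == list(range(len(pts)))
    assert len(set(covered)) == len(pts)


def test_supervoxel_adjacency_symmetric():
    pts = _planar_patch((0, 0.1, 0), n=1500)
    svs = vccs_supervoxels(pts, VCCSConfig())
    for sv in svs:
        for j in sv.adjacency:
            assert sv.id in svs[j].adjacency


def test_no_supervoxel_spans_distant_patches():
    a = _planar_patch((0, 0.1, 0), n=600, seed=1)
    b = _planar_patch((0.15, 0.1, 0), n=600, seed=2)  # 10 x R_seed away
    svs = vccs_supervoxels(np.vstack([a, b]), VCCSConfig())
    for sv in svs:
        in_a = np.any(sv.point_indices < 600)
        in_b = np.any(sv.point_indices >= 600)
        assert not (in_a and in_b)


def test_vccs_rejects_empty_cloud():
    with pytest.raises(ValueError):
        vccs_supervoxels(np.empty((0, 3)), VCCSConfig())


def test_lccp_merges_coplanar_supervoxels():
    sv0 = make_sv(0, [0, 0, 0], [0, 1, 0], adjacency=[1])
    sv1 = make_sv(1, [0.01, 0, 0], [0, 1, 0], adjacency=[0])
    labels = lccp_merge([sv0, sv1], LCCPConfig(min_cluster_points=0))
    assert labels[0] == labels[1]


def test_lccp_cuts_concave_valley():
    # 90-degree concave valley: normals tilt toward each other
    sv0 = make_sv(0, [-0.01, 0.01, 0], [1, 1, 0], adjacency=[1])
    sv1 = make_sv(1, [0.01, 0.01, 0], [-1, 1, 0], adjacency=[0])
    labels = lccp_merge([sv0, sv1], LCCPConfig(min_cluster_points=0))
    assert labels[0] != labels[1]


def test_lccp_merges_convex_roof():
    sv0 = make_sv(0, [-0.01, 0.01, 0], [-1, 1, 0], adjacency=[1])
    sv1 = make_sv(1, [0.01, 0.01, 0], [1, 1, 0], adjacency=[0])
    labels = lccp_merge([sv0, sv1], LCCPConfig(min_cluster_points=0))
    assert labels[0] == labels[1]


def test_lccp_drops_small_clusters():
    sv0 = make_sv(0, [0, 0, 0], [0, 1, 0], pts_idx=np.arange(80))
    labels = lccp_merge([sv0], LCCPConfig(min_cluster_points=100))
    assert labels[0] == -1
    labels = lccp_merge([sv0], LCCPConfig(min_cluster_points=79))
    assert labels[0] == 0


def test_lccp_invariant_to_id_permutation(rng):
    svs = []
    for i in range(6):
        svs.append(
            make_sv(
                i,
                [0.01 * i, 0.0, 0.0],
                [0, 1, 0] if i < 3 else [1, 1, 0],
                pts_idx=np.arange(200),
            )
        )
    for i in range(5):
        svs[i].adjacency.add(i + 1)
        svs[i + 1].adjacency.add(i)
    base = lccp_merge(svs, LCCPConfig(min_cluster_points=0))
    perm = rng.permutation(6)
    permuted = [
        make_sv(
            new_i,
            svs[old].centroid,
            svs[old].normal,
            pts_idx=svs[old].point_indices,
            adjacency={int(np.where(perm == j)[0][0]) for j in svs[old].adjacency},
        )
        for new_i, old in enumerate(perm)
    ]
    out = lccp_merge(permuted, LCCPConfig(min_cluster_points=0))
    # same partition structure: pairs grouped together iff grouped before
    for a in range(6):
        for b in range(6):
            same_base = base[np.where(perm == a)[0][0]] == base[np.where(perm == b)[0][0]]
            assert (out[a] == out[b]) == same_base


@pytest.mark.parametrize(
    "sizes, expected",
    [
        ([100, 100, 250], [1, 1, 1]),  # K = floor(250/150) = 1 -> keep whole
        ([100, 100, 500], [1, 1, 2]),  # K = floor(500/233.3) = 2 -> split
        ([50, 50, 50], [1, 1, 1]),  # equal sizes: nothing anomalous
    ],
)
def test_adaptive_k_floor_rule(sizes, expected):
    np.testing.assert_array_equal(adaptive_k(np.array(sizes)), expected)


@settings(deadline=None, max_examples=50)
@given(
    st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=20)
)
def test_adaptive_k_matches_one_line_oracle(sizes):
    sizes = np.array(sizes)
    got = adaptive_k(sizes)
    mu = sizes.mean()
    for s, k in zip(sizes, got):
        want = int(s // mu) if s > mu else 1
        if want < 2:
            want = 1
        assert k == want


def test_kmeanspp_separates_two_blobs(rng):
    a = rng.normal(size=(300, 3)) * 0.005
    b = rng.normal(size=(300, 3)) * 0.005 + [0.1, 0, 0]
    pts = np.vstack([a, b])
    labels = kmeanspp_split(pts, 2, KMeansConfig(seed=0))
    blob = np.repeat([0, 1], 300)
    agreement = max(np.mean(labels == blob), np.mean(labels != blob))
    assert agreement >= 0.95


def test_kmeanspp_k_equals_n(rng):
    pts = rng.normal(size=(5, 3))
    labels = kmeanspp_split(pts, 5, KMeansConfig(seed=1, min_center_sep=1e-9))
    assert len(set(labels)) == 5


def test_kmeanspp_deterministic_under_seed(rng):
    pts = rng.normal(size=(200, 3))
    l1 = kmeanspp_split(pts, 3, KMeansConfig(seed=7))
    l2 = kmeanspp_split(pts, 3, KMeansConfig(seed=7))
    np.testing.assert_array_equal(l1, l2)


def test_kmeans_defaults_match_operating_point():
    cfg = KMeansConfig()
    assert cfg.max_iter == 100
    assert cfg.tol == pytest.approx(0.001)
    assert cfg.min_center_sep == pytest.approx(0.002)


def test_segment_single_leaf_yields_one_cluster():
    pts = _planar_patch((0, 0.1, 0), n=1200)
    seg = segment_leaves(PointCloud(pts))
    assert seg.n_leaves == 1
    assert np.all(seg.labels == 0)


def test_segment_two_separate_leaves():
    a = _planar_patch((0, 0.1, 0), n=900, seed=3)
    b = _planar_patch((0.2, 0.25, 0.1), n=900, seed=4)
    seg = segment_leaves(PointCloud(np.vstack([a, b])))
    assert seg.n_leaves == 2
    assert len(set(seg.labels[:900])) == 1
    assert len(set(seg.labels[900:])) == 1
    assert seg.labels[0] != seg.labels[-1]
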