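import itertools

import networkx as nx
import numpy as np
import pytest

from skelphen import (
    PointCloud,
    build_mst,
    classify_nodes,
    label_stem,
    principal_direction,
    refine_principal_line,
    root_node,
    select_highest_junction,
    smooth_curve,
    tree_path,
)
from skelphen.stem import INTERNAL, JUNCTION, TIP


def prufer_min_spanning_weight(points):
    """Exhaustive minimum over all labelled trees via Prüfer sequences."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        seq_list = list(seq)
        total = 0.0
        deg = degree[:]
        import heapq

        leaves = [i for i in range(n) if deg[i] == 1]
        heapq.heapify(leaves)
        for v in seq_list:
            leaf = heapq.heappop(leaves)
            total += d[leaf, v]
            deg[v] -= 1
            if deg[v] == 1:
                heapq.heappush(leaves, v)
        u, w = heapq.heappop(leaves), heapq.heappop(leaves)
        total += d[u, w]
        best = min(best, total)
    return best


def prim_weight(points):
    """Independent Prim implementation (array-based)."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    in_tree = np.zeros(n, dtype=bool)
    dist = np.full(n, np.inf)
    dist[0] = 0.0
    total = 0.0
    for _ in range(n):
        u = np.argmin(np.where(in_tree, np.inf, dist))
        total += dist[u]
        in_tree[u] = True
        dist = np.minimum(dist, np.where(in_tree, np.inf, d[u]))
        dist[in_tree] = np.inf
    return total


def mst_weight(g):
    return sum(w for _, _, w in g.edges.data("weight"))


def test_mst_two_points_single_edge():
    g = build_mst(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    assert g.number_of_edges() == 1
    assert mst_weight(g) == pytest.approx(1.0)


def test_mst_collinear_never_takes_long_edge():
    pts = np.array([[0, 0, 0], [0, 0.1, 0], [0, 0.3, 0]], dtype=float)
    g = build_mst(pts)
    assert set(map(frozenset, g.edges)) == {frozenset({0, 1}), frozenset({1, 2})}


def test_mst_matches_exhaustive_enumeration(rng):
    pts = rng.normal(size=(6, 3))
    g = build_mst(pts)
    assert mst_weight(g) == pytest.approx(prufer_min_spanning_weight(pts), rel=1e-12)


def test_mst_matches_independent_prim(rng):
    pts = rng.normal(size=(200, 3))
    g = build_mst(pts)
    assert mst_weight(g) == pytest.approx(prim_weight(pts), rel=1e-10)


def test_mst_knn_fast_path_agrees_with_complete(rng):
    pts = rng.normal(size=(300, 3))
    full = build_mst(pts)
    fast = build_mst(pts, knn=10)
    assert mst_weight(fast) == pytest.approx(mst_weight(full), rel=1e-10)


def test_mst_requires_two_points():
    with pytest.raises(ValueError):
        build_mst(np.zeros((1, 3)))


def test_classify_path_and_star():
    path_pts = np.column_stack([np.zeros(5), np.arange(5.0), np.zeros(5)])
    classes = classify_nodes(build_mst(path_pts))
    assert sum(c == TIP for c in classes.values()) == 2
    assert sum(c == INTERNAL for c in classes.values()) == 3

    star = np.array([[0, 0, 0], [1, 0, 0], [-0.5, 0.9, 0], [-0.5, -0.9, 0]], float)
    classes = classify_nodes(build_mst(star))
    assert classes[0] == JUNCTION
    assert all(classes[i] == TIP for i in (1, 2, 3))


def test_classify_matches_degree_histogram(rng):
    pts = rng.normal(size=(50, 3))
    g = build_mst(pts)
    classes = classify_nodes(g)
    for node in g.nodes:
        deg = g.degree[node]
        expected = TIP if deg <= 1 else INTERNAL if deg == 2 else JUNCTION
        assert classes[node] == expected


def test_principal_direction_along_y_axis():
    pts = np.column_stack([np.zeros(10), np.linspace(0, 1, 10), np.zeros(10)])
    line = principal_direction(pts)
    np.testing.assert_allclose(line.direction, [0, 1, 0], atol=1e-12)


def test_principal_direction_flips_to_positive_y():
    pts = np.column_stack([np.zeros(10), np.linspace(0, -1, 10), np.zeros(10)])
    line = principal_direction(pts)
    assert line.direction[1] > 0


def test_principal_direction_matches_eigensolver(rng):
    sample = rng.normal(size=(3000, 3)) * [10.0, 2.0, 1.0]
    rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    pts = sample @ rot.T
    line = principal_direction(pts)
    evals, evecs = np.linalg.eigh(np.cov(pts.T))
    lead = evecs[:, np.argmax(evals)]
    cos = abs(line.direction @ lead)
    assert np.degrees(np.arccos(min(cos, 1.0))) < 2.0


def test_principal_direction_rejects_identical_points():
    with pytest.raises(ValueError):
        principal_direction(np.ones((5, 3)))


def _vertical_plant_graph():
    """Stem along +Y with two side branches creating junctions."""
    stem = np.column_stack([np.zeros(9), np.arange(9) * 0.05, np.zeros(9)])
    side1 = np.array([[0.01, 0.1, 0.0], [0.05, 0.12, 0.0]])
    side2 = np.array([[0.01, 0.3, 0.0], [0.05, 0.32, 0.0]])
    pts = np.vstack([stem, side1, side2])
    g = build_mst(pts)
    classify_nodes(g)
    return g, pts


def test_highest_junction_prefers_max_y_within_radius():
    g, pts = _vertical_plant_graph()
    line = principal_direction(pts)
    top = select_highest_junction(g, line, radius=0.02)
    classes = nx.get_node_attributes(g, "node_class")
    assert classes[top] == JUNCTION
    junctions = [n for n, c in classes.items() if c == JUNCTION]
    assert pts[top, 1] == max(pts[j, 1] for j in junctions)


def test_junction_outside_radius_is_excluded():
    # a junction 3 cm off the vertical line sits above an on-line junction;
    # the 2 cm band must reject the higher, off-line one
    stem = np.column_stack([np.zeros(9), np.arange(9) * 0.05, np.zeros(9)])
    # two-point side stub attaching at the y=0.2 stem node makes it a junction
    on_line_stub = np.array([[0.015, 0.2, 0.0], [0.03, 0.2, 0.0]])
    off_junction = np.array(
        [[0.03, 0.45, 0.0], [0.05, 0.47, 0.0], [0.05, 0.43, 0.0]]
    )  # branch head 3 cm off line, with two children
    pts = np.vstack([stem, on_line_stub, off_junction])
    g = build_mst(pts)
    classes = classify_nodes(g)
    vertical = principal_direction(stem)
    top = select_highest_junction(g, vertical, radius=0.02)
    assert classes[top] == JUNCTION
    assert vertical.distance(pts[top][None])[0] <= 0.02
    assert pts[top, 1] == pytest.approx(0.2)


def test_root_node_is_lowest_on_line():
    g, pts = _vertical_plant_graph()
    line = principal_direction(pts)
    assert pts[root_node(g, line, 0.02), 1] == pytest.approx(0.0)


def test_root_node_rejects_offline_low_leaf_tip():
    stem = np.column_stack([np.zeros(9), 0.1 + np.arange(9) * 0.05, np.zeros(9)])
    low_tip = np.array([[0.05, 0.0, 0.0]])  # hangs below the base, 5 cm off axis
    pts = np.vstack([stem, low_tip])
    g = build_mst(pts)
    classify_nodes(g)
    line = principal_direction(stem)
    root = root_node(g, line, 0.02)
    assert pts[root, 1] == pytest.approx(0.1)


def test_root_node_errors_when_nothing_near_line():
    pts = np.column_stack([np.zeros(5), np.arange(5.0), np.zeros(5)])
    g = build_mst(pts)
    from skelphen.stem import PrincipalLine

    far_line = PrincipalLine(np.array([0.0, 1.0, 0.0]), np.array([5.0, 0.0, 0.0]))
    with pytest.raises(ValueError):
        root_node(g, far_line, 0.02)


def test_tree_path_trivial_and_full_path():
    pts = np.column_stack([np.zeros(5), np.arange(5.0), np.zeros(5)])
    g = build_mst(pts)
    assert tree_path(g, 2, 2) == [2]
    assert tree_path(g, 0, 4) == [0, 1, 2, 3, 4]


def test_tree_path_equals_dfs_unique_path(rng):
    pts = rng.normal(size=(60, 3))
    g = build_mst(pts)

    def dfs_path(src, dst):
        stack = [(src, [src])]
        seen = {src}
        while stack:
            node, path = stack.pop()
            if node == dst:
                return path
            for nb in g.neighbors(node):
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, path + [nb]))
        raise AssertionError("disconnected")

    for _ in range(20):
        a, b = rng.integers(0, 60, 2)
        assert tree_path(g, int(a), int(b)) == dfs_path(int(a), int(b))


def test_smooth_curve_straight_segment():
    curve = smooth_curve(np.array([[0, 0, 0], [0, 0.4, 0.0]]), step=0.001)
    assert curve.length == pytest.approx(0.4, rel=1e-9)
    cross = np.cross(np.diff(curve.samples, axis=0), [0, 1, 0])
    np.testing.assert_allclose(cross, 0.0, atol=1e-12)


def test_smooth_curve_quarter_circle_arc_length():
    t = np.linspace(0, np.pi / 2, 20)
    pts = 0.1 * np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
    curve = smooth_curve(pts, step=0.0005)
    assert curve.length == pytest.approx(np.pi * 0.1 / 2, rel=0.01)


def test_smooth_curve_dedupes_with_warning():
    pts = np.array([[0, 0, 0], [0, 0, 0], [0, 1.0, 0]])
    with pytest.warns(UserWarning, match="duplicate"):
        curve = smooth_curve(pts)
    assert curve.length == pytest.approx(1.0, rel=1e-9)


def test_label_stem_contains_cylinder_and_excludes_far_point(rng):
    curve = smooth_curve(np.array([[0, 0, 0], [0, 0.3, 0.0]]), step=0.001)
    n = 2000
    psi = rng.uniform(0, 2 * np.pi, n)
    y = rng.uniform(0, 0.3, n)
    cyl = np.column_stack([0.002 * np.cos(psi), y, 0.002 * np.sin(psi)])
    far = np.array([[0.03, 0.15, 0.0]])
    cloud = PointCloud(np.vstack([cyl, far]))
    mask = label_stem(cloud, curve, radius=0.003)
    assert mask[:n].all()
    assert not mask[n]


def test_label_stem_monotone_in_radius(rng):
    curve = smooth_curve(np.array([[0, 0, 0], [0.02, 0.3, 0.01]]), step=0.001)
    cloud = PointCloud(rng.uniform(-0.05, 0.35, (3000, 3)))
    m1 = label_stem(cloud, curve, radius=0.005)
    m2 = label_stem(cloud, curve, radius=0.02)
    assert np.all(m2[m1])


def test_refine_principal_line_recovers_axis_under_asymmetric_clutter(rng):
    stem = np.column_stack([np.zeros(200), np.linspace(0, 0.4, 200), np.zeros(200)])
    # leaf-like clutter around the stem, heavier on one side (tilts raw PCA ~7°)
    right = rng.uniform([0.03, 0.25, -0.02], [0.08, 0.40, 0.02], (60, 3))
    left = rng.uniform([-0.06, 0.05, -0.02], [-0.02, 0.20, 0.02], (30, 3))
    pts = np.vstack([stem, right, left])
    raw = principal_direction(pts)
    # coarse-to-fine trim, as the pipeline applies it
    refined = refine_principal_line(pts, raw, radius=0.04, n_iter=2)
    refined = refine_principal_line(pts, refined, radius=0.02, n_iter=2)
    tilt_raw = np.degrees(np.arccos(raw.direction[1]))
    tilt_ref = np.degrees(np.arccos(refined.direction[1]))
    assert tilt_ref < tilt_raw
    assert tilt_ref < 1.0
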