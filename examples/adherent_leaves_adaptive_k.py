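"""Split two adhering leaves with the adaptive-K refinement.

Convexity-based merging cannot separate two coplanar leaves that touch:
their shared border is neither concave nor a gap. The adaptive rule flags the
merged cluster as anomalously large (K = floor(size / mean leaf size) >= 2)
and K-means++ splits it spatially.
"""

import numpy as np

from skelphen import KMeansConfig, PointCloud, adaptive_k, segment_leaves

rng = np.random.default_rng(0)


def ellipse_patch(center, a, b, n):
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-1, 1, (n, 2))
        cand = cand[cand[:, 0] ** 2 + cand[:, 1] ** 2 <= 1][: n - len(pts)]
        pts.extend(cand)
    xy = np.asarray(pts) * [a, b]
    return np.column_stack([xy[:, 0] + center[0], np.full(n, center[1]), xy[:, 1] + center[2]])


# four ordinary leaves, well separated
leaves = [ellipse_patch((0.2 * np.cos(i * 1.6), 0.25 + 0.08 * i, 0.2 * np.sin(i * 1.6)),
                        0.025, 0.012, 900) for i in range(4)]
# one adhering pair: two larger ellipses tangent at the origin
pair = np.vstack([ellipse_patch((-0.026, 0.1, 0), 0.025, 0.014, 1300),
                  ellipse_patch((+0.026, 0.1, 0), 0.025, 0.014, 1300)])

cloud = PointCloud(np.vstack(leaves + [pair]))
seg = segment_leaves(cloud, km_cfg=KMeansConfig(seed=0))

print(f"coarse cluster sizes: {list(seg.coarse_sizes)} (mean {seg.mean_size:.0f})")
print(f"adaptive K per coarse cluster: {list(adaptive_k(seg.coarse_sizes))}")
print(f"clusters split by K-means++: {seg.split_k}")
print(f"final leaf instances: {seg.n_leaves} (4 single + 2 from the adhering pair)")
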