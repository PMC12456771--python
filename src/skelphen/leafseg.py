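"""Leaf-instance segmentation of the stem-subtracted cloud.

Three stages:

1. **Supervoxel over-segmentation** (VCCS-style): the cloud is voxelised at
   ``R_voxel``; seeds on an ``R_seed`` grid grow supervoxels by seeded flow
   through the 26-connected voxel graph, assigning each voxel to the seed
   minimising the similarity distance

       D = w_c D_c^2 / c_max^2  +  w_s D_s^2 / (3 R_seed^2)  +  w_n D_n^2

   with D_c the curvature difference, D_s the Euclidean centroid distance and
   D_n the histogram-intersection distance between FPFH descriptors.
2. **LCCP convexity merging**: adjacent supervoxels are merged across locally
   convex edges (with an angular concavity tolerance β_th and a smoothness
   gate θ_th); concave creases — where one leaf presses against another —
   survive as segment borders. Tiny clusters are dropped as noise.
3. **Adaptive K-means++ refinement**: clusters much larger than the average
   leaf (point count S_e with K = ⌊S_e/μ̄⌋ ≥ 2) are split spatially into K
   sub-leaves with K-means++ seeding that enforces a minimum distance between
   initial centres.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .features import FPFH_BLOCK_SUM, fpfh, normals_and_curvature

__all__ = [
    "VCCSConfig",
    "LCCPConfig",
    "KMeansConfig",
    "Supervoxel",
    "LeafSegmentation",
    "similarity_distance",
    "vccs_supervoxels",
    "lccp_merge",
    "adaptive_k",
    "kmeanspp_split",
    "segment_leaves",
]

_26_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)


@dataclass
class VCCSConfig:
    R_voxel: float = 0.008
    R_seed: float = 0.01
    w_c: float = 0.2
    w_s: float = 0.4
    w_n: float = 1.0
    c_max: float | None = None  # None → per-neighbourhood maximum curvature
    max_rounds: int = 10

    def __post_init__(self) -> None:
        if not self.R_voxel > 0:
            raise ValueError(f"R_voxel must be > 0, got {self.R_voxel}")
        if self.R_seed < self.R_voxel:
            raise ValueError("R_seed must be >= R_voxel")
        if min(self.w_c, self.w_s, self.w_n) < 0:
            raise ValueError("weights must be >= 0")


@dataclass
class LCCPConfig:
    beta_th: float = 20.0  # degrees, concavity tolerance
    theta_th: float = 0.1  # radians, smoothness gate on normal angle
    min_cluster_points: int = 100
    # merge only supervoxels whose point sets come this close (m). Voxel
    # 26-connectivity at R_voxel = 8 mm can bridge ~14 mm air gaps between
    # separate blades; the contact test cuts those. None disables the test.
    contact_dist: float | None = 0.004

    def __post_init__(self) -> None:
        if not 0 < self.beta_th < 90:
            raise ValueError(f"beta_th must be in (0, 90) degrees, got {self.beta_th}")
        if self.min_cluster_points < 0:
            raise ValueError("min_cluster_points must be >= 0")


@dataclass
class KMeansConfig:
    max_iter: int = 100
    tol: float = 0.001  # m (0.1 cm convergence threshold)
    min_center_sep: float = 0.002  # m (0.2 cm between initial centres)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")


@dataclass
class Supervoxel:
    id: int
    point_indices: np.ndarray
    centroid: np.ndarray
    normal: np.ndarray
    curvature: float
    fpfh: np.ndarray
    adjacency: set = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.point_indices)


@dataclass
class LeafSegmentation:
    """Final per-point leaf labels plus the statistics that drove splitting."""

    labels: np.ndarray  # -1 = dropped/noise, 0..m-1 leaf instances
    coarse_sizes: np.ndarray  # S_i of the LCCP clusters
    mean_size: float  # μ̄
    split_k: dict  # coarse cluster id → K used (only K >= 2)

    @property
    def n_leaves(self) -> int:
        return int(self.labels.max() + 1) if len(self.labels) else 0


def similarity_distance(
    d_c: float, d_s: float, d_n: float, cfg: VCCSConfig, c_max: float
) -> float:
    """Voxel-to-supervoxel similarity distance (smaller = more similar)."""
    c = max(c_max, 1e-12)
    return (
        cfg.w_c * d_c**2 / c**2
        + cfg.w_s * d_s**2 / (3.0 * cfg.R_seed**2)
        + cfg.w_n * d_n**2
    )


def _hik_distance(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Histogram-intersection-kernel distance between FPFH rows, in [0, 1]."""
    inter = np.minimum(h1, h2).sum(axis=-1)
    return 1.0 - inter / (3.0 * FPFH_BLOCK_SUM)


def _voxelize(points: np.ndarray, R: float):
    origin = points.min(axis=0)
    key = np.floor((points - origin) / R).astype(np.int64)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    return uniq, inv, origin


class _VoxelGrid:
    """Occupied-voxel bookkeeping: centroids, features, 26-neighbour lists."""

    def __init__(self, cloud_pts: np.ndarray, cfg: VCCSConfig):
        self.cfg = cfg
        self.keys, self.point_voxel, self.origin = _voxelize(cloud_pts, cfg.R_voxel)
        nv = len(self.keys)
        self.n_voxels = nv
        counts = np.bincount(self.point_voxel, minlength=nv)
        self.counts = counts
        self.centroids = np.column_stack(
            [
                np.bincount(self.point_voxel, weights=cloud_pts[:, c], minlength=nv)
                for c in range(3)
            ]
        ) / counts[:, None]

        key_set = {tuple(k): i for i, k in enumerate(self.keys)}
        self.neighbors: list[np.ndarray] = []
        for k in self.keys:
            nb = [
                key_set[t]
                for off in _26_OFFSETS
                if (t := tuple(k + off)) in key_set
            ]
            self.neighbors.append(np.array(nb, dtype=np.int64))

        self.normals, self.curvature = self._voxel_normals(cloud_pts)
        self._orient_normals()
        self.fpfh = fpfh(self.centroids, self.normals, radius=1.5 * cfg.R_seed)

        # per-voxel neighbourhood curvature maximum (similarity normaliser)
        self.c_nb = np.array(
            [
                max(self.curvature[i], self.curvature[nb].max() if len(nb) else 0.0)
                for i, nb in enumerate(self.neighbors)
            ]
        )

    def _voxel_normals(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-voxel normal/curvature from raw points of the voxel + neighbours.

        The fit pools each voxel's member points with those of its 26
        neighbours (~a 3-voxel-wide patch, O(10^3) points): a single voxel can
        hold only a sliver of a blade whose in-plane spread is smaller than
        the sensor noise, which makes a lone-voxel fit meaningless, while a
        handful of neighbouring voxel *centroids* is too few samples. Pooled
        raw-point moments give sub-degree normals on noisy planar blades.
        """
        nv = self.n_voxels
        inv = self.point_voxel
        cnt = np.bincount(inv, minlength=nv).astype(float)
        s1 = np.column_stack(
            [np.bincount(inv, weights=pts[:, c], minlength=nv) for c in range(3)]
        )
        s2 = np.empty((nv, 3, 3))
        for a in range(3):
            for b in range(a, 3):
                m = np.bincount(inv, weights=pts[:, a] * pts[:, b], minlength=nv)
                s2[:, a, b] = m
                s2[:, b, a] = m

        cnt_n, s1_n, s2_n = cnt.copy(), s1.copy(), s2.copy()
        for v in range(nv):
            for nb in self.neighbors[v]:
                cnt_n[v] += cnt[nb]
                s1_n[v] += s1[nb]
                s2_n[v] += s2[nb]

        mean = s1_n / np.maximum(cnt_n, 1.0)[:, None]
        cov = s2_n / np.maximum(cnt_n, 1.0)[:, None, None] - np.einsum(
            "ni,nj->nij", mean, mean
        )
        evals, evecs = np.linalg.eigh(cov)
        evals = np.maximum(evals, 0.0)
        normals = evecs[:, :, 0].copy()
        total = evals.sum(axis=1)
        curvature = np.where(total > 1e-18, evals[:, 0] / np.maximum(total, 1e-18), 0.0)
        lone = cnt_n < 3  # not enough support even with neighbours
        normals[lone] = [0.0, 1.0, 0.0]
        curvature[lone] = 0.0
        return normals, curvature

    def _orient_normals(self) -> None:
        anchor = self.centroids.mean(axis=0)
        reference = self.centroids - anchor
        _orient_normals_consistently(self.normals, reference, self.neighbors)


def _orient_normals_consistently(
    normals: np.ndarray, reference: np.ndarray, neighbors: list[np.ndarray]
) -> None:
    """BFS flip-propagation so normals agree across the adjacency graph.

    A pointwise heuristic (e.g. away-from-centroid) flips sign along a line
    across any surface whose plane grazes the reference direction, and a sign
    seam reads as a deep concavity to convexity tests. Propagating
    flip-to-agree along a spanning forest removes seams inside each connected
    surface; each component is then majority-voted against ``reference`` to
    keep the rough outward orientation. In-place.
    """
    n = len(normals)
    visited = np.zeros(n, dtype=bool)
    for start in range(n):
        if visited[start]:
            continue
        comp = [start]
        visited[start] = True
        queue = [start]
        while queue:
            u = queue.pop()
            for v in neighbors[u]:
                if not visited[v]:
                    visited[v] = True
                    if normals[v] @ normals[u] < 0:
                        normals[v] *= -1.0
                    comp.append(int(v))
                    queue.append(int(v))
        comp = np.asarray(comp)
        agree = np.einsum("ij,ij->i", normals[comp], reference[comp])
        if np.sum(agree < 0) > len(comp) / 2:
            normals[comp] *= -1.0


def _pick_seeds(grid: _VoxelGrid, cfg: VCCSConfig) -> np.ndarray:
    """One seed voxel per occupied R_seed cell, culling poorly connected seeds."""
    cell = np.floor((grid.centroids - grid.origin) / cfg.R_seed).astype(np.int64)
    uniq, inv = np.unique(cell, axis=0, return_inverse=True)
    seeds = []
    for c in range(len(uniq)):
        members = np.flatnonzero(inv == c)
        center = grid.origin + (uniq[c] + 0.5) * cfg.R_seed
        best = members[np.argmin(np.linalg.norm(grid.centroids[members] - center, axis=1))]
        if len(grid.neighbors[best]) >= 3:
            seeds.append(best)
    return np.asarray(seeds, dtype=np.int64)


def vccs_supervoxels(
    cloud: PointCloud | np.ndarray, cfg: VCCSConfig | None = None
) -> list[Supervoxel]:
    """Seeded flow clustering of the voxelised cloud into supervoxels.

    Voxels unreachable from any seed (isolated clumps) become their own
    supervoxels so the result is always a partition of occupied voxels.
    """
    cfg = cfg or VCCSConfig()
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, float)
    if len(pts) == 0:
        raise ValueError("cannot build supervoxels on an empty cloud")
    grid = _VoxelGrid(pts, cfg)
    seeds = _pick_seeds(grid, cfg)
    if len(seeds) == 0:
        raise ValueError("no supervoxel seeds survived culling; try a smaller R_seed")

    nv = grid.n_voxels
    n_sv = len(seeds)
    sv_centroid = grid.centroids[seeds].copy()
    sv_curv = grid.curvature[seeds].copy()
    sv_fpfh = grid.fpfh[seeds].copy()

    labels = np.full(nv, -1, dtype=np.int64)
    for _round in range(cfg.max_rounds):
        new_labels = np.full(nv, -1, dtype=np.int64)
        # seeded flow: Dijkstra-style growth restricted to voxel connectivity
        heap = []
        for s, v in enumerate(seeds):
            heapq.heappush(heap, (0.0, s, int(v)))
        while heap:
            d, s, v = heapq.heappop(heap)
            if new_labels[v] != -1:
                continue
            new_labels[v] = s
            for nb in grid.neighbors[v]:
                if new_labels[nb] != -1:
                    continue
                c_max = cfg.c_max if cfg.c_max is not None else grid.c_nb[nb]
                d_c = abs(grid.curvature[nb] - sv_curv[s])
                d_s = float(np.linalg.norm(grid.centroids[nb] - sv_centroid[s]))
                d_n = float(_hik_distance(grid.fpfh[nb], sv_fpfh[s]))
                heapq.heappush(
                    heap, (similarity_distance(d_c, d_s, d_n, cfg, c_max), s, int(nb))
                )
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        # refresh supervoxel features from membership
        for s in range(n_sv):
            members = np.flatnonzero(labels == s)
            if len(members):
                sv_centroid[s] = grid.centroids[members].mean(axis=0)
                sv_curv[s] = grid.curvature[members].mean()
                sv_fpfh[s] = grid.fpfh[members].mean(axis=0)

    # orphan components (no seed reachable) become their own supervoxels
    next_id = n_sv
    for v in np.flatnonzero(labels == -1):
        if labels[v] != -1:
            continue
        stack = [int(v)]
        labels[v] = next_id
        while stack:
            u = stack.pop()
            for nb in grid.neighbors[u]:
                if labels[nb] == -1:
                    labels[nb] = next_id
                    stack.append(int(nb))
        next_id += 1

    supervoxels = []
    for s in range(next_id):
        vox = np.flatnonzero(labels == s)
        if len(vox) == 0:
            continue
        pts_idx = np.flatnonzero(np.isin(grid.point_voxel, vox))
        nrm = grid.normals[vox].mean(axis=0)
        nn = np.linalg.norm(nrm)
        nrm = nrm / nn if nn > 1e-12 else np.array([0.0, 1.0, 0.0])
        supervoxels.append(
            Supervoxel(
                id=len(supervoxels),
                point_indices=pts_idx,
                centroid=grid.centroids[vox].mean(axis=0),
                normal=nrm,
                curvature=float(grid.curvature[vox].mean()),
                fpfh=grid.fpfh[vox].mean(axis=0),
            )
        )
    # adjacency from 26-connectivity of labeled voxels
    remap = {s: i for i, s in enumerate(sorted(set(labels)))}
    compact = np.array([remap[s] for s in labels])
    for v in range(nv):
        for nb in grid.neighbors[v]:
            a, b = compact[v], compact[nb]
            if a != b:
                supervoxels[a].adjacency.add(b)
                supervoxels[b].adjacency.add(a)
    return supervoxels


def _edge_convex(sv_i: Supervoxel, sv_j: Supervoxel, cfg: LCCPConfig) -> bool:
    """Extended convexity + sanity criterion for one adjacency edge."""
    n_i, n_j = sv_i.normal, sv_j.normal
    cosang = float(np.clip(n_i @ n_j, -1.0, 1.0))
    ang = np.arccos(cosang)
    if ang < cfg.theta_th:  # smoothness gate: near-parallel normals
        return True
    d = sv_i.centroid - sv_j.centroid
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        return True
    dhat = d / nd
    # sanity criterion: cut edges whose normal-cross direction is too aligned
    # with the connecting line (geometrically singular configuration)
    if ang > 0.3:
        s = np.cross(n_i, n_j)
        sn = np.linalg.norm(s)
        if sn > 1e-12:
            fold = np.degrees(np.arccos(min(abs(float(s @ dhat / sn)), 1.0)))
            if fold < 60.0:  # s within 30 degrees of the connecting line
                return False
    return float((n_i - n_j) @ dhat) >= -np.sin(np.deg2rad(cfg.beta_th))


def _in_contact(
    sv_i: Supervoxel, sv_j: Supervoxel, points: np.ndarray, dist: float,
    rng_cap: int = 250,
) -> bool:
    """Whether the two supervoxels' member point sets come within ``dist``."""
    pi = points[sv_i.point_indices]
    pj = points[sv_j.point_indices]
    if len(pi) > rng_cap:
        pi = pi[:: len(pi) // rng_cap + 1]
    if len(pj) > rng_cap:
        pj = pj[:: len(pj) // rng_cap + 1]
    d, _ = cKDTree(pj).query(pi, k=1)
    return bool(d.min() <= dist)


def lccp_merge(
    supervoxels: list[Supervoxel],
    cfg: LCCPConfig | None = None,
    points: np.ndarray | None = None,
) -> np.ndarray:
    """Merge supervoxels across convex edges; return per-supervoxel cluster ids.

    ``points`` (the segmented cloud) enables the surface-contact gate on
    merge edges. Clusters whose total point count is <= ``min_cluster_points``
    get id -1 (dropped as noise/outliers).
    """
    cfg = cfg or LCCPConfig()
    n = len(supervoxels)
    uf = _DisjointSet(n)
    for i, sv in enumerate(supervoxels):
        for j in sv.adjacency:
            if j > i and _edge_convex(sv, supervoxels[j], cfg):
                if (
                    points is not None
                    and cfg.contact_dist is not None
                    and not _in_contact(sv, supervoxels[j], points, cfg.contact_dist)
                ):
                    continue
                uf.union(i, j)
    roots = [uf.find(i) for i in range(n)]
    ids = {}
    cluster = np.empty(n, dtype=np.int64)
    for i, r in enumerate(roots):
        cluster[i] = ids.setdefault(r, len(ids))
    # size filter on point counts
    sizes = np.zeros(len(ids), dtype=np.int64)
    for i, sv in enumerate(supervoxels):
        sizes[cluster[i]] += sv.size
    keep = sizes > cfg.min_cluster_points
    remap = np.full(len(ids), -1, dtype=np.int64)
    remap[keep] = np.arange(int(keep.sum()))
    return remap[cluster]


class _DisjointSet:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, a: int) -> int:
        while self.p[a] != a:
            self.p[a] = self.p[self.p[a]]
            a = self.p[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[max(ra, rb)] = min(ra, rb)


def adaptive_k(cluster_sizes: np.ndarray) -> np.ndarray:
    """Per-cluster split count K = ⌊S_e/μ̄⌋ for anomalous clusters (S_i > μ̄).

    Returns K=1 (no split) for normal clusters and whenever the computed K
    is below 2.
    """
    sizes = np.asarray(cluster_sizes, dtype=float)
    if len(sizes) == 0:
        raise ValueError("need at least one cluster")
    mu = sizes.mean()
    k = np.ones(len(sizes), dtype=np.int64)
    anomalous = sizes > mu
    k[anomalous] = np.floor(sizes[anomalous] / mu).astype(np.int64)
    k[k < 2] = 1
    return k


def kmeanspp_split(
    points: np.ndarray, K: int, cfg: KMeansConfig | None = None
) -> np.ndarray:
    """K-means++ (D² seeding with a minimum centre separation) + Lloyd on XYZ."""
    cfg = cfg or KMeansConfig()
    points = np.asarray(points, float)
    n = len(points)
    if not 2 <= K <= n:
        raise ValueError(f"need n >= K >= 2, got n={n}, K={K}")
    rng = np.random.default_rng(cfg.seed)

    sep = cfg.min_center_sep
    centers = [points[rng.integers(n)]]
    while len(centers) < K:
        d2 = np.min(
            [np.sum((points - c) ** 2, axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        placed = False
        for _attempt in range(50):
            if total <= 0:
                cand = points[rng.integers(n)]
            else:
                cand = points[rng.choice(n, p=d2 / total)]
            if all(np.linalg.norm(cand - c) >= sep for c in centers):
                centers.append(cand)
                placed = True
                break
        if not placed:
            sep /= 2.0
            warnings.warn(
                f"could not place separated centres; relaxing min_center_sep to {sep}",
                stacklevel=2,
            )
    centers = np.array(centers)

    labels = np.zeros(n, dtype=np.int64)
    for _it in range(cfg.max_iter):
        d = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
        labels = np.argmin(d, axis=1)
        new_centers = centers.copy()
        for kk in range(K):
            m = labels == kk
            if m.any():
                new_centers[kk] = points[m].mean(axis=0)
            else:  # re-seed empty cluster at the farthest point
                new_centers[kk] = points[np.argmax(np.min(d, axis=1))]
        shift = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        if shift < cfg.tol:
            break
    d = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
    return np.argmin(d, axis=1)


def segment_leaves(
    leaf_cloud: PointCloud,
    vccs_cfg: VCCSConfig | None = None,
    lccp_cfg: LCCPConfig | None = None,
    km_cfg: KMeansConfig | None = None,
) -> LeafSegmentation:
    """Full leaf-instance segmentation: supervoxels → LCCP → adaptive K-means++."""
    if len(leaf_cloud) == 0:
        raise ValueError("empty leaf cloud")
    vccs_cfg = vccs_cfg or VCCSConfig()
    lccp_cfg = lccp_cfg or LCCPConfig()
    km_cfg = km_cfg or KMeansConfig()

    supervoxels = vccs_supervoxels(leaf_cloud, vccs_cfg)
    sv_cluster = lccp_merge(supervoxels, lccp_cfg, points=leaf_cloud.points)

    n_pts = len(leaf_cloud)
    coarse = np.full(n_pts, -1, dtype=np.int64)
    for sv, cid in zip(supervoxels, sv_cluster):
        coarse[sv.point_indices] = cid

    n_coarse = int(sv_cluster.max() + 1) if (sv_cluster >= 0).any() else 0
    if n_coarse == 0:
        return LeafSegmentation(coarse, np.empty(0, np.int64), 0.0, {})

    sizes = np.array([(coarse == c).sum() for c in range(n_coarse)], dtype=np.int64)
    ks = adaptive_k(sizes)

    final = np.full(n_pts, -1, dtype=np.int64)
    split_k = {}
    next_label = 0
    for c in range(n_coarse):
        members = np.flatnonzero(coarse == c)
        if ks[c] >= 2 and len(members) >= ks[c]:
            sub = kmeanspp_split(leaf_cloud.points[members], int(ks[c]), km_cfg)
            split_k[c] = int(ks[c])
            for kk in range(int(ks[c])):
                final[members[sub == kk]] = next_label
                next_label += 1
        else:
            final[members] = next_label
            next_label += 1
    return LeafSegmentation(final, sizes, float(sizes.mean()), split_k)
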