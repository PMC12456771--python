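"""Leaf surface meshing: triangulation, boundary rings, hole repair, area.

Leaves are planar-to-slightly-curved, so each leaf cloud is projected onto its
PCA plane and Delaunay-triangulated there; triangles with any edge longer than
``mu`` x (median nearest-neighbour spacing), capped at ``max_edge``, are
discarded. That deliberately opens holes wherever the sampling is locally
sparse — exactly the defect the boundary-ring detector and the point-link hole
filler then repair. Areas are summed over the (3D) triangles of the repaired
mesh; the optional halving serves registered multi-view clouds that sample
both faces of each leaf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "LeafMesh",
    "smooth_to_local_plane",
    "triangulate_leaf",
    "boundary_rings",
    "fill_holes",
    "leaf_area",
]


@dataclass
class LeafMesh:
    vertices: np.ndarray  # (V, 3)
    triangles: np.ndarray  # (F, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if len(self.triangles) and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle indices out of range")

    def edge_set(self) -> dict[tuple[int, int], int]:
        """Undirected edge → number of incident triangles."""
        count: dict[tuple[int, int], int] = {}
        for tri in self.triangles:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                e = (min(a, b), max(a, b))
                count[e] = count.get(e, 0) + 1
        return count


def smooth_to_local_plane(points: np.ndarray, k: int = 20) -> np.ndarray:
    """Project each point onto the best-fit plane of its k nearest neighbours.

    A moving-least-squares-style denoiser: surface roughness inflates summed
    triangle area, so leaf clouds are flattened locally before meshing.
    """
    points = np.asarray(points, float)
    if len(points) <= k:
        return points.copy()
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1, workers=-1)
    nbr = points[idx]
    mean = nbr.mean(axis=1)
    centered = nbr - mean[:, None, :]
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, evecs = np.linalg.eigh(cov)
    normal = evecs[:, :, 0]
    off = np.einsum("ij,ij->i", points - mean, normal)
    return points - off[:, None] * normal


def triangulate_leaf(
    points: np.ndarray, mu: float = 6.0, max_edge: float = 0.01
) -> LeafMesh:
    """Triangulate a near-planar leaf cloud, leaving holes at sparse spots.

    The cloud is projected onto its PCA plane, Delaunay-triangulated in 2D,
    and triangles with any 3D edge exceeding min(mu x median NN spacing,
    max_edge) are removed.
    """
    points = np.asarray(points, float)
    if len(points) < 3:
        raise ValueError(f"need at least 3 points to triangulate, got {len(points)}")
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    plane2d = centered @ vt[:2].T

    if len(points) == 3:
        tris = np.array([[0, 1, 2]])
    else:
        try:
            tris = Delaunay(plane2d).simplices
        except Exception as exc:  # qhull degenerate input
            raise ValueError(f"degenerate leaf cloud, cannot triangulate: {exc}") from exc

    if len(points) > 3:
        tree = cKDTree(points)
        nn = tree.query(points, k=2, workers=-1)[0][:, 1]
        thresh = min(mu * float(np.median(nn)), max_edge)
        e = points[tris]
        lengths = np.stack(
            [
                np.linalg.norm(e[:, 0] - e[:, 1], axis=1),
                np.linalg.norm(e[:, 1] - e[:, 2], axis=1),
                np.linalg.norm(e[:, 2] - e[:, 0], axis=1),
            ]
        )
        tris = tris[lengths.max(axis=0) <= thresh]
    if len(tris) == 0:
        raise ValueError("no triangles within the edge-length threshold")
    return LeafMesh(points, tris)


def boundary_rings(mesh: LeafMesh) -> tuple[list[list[int]], int | None]:
    """Closed loops of boundary edges (edges with exactly one triangle).

    Returns (rings, outer_ring_index); the ring with the greatest total edge
    length is the outer boundary, all others are internal holes. A closed mesh
    returns ([], None).
    """
    counts = mesh.edge_set()
    boundary = [e for e, c in counts.items() if c == 1]
    if not boundary:
        return [], None
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    for v, nbrs in adj.items():
        if len(nbrs) % 2 == 1:
            raise ValueError(f"non-closable boundary chain at vertex {v}")

    unused = {e for e in boundary}
    rings: list[list[int]] = []
    while unused:
        a, b = next(iter(unused))
        unused.discard((a, b))
        ring = [a, b]
        while True:
            cur, prev = ring[-1], ring[-2]
            nxt = None
            for cand in adj[cur]:
                e = (min(cur, cand), max(cur, cand))
                if cand != prev and e in unused:
                    nxt = cand
                    unused.discard(e)
                    break
            if nxt is None:
                if ring[-1] == ring[0] or (
                    (min(ring[-1], ring[0]), max(ring[-1], ring[0])) not in counts
                ):
                    break
                raise ValueError(f"non-closable boundary chain at vertex {cur}")
            if nxt == ring[0]:
                break
            ring.append(nxt)
        if len(ring) >= 3:
            rings.append(ring)

    lengths = [
        float(
            sum(
                np.linalg.norm(mesh.vertices[r[i]] - mesh.vertices[r[(i + 1) % len(r)]])
                for i in range(len(r))
            )
        )
        for r in rings
    ]
    outer = int(np.argmax(lengths)) if rings else None
    return rings, outer


def _ear_clip_ring(vertices: np.ndarray, ring: list[int]) -> list[tuple[int, int, int]]:
    """Fill one hole by repeatedly clipping the minimum-interior-angle vertex."""
    loop = list(ring)
    tris: list[tuple[int, int, int]] = []
    guard = 4 * len(loop)
    while len(loop) > 3 and guard > 0:
        guard -= 1
        best, best_ang = None, np.inf
        m = len(loop)
        for i in range(m):
            a, b, c = loop[i - 1], loop[i], loop[(i + 1) % m]
            v1 = vertices[a] - vertices[b]
            v2 = vertices[c] - vertices[b]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-15 or n2 < 1e-15:
                continue
            ang = np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
            if ang < best_ang:
                best_ang, best = ang, i
        if best is None:
            raise ValueError("degenerate ring")
        a, b, c = loop[best - 1], loop[best], loop[(best + 1) % len(loop)]
        tris.append((a, b, c))
        loop.pop(best)
    if len(loop) == 3:
        tris.append((loop[0], loop[1], loop[2]))
    elif guard == 0:
        raise ValueError("ear clipping did not converge")
    return tris


def fill_holes(mesh: LeafMesh, rings: list[list[int]], outer: int | None) -> LeafMesh:
    """Fill every internal ring with ear-style point linking; outer untouched.

    A self-intersecting/degenerate ring falls back to a centroid fan with a
    warning. The returned mesh has no internal boundary rings.
    """
    vertices = mesh.vertices
    new_tris = [tuple(t) for t in mesh.triangles]
    extra_vertices = []
    for ri, ring in enumerate(rings):
        if ri == outer:
            continue
        try:
            new_tris.extend(_ear_clip_ring(vertices, ring))
        except ValueError:
            warnings.warn(
                "ear clipping failed on a hole ring; using centroid fan", stacklevel=2
            )
            centroid = vertices[ring].mean(axis=0)
            cid = len(vertices) + len(extra_vertices)
            extra_vertices.append(centroid)
            m = len(ring)
            for i in range(m):
                new_tris.append((ring[i], ring[(i + 1) % m], cid))
    verts = vertices if not extra_vertices else np.vstack([vertices, extra_vertices])
    return LeafMesh(verts, np.array(new_tris, dtype=np.int64))


def leaf_area(mesh: LeafMesh, double_sided: bool = False) -> float:
    """Sum of triangle areas; halved iff the cloud samples both leaf faces."""
    v = mesh.vertices[mesh.triangles]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    area = 0.5 * np.linalg.norm(cross, axis=1).sum()
    return float(area / 2.0) if double_sided else float(area)
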