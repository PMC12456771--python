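"""Local surface features: normals, curvature, and FPFH descriptors.

Normals come from the smallest eigenvector of the k-NN covariance; curvature
is the surface-variation ratio λ0/(λ0+λ1+λ2) ∈ [0, 1/3]. FPFH is the standard
33-dimensional Fast Point Feature Histogram: three Darboux-frame pair angles
(α, φ, θ) binned into 11 bins each over a radius neighbourhood, with each
point's simplified histogram (SPFH) augmented by the distance-weighted SPFHs
of its neighbours. Each 11-bin block is normalised to sum to 100.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["normals_and_curvature", "fpfh", "FPFH_BLOCK_SUM"]

FPFH_BLOCK_SUM = 100.0
_N_BINS = 11


def normals_and_curvature(
    points: np.ndarray, k: int = 15, orient_from: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point unit normals and surface-variation curvature from k-NN PCA.

    Normals are sign-oriented away from ``orient_from`` (default: the cloud
    centroid), a cheap consistent orientation for organs arranged around a
    central stem. Degenerate neighbourhoods get curvature 0 with a warning.
    """
    points = np.asarray(points, float)
    n = len(points)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points, got {n}")
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1, workers=-1)
    nbr = points[idx]  # (n, k+1, 3) includes self
    centered = nbr - nbr.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / (k + 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    normals = evecs[:, :, 0]
    total = evals.sum(axis=1)
    degenerate = total <= 1e-18
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate neighbourhoods; curvature set to 0",
            stacklevel=2,
        )
    curvature = np.where(degenerate, 0.0, evals[:, 0] / np.where(degenerate, 1.0, total))

    anchor = points.mean(axis=0) if orient_from is None else np.asarray(orient_from, float)
    flip = np.einsum("ij,ij->i", normals, points - anchor) < 0
    normals[flip] *= -1.0
    return normals, curvature


def _pair_features(p_i, p_j, n_i, n_j):
    """Darboux pair angles (f1=α, f2=φ, f3=θ) with standard source selection."""
    d = p_j - p_i
    dist = np.linalg.norm(d, axis=1)
    dist[dist == 0.0] = 1.0
    dhat = d / dist[:, None]
    # source = point whose normal makes the smaller angle with the connecting line
    swap = np.abs(np.einsum("ij,ij->i", n_i, dhat)) < np.abs(
        np.einsum("ij,ij->i", n_j, dhat)
    )
    ps = np.where(swap[:, None], p_j, p_i)
    pt = np.where(swap[:, None], p_i, p_j)
    ns = np.where(swap[:, None], n_j, n_i)
    nt = np.where(swap[:, None], n_i, n_j)
    dvec = pt - ps
    dd = np.linalg.norm(dvec, axis=1)
    dd[dd == 0.0] = 1.0
    dhat = dvec / dd[:, None]
    u = ns
    v = np.cross(dhat, u)
    vnorm = np.linalg.norm(v, axis=1)
    vnorm[vnorm == 0.0] = 1.0
    v = v / vnorm[:, None]
    w = np.cross(u, v)
    f1 = np.einsum("ij,ij->i", v, nt)  # α ∈ [-1, 1]
    f2 = np.einsum("ij,ij->i", u, dhat)  # φ ∈ [-1, 1]
    f3 = np.arctan2(np.einsum("ij,ij->i", w, nt), np.einsum("ij,ij->i", u, nt))
    return f1, f2, f3


def _bin(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    b = np.floor((values - lo) / (hi - lo) * _N_BINS).astype(np.int64)
    return np.clip(b, 0, _N_BINS - 1)


def fpfh(points: np.ndarray, normals: np.ndarray, radius: float) -> np.ndarray:
    """33-dim FPFH per point (3 blocks of 11 bins, each summing to 100).

    Isolated points (no neighbour within ``radius``) get a zero histogram.
    """
    points = np.asarray(points, float)
    normals = np.asarray(normals, float)
    n = len(points)
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    spfh = np.zeros((n, 3, _N_BINS))
    deg = np.zeros(n)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        f1, f2, f3 = _pair_features(points[i], points[j], normals[i], normals[j])
        b1 = _bin(f1, -1.0, 1.0)
        b2 = _bin(f2, -1.0, 1.0)
        b3 = _bin(f3, -np.pi, np.pi)
        for side in (i, j):
            np.add.at(spfh, (side, 0, b1), 1.0)
            np.add.at(spfh, (side, 1, b2), 1.0)
            np.add.at(spfh, (side, 2, b3), 1.0)
        np.add.at(deg, i, 1.0)
        np.add.at(deg, j, 1.0)

    iso = deg == 0
    if iso.any():
        warnings.warn(f"{int(iso.sum())} isolated points: zero FPFH", stacklevel=2)

    # FPFH_i = SPFH_i + (1/k) Σ_j SPFH_j / ω_ij, ω = neighbour distance
    out = spfh.copy()
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        w_ij = np.linalg.norm(points[i] - points[j], axis=1)
        w_ij[w_ij == 0.0] = 1e-12
        inv = 1.0 / w_ij
        contrib_j = spfh[j] * inv[:, None, None]
        contrib_i = spfh[i] * inv[:, None, None]
        acc = np.zeros_like(spfh)
        np.add.at(acc, i, contrib_j)
        np.add.at(acc, j, contrib_i)
        k_i = np.maximum(deg, 1.0)
        out = spfh + acc / k_i[:, None, None]

    sums = out.sum(axis=2, keepdims=True)
    sums[sums == 0.0] = 1.0
    out = out / sums * FPFH_BLOCK_SUM
    out[iso] = 0.0
    return out.reshape(n, 3 * _N_BINS)
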