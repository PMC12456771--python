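"""Denoising and cropping of merged plant clouds.

Statistical outlier removal (SOR) discards points whose mean distance to their
k nearest neighbours exceeds the cloud-wide mean by more than a multiple of the
cloud-wide standard deviation. Defaults k=100, multiplier=1.1 follow the
published operating point of the acquisition pipeline this package models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud

__all__ = ["SORConfig", "sor_filter", "crop_box"]


@dataclass
class SORConfig:
    k_neighbors: int = 100
    std_multiplier: float = 1.1

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError(f"k_neighbors must be >= 1, got {self.k_neighbors}")
        if not self.std_multiplier > 0:
            raise ValueError(f"std_multiplier must be > 0, got {self.std_multiplier}")


def sor_filter(
    cloud: PointCloud, cfg: SORConfig | None = None
) -> tuple[PointCloud, np.ndarray]:
    """Single-pass statistical outlier removal.

    Returns (kept cloud with original point order, removed indices). Global
    mean/std are computed once on the input cloud; the k-NN set excludes the
    query point itself.
    """
    cfg = cfg or SORConfig()
    n = len(cloud)
    if n <= cfg.k_neighbors:
        raise ValueError(
            f"SOR needs more than k_neighbors={cfg.k_neighbors} points, got {n}"
        )
    tree = cKDTree(cloud.points)
    # +1 because the nearest neighbour of each point is itself
    dists, _ = tree.query(cloud.points, k=cfg.k_neighbors + 1, workers=-1)
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + cfg.std_multiplier * mean_d.std()
    keep = mean_d <= thresh
    removed = np.flatnonzero(~keep)
    return cloud.select(keep), removed


def crop_box(cloud: PointCloud, min_corner, max_corner) -> PointCloud:
    """Keep points inside the closed axis-aligned box [min_corner, max_corner]."""
    lo = np.asarray(min_corner, dtype=float)
    hi = np.asarray(max_corner, dtype=float)
    if np.any(lo >= hi):
        raise ValueError(f"min_corner {lo} must be < max_corner {hi} componentwise")
    inside = np.all((cloud.points >= lo) & (cloud.points <= hi), axis=1)
    if not inside.any():
        warnings.warn("crop_box produced an empty cloud", stacklevel=2)
    return cloud.select(inside)
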