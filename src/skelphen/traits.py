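"""Phenotypic trait computation: height, stem length, stem diameter, leaf area.

- Plant height H = Ymax - Ymin over the preprocessed cloud (gravity is +Y).
- Stem length is the polyline arc length of the smoothed stem curve.
- Stem diameter: thin slices perpendicular to the stem's PCA axis at fixed
  stations above the base; an ellipse is fitted to each slice's in-plane
  projection and the diameter is twice the mean minor semi-axis (a circular
  stem of radius r has minor semi-axis r). ``literal_minor_axis`` instead
  reports the unscaled mean minor semi-axis.
- Leaf area: triangulated, hole-repaired mesh area per leaf instance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud
from .meshing import (
    boundary_rings,
    fill_holes,
    leaf_area,
    smooth_to_local_plane,
    triangulate_leaf,
)
from .stem import StemCurve

__all__ = [
    "EllipseFit",
    "TraitReport",
    "plant_height",
    "stem_length",
    "fit_ellipse",
    "stem_diameter",
    "measure_leaf_area",
]


@dataclass
class EllipseFit:
    center: np.ndarray  # 2D
    semi_axes: tuple[float, float]  # (a, b) with a >= b
    rotation: float  # radians
    rms_residual: float


@dataclass
class TraitReport:
    """The four phenotypic parameters with provenance metadata."""

    height: float  # m
    stem_length: float  # m
    stem_diameter: float  # m
    leaf_areas: np.ndarray  # m^2 per leaf instance
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "height_m": float(self.height),
            "stem_length_m": float(self.stem_length),
            "stem_diameter_m": float(self.stem_diameter),
            "leaf_areas_m2": np.asarray(self.leaf_areas, float).tolist(),
            "metadata": self.metadata,
        }

    def to_frame(self):
        """Long-format pandas frame: one row per trait / per-leaf row."""
        import pandas as pd

        rows = [
            {"trait": "plant_height", "value": self.height, "unit": "m"},
            {"trait": "stem_length", "value": self.stem_length, "unit": "m"},
            {"trait": "stem_diameter", "value": self.stem_diameter, "unit": "m"},
        ]
        for i, a in enumerate(np.asarray(self.leaf_areas, float)):
            rows.append({"trait": f"leaf_area[{i}]", "value": float(a), "unit": "m^2"})
        return pd.DataFrame(rows)


def plant_height(cloud: PointCloud) -> float:
    """H = Ymax - Ymin of the (preprocessed) full cloud."""
    if len(cloud) == 0:
        raise ValueError("empty cloud has no height")
    y = cloud.points[:, 1]
    return float(y.max() - y.min())


def stem_length(curve: StemCurve) -> float:
    """Sum of Euclidean distances between consecutive curve samples."""
    if len(curve.samples) < 2:
        raise ValueError("stem curve needs at least 2 samples")
    return curve.length


def fit_ellipse(points_2d: np.ndarray) -> EllipseFit:
    """Direct least-squares conic fit constrained to an ellipse.

    Solves the ellipse-specific generalised eigenproblem (the 4ac - b^2 = 1
    constrained algebraic fit), then converts the conic coefficients to
    center / semi-axes / rotation.
    """
    pts = np.asarray(points_2d, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("fit_ellipse expects (N, 2) points")
    if len(pts) < 6:
        raise ValueError(f"ellipse fit needs >= 6 points, got {len(pts)}")
    # work in a centered/scaled frame for conditioning
    mean = pts.mean(axis=0)
    scale = pts.std(axis=0).mean()
    if scale <= 0:
        raise ValueError("degenerate (coincident) points")
    q = (pts - mean) / scale
    x, y = q[:, 0], q[:, 1]
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate point configuration: {exc}") from exc
    M = S1 + S2 @ T
    C_inv = np.array([[0.0, 0.0, 0.5], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0]])
    evals, evecs = np.linalg.eig(C_inv @ M)
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.flatnonzero((cond > 0) & np.isreal(evals))
    if len(ok) == 0:
        raise ValueError("no ellipse solution (degenerate/collinear input?)")
    a1 = np.real(evecs[:, ok[0]])
    coeffs = np.concatenate([a1, T @ a1])  # A, B, C, D, E, F in scaled frame

    A, B, C, D, E, F = coeffs
    den = B * B - 4 * A * C
    if den >= 0:
        raise ValueError("fit is not an ellipse")
    cx = (2 * C * D - B * E) / den
    cy = (2 * A * E - B * D) / den
    # semi-axes via the standard conic reduction
    num = 2 * (A * E * E + C * D * D + F * B * B - B * D * E - 4 * A * C * F)
    s = np.sqrt((A - C) ** 2 + B * B)
    t1 = num / (den * (s - (A + C)))
    t2 = num / (den * (-s - (A + C)))
    if t1 <= 0 or t2 <= 0:
        raise ValueError("fit is not an ellipse (non-positive axis)")
    r1, r2 = np.sqrt(t1), np.sqrt(t2)
    a_s, b_s = max(r1, r2), min(r1, r2)
    # major-axis direction = eigenvector of the smaller eigenvalue of the
    # quadratic form [[A, B/2], [B/2, C]]
    m2 = np.array([[A, B / 2.0], [B / 2.0, C]])
    w2, v2 = np.linalg.eigh(m2 * np.sign(A + C))
    major = v2[:, 0]
    theta = np.arctan2(major[1], major[0])

    # back to original frame
    center = mean + scale * np.array([cx, cy])
    a_out, b_out = a_s * scale, b_s * scale
    theta = float(np.mod(theta, np.pi))

    # rms of radial residual (distance from points to ellipse along the ray)
    ct, st = np.cos(theta), np.sin(theta)
    rel = pts - center
    u = rel[:, 0] * ct + rel[:, 1] * st
    v = -rel[:, 0] * st + rel[:, 1] * ct
    r = np.hypot(u / a_out, v / b_out)
    radial = np.hypot(u, v)
    resid = radial * (1.0 - 1.0 / np.maximum(r, 1e-12))
    rms = float(np.sqrt(np.mean(resid**2)))
    return EllipseFit(center=center, semi_axes=(float(a_out), float(b_out)),
                      rotation=theta, rms_residual=rms)


def stem_diameter(
    stem_cloud: PointCloud,
    slice_start: float = 0.05,
    slice_spacing: float = 0.01,
    n_slices: int = 4,
    slice_thickness: float = 0.002,
    literal_minor_axis: bool = False,
) -> float:
    """Mean ellipse-slice stem diameter (meters).

    Slices are taken perpendicular to the stem cloud's PCA principal axis at
    ``slice_start + i * slice_spacing`` above the stem base; each slice's
    points are projected in-plane and fitted with an ellipse. The diameter is
    2 x mean minor semi-axis, or the bare mean minor semi-axis when
    ``literal_minor_axis`` is set.
    """
    pts = stem_cloud.points
    if len(pts) < 10:
        raise ValueError("stem cloud too small for diameter estimation")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis[1] < 0:
        axis = -axis
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(axis, [0.0, 0.0, 1.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    t = pts @ axis
    base = t.min()
    extent = t.max() - base
    needed = slice_start + (n_slices - 1) * slice_spacing
    if extent < needed:
        raise ValueError(
            f"stem spans {extent:.3f} m along its axis; "
            f"slicing needs at least {needed:.3f} m"
        )
    minors = []
    for i in range(n_slices):
        station = base + slice_start + i * slice_spacing
        sel = np.abs(t - station) <= slice_thickness / 2.0
        if sel.sum() < 6:
            warnings.warn(
                f"slice {i} at +{slice_start + i * slice_spacing:.3f} m has "
                f"{int(sel.sum())} points; skipped",
                stacklevel=2,
            )
            continue
        proj = np.column_stack([pts[sel] @ e1, pts[sel] @ e2])
        try:
            fit = fit_ellipse(proj)
        except ValueError as exc:
            warnings.warn(f"slice {i} ellipse fit failed ({exc}); skipped", stacklevel=2)
            continue
        minors.append(fit.semi_axes[1])
    if not minors:
        raise ValueError("all stem slices were skipped; cannot estimate diameter")
    mean_minor = float(np.mean(minors))
    return mean_minor if literal_minor_axis else 2.0 * mean_minor


def measure_leaf_area(
    leaf_points: np.ndarray,
    mu: float = 6.0,
    max_edge: float = 0.01,
    double_sided: bool = False,
    smooth_k: int = 120,
) -> float:
    """Mesh-based area of one leaf cloud (smoothing → mesh → hole repair → sum)."""
    pts = np.asarray(leaf_points, float)
    if smooth_k and len(pts) > smooth_k:
        pts = smooth_to_local_plane(pts, k=smooth_k)
    mesh = triangulate_leaf(pts, mu=mu, max_edge=max_edge)
    rings, outer = boundary_rings(mesh)
    if len(rings) > 1:
        mesh = fill_holes(mesh, rings, outer)
    return leaf_area(mesh, double_sided=double_sided)
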