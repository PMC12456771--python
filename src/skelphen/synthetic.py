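"""Synthetic seedling point clouds with analytic ground truth.

Emulates a nursery seedling as scanned by a depth-camera turntable rig after
registration: a thin, slightly bowed vertical stem (cylinder surface sample),
4-15 planar elliptical leaves attached around the stem through short petiole
stubs, Gaussian surface noise, and sparse far outliers mimicking time-of-flight
artefacts. Every point carries a ground-truth organ label and the generator
reports the analytic trait values (height, stem arc length, diameter, per-leaf
ellipse areas), so the whole segmentation/phenotyping pipeline can be scored
without any scan data.

Conventions: metric units (meters), gravity along +Y. Labels: 0 = stem,
1..n_leaves = leaf instances (petiole included with its leaf), -1 = outlier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cloud import PointCloud, write_cloud

__all__ = [
    "SyntheticPlantSpec",
    "GroundTruth",
    "generate_plant",
    "write_fixture",
    "read_fixture",
    "random_spec",
]

_GOLDEN_ANGLE = np.deg2rad(137.508)
_AXIS_SAMPLES = 8001  # dense enough that polyline sagitta ≪ 1 nm
_PETIOLE_LENGTH = 0.003  # 3 mm stub keeps the stem-leaf junction ambiguity real


@dataclass
class SyntheticPlantSpec:
    """Parameters of one synthetic seedling.

    ``leaf_attach_heights`` are fractions of ``stem_height`` in (0, 1);
    ``stem_curvature`` is the lateral bow amplitude as a fraction of height.
    Any of the per-leaf arrays may be None, in which case realistic values are
    drawn deterministically from ``seed``.
    """

    stem_height: float = 0.40
    stem_radius: float = 0.0025
    stem_curvature: float = 0.04
    n_leaves: int = 8
    leaf_semi_axes: np.ndarray | None = None  # (n_leaves, 2): a >= b
    leaf_attach_heights: np.ndarray | None = None  # fractions of stem height
    leaf_azimuths: np.ndarray | None = None  # radians
    noise_sigma: float = 0.001
    outlier_count: int = 200
    points_per_m2: float = 2.0e6
    seed: int = 0

    def __post_init__(self) -> None:
        # tolerate YAML quirks ("8.0e5" parses as a string) in config files
        for name in ("stem_height", "stem_radius", "stem_curvature",
                     "noise_sigma", "points_per_m2"):
            setattr(self, name, float(getattr(self, name)))
        self.n_leaves = int(self.n_leaves)
        self.outlier_count = int(self.outlier_count)
        self.seed = int(self.seed)

    def validate(self) -> None:
        if not self.stem_height > 0:
            raise ValueError(f"stem_height must be > 0, got {self.stem_height}")
        if not self.stem_radius > 0:
            raise ValueError(f"stem_radius must be > 0, got {self.stem_radius}")
        if self.stem_curvature < 0:
            raise ValueError(f"stem_curvature must be >= 0, got {self.stem_curvature}")
        if self.n_leaves < 0:
            raise ValueError(f"n_leaves must be >= 0, got {self.n_leaves}")
        if not self.points_per_m2 > 0:
            raise ValueError(f"points_per_m2 must be > 0, got {self.points_per_m2}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.outlier_count < 0:
            raise ValueError(f"outlier_count must be >= 0, got {self.outlier_count}")
        if self.leaf_attach_heights is not None:
            h = np.asarray(self.leaf_attach_heights, float)
            if len(h) != self.n_leaves:
                raise ValueError("leaf_attach_heights length must equal n_leaves")
            if np.any(h <= 0) or np.any(h >= 1):
                raise ValueError(
                    "leaf_attach_heights must be fractions strictly inside (0, 1)"
                )
        if self.leaf_semi_axes is not None:
            ab = np.asarray(self.leaf_semi_axes, float)
            if ab.shape != (self.n_leaves, 2):
                raise ValueError("leaf_semi_axes must have shape (n_leaves, 2)")
            if np.any(ab[:, 1] <= 0) or np.any(ab[:, 0] < ab[:, 1]):
                raise ValueError("leaf_semi_axes must satisfy a >= b > 0 per leaf")
        if self.leaf_azimuths is not None and len(self.leaf_azimuths) != self.n_leaves:
            raise ValueError("leaf_azimuths length must equal n_leaves")


@dataclass
class GroundTruth:
    """Analytic truth for one generated plant."""

    per_point_label: np.ndarray
    true_height: float
    true_stem_length: float
    true_stem_diameter: float
    true_leaf_areas: np.ndarray
    stem_axis_samples: np.ndarray

    def to_dict(self) -> dict:
        return {
            "per_point_label": self.per_point_label.tolist(),
            "true_height": float(self.true_height),
            "true_stem_length": float(self.true_stem_length),
            "true_stem_diameter": float(self.true_stem_diameter),
            "true_leaf_areas": np.asarray(self.true_leaf_areas).tolist(),
            "stem_axis_samples": np.asarray(self.stem_axis_samples).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            per_point_label=np.asarray(d["per_point_label"], dtype=np.int64),
            true_height=float(d["true_height"]),
            true_stem_length=float(d["true_stem_length"]),
            true_stem_diameter=float(d["true_stem_diameter"]),
            true_leaf_areas=np.asarray(d["true_leaf_areas"], dtype=float),
            stem_axis_samples=np.asarray(d["stem_axis_samples"], dtype=float),
        )


def _stem_axis(spec: SyntheticPlantSpec, bow_dir: np.ndarray):
    """Return axis(t) and tangent(t) callables for t in [0, 1] (y = t * H)."""
    H = spec.stem_height
    amp = spec.stem_curvature * H

    def axis(t):
        t = np.atleast_1d(np.asarray(t, float))
        lateral = amp * np.sin(np.pi * t)[:, None] * bow_dir[None, :]
        pts = np.column_stack([np.zeros_like(t), t * H, np.zeros_like(t)]) + lateral
        return pts

    def tangent(t):
        t = np.atleast_1d(np.asarray(t, float))
        dl = amp * np.pi * np.cos(np.pi * t)[:, None] * bow_dir[None, :]
        d = np.column_stack([np.zeros_like(t), np.full_like(t, H), np.zeros_like(t)]) + dl
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    return axis, tangent


def _frames(tangents: np.ndarray):
    """Orthonormal (n1, n2) perpendicular to each unit tangent."""
    ref = np.array([1.0, 0.0, 0.0])
    n1 = np.cross(tangents, ref)
    bad = np.linalg.norm(n1, axis=1) < 1e-8
    if np.any(bad):
        n1[bad] = np.cross(tangents[bad], [0.0, 0.0, 1.0])
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangents, n1)
    return n1, n2


def _sample_cylinder(axis_fn, tangent_fn, t_lo, t_hi, radius, n, rng):
    """Uniform surface sample of a swept cylinder between axis parameters."""
    # arc-length-uniform in t via dense lookup
    tt = np.linspace(t_lo, t_hi, 512)
    pts = axis_fn(tt)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    u = rng.uniform(0.0, cum[-1], n)
    t = np.interp(u, cum, tt)
    psi = rng.uniform(0.0, 2.0 * np.pi, n)
    centers = axis_fn(t)
    tan = tangent_fn(t)
    n1, n2 = _frames(tan)
    normal = np.cos(psi)[:, None] * n1 + np.sin(psi)[:, None] * n2
    return centers + radius * normal, normal


def _sample_ellipse(center, u, v, a, b, n, rng):
    """Uniform sample of a planar elliptical patch; returns points + normal."""
    pts = np.empty((n, 2))
    have = 0
    while have < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - have) + 16, 2))
        keep = cand[:, 0] ** 2 + cand[:, 1] ** 2 <= 1.0
        cand = cand[keep][: n - have]
        pts[have : have + len(cand)] = cand
        have += len(cand)
    xy = pts * [a, b]
    world = center + xy[:, :1] * u + xy[:, 1:] * v
    normal = np.cross(u, v)
    normal = normal / np.linalg.norm(normal)
    return world, np.broadcast_to(normal, world.shape).copy()


def _resolve_leaf_params(spec: SyntheticPlantSpec, rng: np.random.Generator):
    n = spec.n_leaves
    if spec.leaf_attach_heights is None:
        # bottom leaves start ~1/4 up; topmost is the apical leaf near the tip
        base = np.linspace(0.25, 0.97, n) if n > 1 else np.array([0.6])
        h = np.clip(base + rng.uniform(-0.01, 0.01, n), 0.02, 0.98)
    else:
        h = np.asarray(spec.leaf_attach_heights, float)
    if spec.leaf_azimuths is None:
        az = (_GOLDEN_ANGLE * np.arange(n) + rng.uniform(-0.2, 0.2, n)) % (2 * np.pi)
    else:
        az = np.asarray(spec.leaf_azimuths, float)
    if spec.leaf_semi_axes is None:
        a = rng.uniform(0.025, 0.040, n)
        b = a * rng.uniform(0.45, 0.60, n)
        ab = np.column_stack([a, b])
    else:
        ab = np.asarray(spec.leaf_semi_axes, float)
    pitch = rng.uniform(np.deg2rad(25), np.deg2rad(50), n)
    return h, az, ab, pitch


def generate_plant(spec: SyntheticPlantSpec) -> tuple[PointCloud, GroundTruth]:
    """Generate one labeled plant cloud plus its analytic ground truth.

    Deterministic for a fixed ``spec.seed``. The returned cloud carries the
    same labels as ``GroundTruth.per_point_label``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    bow_az = rng.uniform(0.0, 2.0 * np.pi)
    bow_dir = np.array([np.cos(bow_az), 0.0, np.sin(bow_az)])
    axis_fn, tangent_fn = _stem_axis(spec, bow_dir)

    t_axis = np.linspace(0.0, 1.0, _AXIS_SAMPLES)
    axis_pts = axis_fn(t_axis)
    seg = np.linalg.norm(np.diff(axis_pts, axis=0), axis=1)
    stem_arc = float(seg.sum())

    # --- stem surface
    n_stem = max(int(spec.points_per_m2 * 2 * np.pi * spec.stem_radius * stem_arc), 50)
    stem_pts, stem_nrm = _sample_cylinder(
        axis_fn, tangent_fn, 0.0, 1.0, spec.stem_radius, n_stem, rng
    )
    parts = [stem_pts]
    normals = [stem_nrm]
    labels = [np.zeros(n_stem, dtype=np.int64)]

    # --- leaves (petiole stub + elliptical blade)
    h, az, ab, pitch = _resolve_leaf_params(spec, rng)
    leaf_areas = np.pi * ab[:, 0] * ab[:, 1] if spec.n_leaves else np.empty(0)
    for k in range(spec.n_leaves):
        t_k = h[k]
        attach = axis_fn(t_k)[0]
        d_out = np.array([np.cos(az[k]), 0.0, np.sin(az[k])])
        u = np.cos(pitch[k]) * d_out + np.sin(pitch[k]) * np.array([0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.array([-np.sin(az[k]), 0.0, np.cos(az[k])])

        # petiole: small cylinder along u from the stem surface
        pet_r = min(0.0008, 0.5 * spec.stem_radius)
        pet_start = attach + spec.stem_radius * d_out
        n_pet = max(int(spec.points_per_m2 * 2 * np.pi * pet_r * _PETIOLE_LENGTH), 12)
        s = rng.uniform(0.0, _PETIOLE_LENGTH, n_pet)
        psi = rng.uniform(0.0, 2 * np.pi, n_pet)
        p1 = v
        p2 = np.cross(u, v)
        pet_nrm = np.cos(psi)[:, None] * p1 + np.sin(psi)[:, None] * p2
        pet_pts = pet_start + s[:, None] * u + pet_r * pet_nrm

        a_k, b_k = ab[k]
        center = pet_start + (_PETIOLE_LENGTH + a_k) * u
        n_leaf = max(int(spec.points_per_m2 * np.pi * a_k * b_k), 30)
        leaf_pts, leaf_nrm = _sample_ellipse(center, u, v, a_k, b_k, n_leaf, rng)

        parts += [pet_pts, leaf_pts]
        normals += [pet_nrm, leaf_nrm]
        labels += [
            np.full(n_pet, k + 1, dtype=np.int64),
            np.full(n_leaf, k + 1, dtype=np.int64),
        ]

    clean = np.vstack(parts)
    nrm = np.vstack(normals)
    lab = np.concatenate(labels)
    true_height = float(clean[:, 1].max() - clean[:, 1].min())

    noisy = clean + spec.noise_sigma * rng.standard_normal(len(clean))[:, None] * nrm

    if spec.outlier_count:
        lo, hi = clean.min(axis=0), clean.max(axis=0)
        ctr, ext = (lo + hi) / 2, hi - lo
        out = rng.uniform(ctr - 1.5 * ext, ctr + 1.5 * ext, size=(spec.outlier_count, 3))
        noisy = np.vstack([noisy, out])
        lab = np.concatenate([lab, np.full(spec.outlier_count, -1, dtype=np.int64)])

    truth = GroundTruth(
        per_point_label=lab,
        true_height=true_height,
        true_stem_length=stem_arc,
        true_stem_diameter=2.0 * spec.stem_radius,
        true_leaf_areas=leaf_areas,
        stem_axis_samples=axis_pts,
    )
    return PointCloud(noisy, lab.copy()), truth


def random_spec(
    seed: int,
    height_range: tuple[float, float] = (0.30, 0.50),
    n_leaves_range: tuple[int, int] = (5, 10),
    noise_sigma: float = 0.001,
    outlier_count: int = 200,
    stem_radius: float = 0.0025,
) -> SyntheticPlantSpec:
    """Draw one plant spec from the study population (heights, leaf counts)."""
    rng = np.random.default_rng(seed)
    return SyntheticPlantSpec(
        stem_height=float(rng.uniform(*height_range)),
        stem_radius=stem_radius,
        stem_curvature=float(rng.uniform(0.01, 0.06)),
        n_leaves=int(rng.integers(n_leaves_range[0], n_leaves_range[1] + 1)),
        noise_sigma=noise_sigma,
        outlier_count=outlier_count,
        seed=seed,
    )


def write_fixture(cloud: PointCloud, truth: GroundTruth, path: str | Path) -> dict:
    """Write ``plant.ply`` + ``truth.json`` under ``path``; returns file map."""
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
        ply = path / "plant.ply"
        js = path / "truth.json"
        write_cloud(cloud, ply)
        with open(js, "w") as fh:
            json.dump(truth.to_dict(), fh)
    except OSError as exc:
        raise OSError(f"failed writing fixture under {path}: {exc}") from exc
    return {"cloud": ply, "truth": js}


def read_fixture(path: str | Path) -> tuple[PointCloud, GroundTruth]:
    from .cloud import read_cloud

    path = Path(path)
    cloud = read_cloud(path / "plant.ply")
    with open(path / "truth.json") as fh:
        truth = GroundTruth.from_dict(json.load(fh))
    return cloud, truth
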