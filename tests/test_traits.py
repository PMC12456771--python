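import numpy as np
import pytest

from skelphen import (
    PointCloud,
    fit_ellipse,
    measure_leaf_area,
    plant_height,
    smooth_curve,
    stem_diameter,
    stem_length,
)
from skelphen.stem import StemCurve


# ------------------------------------------------------------- plant height
def test_plant_height_is_y_extent():
    cloud = PointCloud(np.array([[0, 0, 0], [1, 0.42, 2], [0.3, 0.1, 0.5]]))
    assert plant_height(cloud) == pytest.approx(0.42)


def test_plant_height_translation_invariant(rng):
    pts = rng.uniform(size=(100, 3))
    assert plant_height(PointCloud(pts + [1, 1, 1])) == pytest.approx(
        plant_height(PointCloud(pts))
    )


def test_plant_height_empty_cloud_errors():
    with pytest.raises(ValueError):
        plant_height(PointCloud(np.empty((0, 3))))


# ------------------------------------------------------------- stem length
def test_stem_length_straight_curve():
    curve = smooth_curve(np.array([[0, 0, 0], [0, 0.4, 0]]))
    assert stem_length(curve) == pytest.approx(0.4, rel=1e-9)


def test_stem_length_semicircle():
    t = np.linspace(0, np.pi, 400)
    pts = 0.1 * np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
    assert stem_length(StemCurve(pts)) == pytest.approx(np.pi * 0.1, rel=0.01)


def test_polyline_length_monotone_under_refinement():
    t_coarse = np.linspace(0, np.pi, 20)
    t_fine = np.linspace(0, np.pi, 200)
    arc = lambda t: 0.1 * np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
    assert stem_length(StemCurve(arc(t_fine))) >= stem_length(StemCurve(arc(t_coarse)))


# ------------------------------------------------------------- ellipse fit
def test_fit_ellipse_unit_circle():
    t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
    fit = fit_ellipse(np.column_stack([np.cos(t), np.sin(t)]))
    assert fit.semi_axes[0] == pytest.approx(1.0, abs=1e-9)
    assert fit.semi_axes[1] == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(fit.center, 0.0, atol=1e-9)


def test_fit_ellipse_recovers_rotated_ellipse():
    a, b, phi = 0.003, 0.0015, np.deg2rad(30)
    t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    pts = np.column_stack([x, y]) @ R.T + [0.01, -0.02]
    fit = fit_ellipse(pts)
    assert fit.semi_axes[0] == pytest.approx(a, rel=1e-3)
    assert fit.semi_axes[1] == pytest.approx(b, rel=1e-3)
    np.testing.assert_allclose(fit.center, [0.01, -0.02], atol=1e-8)
    # rotation modulo pi
    assert min(abs(fit.rotation - phi), abs(abs(fit.rotation - phi) - np.pi)) < 1e-3
    assert fit.rms_residual < 1e-9


def test_fit_ellipse_needs_six_points():
    t = np.linspace(0, 2 * np.pi, 5, endpoint=False)
    with pytest.raises(ValueError):
        fit_ellipse(np.column_stack([np.cos(t), np.sin(t)]))


def test_fit_ellipse_rejects_collinear():
    pts = np.column_stack([np.linspace(0, 1, 20), np.linspace(0, 2, 20)])
    with pytest.raises(ValueError):
        fit_ellipse(pts)


# ------------------------------------------------------------- stem diameter
def _cylinder(radius=0.002, height=0.15, n=8000, seed=0, tilt_deg=0.0):
    rng = np.random.default_rng(seed)
    psi = rng.uniform(0, 2 * np.pi, n)
    y = rng.uniform(0, height, n)
    pts = np.column_stack([radius * np.cos(psi), y, radius * np.sin(psi)])
    if tilt_deg:
        a = np.deg2rad(tilt_deg)
        rot = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        )
        pts = pts @ rot.T
    return PointCloud(pts)


def test_stem_diameter_vertical_cylinder():
    d = stem_diameter(_cylinder())
    assert d == pytest.approx(0.004, rel=0.02)


def test_stem_diameter_invariant_to_tilt():
    d0 = stem_diameter(_cylinder(seed=3))
    d20 = stem_diameter(_cylinder(seed=3, tilt_deg=20.0))
    assert d20 == pytest.approx(d0, rel=0.02)
    assert d20 == pytest.approx(0.004, rel=0.02)


def test_stem_diameter_literal_minor_axis_flag():
    cyl = _cylinder(seed=5)
    assert stem_diameter(cyl, literal_minor_axis=True) == pytest.approx(
        stem_diameter(cyl) / 2.0
    )


def test_stem_diameter_short_cylinder_errors():
    with pytest.raises(ValueError, match="span"):
        stem_diameter(_cylinder(height=0.04))


# ------------------------------------------------------------- leaf area
def test_measure_leaf_area_noiseless_disk():
    rng = np.random.default_rng(2)
    n = 5000
    r = 0.03 * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack([r * np.cos(th), np.zeros(n), r * np.sin(th)])
    assert measure_leaf_area(pts) == pytest.approx(np.pi * 0.03**2, rel=0.05)


def test_measure_leaf_area_recovers_noisy_generator_leaf(default_plant):
    spec, cloud, truth = default_plant
    errs = []
    for k in range(1, spec.n_leaves + 1):
        pts = cloud.points[truth.per_point_label == k]
        a = measure_leaf_area(pts)
        errs.append(abs(a - truth.true_leaf_areas[k - 1]) / truth.true_leaf_areas[k - 1])
    assert np.mean(errs) < 0.10
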