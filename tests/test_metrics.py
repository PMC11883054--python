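"""Pore, volume and stress read-outs against analytic oracles."""

import numpy as np
import pytest

from stomamech import SurfaceMesh
from stomamech import metrics

from conftest import make_icosphere, make_unit_cube


def _rim_mesh(points2d):
    pts = np.column_stack([points2d, np.zeros(len(points2d))])
    n = len(pts)
    tris = np.array([[0, 1, 2]])
    return SurfaceMesh(
        vertices=pts, triangles=tris,
        cell_front=np.array([0]), cell_back=np.array([-1]),
        thickness=np.array([0.1]), fibre=np.array([[1.0, 0, 0]]),
        region=np.array(["bulbous_end"]), fixed_vertices=np.zeros(n, bool),
        pore_rim=np.arange(n), cell_names={0: "GC1"},
    )


def test_unit_square_rim_area():
    mesh = _rim_mesh(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))
    assert metrics.pore_area(mesh) == pytest.approx(1.0, rel=1e-14)


def test_ellipse_polygon_area_matches_same_resolution_polygon():
    """A 64-gon sampling an ellipse matches the analytic polygon area
    (the shoelace value of the exact inscribed polygon), close to pi a b."""
    a, b, n = 3.0, 1.0, 64
    th = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
    mesh = _rim_mesh(pts)
    analytic_polygon = 0.5 * n * a * b * np.sin(2 * np.pi / n)
    assert metrics.pore_area(mesh) == pytest.approx(analytic_polygon, rel=1e-12)
    assert metrics.pore_area(mesh) == pytest.approx(np.pi * a * b, rel=5e-3)


def test_best_fit_plane_recovers_area_of_tilted_rim():
    a, b, n = 3.0, 1.0, 64
    th = 2 * np.pi * np.arange(n) / n
    mesh = _rim_mesh(np.column_stack([a * np.cos(th), b * np.sin(th)]))
    flat = metrics.pore_area(mesh)
    rng = np.random.default_rng(0)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    mesh.vertices = mesh.vertices @ q.T
    assert metrics.pore_area(mesh, plane="best_fit") == pytest.approx(flat, rel=1e-10)


def test_reference_dumbbell_pore_is_a_thin_slit(dumbbell_mesh):
    """Initial pore area ~ 2 x slit half-width x slit length."""
    from stomamech.geometry import default_dumbbell_template

    tpl = default_dumbbell_template()
    area = metrics.pore_area(dumbbell_mesh)
    rim = dumbbell_mesh.vertices[dumbbell_mesh.pore_rim]
    slit_length = rim[:, 0].max() - rim[:, 0].min()
    assert area == pytest.approx(2 * tpl.slit_half_width * slit_length, rel=0.15)


def test_rim_orientation_independence(kidney_mesh):
    m2 = kidney_mesh.copy()
    m2.pore_rim = m2.pore_rim[::-1]
    assert metrics.pore_area(m2) == pytest.approx(metrics.pore_area(kidney_mesh), rel=1e-14)


def test_unit_cube_volume_and_area(unit_cube):
    assert metrics.cell_volume(unit_cube, 0) == pytest.approx(1.0, rel=1e-14)
    assert metrics.cell_surface_area(unit_cube, 0) == pytest.approx(6.0, rel=1e-14)


def test_icosphere_volume_close_to_analytic():
    R = 5.0
    sphere = make_icosphere(radius=R, subdivisions=3)
    vol = metrics.cell_volume(sphere, 0)
    assert vol == pytest.approx(4 / 3 * np.pi * R**3, rel=0.01)


def test_volume_translation_invariance(kidney_mesh):
    v0 = metrics.cell_volume(kidney_mesh, 0)
    shifted = kidney_mesh.vertices + np.array([100.0, -50.0, 20.0])
    v1 = metrics.cell_volume(kidney_mesh, 0, shifted)
    assert v1 == pytest.approx(v0, rel=1e-9)


def test_pair_percent_difference_formula():
    assert metrics.pair_percent_difference(100.0, 100.0) == 0.0
    assert metrics.pair_percent_difference(110.0, 100.0) == pytest.approx(
        100 * 10 / 105, rel=1e-12
    )
    with pytest.raises(ValueError):
        metrics.pair_percent_difference(-1.0, 5.0)


def test_top_decile_mean_stress_oracle():
    assert metrics.top_decile_mean_stress(np.full(50, 3.25)) == 3.25
    # 20 elements, traces 1..20 -> mean of {20, 19}
    assert metrics.top_decile_mean_stress(np.arange(1, 21)) == pytest.approx(19.5)
    with pytest.raises(ValueError):
        metrics.top_decile_mean_stress(np.array([]))


def test_top_decile_exceeds_overall_mean():
    rng = np.random.default_rng(0)
    for _ in range(5):
        tr = rng.normal(size=rng.integers(10, 200))
        assert metrics.top_decile_mean_stress(tr) >= tr.mean()


def test_pore_metrics_bounds(dumbbell_mesh):
    pm = metrics.pore_metrics(dumbbell_mesh)
    assert pm.pore_area >= 0
    assert pm.pore_area <= pm.complex_length * pm.complex_width
    assert pm.pore_length > pm.pore_width  # slit along the pore axis
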