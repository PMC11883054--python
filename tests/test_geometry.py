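"""Parametric stomatal complex generators."""

import numpy as np
import pytest

from stomamech import (
    build_dumbbell_complex,
    build_kidney_pair,
    default_dumbbell_template,
    default_kidney_template,
    validate_mesh,
)
from stomamech import metrics
from stomamech.geometry import TemplateError


def test_rod_wall_three_times_thicker_than_bulb(dumbbell_mesh):
    tpl = default_dumbbell_template()
    rod = dumbbell_mesh.thickness[dumbbell_mesh.region == "rod"]
    bulb = dumbbell_mesh.thickness[dumbbell_mesh.region == "bulbous_end"]
    assert np.all(rod == tpl.wall_thickness_rod)
    assert np.all(bulb == tpl.wall_thickness_bulb)
    assert tpl.wall_thickness_rod / tpl.wall_thickness_bulb == pytest.approx(3.0)


def test_kidney_thickness_uniform(kidney_mesh):
    assert np.unique(kidney_mesh.thickness).size == 1


def test_symmetric_construction_balances_volumes(dumbbell_mesh, kidney_mesh):
    for mesh in (dumbbell_mesh, kidney_mesh):
        v1 = metrics.cell_volume(mesh, 0)
        v2 = metrics.cell_volume(mesh, 1)
        assert metrics.pair_percent_difference(v1, v2) < 1.0


def test_kidney_mirror_symmetry(kidney_mesh):
    """volume_asymmetry = 0 gives a mirror-symmetric mesh about the pore axis."""
    v = kidney_mesh.vertices
    mirrored = v * np.array([1.0, -1.0, 1.0])
    # every vertex has a mirror partner
    from scipy.spatial import cKDTree

    d, _ = cKDTree(v).query(mirrored)
    assert d.max() < 1e-9


@pytest.mark.parametrize(
    "builder, template, target",
    [
        (build_dumbbell_complex, default_dumbbell_template, 0.09),
        (build_kidney_pair, default_kidney_template, 0.06),
    ],
    ids=["dumbbell-9pct", "kidney-6pct"],
)
def test_volume_asymmetry_hits_target(builder, template, target):
    mesh = builder(template(volume_asymmetry=target))
    v1 = metrics.cell_volume(mesh, 0)
    v2 = metrics.cell_volume(mesh, 1)
    assert v1 > v2
    got = metrics.pair_percent_difference(v1, v2)
    assert got == pytest.approx(100 * target, rel=2e-3)
    assert validate_mesh(mesh).passed


def test_fibre_fields_tangent_and_directional(dumbbell_mesh, kidney_mesh):
    for mesh, check in ((dumbbell_mesh, "longitudinal"), (kidney_mesh, "hoop")):
        n, _ = mesh.triangle_normals()
        assert np.abs(np.einsum("ij,ij->i", mesh.fibre, n)).max() < 1e-8
        assert np.abs(np.linalg.norm(mesh.fibre, axis=1) - 1).max() < 1e-12
    # dumbbell rod fibres are essentially the pore axis
    rod = dumbbell_mesh.region == "rod"
    assert np.abs(dumbbell_mesh.fibre[rod, 0]).min() > 0.9
    # kidney fibres are perpendicular to the local centreline tangent
    cent = kidney_mesh.triangle_corners().mean(axis=1)
    t = np.arctan2(cent[:, 1] / 6.0, cent[:, 0] / 12.5)
    T = np.stack([-12.5 * np.sin(t), 6.0 * np.cos(t), np.zeros(len(t))], 1)
    T /= np.linalg.norm(T, axis=1)[:, None]
    dots = np.abs(np.einsum("ij,ij->i", kidney_mesh.fibre, T))
    assert np.quantile(dots, 0.95) < 0.2


def test_determinism_bit_identical():
    a = build_dumbbell_complex(default_dumbbell_template(random_seed=42, jitter_amplitude=0.2))
    b = build_dumbbell_complex(default_dumbbell_template(random_seed=42, jitter_amplitude=0.2))
    assert np.array_equal(a.vertices, b.vertices)
    assert np.array_equal(a.triangles, b.triangles)
    assert np.array_equal(a.fibre, b.fibre)


def test_resolution_convergence_of_cell_volumes():
    """Halving the target edge length changes each cell volume by < 2%."""
    coarse = build_kidney_pair(default_kidney_template())
    fine = build_kidney_pair(default_kidney_template(mesh_resolution=0.65))
    for cell in (0, 1):
        vc = metrics.cell_volume(coarse, cell)
        vf = metrics.cell_volume(fine, cell)
        assert abs(vf - vc) / vc < 0.02


def test_degenerate_templates_rejected():
    with pytest.raises(TemplateError):
        build_dumbbell_complex(
            default_dumbbell_template(slit_half_width=2.0, rod_radius=1.4)
        )
    with pytest.raises(TemplateError):
        build_dumbbell_complex(default_dumbbell_template(mesh_resolution=4.0))
    with pytest.raises(TemplateError):
        build_kidney_pair(default_kidney_template(pore_semi_axis_a=2.0, tube_radius=4.5))
    with pytest.raises(TemplateError):
        default_dumbbell_template(volume_asymmetry=0.7)
    with pytest.raises(TemplateError):
        build_kidney_pair(default_dumbbell_template())


def test_validator_passes_both_defaults(dumbbell_mesh, kidney_mesh):
    assert validate_mesh(dumbbell_mesh).passed
    assert validate_mesh(kidney_mesh).passed
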