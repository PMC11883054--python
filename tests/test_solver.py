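"""Dynamic-relaxation equilibrium solver against analytic oracles."""

import numpy as np
import pytest

from stomamech import LoadCase, MembraneModel, SolverOptions, solve_equilibrium
from stomamech import metrics
from stomamech.material import isotropic

from conftest import make_icosphere


def test_zero_load_is_immediately_converged(kidney_model):
    state = solve_equilibrium(kidney_model, LoadCase(0.0, 0.5), SolverOptions())
    assert state.converged
    assert state.iterations <= 2
    assert np.array_equal(state.positions, kidney_model.mesh.vertices)


def test_pressurised_sphere_matches_thin_shell_strain():
    """Inflation strain within 5% of pR(1-nu)/(2Et) in the small-strain regime."""
    R, t, E, nu, p = 10.0, 0.5, 30.0, 0.2, 0.1
    sphere = make_icosphere(radius=R, thickness=t)
    model = MembraneModel(sphere, {"default": isotropic(E, nu)})
    state = solve_equilibrium(model, LoadCase(2 * p, 0.5), SolverOptions())
    assert state.converged
    centre = state.positions.mean(axis=0)
    strain = np.linalg.norm(state.positions - centre, axis=1).mean() / R - 1.0
    analytic = p * R * (1 - nu) / (2 * E * t)
    assert analytic < 0.05  # oracle regime
    assert strain == pytest.approx(analytic, rel=0.05)


def test_fixed_vertices_never_move(kidney_model):
    state = solve_equilibrium(kidney_model, LoadCase(3.0, 0.4), SolverOptions())
    mesh = kidney_model.mesh
    assert state.converged
    assert np.array_equal(
        state.positions[mesh.fixed_vertices], mesh.vertices[mesh.fixed_vertices]
    )


def test_converged_residual_below_tolerance(kidney_model):
    opts = SolverOptions()
    state = solve_equilibrium(kidney_model, LoadCase(2.0, 0.5), opts)
    assert state.converged
    mesh = kidney_model.mesh
    lc = LoadCase(2.0, 0.5)
    f = kidney_model.assemble_forces(state.positions, lc.cell_pressures(mesh))
    free = ~mesh.fixed_vertices
    char = kidney_model.pressure_forces(mesh.vertices, lc.cell_pressures(mesh))
    scale = np.linalg.norm(char[free], axis=1)
    scale = scale[scale > 0].mean()
    rms = np.sqrt(np.mean(np.sum(f[free] ** 2, axis=1)))
    assert rms <= opts.tol_rel * scale * 1.001


def test_objectivity_under_rigid_rotation(kidney_model):
    """Strain, S and the Cauchy trace are invariant when a converged
    configuration is rigidly rotated together with its reference."""
    state = solve_equilibrium(kidney_model, LoadCase(2.0, 0.5), SolverOptions())
    mesh = kidney_model.mesh
    rng = np.random.default_rng(0)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.linalg.det(q)
    rotated_mesh = mesh.copy()
    rotated_mesh.vertices = mesh.vertices @ q.T
    rotated_mesh.fibre = mesh.fibre @ q.T
    from stomamech.geometry import default_materials

    rotated = MembraneModel(rotated_mesh, default_materials("kidney"))
    e0 = kidney_model.strains(state.positions)
    e1 = rotated.strains(state.positions @ q.T)
    assert np.allclose(e0, e1, atol=1e-9)
    assert np.allclose(
        kidney_model.pk2_stresses(state.positions),
        rotated.pk2_stresses(state.positions @ q.T),
        atol=1e-9,
    )
    assert np.allclose(
        kidney_model.cauchy_traces(state.positions),
        rotated.cauchy_traces(state.positions @ q.T),
        atol=1e-9,
    )


def test_mirror_symmetric_ratios_give_mirror_pore_areas(kidney_model):
    """Solving (T, r) and (T, 1-r) on a symmetric mesh gives pore areas
    equal within 0.5% and mirror-image displacement fields."""
    mesh = kidney_model.mesh
    s1 = solve_equilibrium(kidney_model, LoadCase(3.0, 0.3), SolverOptions())
    s2 = solve_equilibrium(kidney_model, LoadCase(3.0, 0.7), SolverOptions())
    a1 = metrics.pore_area(mesh, s1.positions)
    a2 = metrics.pore_area(mesh, s2.positions)
    assert a1 == pytest.approx(a2, rel=5e-3)
    # mirrored displacement magnitude fields agree in distribution
    d1 = np.linalg.norm(s1.positions - mesh.vertices, axis=1)
    d2 = np.linalg.norm(s2.positions - mesh.vertices, axis=1)
    assert np.sort(d1) == pytest.approx(np.sort(d2), rel=2e-2, abs=1e-4)


def test_symmetric_pressures_open_the_dumbbell_pore(dumbbell_model):
    """Equal inflation of the two GCs opens the pore and deforms the
    complex mirror-symmetrically about the pore mid-plane."""
    from stomamech.geometry import DEFAULT_SC_PRESSURE

    mesh = dumbbell_model.mesh
    state = solve_equilibrium(
        dumbbell_model, LoadCase(5.0, 0.5, DEFAULT_SC_PRESSURE), SolverOptions()
    )
    assert state.converged
    assert metrics.pore_area(mesh, state.positions) > metrics.pore_area(mesh)
    # mirror symmetry: GC1 and GC2 crest displacements are reflections
    disp = state.positions - mesh.vertices
    rim = mesh.pore_rim
    half = len(rim) // 2
    dy1 = disp[rim[:half], 1]
    dy2 = disp[rim[half:], 1][::-1]
    assert dy1 == pytest.approx(-dy2, abs=5e-3 * np.abs(dy1).max())


def test_nonconvergence_is_reported_not_raised(kidney_model):
    state = solve_equilibrium(
        kidney_model, LoadCase(2.0, 0.5), SolverOptions(max_iter=50, ramp_steps=10)
    )
    assert not state.converged
    assert state.iterations == 50
    assert "final_residual" in state.diagnostics
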