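"""Element-level kinematics and stress measures against closed forms."""

import numpy as np
import pytest

from stomamech.fem import (
    DegenerateElementError,
    cauchy_stress,
    constitutive_stress,
    element_strain,
)
from stomamech.material import isotropic

REF = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.5, 1.5, 0.0]])
FIBRE = np.array([1.0, 0.0, 0.0])


def test_identity_deformation_gives_zero_strain():
    E = element_strain(REF, REF, FIBRE)
    assert np.allclose(E, 0.0, atol=1e-14)


def test_uniaxial_fibre_stretch_closed_form():
    """Stretch by lambda=1.1 along the fibre: E11 = (1.1^2-1)/2, E22 = E12 = 0."""
    lam = 1.1
    deformed = REF * np.array([lam, 1.0, 1.0])
    E = element_strain(REF, deformed, FIBRE)
    assert E[0, 0] == pytest.approx((lam**2 - 1) / 2, rel=1e-12)
    assert abs(E[1, 1]) < 1e-12 and abs(E[0, 1]) < 1e-12


def _strain_oracle(ref, deformed, fibre):
    """Independent brute-force oracle: solve for F from edge vectors in an
    explicit orthonormal frame, then E = (F^T F - I)/2."""
    e1, e2 = ref[1] - ref[0], ref[2] - ref[0]
    n = np.cross(e1, e2)
    n /= np.linalg.norm(n)
    t1 = fibre - (fibre @ n) * n
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    A = np.array([[e1 @ t1, e2 @ t1], [e1 @ t2, e2 @ t2]])  # ref edges, 2D
    D = np.stack([deformed[1] - deformed[0], deformed[2] - deformed[0]], axis=1)
    F, *_ = np.linalg.lstsq(A.T, D.T, rcond=None)  # F (3x2): D = F A
    F = F.T
    return 0.5 * (F.T @ F - np.eye(2))


def test_strain_matches_least_squares_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        deformed = REF + 0.05 * rng.normal(size=(3, 3))
        E = element_strain(REF, deformed, FIBRE)
        assert np.allclose(E, _strain_oracle(REF, deformed, FIBRE), atol=1e-10)


def test_strain_invariant_to_rigid_motion():
    rng = np.random.default_rng(3)
    deformed = REF + 0.05 * rng.normal(size=(3, 3))
    E0 = element_strain(REF, deformed, FIBRE)
    # random rotation + translation of the deformed triangle
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.linalg.det(q)
    moved = deformed @ q.T + np.array([5.0, -2.0, 1.0])
    E1 = element_strain(REF, moved, FIBRE)
    assert np.allclose(E0, E1, atol=1e-12)


def test_degenerate_triangle_raises():
    bad = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    with pytest.raises(DegenerateElementError):
        element_strain(bad, bad, FIBRE)


def test_zero_strain_zero_stress():
    S = constitutive_stress(np.zeros((2, 2)), isotropic(30.0, 0.2))
    assert np.allclose(S, 0.0)


def test_cauchy_pushforward_identities():
    mat = isotropic(25.0, 0.25)
    # S = 0 -> sigma = 0
    sigma, tr = cauchy_stress(REF, REF, np.zeros((2, 2)), FIBRE)
    assert np.allclose(sigma, 0.0) and tr == 0.0
    # identity F -> sigma = S
    S = np.array([[3.0, 0.5], [0.5, -1.0]])
    sigma, tr = cauchy_stress(REF, REF, S, FIBRE)
    assert np.allclose(sigma, S, atol=1e-12)
    assert tr == pytest.approx(np.trace(S), rel=1e-12)


def test_cauchy_trace_equals_eigenvalue_sum():
    rng = np.random.default_rng(11)
    mat = isotropic(40.0, 0.3)
    for _ in range(10):
        deformed = REF + 0.1 * rng.normal(size=(3, 3))
        E = element_strain(REF, deformed, FIBRE)
        S = constitutive_stress(E, mat)
        sigma, tr = cauchy_stress(REF, deformed, S, FIBRE)
        assert tr == pytest.approx(np.linalg.eigvalsh(sigma).sum(), abs=1e-12)
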