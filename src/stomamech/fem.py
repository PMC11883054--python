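"""Membrane finite elements and the dynamic-relaxation equilibrium solver.

Constant-strain triangular membrane elements (no bending stiffness, plane
stress) carry a transverse isotropic Saint-Venant Kirchhoff material.
Turgor is a follower load normal to the deformed elements; for shared
walls the net load is the pressure difference across the wall.  Quasi-
static equilibrium is found by pseudo time-stepping: damped explicit
dynamic relaxation with fictitious per-vertex masses.

Consistent units: μm, MPa, μN (1 MPa × 1 μm² = 1 μN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .material import WallMaterial
from .mesh import SurfaceMesh

__all__ = [
    "LoadCase",
    "SolverOptions",
    "EquilibriumState",
    "MembraneModel",
    "element_strain",
    "constitutive_stress",
    "cauchy_stress",
    "solve_equilibrium",
]


class DegenerateElementError(ValueError):
    """A triangle with (near-)zero area was encountered."""


_MIN_AREA = 1e-12  # μm²

_KERNEL = None
_KERNEL_TRIED = False


def _numba_kernel():
    """Compile (once) a fused per-element force kernel if numba is present.

    The kernel computes exactly what ``internal_forces`` +
    ``pressure_forces`` compute; equality is covered by the test suite.
    Returns None when numba is unavailable.
    """
    global _KERNEL, _KERNEL_TRIED
    if _KERNEL_TRIED:
        return _KERNEL
    _KERNEL_TRIED = True
    try:
        import numba
    except ImportError:  # pragma: no cover - numba is an optional speed-up
        return None

    @numba.njit(cache=False, fastmath=False)
    def kernel(x, tri, Ginv, C, at, pnet):  # pragma: no cover - jitted
        n_v = x.shape[0]
        n_t = tri.shape[0]
        f = np.zeros((n_v, 3))
        for e in range(n_t):
            i0, i1, i2 = tri[e, 0], tri[e, 1], tri[e, 2]
            d1x = x[i1, 0] - x[i0, 0]
            d1y = x[i1, 1] - x[i0, 1]
            d1z = x[i1, 2] - x[i0, 2]
            d2x = x[i2, 0] - x[i0, 0]
            d2y = x[i2, 1] - x[i0, 1]
            d2z = x[i2, 2] - x[i0, 2]
            g11, g12 = Ginv[e, 0, 0], Ginv[e, 0, 1]
            g21, g22 = Ginv[e, 1, 0], Ginv[e, 1, 1]
            # F = D @ Ginv (3x2)
            f11 = d1x * g11 + d2x * g21
            f12 = d1x * g12 + d2x * g22
            f21 = d1y * g11 + d2y * g21
            f22 = d1y * g12 + d2y * g22
            f31 = d1z * g11 + d2z * g21
            f32 = d1z * g12 + d2z * g22
            c11 = f11 * f11 + f21 * f21 + f31 * f31
            c22 = f12 * f12 + f22 * f22 + f32 * f32
            c12 = f11 * f12 + f21 * f22 + f31 * f32
            e1 = 0.5 * (c11 - 1.0)
            e2 = 0.5 * (c22 - 1.0)
            e3 = c12
            s1 = C[e, 0, 0] * e1 + C[e, 0, 1] * e2 + C[e, 0, 2] * e3
            s2 = C[e, 1, 0] * e1 + C[e, 1, 1] * e2 + C[e, 1, 2] * e3
            s3 = C[e, 2, 0] * e1 + C[e, 2, 1] * e2 + C[e, 2, 2] * e3
            # M = Ginv S Ginv^T (2x2 symmetric)
            a11 = g11 * s1 + g12 * s3
            a12 = g11 * s3 + g12 * s2
            a21 = g21 * s1 + g22 * s3
            a22 = g21 * s3 + g22 * s2
            m11 = a11 * g11 + a12 * g12
            m12 = a11 * g21 + a12 * g22
            m21 = a21 * g11 + a22 * g12
            m22 = a21 * g21 + a22 * g22
            w = at[e]
            # H = w * D M ; columns are dU/dx1-edge derivatives
            h11 = w * (d1x * m11 + d2x * m21)
            h21 = w * (d1y * m11 + d2y * m21)
            h31 = w * (d1z * m11 + d2z * m21)
            h12 = w * (d1x * m12 + d2x * m22)
            h22 = w * (d1y * m12 + d2y * m22)
            h32 = w * (d1z * m12 + d2z * m22)
            # follower pressure: pnet * (d1 x d2) / 6 per vertex
            q = pnet[e] / 6.0
            px = q * (d1y * d2z - d1z * d2y)
            py = q * (d1z * d2x - d1x * d2z)
            pz = q * (d1x * d2y - d1y * d2x)
            f[i0, 0] += h11 + h12 + px
            f[i0, 1] += h21 + h22 + py
            f[i0, 2] += h31 + h32 + pz
            f[i1, 0] += -h11 + px
            f[i1, 1] += -h21 + py
            f[i1, 2] += -h31 + pz
            f[i2, 0] += -h12 + px
            f[i2, 1] += -h22 + py
            f[i2, 2] += -h32 + pz
        return f

    _KERNEL = kernel
    return _KERNEL


# ---------------------------------------------------------------------------
# load cases
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class LoadCase:
    """Per-cell turgor pressures defined by a total and a split ratio.

    ``total`` is the summed guard-cell pressure T (MPa); ``ratio`` is
    r = P_GC1 / T, so P_GC1 = r T and P_GC2 = (1 - r) T exactly.
    Subsidiary cells, when present, are held at ``sc_pressure``.
    """

    total: float
    ratio: float
    sc_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError("total pressure must be >= 0")
        if not 0 < self.ratio < 1:
            raise ValueError("ratio must lie strictly in (0, 1)")

    @property
    def p_gc1(self) -> float:
        return self.ratio * self.total

    @property
    def p_gc2(self) -> float:
        return self.total - self.p_gc1

    def cell_pressures(self, mesh: SurfaceMesh) -> np.ndarray:
        """Pressure per cell id (indexed by id), from the mesh's cell names."""
        ids = mesh.cell_ids
        p = np.zeros(max(ids) + 1)
        for cid in ids:
            name = mesh.cell_names.get(cid, f"cell{cid}")
            if name == "GC1":
                p[cid] = self.p_gc1
            elif name == "GC2":
                p[cid] = self.p_gc2
            elif name.startswith("SC"):
                p[cid] = self.sc_pressure
            else:
                raise ValueError(f"cell {cid} ({name}) has no pressure rule")
        return p

    def label(self) -> str:
        return f"T={self.total:g} r={self.ratio:g}"


# ---------------------------------------------------------------------------
# single-element operations (also the vectorised kernels' reference forms)
# ---------------------------------------------------------------------------
def _element_frame(ref: np.ndarray, fibre: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane frame (t1=fibre, t2) of a reference triangle."""
    e1 = ref[1] - ref[0]
    e2 = ref[2] - ref[0]
    n = np.cross(e1, e2)
    a2 = np.linalg.norm(n)
    if a2 / 2 <= _MIN_AREA:
        raise DegenerateElementError("degenerate reference triangle")
    n = n / a2
    t1 = fibre - np.dot(fibre, n) * n
    nt = np.linalg.norm(t1)
    if nt < 1e-12:
        raise ValueError("fibre direction parallel to element normal")
    t1 = t1 / nt
    t2 = np.cross(n, t1)
    return t1, t2


def element_strain(
    reference: np.ndarray, deformed: np.ndarray, fibre: np.ndarray | None = None
) -> np.ndarray:
    """Green-Lagrange strain of one triangle, in its reference fibre frame.

    ``reference`` and ``deformed`` are (3, 3) corner arrays.  The strain is
    E = (F^T F - I)/2 with F the in-plane deformation gradient mapping
    reference edge vectors to deformed edge vectors; the 2D frame's first
    axis is the (projected) fibre direction, so E[0, 0] is the fibre strain.
    Rigid motions of the deformed triangle leave E unchanged.
    """
    reference = np.asarray(reference, float)
    deformed = np.asarray(deformed, float)
    if fibre is None:
        fibre = reference[1] - reference[0]
    t1, t2 = _element_frame(reference, np.asarray(fibre, float))
    e1, e2 = reference[1] - reference[0], reference[2] - reference[0]
    G = np.array([[e1 @ t1, e2 @ t1], [e1 @ t2, e2 @ t2]])
    d = np.cross(deformed[1] - deformed[0], deformed[2] - deformed[0])
    if np.linalg.norm(d) / 2 <= _MIN_AREA:
        raise DegenerateElementError("degenerate deformed triangle")
    D = np.stack([deformed[1] - deformed[0], deformed[2] - deformed[0]], axis=1)
    F = D @ np.linalg.inv(G)  # 3x2
    return 0.5 * (F.T @ F - np.eye(2))


def constitutive_stress(strain: np.ndarray, material: WallMaterial) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = C : E (MPa), fibre frame.

    Linear in the Green-Lagrange strain; axis 1 of ``strain`` must be the
    fibre direction.
    """
    C = material.stiffness()
    e = np.array([strain[0, 0], strain[1, 1], strain[0, 1] + strain[1, 0]])
    s = C @ e
    return np.array([[s[0], s[2]], [s[2], s[1]]])


def cauchy_stress(
    reference: np.ndarray,
    deformed: np.ndarray,
    S: np.ndarray,
    fibre: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """In-plane Cauchy stress sigma = F S F^T / J and its trace (MPa).

    ``J`` is the in-plane area ratio; the out-of-plane component is zero
    under the plane-stress assumption, so the trace equals the sum of the
    two in-plane eigenvalues.
    """
    reference = np.asarray(reference, float)
    deformed = np.asarray(deformed, float)
    if fibre is None:
        fibre = reference[1] - reference[0]
    t1, t2 = _element_frame(reference, np.asarray(fibre, float))
    e1, e2 = reference[1] - reference[0], reference[2] - reference[0]
    G = np.array([[e1 @ t1, e2 @ t1], [e1 @ t2, e2 @ t2]])
    # deformed in-plane frame
    d1, d2 = deformed[1] - deformed[0], deformed[2] - deformed[0]
    nd = np.cross(d1, d2)
    and2 = np.linalg.norm(nd)
    if and2 / 2 <= _MIN_AREA:
        raise DegenerateElementError("degenerate deformed triangle")
    u1 = d1 / np.linalg.norm(d1)
    u2 = np.cross(nd / and2, u1)
    Dd = np.array([[d1 @ u1, d2 @ u1], [d1 @ u2, d2 @ u2]])
    F2 = Dd @ np.linalg.inv(G)  # 2x2 in-plane deformation gradient
    J = np.linalg.det(F2)
    sigma = F2 @ S @ F2.T / J
    return sigma, float(np.trace(sigma))


# ---------------------------------------------------------------------------
# vectorised model
# ---------------------------------------------------------------------------
class MembraneModel:
    """Precomputed element data for fast vectorised assembly.

    Parameters
    ----------
    mesh : SurfaceMesh
        Reference geometry with per-element thickness/fibre/region data.
    materials : dict[str, WallMaterial]
        Material per region label; a ``"default"`` entry covers regions not
        listed explicitly.
    """

    def __init__(self, mesh: SurfaceMesh, materials: dict[str, WallMaterial]):
        self.mesh = mesh
        self.materials = dict(materials)
        tri = mesh.triangles
        ref = mesh.vertices[tri]  # (n,3,3)
        e1 = ref[:, 1] - ref[:, 0]
        e2 = ref[:, 2] - ref[:, 0]
        n = np.cross(e1, e2)
        a2 = np.linalg.norm(n, axis=1)
        if np.any(a2 / 2 <= _MIN_AREA):
            bad = np.flatnonzero(a2 / 2 <= _MIN_AREA)
            raise DegenerateElementError(f"degenerate reference elements: {bad[:10]}")
        nhat = n / a2[:, None]
        self.area = 0.5 * a2
        # fibre-aligned in-plane frame
        t1 = mesh.fibre - np.einsum("ij,ij->i", mesh.fibre, nhat)[:, None] * nhat
        nt = np.linalg.norm(t1, axis=1)
        if np.any(nt < 1e-12):
            raise ValueError("fibre parallel to element normal")
        t1 /= nt[:, None]
        t2 = np.cross(nhat, t1)
        self.t1, self.t2 = t1, t2
        G = np.empty((len(tri), 2, 2))
        G[:, 0, 0] = np.einsum("ij,ij->i", e1, t1)
        G[:, 0, 1] = np.einsum("ij,ij->i", e2, t1)
        G[:, 1, 0] = np.einsum("ij,ij->i", e1, t2)
        G[:, 1, 1] = np.einsum("ij,ij->i", e2, t2)
        det = G[:, 0, 0] * G[:, 1, 1] - G[:, 0, 1] * G[:, 1, 0]
        Ginv = np.empty_like(G)
        Ginv[:, 0, 0] = G[:, 1, 1]
        Ginv[:, 0, 1] = -G[:, 0, 1]
        Ginv[:, 1, 0] = -G[:, 1, 0]
        Ginv[:, 1, 1] = G[:, 0, 0]
        Ginv /= det[:, None, None]
        self.Ginv = Ginv

        # per-element stiffness matrices
        self.C = np.empty((len(tri), 3, 3))
        for label in np.unique(mesh.region):
            mat = self.materials.get(label) or self.materials.get("default")
            if mat is None:
                raise KeyError(f"no material for region '{label}' and no default")
            self.C[mesh.region == label] = mat.stiffness()
        self.thickness = mesh.thickness

        # scatter matrix: (n_v*3,) <- per-triangle-corner forces (n*3, 3)
        n_v = mesh.n_vertices
        rows = tri.ravel()
        cols = np.arange(tri.size)
        self._scatter = sp.csr_matrix(
            (np.ones(tri.size), (rows, cols)), shape=(n_v, tri.size)
        )

        # pressure bookkeeping
        self.cell_front = mesh.cell_front
        self.cell_back = mesh.cell_back
        self.free = ~mesh.fixed_vertices

    # -- kinematics ----------------------------------------------------
    def deformation(self, positions: np.ndarray) -> np.ndarray:
        """Per-element 3x2 deformation gradients F = D Ginv."""
        p = positions[self.mesh.triangles]
        D = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)  # (n,3,2)
        return D @ self.Ginv

    def strains(self, positions: np.ndarray) -> np.ndarray:
        """Green-Lagrange strain per element, Voigt (E11, E22, 2 E12)."""
        F = self.deformation(positions)
        C = np.einsum("nki,nkj->nij", F, F)
        return np.stack(
            [0.5 * (C[:, 0, 0] - 1), 0.5 * (C[:, 1, 1] - 1), C[:, 0, 1]], axis=1
        )

    def pk2_stresses(self, positions: np.ndarray) -> np.ndarray:
        """Second Piola-Kirchhoff stress per element, Voigt (S11, S22, S12)."""
        return np.einsum("nij,nj->ni", self.C, self.strains(positions))

    def energy(self, positions: np.ndarray) -> float:
        """Total stored elastic energy (μN·μm = pJ)."""
        e = self.strains(positions)
        s = np.einsum("nij,nj->ni", self.C, e)
        dens = 0.5 * np.einsum("ni,ni->n", e, s)
        return float(np.sum(dens * self.thickness * self.area))

    def internal_forces(self, positions: np.ndarray) -> np.ndarray:
        """Per-vertex elastic forces = -grad of stored energy (μN)."""
        p = positions[self.mesh.triangles]
        D = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)  # (n,3,2)
        F = D @ self.Ginv
        Cg = np.einsum("nki,nkj->nij", F, F)
        e = np.stack(
            [0.5 * (Cg[:, 0, 0] - 1), 0.5 * (Cg[:, 1, 1] - 1), Cg[:, 0, 1]], axis=1
        )
        s = np.einsum("nij,nj->ni", self.C, e)
        S = np.empty((len(s), 2, 2))
        S[:, 0, 0] = s[:, 0]
        S[:, 1, 1] = s[:, 1]
        S[:, 0, 1] = S[:, 1, 0] = s[:, 2]
        # dU/dD = A t  D Ginv S Ginv^T
        M = self.Ginv @ S @ np.swapaxes(self.Ginv, 1, 2)
        H = (self.area * self.thickness)[:, None, None] * (D @ M)  # (n,3,2)
        f = np.empty((len(s), 3, 3))
        f[:, 1] = -H[:, :, 0]
        f[:, 2] = -H[:, :, 1]
        f[:, 0] = H[:, :, 0] + H[:, :, 1]
        return self._scatter @ f.reshape(-1, 3)

    def pressure_forces(
        self, positions: np.ndarray, pressures: np.ndarray
    ) -> np.ndarray:
        """Follower pressure loads (μN) in the given configuration.

        Each triangle contributes p_net x (deformed area) x (deformed unit
        normal) split equally over its three vertices, where p_net is the
        front-cell pressure minus the back-cell pressure (ambient = 0).
        """
        p = positions[self.mesh.triangles]
        nvec = 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # area-weighted
        p_front = pressures[self.cell_front]
        p_back = np.where(self.cell_back >= 0, pressures[self.cell_back.clip(min=0)], 0.0)
        pnet = p_front - p_back
        contrib = (pnet[:, None] * nvec) / 3.0
        f = np.repeat(contrib[:, None, :], 3, axis=1)
        return self._scatter @ f.reshape(-1, 3)

    def cauchy_traces(self, positions: np.ndarray) -> np.ndarray:
        """Trace of the in-plane Cauchy stress per element (MPa).

        sigma = F S F^T / J with J the in-plane area ratio; the trace is the
        sum of the two in-plane eigenvalues (out-of-plane component zero).
        """
        F = self.deformation(positions)
        Cg = np.einsum("nki,nkj->nij", F, F)
        e = np.stack(
            [0.5 * (Cg[:, 0, 0] - 1), 0.5 * (Cg[:, 1, 1] - 1), Cg[:, 0, 1]], axis=1
        )
        s = np.einsum("nij,nj->ni", self.C, e)
        # tr(F S F^T)/J = tr(S C)/J with C = F^T F;  J = sqrt(det C)
        trSC = s[:, 0] * Cg[:, 0, 0] + s[:, 1] * Cg[:, 1, 1] + 2 * s[:, 2] * Cg[:, 0, 1]
        detC = Cg[:, 0, 0] * Cg[:, 1, 1] - Cg[:, 0, 1] ** 2
        J = np.sqrt(np.maximum(detC, 1e-30))
        return trSC / J

    def assemble_forces(
        self, positions: np.ndarray, pressures: np.ndarray
    ) -> np.ndarray:
        """Internal plus follower pressure forces in one fused pass."""
        p_front = pressures[self.cell_front]
        p_back = np.where(
            self.cell_back >= 0, pressures[self.cell_back.clip(min=0)], 0.0
        )
        pnet = p_front - p_back
        kern = _numba_kernel()
        if kern is not None:
            f = kern(
                positions, self.mesh.triangles, self.Ginv, self.C,
                self.area * self.thickness, pnet,
            )
            return f
        return self.internal_forces(positions) + self.pressure_forces(
            positions, pressures
        )

    # -- diagonal stiffness estimate for DR masses ---------------------
    def stiffness_scale(self, pressures: np.ndarray | None = None) -> np.ndarray:
        """Per-vertex stiffness estimate used to build fictitious masses."""
        cmax = np.abs(self.C).sum(axis=(1, 2))
        gnorm = np.einsum("nij,nij->n", self.Ginv, self.Ginv)  # |Ginv|_F^2
        k_tri = self.thickness * self.area * cmax * gnorm
        if pressures is not None:
            p_front = pressures[self.cell_front]
            p_back = np.where(
                self.cell_back >= 0, pressures[self.cell_back.clip(min=0)], 0.0
            )
            k_tri = k_tri + np.abs(p_front - p_back) * np.sqrt(self.area) * self.area
        k = np.repeat(k_tri[:, None] / 3.0, 3, axis=1)
        return self._scatter @ k.reshape(-1, 1)[:, 0]


# ---------------------------------------------------------------------------
# dynamic relaxation
# ---------------------------------------------------------------------------
@dataclass
class SolverOptions:
    """Knobs of the pseudo time-stepping (dynamic relaxation) solver.

    ``damping`` is a mass-proportional viscous coefficient applied per unit
    pseudo-time; ``kinetic_damping`` additionally zeroes velocities at
    kinetic-energy peaks, which removes the need to tune ``damping`` per
    problem.  ``ramp_steps`` linearly ramps the pressure from zero when
    starting from the reference configuration (skipped on warm starts).
    """

    damping: float = 0.02
    dt_scale: float = 0.9
    tol_rel: float = 1e-4
    max_iter: int = 200_000
    ramp_steps: int = 400
    kinetic_damping: bool = True
    check_every: int = 20


@dataclass
class EquilibriumState:
    """Converged (or diagnosed) solution of one load case."""

    positions: np.ndarray
    strain_voigt: np.ndarray
    pk2_voigt: np.ndarray
    cauchy_trace: np.ndarray
    residual_history: list[float]
    converged: bool
    iterations: int
    load_case: LoadCase | None = None
    diagnostics: dict = field(default_factory=dict)


def solve_equilibrium(
    model: MembraneModel,
    load_case: LoadCase,
    options: SolverOptions | None = None,
    x0: np.ndarray | None = None,
) -> EquilibriumState:
    """Relax the pressurised complex to quasi-static mechanical equilibrium.

    Vertices carry fictitious masses proportional to a local stiffness
    estimate; velocities are damped every step and positions advance under
    the sum of elastic and follower pressure forces until the RMS residual
    on free vertices falls below ``tol_rel`` times the characteristic
    pressure-load magnitude.  Fixed vertices never move.  Non-convergence
    returns ``converged=False`` with diagnostics rather than raising; NaNs
    abort with the iteration index.
    """
    opts = options or SolverOptions()
    mesh = model.mesh
    pressures = load_case.cell_pressures(mesh)
    free = model.free

    x = mesh.vertices.copy() if x0 is None else np.array(x0, dtype=float)
    if x.shape != mesh.vertices.shape:
        raise ValueError("x0 has wrong shape")
    x[mesh.fixed_vertices] = mesh.vertices[mesh.fixed_vertices]
    warm = x0 is not None

    # characteristic load for the convergence test (full pressure)
    f_char = model.pressure_forces(mesh.vertices, pressures)
    char = np.linalg.norm(f_char[free], axis=1)
    scale = float(np.mean(char[char > 0])) if np.any(char > 0) else 0.0

    if load_case.total == 0 and load_case.sc_pressure == 0 and not warm:
        return _finalise(model, x, load_case, [0.0], True, 0)

    m = model.stiffness_scale(pressures)
    m = np.maximum(m, 1e-12)
    dt = opts.dt_scale
    visc = max(0.0, 1.0 - opts.damping * dt)
    v = np.zeros_like(x)
    ke_prev = 0.0
    history: list[float] = []
    converged = False
    it = 0
    ramp = 0 if warm else opts.ramp_steps
    for it in range(1, opts.max_iter + 1):
        lam = min(1.0, it / ramp) if ramp else 1.0
        f = model.assemble_forces(x, lam * pressures)
        f[~free] = 0.0
        if it % opts.check_every == 0 or it == 1:
            if not np.all(np.isfinite(f)):
                raise FloatingPointError(
                    f"non-finite forces at iteration {it} ({load_case.label()})"
                )
            res = float(np.sqrt(np.mean(np.sum(f[free] ** 2, axis=1))))
            history.append(res)
            if lam >= 1.0 and scale > 0 and res <= opts.tol_rel * scale:
                converged = True
                break
            if scale == 0 and res <= 1e-12:
                converged = True
                break
        a = f / m[:, None]
        v = visc * v + dt * a
        if opts.kinetic_damping:
            ke = float(np.sum(m * np.sum(v**2, axis=1)))
            if ke < ke_prev and lam >= 1.0:
                v[:] = 0.0
                ke = 0.0
            ke_prev = ke
        x = x + dt * v

    return _finalise(model, x, load_case, history, converged, it)


def _finalise(model, x, load_case, history, converged, it) -> EquilibriumState:
    state = EquilibriumState(
        positions=x,
        strain_voigt=model.strains(x),
        pk2_voigt=model.pk2_stresses(x),
        cauchy_trace=model.cauchy_traces(x),
        residual_history=history,
        converged=converged,
        iterations=it,
        load_case=load_case,
        diagnostics={"final_residual": history[-1] if history else 0.0},
    )
    return state
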