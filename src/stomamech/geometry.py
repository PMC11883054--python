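"""Parametric synthetic stomatal complex geometries.

Stand-ins for confocal-derived surface meshes: a dumbbell (grass-like)
guard-cell pair flanked by two subsidiary cells, and a kidney
(onion-like) pair.  The dumbbell guard cell is a swept capsule — a
thick-walled central rod joining two thin-walled bulbous ends — whose
bulbous ends share a flat ventral wall disc with the sister cell across
the pore mid-plane.  Subsidiary cells are lens-shaped shells closed
against the guard cells' dorsal walls.  The kidney guard cell is a bent
circular tube around an elliptical pore with uniform wall thickness.

Coordinates: epidermal plane = XY, pore long axis = X, Z outward.
All lengths in μm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .mesh import SurfaceMesh

__all__ = [
    "StomatalTemplate",
    "TemplateError",
    "default_dumbbell_template",
    "default_kidney_template",
    "build_dumbbell_complex",
    "build_kidney_pair",
    "build_complex",
]


class TemplateError(ValueError):
    """Template parameters describe a degenerate or unmeshable geometry."""


@dataclass(frozen=True)
class StomatalTemplate:
    """Parametric description of a stomatal complex (lengths in μm).

    Dumbbell-only fields: ``rod_length``, ``rod_radius`` (lumen radius of
    the central rod), ``bulb_radius``, ``contact_radius`` (radius of the
    flat ventral wall disc shared between the bulbous ends) and the
    subsidiary-cell (SC) shape parameters.  Kidney-only fields:
    ``tube_radius``, the initial pore ellipse semi-axes and the polar
    margin.  ``volume_asymmetry`` is the signed fraction by which GC1's
    volume exceeds GC2's, realised by scaling bulb/tube radii.
    """

    morphology: str = "dumbbell"
    # dumbbell
    rod_length: float = 22.0
    rod_radius: float = 1.4
    bulb_radius: float = 7.0
    contact_radius: float = 4.5
    sc_bulge: float = 5.0
    sc_arc_frac: float = 0.45
    # kidney
    tube_radius: float = 4.5
    pore_semi_axis_a: float = 8.0
    pore_semi_axis_b: float = 1.5
    polar_margin: float = 0.18  # rad
    # common
    wall_thickness_bulb: float = 0.2
    wall_thickness_rod: float = 0.6
    slit_half_width: float = 0.25
    volume_asymmetry: float = 0.0
    mesh_resolution: float = 1.6  # target triangle edge length
    random_seed: int = 0
    jitter_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.morphology not in ("dumbbell", "kidney"):
            raise TemplateError(f"unknown morphology {self.morphology!r}")
        for name in (
            "rod_length", "rod_radius", "bulb_radius", "contact_radius",
            "tube_radius", "pore_semi_axis_a", "pore_semi_axis_b",
            "wall_thickness_bulb", "wall_thickness_rod", "slit_half_width",
            "mesh_resolution",
        ):
            if getattr(self, name) <= 0:
                raise TemplateError(f"{name} must be > 0")
        if abs(self.volume_asymmetry) >= 0.5:
            raise TemplateError("|volume_asymmetry| must be < 0.5")

    @property
    def length(self) -> float:
        """Overall complex length along the pore axis."""
        if self.morphology == "dumbbell":
            xb = self.rod_length / 2 + np.sqrt(self.bulb_radius**2 - self.rod_radius**2)
            return 2 * (xb + self.bulb_radius)
        return 2 * (self.pore_semi_axis_a + 2 * self.tube_radius)

    @property
    def width(self) -> float:
        if self.morphology == "dumbbell":
            cb = np.sqrt(max(self.bulb_radius**2 - self.contact_radius**2, 0.0))
            return 2 * (cb + self.bulb_radius)
        return 2 * (self.pore_semi_axis_b + 2 * self.tube_radius)


def default_dumbbell_template(**overrides) -> StomatalTemplate:
    """Barley-like dumbbell complex, ~45 μm long GC pair."""
    overrides.setdefault("morphology", "dumbbell")
    return StomatalTemplate(**overrides)


def default_kidney_template(**overrides) -> StomatalTemplate:
    """Onion-like kidney pair with uniform wall thickness, ~34 μm long."""
    overrides.setdefault("morphology", "kidney")
    overrides.setdefault("wall_thickness_bulb", 0.6)
    overrides.setdefault("wall_thickness_rod", 0.6)
    overrides.setdefault("mesh_resolution", 1.3)
    return StomatalTemplate(**overrides)


#: Default wall materials: the grass guard cell is stiffest along its
#: longitudinal microfibrils, the onion guard cell along the hoop
#: direction; subsidiary cells are isotropic.  Values (MPa) are chosen so
#: wall strains stay moderate (< ~0.4) over the 2-9 MPa pressure range.
DEFAULT_MATERIALS = {
    "dumbbell": {
        "default": {"fibre_modulus": 600.0, "transverse_modulus": 150.0, "poisson": 0.3},
        "sc_wall": {"fibre_modulus": 150.0, "transverse_modulus": 150.0, "poisson": 0.3},
    },
    "kidney": {
        "default": {"fibre_modulus": 600.0, "transverse_modulus": 100.0, "poisson": 0.3},
    },
}

#: Subsidiary-cell turgor (MPa), held constant across all load cases in the
#: dumbbell model; slightly above the per-GC pressure of the lowest total,
#: so subsidiary backpressure dominates when guard-cell turgor is low.
DEFAULT_SC_PRESSURE = 1.2


def default_materials(morphology: str):
    """Default region -> :class:`~stomamech.material.WallMaterial` map."""
    from .material import WallMaterial

    return {
        region: WallMaterial(**params)
        for region, params in DEFAULT_MATERIALS[morphology].items()
    }


# ---------------------------------------------------------------------------
# builder utility
# ---------------------------------------------------------------------------
class _Builder:
    def __init__(self) -> None:
        self.verts: list[np.ndarray] = []
        self.tris: list[tuple[int, int, int]] = []
        self.front: list[int] = []
        self.back: list[int] = []
        self.region: list[str] = []

    def add_vertex(self, p) -> int:
        self.verts.append(np.asarray(p, float))
        return len(self.verts) - 1

    def add_tri(self, a, b_, c, front, region, back=-1, reverse=False) -> int:
        self.tris.append((a, c, b_) if reverse else (a, b_, c))
        self.front.append(front)
        self.back.append(back)
        self.region.append(region)
        return len(self.tris) - 1


def _signed_cell_volume(b: _Builder, cell: int) -> float:
    v = np.array(b.verts)
    tot = 0.0
    for (i, j, k), f, bk in zip(b.tris, b.front, b.back):
        sgn = 1.0 if f == cell else (-1.0 if bk == cell else 0.0)
        if sgn:
            tot += sgn * np.dot(v[i], np.cross(v[j], v[k]))
    return tot / 6.0


def _orient_cell(b: _Builder, cell: int) -> bool:
    """Flip a cell's own triangles if its enclosed volume is negative.

    Returns True if a flip was applied.  Shared triangles (back >= 0) are
    left untouched; callers must orient a cell before its walls become
    shared.
    """
    if _signed_cell_volume(b, cell) >= 0:
        return False
    for ti, (f, bk) in enumerate(zip(b.front, b.back)):
        if f == cell and bk == -1:
            i, j, k = b.tris[ti]
            b.tris[ti] = (i, k, j)
    if _signed_cell_volume(b, cell) < 0:  # pragma: no cover - sanity
        raise RuntimeError("could not orient cell surface outward")
    return True


# ---------------------------------------------------------------------------
# dumbbell complex
# ---------------------------------------------------------------------------
def _dumbbell_frame(tpl: StomatalTemplate) -> dict:
    lr2 = tpl.rod_length / 2
    rr, rb, a = tpl.rod_radius, tpl.bulb_radius, tpl.contact_radius
    if a >= rb:
        raise TemplateError("contact_radius must be smaller than bulb_radius")
    if tpl.slit_half_width >= rr:
        raise TemplateError("slit half-width must be smaller than the rod lumen radius")
    xb = lr2 + np.sqrt(rb**2 - rr**2)
    return {"lr2": lr2, "rr": rr, "rb": rb, "a": a, "xb": xb,
            "xw0": xb - a, "xw1": xb + a}


def _dumbbell_stations(tpl: StomatalTemplate, fr: dict) -> np.ndarray:
    h = tpl.mesh_resolution
    lr2, a, rb, xb, xw0 = fr["lr2"], fr["a"], fr["rb"], fr["xb"], fr["xw0"]
    xs: list[float] = []
    m_rod = max(1, int(np.ceil(lr2 / h)))
    xs.extend(np.linspace(0.0, lr2, m_rod + 1))
    lt = xw0 - lr2
    m_tr = max(2, int(np.ceil(lt / h)))
    xs.extend(lr2 + lt * np.arange(1, m_tr + 1) / (m_tr + 1))
    m_w = max(3, int(np.ceil(2 * a / h)))
    xs.extend(xw0 + 2 * a * (np.arange(m_w) + 0.5) / m_w)
    alpha0 = np.arcsin(a / rb)
    m_out = max(2, int(np.ceil(rb * (np.pi / 2 - alpha0) / h)))
    for al in alpha0 + (np.pi / 2 - alpha0) * np.arange(1, m_out + 1) / m_out:
        xi = rb * np.sin(al)
        if np.sqrt(max(rb**2 - xi**2, 0.0)) < 0.45 * h:
            break
        if xi > a:
            xs.append(xb + xi)
    xs = np.array(sorted(set(np.round(xs, 10))))
    return np.concatenate([-xs[::-1][:-1], xs])


def _dumbbell_profile(x: float, fr: dict, scale: float, slit: float):
    """(ring radius, centreline offset, in_flat_window, chord half-width)."""
    ax = abs(x)
    lr2, rr, rb, a, xb = fr["lr2"], fr["rr"], fr["rb"], fr["a"], fr["xb"]
    if ax <= lr2:
        return rr, rr + slit, False, 0.0
    xi = ax - xb
    if abs(xi) < a:  # flat shared-wall window
        rho = scale * np.sqrt(rb**2 - xi**2)
        w = np.sqrt(a**2 - xi**2)
        return rho, np.sqrt(max(rho**2 - w**2, 0.0)), True, w
    if xi <= -a:  # transition rod -> bulb
        u = (ax - lr2) / (fr["xw0"] - lr2)
        sm = u * u * (3 - 2 * u)
        rho = rr + (scale * np.sqrt(rb**2 - a**2) - rr) * sm
        return rho, rho + slit * (1 - sm), False, 0.0
    rho = scale * np.sqrt(max(rb**2 - xi**2, 0.0))  # outer bulb
    return rho, rho + slit * (xi - a) / (rb - a), False, 0.0


def _station_ring(tpl, fr, x, scale, n_theta, k_flat):
    """Cross-section ring (n,2) in (y,z), plus per-point flat-wall flags.

    A fixed, contiguous index window around the ventral direction is
    mapped onto the flat shared-wall chord when the station lies inside
    the contact disc; chord positions depend only on the disc geometry, so
    the two guard cells produce bit-identical shared-wall vertices.
    """
    rho, c, in_win, w = _dumbbell_profile(x, fr, scale, tpl.slit_half_width)
    i = np.arange(n_theta)
    psi = 2 * np.pi * i / n_theta
    psis = np.where(psi > np.pi, psi - 2 * np.pi, psi)
    if not in_win:
        return np.stack([c - rho * np.cos(psi), rho * np.sin(psi)], 1), np.zeros(n_theta, bool)
    flat = np.minimum(i, n_theta - i) <= k_flat
    delta = 2 * np.pi * k_flat / n_theta
    y = np.empty(n_theta)
    z = np.empty(n_theta)
    y[flat] = 0.0
    z[flat] = w * psis[flat] / delta
    arc = ~flat
    phi0 = np.arccos(np.clip(c / rho, -1.0, 1.0))
    phi = phi0 + (psi[arc] - delta) * (2 * np.pi - 2 * phi0) / (2 * np.pi - 2 * delta)
    y[arc] = c - rho * np.cos(phi)
    z[arc] = rho * np.sin(phi)
    return np.stack([y, z], 1), flat


def build_dumbbell_complex(template: StomatalTemplate) -> SurfaceMesh:
    """Four-cell barley-like complex: GC1 (y > 0), GC2, SC1, SC2.

    The guard cells share a flat ventral wall disc at each bulbous end;
    each subsidiary cell shares the adjacent guard cell's dorsal wall and
    closes over it as a lens-shaped shell whose outermost lateral patch is
    fixed in space.  Rod-span elements carry ``wall_thickness_rod``
    (3x the bulb wall by default); fibres are longitudinal.
    """
    tpl = template
    if tpl.morphology != "dumbbell":
        raise TemplateError("template.morphology must be 'dumbbell'")
    fr = _dumbbell_frame(tpl)
    h = tpl.mesh_resolution
    if int(2 * np.pi * tpl.rod_radius / h) < 4:
        raise TemplateError(
            "mesh_resolution too coarse: fewer than 4 triangles around the rod"
        )
    scale1, scale2 = _asymmetry_scales(tpl)
    xs = _dumbbell_stations(tpl, fr)
    n_theta = max(12, int(round(2 * np.pi * tpl.bulb_radius / h)))
    n_theta += n_theta % 2
    k_flat = int(np.clip(
        round(np.arcsin(tpl.contact_radius / tpl.bulb_radius) / (2 * np.pi / n_theta)),
        1, n_theta // 4,
    ))

    b = _Builder()
    GC1, GC2, SC1, SC2 = 0, 1, 2, 3
    flat_vmap: dict[tuple[int, int], int] = {}
    flat_tmap: dict[frozenset, int] = {}
    grids: dict[int, np.ndarray] = {}
    gc1_flipped = False

    for gc, scale, mirror in ((GC1, scale1, False), (GC2, scale2, True)):
        grid = np.empty((len(xs), n_theta), dtype=int)
        for si, x in enumerate(xs):
            ring, flat = _station_ring(tpl, fr, x, scale, n_theta, k_flat)
            for i in range(n_theta):
                if flat[i] and (si, i) in flat_vmap:
                    grid[si, i] = flat_vmap[(si, i)]
                    continue
                y, z = ring[i]
                grid[si, i] = b.add_vertex((x, -y if mirror else y, z))
                if flat[i]:
                    flat_vmap[(si, i)] = grid[si, i]
        ymul = -1.0 if mirror else 1.0
        capL = b.add_vertex((xs[0] - 0.4 * h, ymul * tpl.slit_half_width, 0.0))
        capR = b.add_vertex((xs[-1] + 0.4 * h, ymul * tpl.slit_half_width, 0.0))
        grids[gc] = grid

        # mirroring reverses orientation; counter-reverse unless GC1 itself
        # was built inward and then flipped
        rev = mirror != gc1_flipped
        for si in range(len(xs) - 1):
            reg = "rod" if abs(0.5 * (xs[si] + xs[si + 1])) <= fr["lr2"] else "bulbous_end"
            for i in range(n_theta):
                j = (i + 1) % n_theta
                v00, v01 = grid[si, i], grid[si, j]
                v10, v11 = grid[si + 1, i], grid[si + 1, j]
                for (p, q, r) in ((v00, v10, v11), (v00, v11, v01)):
                    key = frozenset((p, q, r))
                    if mirror and key in flat_tmap:
                        b.back[flat_tmap[key]] = GC2
                        continue
                    ti = b.add_tri(p, q, r, gc, reg, reverse=rev)
                    if not mirror and all(b.verts[v][1] == 0.0 for v in (p, q, r)):
                        b.region[ti] = "ventral_wall"
                        flat_tmap[key] = ti
        for i in range(n_theta):
            j = (i + 1) % n_theta
            b.add_tri(capL, grid[0, i], grid[0, j], gc, "polar", reverse=rev)
            b.add_tri(capR, grid[-1, j], grid[-1, i], gc, "polar", reverse=rev)
        if not mirror:
            gc1_flipped = _orient_cell(b, GC1)
        else:
            _orient_cell(b, GC2)  # safety; should be a no-op

    fixed: set[int] = set()
    for gc, sc in ((GC1, SC1), (GC2, SC2)):
        _attach_sc(b, tpl, xs, fr, grids[gc], n_theta, gc, sc, fixed)

    rim: list[int] = []
    crest = [si for si, x in enumerate(xs) if abs(x) <= fr["xw0"]]
    rim.extend(int(grids[GC1][si, 0]) for si in crest)
    rim.extend(int(grids[GC2][si, 0]) for si in reversed(crest))

    mesh = _finalise_builder(
        b, tpl, fixed, rim, {GC1: "GC1", GC2: "GC2", SC1: "SC1", SC2: "SC2"}
    )
    _set_fibres(mesh, np.array([1.0, 0.0, 0.0]))
    _apply_jitter(mesh, tpl)
    return mesh


def _attach_sc(b, tpl, xs, fr, grid, n_theta, gc, sc, fixed: set[int]) -> None:
    """Mark the dorsal strip as shared with the SC and close a lens over it."""
    span = [si for si, x in enumerate(xs) if abs(x) <= fr["xw0"]]
    beta = tpl.sc_arc_frac * np.pi
    thetas = [i for i in range(n_theta) if abs(2 * np.pi * i / n_theta - np.pi) <= beta]
    sub = grid[np.ix_(span, thetas)]
    strip_verts = set(int(v) for v in sub.ravel())
    for ti, (p, q, r) in enumerate(b.tris):
        if b.front[ti] == gc and b.back[ti] == -1 and {p, q, r} <= strip_verts:
            b.back[ti] = sc
            b.region[ti] = "dorsal_wall"

    m, n = sub.shape
    verts = np.array(b.verts)
    ydir = 1.0 if np.mean(verts[sub.ravel(), 1]) > 0 else -1.0
    shell = np.empty((m, n), dtype=int)
    bumps = np.empty((m, n))
    for iu in range(m):
        for iv in range(n):
            u, v = iu / (m - 1), iv / (n - 1)
            bump = np.sin(np.pi * u) * np.sin(np.pi * v)
            bumps[iu, iv] = bump
            if bump < 1e-12:
                shell[iu, iv] = sub[iu, iv]
                continue
            p = verts[sub[iu, iv]].copy()
            c = _dumbbell_profile(p[0], fr, 1.0, tpl.slit_half_width)[1]
            d = np.array([0.0, p[1] - ydir * c, p[2]])
            nd = np.linalg.norm(d)
            d = d / nd if nd > 1e-9 else np.array([0.0, ydir, 0.0])
            shell[iu, iv] = b.add_vertex(p + tpl.sc_bulge * bump * d)
            if bump >= 0.5:
                fixed.add(int(shell[iu, iv]))

    first_shell_tri = len(b.tris)
    for iu in range(m - 1):
        for iv in range(n - 1):
            v00, v01 = shell[iu, iv], shell[iu, iv + 1]
            v10, v11 = shell[iu + 1, iv], shell[iu + 1, iv + 1]
            # keep the quad diagonal off the rim, else a corner quad would
            # emit a fully-rim triangle duplicating a strip triangle
            if bumps[iu, iv] < 1e-12 and bumps[iu + 1, iv + 1] < 1e-12:
                b.add_tri(v00, v01, v10, sc, "sc_wall")
                b.add_tri(v01, v11, v10, sc, "sc_wall")
            else:
                b.add_tri(v00, v11, v10, sc, "sc_wall")
                b.add_tri(v00, v01, v11, sc, "sc_wall")
    # orient the shell by a local test: the central shell triangle's normal
    # must point along the bump (outward) direction
    iu, iv = (m - 1) // 2, (n - 1) // 2
    p0 = verts[sub[iu, iv]]
    cmid = _dumbbell_profile(p0[0], fr, 1.0, tpl.slit_half_width)[1]
    out_dir = np.array([0.0, p0[1] - ydir * cmid, p0[2]])
    vv = np.array(b.verts)
    i0, j0, k0 = b.tris[first_shell_tri + 2 * ((iu * (n - 1)) + iv)]
    nrm = np.cross(vv[j0] - vv[i0], vv[k0] - vv[i0])
    if np.dot(nrm, out_dir) < 0:
        for ti in range(first_shell_tri, len(b.tris)):
            i, j, k = b.tris[ti]
            b.tris[ti] = (i, k, j)


# ---------------------------------------------------------------------------
# kidney pair
# ---------------------------------------------------------------------------
def build_kidney_pair(template: StomatalTemplate) -> SurfaceMesh:
    """Two-cell onion-like complex of kidney guard cells.

    Each GC is a circular tube swept along half of an ellipse around the
    pore, capped near the poles where the pair is fixed in space.  Wall
    thickness is uniform; fibres run circumferentially (hoop direction).
    """
    tpl = template
    if tpl.morphology != "kidney":
        raise TemplateError("template.morphology must be 'kidney'")
    rt = tpl.tube_radius
    A = tpl.pore_semi_axis_a + rt
    B = tpl.pore_semi_axis_b + rt
    if tpl.pore_semi_axis_a <= rt or tpl.pore_semi_axis_b >= tpl.pore_semi_axis_a:
        raise TemplateError("pore semi-axes incompatible with complex dimensions")
    scale1, scale2 = _asymmetry_scales(tpl)
    h = tpl.mesh_resolution
    t0 = tpl.polar_margin

    tt = np.linspace(t0, np.pi - t0, 720)
    d = np.hypot(-A * np.sin(tt), B * np.cos(tt))
    s_cum = np.concatenate([[0], np.cumsum(0.5 * (d[1:] + d[:-1]) * np.diff(tt))])
    m_st = max(8, int(np.ceil(s_cum[-1] / h)))
    ts = np.interp(np.linspace(0, s_cum[-1], m_st + 1), s_cum, tt)
    n_theta = max(10, int(round(2 * np.pi * rt / h)))
    n_theta += n_theta % 2
    zhat = np.array([0.0, 0.0, 1.0])

    b = _Builder()
    GC1, GC2 = 0, 1
    fixed: set[int] = set()
    crest: dict[int, list[int]] = {GC1: [], GC2: []}

    for gc, scale, ymul in ((GC1, scale1, 1.0), (GC2, scale2, -1.0)):
        r = rt * scale
        grid = np.empty((len(ts), n_theta), dtype=int)
        phi = 2 * np.pi * np.arange(n_theta) / n_theta
        for si, t in enumerate(ts):
            P = np.array([A * np.cos(t), ymul * B * np.sin(t), 0.0])
            nrm = np.array([np.cos(t) / A, ymul * np.sin(t) / B, 0.0])
            inner = -nrm / np.linalg.norm(nrm)
            pts = P[None] + r * (np.cos(phi)[:, None] * inner[None] + np.sin(phi)[:, None] * zhat[None])
            for i in range(n_theta):
                grid[si, i] = b.add_vertex(pts[i])
            # the inner crest near the poles can cross the mid-plane where
            # the tubes meet; the pore rim keeps only the open part
            if ymul * pts[0][1] > 0.05 * r:
                crest[gc].append(int(grid[si, 0]))
        T0 = np.array([-A * np.sin(ts[0]), ymul * B * np.cos(ts[0]), 0.0])
        T1 = np.array([-A * np.sin(ts[-1]), ymul * B * np.cos(ts[-1]), 0.0])
        cap0 = b.add_vertex(np.array([A * np.cos(ts[0]), ymul * B * np.sin(ts[0]), 0.0]) - 0.5 * r * T0 / np.linalg.norm(T0))
        cap1 = b.add_vertex(np.array([A * np.cos(ts[-1]), ymul * B * np.sin(ts[-1]), 0.0]) + 0.5 * r * T1 / np.linalg.norm(T1))
        for si in range(len(ts) - 1):
            for i in range(n_theta):
                j = (i + 1) % n_theta
                b.add_tri(grid[si, i], grid[si + 1, i], grid[si + 1, j], gc, "bulbous_end")
                b.add_tri(grid[si, i], grid[si + 1, j], grid[si, j], gc, "bulbous_end")
        for i in range(n_theta):
            j = (i + 1) % n_theta
            b.add_tri(cap0, grid[0, i], grid[0, j], gc, "polar")
            b.add_tri(cap1, grid[-1, j], grid[-1, i], gc, "polar")
        _orient_cell(b, gc)
        fixed.update([cap0, cap1])
        fixed.update(int(v) for v in grid[:2].ravel())
        fixed.update(int(v) for v in grid[-2:].ravel())

    rim = crest[GC1] + list(reversed(crest[GC2]))
    mesh = _finalise_builder(b, tpl, fixed, rim, {GC1: "GC1", GC2: "GC2"})
    _set_kidney_fibres(mesh, A, B)
    _apply_jitter(mesh, tpl)
    return mesh


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------
_SCALE_OVERRIDE: tuple[float, float] | None = None


def _asymmetry_scales(tpl: StomatalTemplate) -> tuple[float, float]:
    """Radius scale factors (GC1 up, GC2 down) for the target asymmetry.

    Found by root bisection on the within-pair fractional volume
    difference, to 0.1% of the target.
    """
    if _SCALE_OVERRIDE is not None:
        return _SCALE_OVERRIDE
    target = tpl.volume_asymmetry
    if target == 0.0:
        return 1.0, 1.0
    from . import metrics

    base = replace(tpl, volume_asymmetry=0.0, jitter_amplitude=0.0)
    build = build_dumbbell_complex if tpl.morphology == "dumbbell" else build_kidney_pair

    def pair_diff(dd: float) -> float:
        global _SCALE_OVERRIDE
        _SCALE_OVERRIDE = (1.0 + dd, 1.0 - dd)
        try:
            m = build(base)
        finally:
            _SCALE_OVERRIDE = None
        v1 = metrics.cell_volume(m, 0)
        v2 = metrics.cell_volume(m, 1)
        return (v1 - v2) / (0.5 * (v1 + v2)) - target

    dd = brentq(pair_diff, -0.3, 0.3, xtol=max(abs(target) * 2e-4, 1e-6))
    return 1.0 + dd, 1.0 - dd


def _finalise_builder(b: _Builder, tpl: StomatalTemplate, fixed: set[int],
                      rim: list[int], names: dict[int, str]) -> SurfaceMesh:
    verts = np.array(b.verts)
    tris = np.array(b.tris, dtype=np.int64)
    region = np.array(b.region, dtype="U12")
    if tpl.morphology == "dumbbell":
        # thickness by axial span: the central rod is ~3x thicker all around
        cx = verts[tris].mean(axis=1)[:, 0]
        thickness = np.where(
            (np.abs(cx) <= tpl.rod_length / 2) & (region != "sc_wall"),
            tpl.wall_thickness_rod, tpl.wall_thickness_bulb,
        )
    else:
        thickness = np.full(len(tris), tpl.wall_thickness_bulb)
    fixed_mask = np.zeros(len(verts), bool)
    if fixed:
        fixed_mask[sorted(fixed)] = True
    return SurfaceMesh(
        vertices=verts, triangles=tris,
        cell_front=np.array(b.front), cell_back=np.array(b.back),
        thickness=thickness, fibre=np.zeros((len(tris), 3)), region=region,
        fixed_vertices=fixed_mask, pore_rim=np.array(rim, dtype=np.int64),
        cell_names=names,
    )


def _project_tangent(mesh: SurfaceMesh, directions: np.ndarray) -> None:
    """Project per-element directions into element planes, unit norm."""
    n, _ = mesh.triangle_normals()
    d = directions - np.einsum("ij,ij->i", directions, n)[:, None] * n
    bad = np.linalg.norm(d, axis=1) < 1e-8
    if np.any(bad):
        alt = np.cross(n[bad], np.array([0.0, 0.0, 1.0]))
        alt2 = np.cross(n[bad], np.array([0.0, 1.0, 0.0]))
        use2 = np.linalg.norm(alt, axis=1) < 1e-8
        alt[use2] = alt2[use2]
        d[bad] = alt
    mesh.fibre = d / np.linalg.norm(d, axis=1)[:, None]


def _set_fibres(mesh: SurfaceMesh, axis: np.ndarray) -> None:
    _project_tangent(mesh, np.tile(axis, (mesh.n_triangles, 1)))


def _set_kidney_fibres(mesh: SurfaceMesh, A: float, B: float) -> None:
    """Hoop (circumferential) fibres around each guard-cell tube."""
    cent = mesh.triangle_corners().mean(axis=1)
    t = np.arctan2(cent[:, 1] / B, cent[:, 0] / A)
    T = np.stack([-A * np.sin(t), B * np.cos(t), np.zeros(len(t))], axis=1)
    T /= np.linalg.norm(T, axis=1)[:, None]
    n, _ = mesh.triangle_normals()
    _project_tangent(mesh, np.cross(n, T))


def _apply_jitter(mesh: SurfaceMesh, tpl: StomatalTemplate) -> None:
    """Optional smooth surface jitter (off by default).

    A low-frequency random trigonometric displacement field evaluated at
    vertex positions keeps shared walls watertight; fixed vertices do not
    move.  Fibres are re-projected afterwards.
    """
    if tpl.jitter_amplitude <= 0:
        return
    rng = np.random.default_rng(tpl.random_seed)
    disp = np.zeros_like(mesh.vertices)
    scale = max(tpl.length, tpl.width)
    for _ in range(4):
        k = rng.normal(size=3) * (2 * np.pi / (0.5 * scale))
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.normal(size=3)
        amp *= tpl.jitter_amplitude / (2 * np.linalg.norm(amp))
        disp += np.sin(mesh.vertices @ k + phase)[:, None] * amp[None]
    disp[mesh.fixed_vertices] = 0.0
    mesh.vertices = mesh.vertices + disp
    _project_tangent(mesh, mesh.fibre)


def build_complex(template: StomatalTemplate) -> SurfaceMesh:
    """Dispatch on template morphology."""
    if template.morphology == "dumbbell":
        return build_dumbbell_complex(template)
    return build_kidney_pair(template)
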