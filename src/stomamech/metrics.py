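"""Geometric and stress read-outs from meshes and equilibrium states.

Pore area is the epidermal-plane (XY) projection of the rim polygon;
cell volumes use the divergence theorem over the closed, outward-oriented
per-cell surface.  The scalar stress summary is the mean of the top 10%
of per-element Cauchy stress traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh import SurfaceMesh, _polygon_self_intersects

__all__ = [
    "PoreMetrics",
    "CellGeometry",
    "pore_area",
    "pore_metrics",
    "cell_volume",
    "cell_surface_area",
    "cell_geometry",
    "pair_percent_difference",
    "top_decile_mean_stress",
]


@dataclass(frozen=True)
class PoreMetrics:
    pore_area: float  # μm²
    pore_width: float  # μm, extent across the short (y) axis
    pore_length: float  # μm, extent along the pore (x) axis
    complex_length: float  # μm
    complex_width: float  # μm


@dataclass(frozen=True)
class CellGeometry:
    volume: float  # μm³
    surface_area: float  # μm²

    @property
    def sa_v(self) -> float:
        return self.surface_area / self.volume


def pore_area(
    mesh: SurfaceMesh, positions: np.ndarray | None = None, plane: str = "xy"
) -> float:
    """Projected pore area (μm²) by the shoelace formula over the rim loop.

    Projection is onto the epidermal (XY) plane by default, or onto the
    rim's least-squares best-fit plane (``plane="best_fit"``) for tilted
    imported meshes.  Orientation-independent (absolute value).  A
    self-intersecting projected rim triggers a warning and falls back to
    the magnitude of the signed area.
    """
    pos = mesh.vertices if positions is None else positions
    rim3 = pos[mesh.pore_rim]
    if plane == "best_fit":
        centred = rim3 - rim3.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        pts = centred @ vt[:2].T
    elif plane == "xy":
        pts = rim3[:, :2]
    else:
        raise ValueError("plane must be 'xy' or 'best_fit'")
    if len(pts) < 3:
        raise ValueError("pore rim needs at least 3 vertices")
    if _polygon_self_intersects(pts):
        warnings.warn("projected pore rim self-intersects; using signed-area fallback")
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)


def pore_metrics(mesh: SurfaceMesh, positions: np.ndarray | None = None) -> PoreMetrics:
    pos = mesh.vertices if positions is None else positions
    rim = pos[mesh.pore_rim]
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    return PoreMetrics(
        pore_area=pore_area(mesh, positions),
        pore_width=float(rim[:, 1].max() - rim[:, 1].min()),
        pore_length=float(rim[:, 0].max() - rim[:, 0].min()),
        complex_length=float(hi[0] - lo[0]),
        complex_width=float(hi[1] - lo[1]),
    )


def _oriented_corners(mesh: SurfaceMesh, cell: int, positions: np.ndarray | None):
    pos = mesh.vertices if positions is None else positions
    idx, sign = mesh.cell_triangles(cell)
    tri = mesh.triangles[idx]
    flip = sign < 0
    tri = tri.copy()
    tri[flip] = tri[flip][:, [0, 2, 1]]
    return pos[tri]


def cell_volume(mesh: SurfaceMesh, cell: int, positions: np.ndarray | None = None) -> float:
    """Enclosed volume (μm³) of one cell via the divergence theorem.

    V = (1/6) Σ v1 · (v2 × v3) over the outward-oriented closed surface;
    translation invariant for a closed surface.
    """
    p = _oriented_corners(mesh, cell, positions)
    return float(np.einsum("ij,ij->", p[:, 0], np.cross(p[:, 1], p[:, 2])) / 6.0)


def cell_surface_area(mesh: SurfaceMesh, cell: int, positions: np.ndarray | None = None) -> float:
    p = _oriented_corners(mesh, cell, positions)
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return float(0.5 * np.linalg.norm(n, axis=1).sum())


def cell_geometry(mesh: SurfaceMesh, cell: int, positions: np.ndarray | None = None) -> CellGeometry:
    return CellGeometry(
        volume=cell_volume(mesh, cell, positions),
        surface_area=cell_surface_area(mesh, cell, positions),
    )


def pair_percent_difference(value_gc1: float, value_gc2: float) -> float:
    """100 × |v1 − v2| / mean(v1, v2); the pair mean is the denominator."""
    if value_gc1 <= 0 or value_gc2 <= 0:
        raise ValueError("pair values must be positive")
    return 100.0 * abs(value_gc1 - value_gc2) / (0.5 * (value_gc1 + value_gc2))


def top_decile_mean_stress(cauchy_traces: np.ndarray) -> float:
    """Mean of the largest ceil(0.1 N) per-element Cauchy stress traces.

    Selection is by element count (unweighted by element area), strict
    count after a stable descending sort.
    """
    tr = np.asarray(cauchy_traces, float)
    if tr.size == 0:
        raise ValueError("no elements")
    k = int(np.ceil(0.1 * tr.size))
    top = np.sort(tr, kind="stable")[::-1][:k]
    return float(top.mean())
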