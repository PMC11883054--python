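"""Triangulated multicellular surface meshes with shared-wall bookkeeping.

A stomatal complex is represented as a single triangle soup in which every
triangle belongs to one cell (outer wall) or two cells (shared wall between
adjacent cells).  The triangle winding defines the outward normal of the
*front* cell; for a shared wall the *back* cell sees the same triangle with
the opposite orientation.  All lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised per-triangle region labels.
REGIONS = ("rod", "bulbous_end", "ventral_wall", "dorsal_wall", "polar", "sc_wall")


@dataclass
class SurfaceMesh:
    """Triangulated multicellular geometry.

    Attributes
    ----------
    vertices : (n_v, 3) float array
        Vertex positions in μm.  The epidermal plane is XY, the pore long
        axis is X and Z points out of the leaf surface.
    triangles : (n_t, 3) int array
        Vertex index triples.  The winding (right-hand rule) normal is the
        outward normal of the front cell.
    cell_front : (n_t,) int array
        Cell id on the interior side opposite the winding normal.
    cell_back : (n_t,) int array
        Cell id on the other side of the wall, or ``-1`` for ambient.
    thickness : (n_t,) float array
        Wall thickness per element, μm.
    fibre : (n_t, 3) float array
        Unit vector per element, tangent to the element plane, giving the
        principal cellulose microfibril (stiff) direction.
    region : (n_t,) str array
        One of :data:`REGIONS` per element.
    fixed_vertices : (n_v,) bool array
        Vertices with all displacement components constrained.
    pore_rim : (n_r,) int array
        Ordered vertex loop bounding the stomatal pore.
    cell_names : dict[int, str]
        Human names for the cell ids, e.g. ``{0: "GC1", 1: "GC2"}``.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    cell_front: np.ndarray
    cell_back: np.ndarray
    thickness: np.ndarray
    fibre: np.ndarray
    region: np.ndarray
    fixed_vertices: np.ndarray
    pore_rim: np.ndarray
    cell_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        self.cell_front = np.asarray(self.cell_front, dtype=np.int64)
        self.cell_back = np.asarray(self.cell_back, dtype=np.int64)
        self.thickness = np.asarray(self.thickness, dtype=np.float64)
        self.fibre = np.ascontiguousarray(self.fibre, dtype=np.float64)
        self.region = np.asarray(self.region, dtype="U12")
        self.fixed_vertices = np.asarray(self.fixed_vertices, dtype=bool)
        self.pore_rim = np.asarray(self.pore_rim, dtype=np.int64)

    # -- basic sizes ---------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def cell_ids(self) -> list[int]:
        ids = set(self.cell_front.tolist()) | set(self.cell_back.tolist())
        ids.discard(-1)
        return sorted(ids)

    # -- per-element geometry ------------------------------------------
    def triangle_corners(self, positions: np.ndarray | None = None) -> np.ndarray:
        """(n_t, 3 corners, 3 xyz) corner positions."""
        pos = self.vertices if positions is None else positions
        return pos[self.triangles]

    def triangle_normals(self, positions: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (unit normals, areas) in the given configuration."""
        p = self.triangle_corners(positions)
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        a2 = np.linalg.norm(n, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = n / a2[:, None]
        return unit, 0.5 * a2

    def cell_triangles(self, cell: int) -> tuple[np.ndarray, np.ndarray]:
        """Triangle indices of a cell's closed surface and orientation signs.

        Sign +1 means the winding normal already points out of the cell,
        -1 means it points inward (the cell is the back cell of a shared
        wall) and the triangle must be flipped for outward integrals.
        """
        front = np.flatnonzero(self.cell_front == cell)
        back = np.flatnonzero(self.cell_back == cell)
        idx = np.concatenate([front, back])
        sign = np.concatenate([np.ones(len(front)), -np.ones(len(back))])
        return idx, sign

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(), self.triangles.copy(), self.cell_front.copy(),
            self.cell_back.copy(), self.thickness.copy(), self.fibre.copy(),
            self.region.copy(), self.fixed_vertices.copy(), self.pore_rim.copy(),
            dict(self.cell_names),
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_mesh`; failures are reported, never raised."""

    passed: bool
    issues: list[str]
    per_cell_closed: dict[int, bool]
    shared_wall_counts: dict[tuple[int, int], int]
    bad_fibre_elements: np.ndarray
    bad_thickness_elements: np.ndarray

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def _cell_edge_consistency(mesh: SurfaceMesh, cell: int) -> tuple[bool, bool]:
    """(closed, consistently oriented) for one cell's triangle set.

    A closed orientable surface has every directed edge appearing exactly
    once, paired with its reverse.
    """
    idx, sign = mesh.cell_triangles(cell)
    tris = mesh.triangles[idx].copy()
    flip = sign < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    directed = {}
    for a, b in edges:
        key = (int(a), int(b))
        directed[key] = directed.get(key, 0) + 1
    closed = True
    oriented = True
    for (a, b), c in directed.items():
        if c != 1:
            oriented = False
        if directed.get((b, a), 0) != c:
            closed = False
    return closed, oriented


def validate_mesh(mesh: SurfaceMesh, tol: float = 1e-8) -> ValidationReport:
    """Check every structural invariant of a :class:`SurfaceMesh`.

    Verifies per-cell closedness and orientation consistency, fibre-field
    unit norm and tangency, positive thickness, and a single closed pore
    rim.  Returns a report; never raises.
    """
    issues: list[str] = []

    per_cell: dict[int, bool] = {}
    for cell in mesh.cell_ids:
        closed, oriented = _cell_edge_consistency(mesh, cell)
        per_cell[cell] = closed and oriented
        if not closed:
            issues.append(f"cell {cell} ({mesh.cell_names.get(cell, '?')}): surface not closed")
        if not oriented:
            issues.append(f"cell {cell}: inconsistent triangle orientation")

    # shared-wall bookkeeping
    shared: dict[tuple[int, int], int] = {}
    for f, b in zip(mesh.cell_front, mesh.cell_back):
        if b >= 0:
            key = (int(min(f, b)), int(max(f, b)))
            shared[key] = shared.get(key, 0) + 1
    if np.any(mesh.cell_front < 0):
        issues.append("triangles without a front cell")

    # fibre tangency and unit norm
    normals, areas = mesh.triangle_normals()
    norm = np.linalg.norm(mesh.fibre, axis=1)
    dot = np.abs(np.einsum("ij,ij->i", mesh.fibre, normals))
    bad_fibre = np.flatnonzero((np.abs(norm - 1.0) > 1e-6) | (dot > 1e-6 + tol))
    if len(bad_fibre):
        issues.append(f"{len(bad_fibre)} elements with non-unit or non-tangent fibre vectors")

    bad_thick = np.flatnonzero(~(mesh.thickness > 0))
    if len(bad_thick):
        issues.append(f"{len(bad_thick)} elements with non-positive thickness")

    if np.any(areas <= 0) or np.any(~np.isfinite(areas)):
        issues.append("degenerate (zero-area) triangles present")

    # pore rim: closed, non-self-intersecting loop in XY projection
    rim = mesh.pore_rim
    if len(rim) < 3:
        issues.append("pore rim has fewer than 3 vertices")
    elif len(np.unique(rim)) != len(rim):
        issues.append("pore rim revisits a vertex")
    else:
        pts = mesh.vertices[rim][:, :2]
        if _polygon_self_intersects(pts):
            issues.append("pore rim self-intersects in the epidermal plane")

    return ValidationReport(
        passed=not issues,
        issues=issues,
        per_cell_closed=per_cell,
        shared_wall_counts=shared,
        bad_fibre_elements=bad_fibre,
        bad_thickness_elements=bad_thick,
    )


def _polygon_self_intersects(pts: np.ndarray) -> bool:
    """Brute-force segment intersection test on a closed 2D polygon."""
    n = len(pts)
    seg_a = pts
    seg_b = pts[(np.arange(n) + 1) % n]

    def ccw(p, q, r):
        return (q[..., 0] - p[..., 0]) * (r[..., 1] - p[..., 1]) - (
            q[..., 1] - p[..., 1]
        ) * (r[..., 0] - p[..., 0])

    for i in range(n):
        # skip adjacent segments (share a vertex)
        js = np.arange(i + 2, n if i > 0 else n - 1)
        if len(js) == 0:
            continue
        p1, p2 = seg_a[i], seg_b[i]
        q1, q2 = seg_a[js], seg_b[js]
        d1 = ccw(p1, p2, q1)
        d2 = ccw(p1, p2, q2)
        d3 = ccw(q1, q2, p1[None])
        d4 = ccw(q1, q2, p2[None])
        if np.any((d1 * d2 < 0) & (d3 * d4 < 0)):
            return True
    return False
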