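"""Mesh and state serialisation: PLY, legacy VTK and OBJ (+ sidecar).

Meshes round-trip through binary little-endian PLY carrying the full
attribute schema (per-face ``thickness``, ``fiber_x/y/z``, ``region``,
``cell_front``, ``cell_back``; per-vertex ``fixed`` flag; the pore rim as
its own element; cell names and provenance as comments).  Converged
states are written as legacy ASCII VTK unstructured grids with point
displacements and per-cell stress fields.  OBJ carries geometry only and
is accepted with a JSON sidecar holding the attributes.
"""

from __future__ import annotations

import hashlib
import json
import struct
from pathlib import Path

import numpy as np

from . import __version__
from .mesh import REGIONS, SurfaceMesh

__all__ = ["read_mesh", "write_mesh", "write_state", "read_state", "MeshIOError", "provenance"]

_REGION_CODE = {r: i for i, r in enumerate(REGIONS)}


class MeshIOError(ValueError):
    """Missing attributes or an unreadable mesh file."""


def provenance(seed: int | None = None, config_hash: str | None = None) -> str:
    parts = [f"stomamech {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return " ".join(parts)


def config_digest(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------
def _write_ply(mesh: SurfaceMesh, path: Path, comment: str | None) -> None:
    nv, nt, nr = mesh.n_vertices, mesh.n_triangles, len(mesh.pore_rim)
    header = ["ply", "format binary_little_endian 1.0"]
    header.append(f"comment {provenance()}")
    if comment:
        header.append(f"comment {comment}")
    for cid in sorted(mesh.cell_names):
        header.append(f"comment cell {cid} {mesh.cell_names[cid]}")
    header.append("comment region_codes " + ",".join(REGIONS))
    header += [
        f"element vertex {nv}",
        "property double x", "property double y", "property double z",
        "property uchar fixed",
        f"element face {nt}",
        "property list uchar int vertex_indices",
        "property double thickness",
        "property double fiber_x", "property double fiber_y", "property double fiber_z",
        "property uchar region",
        "property int cell_front", "property int cell_back",
        f"element rim {nr}",
        "property int vertex_index",
        "end_header",
    ]
    vdt = np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("fixed", "u1")])
    varr = np.empty(nv, vdt)
    varr["x"], varr["y"], varr["z"] = mesh.vertices.T
    varr["fixed"] = mesh.fixed_vertices.astype("u1")
    fdt = np.dtype([
        ("n", "u1"), ("v0", "<i4"), ("v1", "<i4"), ("v2", "<i4"),
        ("thickness", "<f8"), ("fx", "<f8"), ("fy", "<f8"), ("fz", "<f8"),
        ("region", "u1"), ("front", "<i4"), ("back", "<i4"),
    ])
    farr = np.empty(nt, fdt)
    farr["n"] = 3
    farr["v0"], farr["v1"], farr["v2"] = mesh.triangles.T.astype("<i4")
    farr["thickness"] = mesh.thickness
    farr["fx"], farr["fy"], farr["fz"] = mesh.fibre.T
    farr["region"] = [_REGION_CODE[r] for r in mesh.region]
    farr["front"] = mesh.cell_front.astype("<i4")
    farr["back"] = mesh.cell_back.astype("<i4")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(varr.tobytes())
        fh.write(farr.tobytes())
        fh.write(mesh.pore_rim.astype("<i4").tobytes())


def _read_ply(path: Path) -> SurfaceMesh:
    with open(path, "rb") as fh:
        data = fh.read()
    end = data.find(b"end_header\n")
    if not data.startswith(b"ply") or end < 0:
        raise MeshIOError(f"{path}: not a PLY file")
    header = data[:end].decode("ascii").splitlines()
    body = data[end + len(b"end_header\n"):]
    if "format binary_little_endian 1.0" not in header[1]:
        raise MeshIOError(f"{path}: only binary little-endian PLY is supported")

    cell_names: dict[int, str] = {}
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    for line in header[2:]:
        if line.startswith("comment cell "):
            _, _, cid, name = line.split(maxsplit=3)
            cell_names[int(cid)] = name
        elif line.startswith("element "):
            _, name, cnt = line.split()
            elements.append((name, int(cnt), []))
        elif line.startswith("property "):
            parts = line.split()
            if parts[1] == "list":
                elements[-1][2].append(("list", parts[-1]))
            else:
                elements[-1][2].append((parts[1], parts[2]))

    type_map = {"double": "<f8", "float": "<f4", "uchar": "u1", "int": "<i4", "uint": "<u4"}
    arrays: dict[str, dict[str, np.ndarray]] = {}
    off = 0
    for name, cnt, props in elements:
        fields = []
        for i, (typ, pname) in enumerate(props):
            if typ == "list":
                fields += [("_n", "u1"), ("v0", "<i4"), ("v1", "<i4"), ("v2", "<i4")]
            else:
                fields.append((pname, type_map[typ]))
        dt = np.dtype(fields)
        arr = np.frombuffer(body, dtype=dt, count=cnt, offset=off)
        off += dt.itemsize * cnt
        arrays[name] = {f: arr[f] for f, _ in fields}

    required_face = {"thickness", "fiber_x", "fiber_y", "fiber_z", "region",
                     "cell_front", "cell_back"}
    have = set(arrays.get("face", {}))
    missing = required_face - have
    if "vertex" not in arrays or "face" not in arrays:
        raise MeshIOError(f"{path}: missing vertex or face element")
    if missing:
        raise MeshIOError(f"{path}: missing face attributes: {sorted(missing)}")
    if "fixed" not in arrays["vertex"]:
        raise MeshIOError(f"{path}: missing vertex attribute 'fixed'")

    v = arrays["vertex"]
    f = arrays["face"]
    verts = np.stack([v["x"], v["y"], v["z"]], axis=1).astype(np.float64)
    tris = np.stack([f["v0"], f["v1"], f["v2"]], axis=1).astype(np.int64)
    rim = arrays.get("rim", {}).get("vertex_index", np.array([], dtype=np.int64))
    return SurfaceMesh(
        vertices=verts,
        triangles=tris,
        cell_front=f["cell_front"].astype(np.int64),
        cell_back=f["cell_back"].astype(np.int64),
        thickness=f["thickness"].astype(np.float64),
        fibre=np.stack([f["fiber_x"], f["fiber_y"], f["fiber_z"]], axis=1).astype(np.float64),
        region=np.array([REGIONS[int(c)] for c in f["region"]], dtype="U12"),
        fixed_vertices=v["fixed"].astype(bool),
        pore_rim=np.asarray(rim, dtype=np.int64),
        cell_names=cell_names,
    )


# ---------------------------------------------------------------------------
# legacy VTK (ASCII unstructured grid)
# ---------------------------------------------------------------------------
def _fmt(x: float) -> str:
    return repr(float(x))


def _write_vtk_mesh(mesh: SurfaceMesh, path: Path, comment: str | None,
                    positions: np.ndarray | None = None,
                    cell_scalars: dict[str, np.ndarray] | None = None,
                    point_vectors: dict[str, np.ndarray] | None = None) -> None:
    pos = mesh.vertices if positions is None else positions
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        title = provenance() + (f" | {comment}" if comment else "")
        title += " | cells " + ";".join(f"{k}:{v}" for k, v in sorted(mesh.cell_names.items()))
        title += " | rim " + ",".join(map(str, mesh.pore_rim.tolist()))
        fh.write(title[:255] + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in pos:
            fh.write(f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")
        nt = mesh.n_triangles
        fh.write(f"CELLS {nt} {4 * nt}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {nt}\n" + "\n".join(["5"] * nt) + "\n")
        fh.write(f"POINT_DATA {mesh.n_vertices}\n")
        fh.write("SCALARS fixed int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(b)) for b in mesh.fixed_vertices) + "\n")
        for name, vec in (point_vectors or {}).items():
            fh.write(f"VECTORS {name} double\n")
            for p in vec:
                fh.write(f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")
        fh.write(f"CELL_DATA {nt}\n")
        base = {
            "thickness": mesh.thickness,
            "region": np.array([_REGION_CODE[r] for r in mesh.region], float),
            "cell_front": mesh.cell_front.astype(float),
            "cell_back": mesh.cell_back.astype(float),
            "fiber_x": mesh.fibre[:, 0], "fiber_y": mesh.fibre[:, 1], "fiber_z": mesh.fibre[:, 2],
        }
        base.update(cell_scalars or {})
        for name, arr in base.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(_fmt(x) for x in arr) + "\n")


def _read_vtk(path: Path):
    """Parse the legacy VTK files this package writes.

    Returns (mesh, point_vectors, cell_scalars); state files re-read this
    way preserve every float64 exactly (values are written with repr).
    """
    lines = Path(path).read_text().splitlines()
    if not lines[0].startswith("# vtk"):
        raise MeshIOError(f"{path}: not a legacy VTK file")
    title = lines[1]
    cell_names: dict[int, str] = {}
    rim: list[int] = []
    for part in title.split(" | "):
        if part.startswith("cells "):
            for item in part[6:].split(";"):
                if item:
                    cid, name = item.split(":")
                    cell_names[int(cid)] = name
        elif part.startswith("rim "):
            rim = [int(x) for x in part[4:].split(",") if x]
    i = 2
    points = None
    tris = None
    point_vectors: dict[str, np.ndarray] = {}
    scalars: dict[str, np.ndarray] = {}
    point_scalars: dict[str, np.ndarray] = {}
    n_pts = n_cells = 0
    section = None
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("POINTS"):
            n_pts = int(ln.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n_pts:
                vals += lines[i].split()
                i += 1
            points = np.array(vals, float).reshape(n_pts, 3)
            continue
        if ln.startswith("CELLS"):
            n_cells = int(ln.split()[1])
            tris = np.empty((n_cells, 3), np.int64)
            for k in range(n_cells):
                parts = lines[i + 1 + k].split()
                tris[k] = [int(parts[1]), int(parts[2]), int(parts[3])]
            i += 1 + n_cells
            continue
        if ln.startswith("CELL_TYPES"):
            i += 1 + n_cells
            continue
        if ln.startswith("POINT_DATA"):
            section = "point"
            i += 1
            continue
        if ln.startswith("CELL_DATA"):
            section = "cell"
            i += 1
            continue
        if ln.startswith("SCALARS"):
            name = ln.split()[1]
            count = n_pts if section == "point" else n_cells
            vals = []
            i += 2  # skip LOOKUP_TABLE
            while len(vals) < count:
                vals += lines[i].split()
                i += 1
            (point_scalars if section == "point" else scalars)[name] = np.array(vals, float)
            continue
        if ln.startswith("VECTORS"):
            name = ln.split()[1]
            vals = []
            i += 1
            while len(vals) < 3 * n_pts:
                vals += lines[i].split()
                i += 1
            point_vectors[name] = np.array(vals, float).reshape(n_pts, 3)
            continue
        i += 1

    needed = {"thickness", "region", "cell_front", "cell_back", "fiber_x", "fiber_y", "fiber_z"}
    missing = needed - set(scalars)
    if missing:
        raise MeshIOError(f"{path}: missing cell attributes: {sorted(missing)}")
    if "fixed" not in point_scalars:
        raise MeshIOError(f"{path}: missing point attribute 'fixed'")
    mesh = SurfaceMesh(
        vertices=points, triangles=tris,
        cell_front=scalars["cell_front"].astype(np.int64),
        cell_back=scalars["cell_back"].astype(np.int64),
        thickness=scalars["thickness"],
        fibre=np.stack([scalars["fiber_x"], scalars["fiber_y"], scalars["fiber_z"]], axis=1),
        region=np.array([REGIONS[int(c)] for c in scalars["region"]], dtype="U12"),
        fixed_vertices=point_scalars["fixed"].astype(bool),
        pore_rim=np.array(rim, dtype=np.int64),
        cell_names=cell_names,
    )
    extra = {k: v for k, v in scalars.items() if k not in needed}
    return mesh, point_vectors, extra


# ---------------------------------------------------------------------------
# OBJ (+ JSON sidecar attributes)
# ---------------------------------------------------------------------------
def _write_obj(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance()}\n")
        for p in mesh.vertices:
            fh.write(f"v {_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")
        for t in mesh.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
    sidecar = path.with_suffix(path.suffix + ".attrs.json")
    sidecar.write_text(json.dumps({
        "thickness": mesh.thickness.tolist(),
        "fibre": mesh.fibre.tolist(),
        "region": mesh.region.tolist(),
        "cell_front": mesh.cell_front.tolist(),
        "cell_back": mesh.cell_back.tolist(),
        "fixed_vertices": mesh.fixed_vertices.astype(int).tolist(),
        "pore_rim": mesh.pore_rim.tolist(),
        "cell_names": {str(k): v for k, v in mesh.cell_names.items()},
    }))


def _read_obj(path: Path) -> SurfaceMesh:
    sidecar = path.with_suffix(path.suffix + ".attrs.json")
    if not sidecar.exists():
        raise MeshIOError(
            f"{path}: OBJ carries no attributes; sidecar {sidecar.name} is required"
        )
    verts, tris = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("v "):
            verts.append([float(x) for x in line.split()[1:4]])
        elif line.startswith("f "):
            tris.append([int(x.split("/")[0]) - 1 for x in line.split()[1:4]])
    att = json.loads(sidecar.read_text())
    return SurfaceMesh(
        vertices=np.array(verts), triangles=np.array(tris, dtype=np.int64),
        cell_front=np.array(att["cell_front"]), cell_back=np.array(att["cell_back"]),
        thickness=np.array(att["thickness"]), fibre=np.array(att["fibre"]),
        region=np.array(att["region"], dtype="U12"),
        fixed_vertices=np.array(att["fixed_vertices"], bool),
        pore_rim=np.array(att["pore_rim"], dtype=np.int64),
        cell_names={int(k): v for k, v in att["cell_names"].items()},
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------
def write_mesh(mesh: SurfaceMesh, path, comment: str | None = None) -> None:
    """Write a mesh as PLY (binary), VTK (legacy ASCII) or OBJ + sidecar."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        _write_ply(mesh, path, comment)
    elif ext == ".vtk":
        _write_vtk_mesh(mesh, path, comment)
    elif ext == ".obj":
        _write_obj(mesh, path)
    else:
        raise MeshIOError(f"unsupported mesh format {ext!r} (use .ply/.vtk/.obj)")


def read_mesh(path) -> SurfaceMesh:
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        return _read_ply(path)
    if ext == ".vtk":
        return _read_vtk(path)[0]
    if ext == ".obj":
        return _read_obj(path)
    raise MeshIOError(f"unsupported mesh format {ext!r} (use .ply/.vtk/.obj)")


def write_state(mesh: SurfaceMesh, state, path, comment: str | None = None) -> None:
    """Write a converged state as VTK with displacements and stress fields."""
    path = Path(path)
    strain_trace = state.strain_voigt[:, 0] + state.strain_voigt[:, 1]
    _write_vtk_mesh(
        mesh, path, comment,
        positions=state.positions,
        point_vectors={"displacement": state.positions - mesh.vertices},
        cell_scalars={"cauchy_trace": state.cauchy_trace, "strain_trace": strain_trace},
    )


def read_state(path):
    """Re-read a state file: (mesh-in-deformed-coordinates, fields dict)."""
    mesh, vectors, extra = _read_vtk(Path(path))
    fields = dict(extra)
    fields.update(vectors)
    return mesh, fields
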