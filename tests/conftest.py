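"""Shared fixtures: analytic oracle meshes and default stomatal complexes."""

from __future__ import annotations

import numpy as np
import pytest

from stomamech import (
    MembraneModel,
    SurfaceMesh,
    build_dumbbell_complex,
    build_kidney_pair,
    default_dumbbell_template,
    default_kidney_template,
)
from stomamech.geometry import default_materials


def make_icosphere(radius: float = 10.0, subdivisions: int = 3, thickness: float = 0.5,
                   pressure_cell: str = "GC1") -> SurfaceMesh:
    """Closed icosphere as a single pressurised cell (oracle geometry)."""
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    nt = len(ico.faces)
    n = ico.face_normals
    f = np.cross(n, [0.0, 0.0, 1.0])
    bad = np.linalg.norm(f, axis=1) < 1e-8
    f[bad] = np.cross(n[bad], [0.0, 1.0, 0.0])
    f /= np.linalg.norm(f, axis=1)[:, None]
    return SurfaceMesh(
        vertices=np.asarray(ico.vertices, float),
        triangles=np.asarray(ico.faces, np.int64),
        cell_front=np.zeros(nt, np.int64),
        cell_back=-np.ones(nt, np.int64),
        thickness=np.full(nt, thickness),
        fibre=f,
        region=np.array(["bulbous_end"] * nt, dtype="U12"),
        fixed_vertices=np.zeros(len(ico.vertices), bool),
        pore_rim=np.array([0, 1, 2], np.int64),
        cell_names={0: pressure_cell},
    )


def make_unit_cube() -> SurfaceMesh:
    """Unit cube (12 triangles, outward-oriented) as a single cell."""
    v = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float
    )
    t = np.array(
        [[0, 2, 1], [0, 3, 2],  # bottom (z=0), outward -z
         [4, 5, 6], [4, 6, 7],  # top
         [0, 1, 5], [0, 5, 4],  # y=0
         [1, 2, 6], [1, 6, 5],  # x=1
         [2, 3, 7], [2, 7, 6],  # y=1
         [3, 0, 4], [3, 4, 7]], np.int64  # x=0
    )
    nt = len(t)
    n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    n /= np.linalg.norm(n, axis=1)[:, None]
    f = np.cross(n, [0.0, 0.0, 1.0])
    bad = np.linalg.norm(f, axis=1) < 1e-8
    f[bad] = np.cross(n[bad], [0.0, 1.0, 0.0])
    f /= np.linalg.norm(f, axis=1)[:, None]
    return SurfaceMesh(
        vertices=v, triangles=t,
        cell_front=np.zeros(nt, np.int64), cell_back=-np.ones(nt, np.int64),
        thickness=np.full(nt, 0.1), fibre=f,
        region=np.array(["bulbous_end"] * nt, dtype="U12"),
        fixed_vertices=np.zeros(8, bool),
        pore_rim=np.array([0, 1, 2, 3], np.int64),
        cell_names={0: "GC1"},
    )


@pytest.fixture(scope="session")
def dumbbell_mesh():
    return build_dumbbell_complex(default_dumbbell_template())


@pytest.fixture(scope="session")
def kidney_mesh():
    return build_kidney_pair(default_kidney_template())


@pytest.fixture(scope="session")
def dumbbell_model(dumbbell_mesh):
    return MembraneModel(dumbbell_mesh, default_materials("dumbbell"))


@pytest.fixture(scope="session")
def kidney_model(kidney_mesh):
    return MembraneModel(kidney_mesh, default_materials("kidney"))


@pytest.fixture(scope="session")
def icosphere():
    return make_icosphere()


@pytest.fixture(scope="session")
def unit_cube():
    return make_unit_cube()
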