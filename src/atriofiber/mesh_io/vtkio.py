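"""Legacy-ASCII VTK unstructured-grid I/O (triangles and tetrahedra).

Element tags are stored as a ``region`` scalar cell array and fibers as a
``fiber`` vector cell array. Only homogeneous Tr/Tt grids are supported.
"""

from __future__ import annotations

import numpy as np

from atriofiber.mesh_io.types import SurfaceMesh, TetMesh

__all__ = ["read_vtk", "write_vtk"]

_VTK_TRIANGLE = 5
_VTK_TETRA = 10


class VtkParseError(ValueError):
    pass


def write_vtk(mesh: SurfaceMesh | TetMesh, path: str) -> None:
    is_surface = isinstance(mesh, SurfaceMesh)
    conn = mesh.triangles if is_surface else mesh.tets
    ctype = _VTK_TRIANGLE if is_surface else _VTK_TETRA
    npts = conn.shape[1]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\natriofiber mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"CELLS {len(conn)} {len(conn) * (npts + 1)}\n")
        for elem in conn:
            fh.write(f"{npts} " + " ".join(str(v) for v in elem) + "\n")
        fh.write(f"CELL_TYPES {len(conn)}\n")
        for _ in range(len(conn)):
            fh.write(f"{ctype}\n")
        fh.write(f"CELL_DATA {len(conn)}\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        for t in mesh.element_tags:
            fh.write(f"{t}\n")
        if mesh.fibers is not None:
            fh.write("VECTORS fiber double\n")
            for f in mesh.fibers:
                fh.write(f"{f[0]:.9g} {f[1]:.9g} {f[2]:.9g}\n")


def _tokens(path: str):
    with open(path) as fh:
        text = fh.read()
    return text.split()


def read_vtk(path: str) -> SurfaceMesh | TetMesh:
    tok = _tokens(path)
    upper = [t.upper() for t in tok]

    def find(kw: str, start: int = 0) -> int:
        try:
            return upper.index(kw, start)
        except ValueError:
            raise VtkParseError(f"{path}: missing {kw} section") from None

    i = find("POINTS")
    n_pts = int(tok[i + 1])
    pts = np.array(tok[i + 3 : i + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)

    i = find("CELLS")
    n_cells = int(tok[i + 1])
    size = int(tok[i + 2])
    flat = np.array(tok[i + 3 : i + 3 + size], dtype=np.int64)
    cells = []
    j = 0
    for _ in range(n_cells):
        k = flat[j]
        cells.append(flat[j + 1 : j + 1 + k])
        j += 1 + k
    i = find("CELL_TYPES")
    types = np.array(tok[i + 2 : i + 2 + n_cells], dtype=int)
    kinds = set(types.tolist())
    if kinds == {_VTK_TRIANGLE}:
        conn = np.vstack(cells)
        cls: type = SurfaceMesh
    elif kinds == {_VTK_TETRA}:
        conn = np.vstack(cells)
        cls = TetMesh
    else:
        raise VtkParseError(f"{path}: unsupported cell types {sorted(kinds)}")

    tags = np.zeros(n_cells, dtype=np.int64)
    fibers = None
    try:
        i = find("CELL_DATA")
    except VtkParseError:
        i = -1
    if i >= 0:
        j = i
        while j < len(tok):
            word = upper[j]
            if word == "SCALARS" and tok[j + 1] == "region":
                # skip SCALARS name type [comps] + LOOKUP_TABLE default
                k = j + 2
                while upper[k] != "LOOKUP_TABLE":
                    k += 1
                tags = np.array(tok[k + 2 : k + 2 + n_cells], dtype=np.int64)
                j = k + 2 + n_cells
            elif word == "VECTORS" and tok[j + 1] == "fiber":
                fibers = np.array(
                    tok[j + 3 : j + 3 + 3 * n_cells], dtype=float
                ).reshape(n_cells, 3)
                j += 3 + 3 * n_cells
            else:
                j += 1
    if cls is SurfaceMesh:
        return SurfaceMesh(vertices=pts, triangles=conn, element_tags=tags, fibers=fibers)
    return TetMesh(vertices=pts, tets=conn, element_tags=tags, fibers=fibers)
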