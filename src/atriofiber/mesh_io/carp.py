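"""CARP text-format mesh I/O (.pts / .elem / .lon).

Dialect fixed here: .pts holds a count line followed by three columns of
mm coordinates (use ``units`` to convert, e.g. ``units="um"`` for files
written in micrometers); .elem holds a count line followed by ``Tr``
(triangle) or ``Tt`` (tetrahedron) records with a trailing integer region
tag; .lon holds a leading axes-per-element count (always 1 here) and one
unit axis per element.
"""

from __future__ import annotations

import os

import numpy as np

from atriofiber.mesh_io.types import MeshValidationError, SurfaceMesh, TetMesh

__all__ = ["read_carp", "write_carp", "CarpParseError"]

_UNIT_SCALE = {"mm": 1.0, "um": 1e-3, "cm": 10.0, "m": 1e3}


class CarpParseError(ValueError):
    def __init__(self, path: str, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


def _read_pts(path: str, scale: float) -> np.ndarray:
    with open(path) as fh:
        lines = fh.read().split("\n")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise CarpParseError(path, 1, "expected vertex count header") from None
    pts = np.empty((n, 3))
    for i in range(n):
        parts = lines[1 + i].split()
        if len(parts) < 3:
            raise CarpParseError(path, i + 2, f"expected 3 coordinates, got {parts!r}")
        try:
            pts[i] = [float(p) for p in parts[:3]]
        except ValueError:
            raise CarpParseError(path, i + 2, f"non-numeric coordinate in {parts!r}") from None
    return pts * scale


def _read_elem(path: str) -> tuple[str, np.ndarray, np.ndarray]:
    with open(path) as fh:
        lines = fh.read().split("\n")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise CarpParseError(path, 1, "expected element count header") from None
    kind = None
    conn, tags = [], []
    for i in range(n):
        parts = lines[1 + i].split()
        if not parts:
            raise CarpParseError(path, i + 2, "unexpected blank element record")
        etype = parts[0]
        if etype not in ("Tr", "Tt"):
            raise CarpParseError(
                path, i + 2, f"unsupported element type {etype!r} (only Tr/Tt)"
            )
        if kind is None:
            kind = etype
        elif etype != kind:
            raise CarpParseError(
                path, i + 2, f"mixed element types {kind}/{etype} not supported"
            )
        nv = 3 if etype == "Tr" else 4
        if len(parts) < 1 + nv:
            raise CarpParseError(path, i + 2, f"expected {nv} vertex indices")
        try:
            conn.append([int(p) for p in parts[1 : 1 + nv]])
            tags.append(int(parts[1 + nv]) if len(parts) > 1 + nv else 0)
        except ValueError:
            raise CarpParseError(path, i + 2, "non-integer field in element record") from None
    if kind is None:
        raise CarpParseError(path, 1, "empty element file")
    return kind, np.asarray(conn, dtype=np.int64), np.asarray(tags, dtype=np.int64)


def _read_lon(path: str, n_elem: int) -> np.ndarray:
    with open(path) as fh:
        lines = [ln for ln in fh.read().split("\n") if ln.strip()]
    start = 0
    if len(lines) == n_elem + 1 and len(lines[0].split()) == 1:
        start = 1  # leading axes-per-element header
    if len(lines) - start != n_elem:
        raise CarpParseError(
            path, 1, f"expected {n_elem} fiber records, found {len(lines) - start}"
        )
    fib = np.empty((n_elem, 3))
    for i in range(n_elem):
        parts = lines[start + i].split()
        if len(parts) < 3:
            raise CarpParseError(path, start + i + 1, "expected 3 axis components")
        fib[i] = [float(p) for p in parts[:3]]
    return fib


def read_carp(basename: str, units: str = "mm") -> SurfaceMesh | TetMesh:
    """Read a mesh from ``basename``.pts/.elem (and .lon when present)."""
    scale = _UNIT_SCALE[units]
    pts = _read_pts(basename + ".pts", scale)
    kind, conn, tags = _read_elem(basename + ".elem")
    fibers = None
    if os.path.exists(basename + ".lon"):
        fibers = _read_lon(basename + ".lon", len(conn))
    if kind == "Tr":
        return SurfaceMesh(vertices=pts, triangles=conn, element_tags=tags, fibers=fibers)
    return TetMesh(vertices=pts, tets=conn, element_tags=tags, fibers=fibers)


def write_carp(mesh: SurfaceMesh | TetMesh, basename: str, units: str = "mm") -> None:
    """Write .pts/.elem; a .lon file is emitted iff the mesh carries fibers."""
    if mesh.fibers is not None:
        norms = np.linalg.norm(mesh.fibers, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise MeshValidationError("refusing to write non-unit fibers to .lon")
    scale = _UNIT_SCALE[units]
    with open(basename + ".pts", "w") as fh:
        fh.write(f"{mesh.n_vertices}\n")
        for p in mesh.vertices / scale:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
    is_surface = isinstance(mesh, SurfaceMesh)
    kind = "Tr" if is_surface else "Tt"
    conn = mesh.triangles if is_surface else mesh.tets
    with open(basename + ".elem", "w") as fh:
        fh.write(f"{len(conn)}\n")
        for elem, tag in zip(conn, mesh.element_tags):
            fh.write(f"{kind} " + " ".join(str(v) for v in elem) + f" {tag}\n")
    lon = basename + ".lon"
    if mesh.fibers is not None:
        with open(lon, "w") as fh:
            fh.write("1\n")
            for f in mesh.fibers:
                fh.write(f"{f[0]:.9g} {f[1]:.9g} {f[2]:.9g}\n")
    elif os.path.exists(lon):
        os.remove(lon)
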