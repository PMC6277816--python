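"""Mesh/image containers, CARP + legacy-VTK + NIfTI/MetaImage I/O, topology."""

from __future__ import annotations

import os

from atriofiber.mesh_io.carp import CarpParseError, read_carp, write_carp
from atriofiber.mesh_io.image import read_image, write_image
from atriofiber.mesh_io.topology import (
    BoundaryComponent,
    TopologyError,
    boundary_faces,
    element_adjacency,
    enclosed_volume,
    extract_boundary_surfaces,
    trace_edge_loops,
)
from atriofiber.mesh_io.types import (
    MeshValidationError,
    SurfaceMesh,
    TetMesh,
    VoxelImage,
)
from atriofiber.mesh_io.vtkio import read_vtk, write_vtk

__all__ = [
    "BoundaryComponent",
    "CarpParseError",
    "MeshValidationError",
    "SurfaceMesh",
    "TetMesh",
    "TopologyError",
    "VoxelImage",
    "boundary_faces",
    "element_adjacency",
    "enclosed_volume",
    "extract_boundary_surfaces",
    "read_mesh",
    "read_carp",
    "read_image",
    "read_vtk",
    "trace_edge_loops",
    "write_carp",
    "write_image",
    "write_mesh",
    "write_vtk",
]


def read_mesh(path: str, format: str | None = None, units: str = "mm"):
    """Read a mesh, dispatching on ``format`` or the file extension.

    For CARP, ``path`` may be the basename or any of the .pts/.elem files.
    """
    fmt = format or ("vtk" if path.endswith(".vtk") else "carp")
    if fmt == "vtk":
        return read_vtk(path)
    if fmt == "carp":
        base, ext = os.path.splitext(path)
        if ext in (".pts", ".elem", ".lon"):
            path = base
        return read_carp(path, units=units)
    raise ValueError(f"unknown mesh format {fmt!r}")


def write_mesh(mesh, path: str, format: str | None = None, units: str = "mm") -> None:
    fmt = format or ("vtk" if path.endswith(".vtk") else "carp")
    if fmt == "vtk":
        write_vtk(mesh, path)
    elif fmt == "carp":
        base, ext = os.path.splitext(path)
        if ext in (".pts", ".elem", ".lon"):
            path = base
        write_carp(mesh, path, units=units)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")
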