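"""Core mesh and image containers shared by all pipeline stages.

Units are fixed package-wide: coordinates and spacings in mm, time in ms.
Fibers are stored per *element* (one unit axis per triangle/tetrahedron);
they are line fields, i.e. ``f`` and ``-f`` are equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelImage", "SurfaceMesh", "TetMesh", "MeshValidationError"]

_FIBER_NORM_TOL = 1e-6


class MeshValidationError(ValueError):
    """Raised when a mesh or image violates a structural invariant."""


@dataclass
class VoxelImage:
    """Scalar intensity grid with physical geometry.

    ``origin`` is the physical coordinate of the *center* of voxel (0,0,0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise MeshValidationError(
                f"voxel data must have 3 axes, got {self.data.ndim}"
            )
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise MeshValidationError("spacing must be 3 strictly positive values")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_physical(self, ijk: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to physical mm coordinates."""
        return self.origin + np.asarray(ijk, dtype=float) * self.spacing

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing


def _validate_fibers(fibers: np.ndarray, n_elem: int, what: str) -> np.ndarray:
    fibers = np.asarray(fibers, dtype=float)
    if fibers.shape != (n_elem, 3):
        raise MeshValidationError(
            f"{what}: fibers shape {fibers.shape} != ({n_elem}, 3)"
        )
    norms = np.linalg.norm(fibers, axis=1)
    if not np.allclose(norms, 1.0, atol=_FIBER_NORM_TOL):
        bad = int(np.argmax(np.abs(norms - 1.0)))
        raise MeshValidationError(
            f"{what}: fiber {bad} has norm {norms[bad]:.8f} (must be unit)"
        )
    return fibers


@dataclass
class SurfaceMesh:
    """Indexed triangle mesh with per-triangle integer tags and optional fibers."""

    vertices: np.ndarray
    triangles: np.ndarray
    element_tags: np.ndarray = None  # type: ignore[assignment]
    fibers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise MeshValidationError("triangle indices out of range")
        if self.element_tags is None:
            self.element_tags = np.zeros(len(self.triangles), dtype=np.int64)
        self.element_tags = np.asarray(self.element_tags, dtype=np.int64)
        if self.element_tags.shape != (len(self.triangles),):
            raise MeshValidationError("element_tags length != triangle count")
        if self.fibers is not None:
            self.fibers = _validate_fibers(self.fibers, len(self.triangles), "surface")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def triangle_centers(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def triangle_normals(self, normalized: bool = True) -> np.ndarray:
        v = self.vertices[self.triangles]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        if normalized:
            n = n / np.linalg.norm(n, axis=1, keepdims=True)
        return n

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_normals(normalized=False), axis=1)


@dataclass
class TetMesh:
    """Indexed tetrahedral mesh with per-tet integer tags and optional fibers.

    Node ordering convention: signed volume
    ``det(v1-v0, v2-v0, v3-v0) / 6`` is strictly positive for every element.
    """

    vertices: np.ndarray
    tets: np.ndarray
    element_tags: np.ndarray = None  # type: ignore[assignment]
    fibers: np.ndarray | None = None
    vertex_tags: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        n = len(self.vertices)
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= n):
            raise MeshValidationError("tet indices out of range")
        if self.element_tags is None:
            self.element_tags = np.zeros(len(self.tets), dtype=np.int64)
        self.element_tags = np.asarray(self.element_tags, dtype=np.int64)
        if self.element_tags.shape != (len(self.tets),):
            raise MeshValidationError("element_tags length != tet count")
        if self.fibers is not None:
            self.fibers = _validate_fibers(self.fibers, len(self.tets), "tet mesh")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def tet_centers(self) -> np.ndarray:
        return self.vertices[self.tets].mean(axis=1)

    def signed_volumes(self) -> np.ndarray:
        v = self.vertices[self.tets]
        a, b, c = v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def validate_orientation(self) -> None:
        vol = self.signed_volumes()
        if np.any(vol <= 0):
            bad = int(np.argmin(vol))
            raise MeshValidationError(
                f"tet {bad} has non-positive signed volume {vol[bad]:.3e}"
            )
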