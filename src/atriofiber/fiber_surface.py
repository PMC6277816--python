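"""Per-triangle fiber axes on atrial surfaces from per-region Laplace solves.

Each atlas region is solved independently (u=0 on its gamma0 lines, u=1 on
gamma1, zero-flux elsewhere); the normalized in-plane gradient — rotated
90 degrees in-plane when the region's ``orthogonal`` flag is set — becomes
the fiber axis of every triangle in the region. Axes are *line* fields:
all averaging here is sign-aligned before summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from atriofiber.atlas_regions import AtlasError, RegionAtlas
from atriofiber.laplace_fem import BoundaryConditionSpec, element_gradient, solve_laplace
from atriofiber.mesh_io import SurfaceMesh, element_adjacency

__all__ = [
    "SurfaceFiberField",
    "region_fibers",
    "fill_undefined",
    "smooth_interregional",
    "project_tangential",
    "generate_surface_fibers",
    "rim_winding_number",
]

PROV_LAPLACE, PROV_FILLED, PROV_SMOOTHED = 0, 1, 2
_DEGENERATE_GRAD = 1e-8


@dataclass
class SurfaceFiberField:
    axes: np.ndarray  # (n_tri, 3); rows of undefined triangles are zero
    defined: np.ndarray  # bool per triangle
    provenance: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.axes = np.asarray(self.axes, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.provenance is None:
            self.provenance = np.full(len(self.axes), PROV_LAPLACE, dtype=np.int8)

    def copy(self) -> "SurfaceFiberField":
        return SurfaceFiberField(
            self.axes.copy(), self.defined.copy(), self.provenance.copy()
        )


def _region_triangles(atlas: RegionAtlas, rid: int) -> np.ndarray:
    if atlas.triangle_region is None:
        raise AtlasError("atlas has no triangle partition; run partition_regions")
    return np.flatnonzero(atlas.triangle_region == rid)


def region_fibers(surface: SurfaceMesh, atlas: RegionAtlas) -> SurfaceFiberField:
    """Solve Laplace per region and take the normalized in-plane gradient."""
    axes = np.zeros((surface.n_elements, 3))
    defined = np.zeros(surface.n_elements, dtype=bool)
    normals = surface.triangle_normals()
    for rid, (name, reg) in enumerate(atlas.regions.items()):
        tri_ids = _region_triangles(atlas, rid)
        if tri_ids.size == 0:
            continue
        if not reg.gamma0_lines or not reg.gamma1_lines:
            raise AtlasError(f"region {name!r} lacks gamma0/gamma1 line assignments")
        tris = surface.triangles[tri_ids]
        used = np.unique(tris)
        local = -np.ones(surface.n_vertices, dtype=np.int64)
        local[used] = np.arange(used.size)
        sub = SurfaceMesh(vertices=surface.vertices[used], triangles=local[tris])
        region_vset = set(used.tolist())

        def bc_vertices(line_names: list[str]) -> np.ndarray:
            vs: list[int] = []
            for ln in line_names:
                vs.extend(int(v) for v in atlas.lines[ln] if int(v) in region_vset)
            return local[np.unique(np.asarray(vs, dtype=np.int64))]

        d0 = bc_vertices(reg.gamma0_lines)
        d1 = bc_vertices(reg.gamma1_lines)
        if d0.size == 0 or d1.size == 0:
            raise AtlasError(
                f"region {name!r}: boundary lines contribute no vertices on the region"
            )
        d1 = np.setdiff1d(d1, d0)
        u = solve_laplace(sub, BoundaryConditionSpec(d0, d1))
        grad = element_gradient(sub, u)
        nrm = np.linalg.norm(grad, axis=1)
        ok = nrm > _DEGENERATE_GRAD
        ax = np.zeros_like(grad)
        ax[ok] = grad[ok] / nrm[ok, None]
        if reg.orthogonal:
            ax[ok] = np.cross(normals[tri_ids[ok]], ax[ok])
            ax[ok] /= np.linalg.norm(ax[ok], axis=1, keepdims=True)
        axes[tri_ids[ok]] = ax[ok]
        defined[tri_ids[ok]] = True
    return SurfaceFiberField(axes=axes, defined=defined)


def _sign_aligned_mean(vectors: np.ndarray) -> np.ndarray:
    """Mean of a set of axes after flipping each to the first one's hemisphere."""
    ref = vectors[0]
    signs = np.where(vectors @ ref < 0, -1.0, 1.0)
    m = (vectors * signs[:, None]).mean(axis=0)
    n = np.linalg.norm(m)
    return m / n if n > 0 else ref


def fill_undefined(
    field: SurfaceFiberField,
    adjacency: list[list[int]] | None = None,
    surface: SurfaceMesh | None = None,
) -> SurfaceFiberField:
    """Propagate axes into undefined triangles from defined neighbors.

    Deterministic: sweeps in ascending triangle index until full coverage.
    """
    if adjacency is None:
        if surface is None:
            raise ValueError("need adjacency or surface")
        adjacency = element_adjacency(surface)
    out = field.copy()
    pending = np.flatnonzero(~out.defined)
    while pending.size:
        progressed = False
        still = []
        for t in pending:
            nb = [n for n in adjacency[t] if out.defined[n]]
            if not nb:
                still.append(t)
                continue
            out.axes[t] = _sign_aligned_mean(out.axes[nb])
            out.defined[t] = True
            out.provenance[t] = PROV_FILLED
            progressed = True
        if not progressed:
            raise AtlasError(
                f"{len(still)} triangles unreachable from any defined axis"
            )
        pending = np.asarray(still, dtype=np.int64)
    return out


def _band_triangles(
    surface: SurfaceMesh,
    atlas: RegionAtlas,
    adjacency: list[list[int]],
    band_width: int,
) -> np.ndarray:
    """Triangles within ``band_width`` edge-hops of any auxiliary-line edge."""
    line_edges = set()
    for path in atlas.lines.values():
        p = np.asarray(path)
        for u, v in zip(p[:-1], p[1:]):
            line_edges.add((min(int(u), int(v)), max(int(u), int(v))))
    on_line = np.zeros(surface.n_elements, dtype=bool)
    for t, tri in enumerate(surface.triangles):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            u, v = int(tri[a]), int(tri[b])
            if (min(u, v), max(u, v)) in line_edges:
                on_line[t] = True
                break
    band = on_line.copy()
    frontier = set(np.flatnonzero(on_line).tolist())
    for _ in range(band_width - 1):
        nxt = set()
        for t in frontier:
            for n in adjacency[t]:
                if not band[n]:
                    band[n] = True
                    nxt.add(n)
        frontier = nxt
    return band


def smooth_interregional(
    field: SurfaceFiberField,
    surface: SurfaceMesh,
    atlas: RegionAtlas,
    band_width: int = 2,
    passes: int = 3,
) -> SurfaceFiberField:
    """Sign-aligned neighborhood averaging near auxiliary lines.

    Triangles outside the band are untouched. After averaging, axes are
    re-projected to their triangle plane and renormalized.
    """
    if not field.defined.all():
        raise AtlasError("smooth_interregional requires a fully defined field")
    adjacency = element_adjacency(surface)
    band = _band_triangles(surface, atlas, adjacency, band_width)
    normals = surface.triangle_normals()
    out = field.copy()
    band_ids = np.flatnonzero(band)
    for _ in range(passes):
        new_axes = out.axes.copy()
        for t in band_ids:
            vecs = np.vstack([out.axes[t]] + [out.axes[n] for n in adjacency[t]])
            m = _sign_aligned_mean(vecs)
            m = m - (m @ normals[t]) * normals[t]
            n = np.linalg.norm(m)
            new_axes[t] = m / n if n > _DEGENERATE_GRAD else out.axes[t]
        changed = np.any(np.abs(new_axes - out.axes) > 0, axis=1)
        out.axes = new_axes
        out.provenance[band & changed & (out.provenance == PROV_LAPLACE)] = PROV_SMOOTHED
    return out


def project_tangential(
    field: SurfaceFiberField, surface: SurfaceMesh, _depth: int = 0
) -> SurfaceFiberField:
    """Project every axis onto its triangle plane and renormalize.

    Axes (near-)parallel to the normal lose their in-plane meaning; they
    are marked undefined and refilled from neighbors.
    """
    normals = surface.triangle_normals()
    out = field.copy()
    proj = out.axes - np.einsum("ij,ij->i", out.axes, normals)[:, None] * normals
    nrm = np.linalg.norm(proj, axis=1)
    ok = nrm > _DEGENERATE_GRAD
    out.axes[ok] = proj[ok] / nrm[ok, None]
    degen = out.defined & ~ok
    if degen.any():
        if _depth > 3:
            raise AtlasError("projection degeneracy persists after neighbor fill")
        out.defined[degen] = False
        out.axes[degen] = 0.0
        out = fill_undefined(out, surface=surface)
        # refilled axes may again be off-plane: one more exact projection
        return project_tangential(out, surface, _depth + 1)
    return out


def rim_winding_number(
    surface: SurfaceMesh,
    field: SurfaceFiberField,
    ring_triangles: np.ndarray,
    center: np.ndarray,
    plane_normal: np.ndarray,
) -> tuple[float, float]:
    """Winding number of the axis line field along a closed triangle ring.

    Projects axes into the rim plane, orders triangles by position angle
    around ``center``, and accumulates angle increments wrapped to
    (-pi/2, pi/2] (axes are directionless). Returns ``(winding,
    max_step_deg)``; the estimate is reliable only when the largest single
    step stays clearly below 90 degrees, i.e. on meshes fine enough that
    the field varies slowly between angularly adjacent triangles.
    """
    n = np.asarray(plane_normal, dtype=float)
    n /= np.linalg.norm(n)
    e1 = np.cross(n, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    centers = surface.triangle_centers()[ring_triangles]
    rel = centers - np.asarray(center, dtype=float)
    order = np.argsort(np.arctan2(rel @ e2, rel @ e1))
    ring = np.asarray(ring_triangles)[order]
    a = np.arctan2(field.axes[ring] @ e2, field.axes[ring] @ e1)
    d = np.diff(np.concatenate([a, a[:1]]))
    d = (d + np.pi / 2) % np.pi - np.pi / 2
    return float(d.sum() / (2 * np.pi)), float(np.degrees(np.abs(d).max()))


def generate_surface_fibers(
    surface: SurfaceMesh,
    atlas: RegionAtlas,
    band_width: int = 2,
    passes: int = 3,
) -> SurfaceFiberField:
    """Full surface-fiber pipeline: solve, fill, smooth, project."""
    field = region_fibers(surface, atlas)
    field = fill_undefined(field, surface=surface)
    field = smooth_interregional(field, surface, atlas, band_width, passes)
    return project_tangential(field, surface)
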