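"""Endo-epi correspondence through the wall and per-tet fiber assignment.

The transmural coordinate is a Laplace field (0 on the endocardium, 1 on
the epicardium, zero-flux on open rims). From each tet barycenter the
normalized gradient field is traced downhill to an endocardial triangle
and uphill to an epicardial one; tracing hops element-to-element along the
piecewise-constant P1 gradient, which is exact for this discretization.
Fibers then blend the two surface axes with a transmural weight and are
projected orthogonal to the local field line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from atriofiber.laplace_fem import (
    BoundaryConditionSpec,
    element_basis_gradients,
    element_gradient,
    solve_laplace,
)
from atriofiber.mesh_io import SurfaceMesh, TetMesh
from atriofiber.mesh_io.topology import _TET_FACES

__all__ = [
    "TransmuralMap",
    "SCHEMES",
    "transmural_laplace",
    "build_correspondence",
    "interpolation_weight",
    "blend_fibers",
    "assign_volume_fibers",
]

SCHEMES = ("two_layer", "five_layer", "linear", "sigmoid")

FLAG_TRACED = 0
FLAG_NEAREST_FALLBACK = 1  # trajectory left through an open rim


@dataclass
class TransmuralMap:
    """Per-tet correspondence record."""

    phi: np.ndarray  # normalized transmural coordinate in [0, 1]
    endo_triangle: np.ndarray  # index into the endo surface triangle list
    epi_triangle: np.ndarray
    fieldline_dir: np.ndarray  # unit grad(u) per tet
    flags: np.ndarray  # FLAG_* provenance


def transmural_laplace(
    tet_mesh: TetMesh,
    endo_vertices: np.ndarray,
    epi_vertices: np.ndarray,
) -> np.ndarray:
    """u = 0 on the endocardium, 1 on the epicardium, zero-flux on rims."""
    return solve_laplace(tet_mesh, BoundaryConditionSpec(endo_vertices, epi_vertices))


def _face_lookup(surface: SurfaceMesh) -> dict[tuple, int]:
    return {tuple(sorted(tri)): i for i, tri in enumerate(surface.triangles)}


@njit(cache=True)
def _trace_all(vertices, tets, grads, neighbors, face_tri, downhill, max_hops):
    """Hop element-to-element along +/-grad from each barycenter.

    ``face_tri[t, f]`` is the surface-triangle id of boundary face f of tet
    t (-1 if not on the target surface). Returns hit triangle or -1 per tet.
    """
    n = tets.shape[0]
    out = -np.ones(n, dtype=np.int64)
    faces = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    for start in range(n):
        x = np.zeros(3)
        for k in range(4):
            for c in range(3):
                x[c] += vertices[tets[start, k], c]
        x /= 4.0
        tet = start
        for _ in range(max_hops):
            g = grads[tet]
            gn = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
            if gn < 1e-12:
                break
            s = -1.0 if downhill else 1.0
            d0, d1, d2 = s * g[0] / gn, s * g[1] / gn, s * g[2] / gn
            best_t = 1e300
            best_f = -1
            for fi in range(4):
                ia, ib, ic = (
                    tets[tet, faces[fi, 0]],
                    tets[tet, faces[fi, 1]],
                    tets[tet, faces[fi, 2]],
                )
                ax, ay, az = vertices[ia]
                e1x, e1y, e1z = vertices[ib, 0] - ax, vertices[ib, 1] - ay, vertices[ib, 2] - az
                e2x, e2y, e2z = vertices[ic, 0] - ax, vertices[ic, 1] - ay, vertices[ic, 2] - az
                nx = e1y * e2z - e1z * e2y
                ny = e1z * e2x - e1x * e2z
                nz = e1x * e2y - e1y * e2x
                dn = d0 * nx + d1 * ny + d2 * nz
                if dn <= 1e-14:
                    continue
                t = ((ax - x[0]) * nx + (ay - x[1]) * ny + (az - x[2]) * nz) / dn
                if -1e-9 < t < best_t:
                    best_t = t if t > 0.0 else 0.0
                    best_f = fi
            if best_f < 0:
                break
            x[0] += d0 * best_t
            x[1] += d1 * best_t
            x[2] += d2 * best_t
            nb = neighbors[tet, best_f]
            if nb < 0:  # boundary face
                out[start] = face_tri[tet, best_f]
                break
            tet = nb
    return out


def _face_neighbors(mesh: TetMesh) -> np.ndarray:
    """(n_tets, 4) neighbor tet per local face, -1 on the boundary."""
    owner: dict[tuple, tuple[int, int]] = {}
    nbr = -np.ones((mesh.n_elements, 4), dtype=np.int64)
    for ti, tet in enumerate(mesh.tets):
        for fi, loc in enumerate(_TET_FACES):
            key = tuple(sorted(tet[loc]))
            if key in owner:
                tj, fj = owner.pop(key)
                nbr[ti, fi] = tj
                nbr[tj, fj] = ti
            else:
                owner[key] = (ti, fi)
    return nbr


def build_correspondence(
    tet_mesh: TetMesh,
    u: np.ndarray,
    endo_surface: SurfaceMesh,
    epi_surface: SurfaceMesh,
    max_hops: int | None = None,
) -> TransmuralMap:
    """Trace field lines both ways from every tet barycenter.

    Trajectories exiting through an open rim (or stalling on a degenerate
    gradient) fall back to the nearest surface triangle and are flagged.
    """
    n = tet_mesh.n_elements
    grads = element_gradient(tet_mesh, u)
    nrm = np.linalg.norm(grads, axis=1)
    fieldline = np.zeros_like(grads)
    ok = nrm > 1e-12
    fieldline[ok] = grads[ok] / nrm[ok, None]
    phi = np.clip(u[tet_mesh.tets].mean(axis=1), 0.0, 1.0)

    neighbors = _face_neighbors(tet_mesh)
    hops = max_hops or max(64, 4 * int(np.ceil(n ** (1 / 3))) * 8)

    def face_tri_table(surface):
        lookup = _face_lookup(surface)
        table = -np.ones((n, 4), dtype=np.int64)
        for t in range(n):
            for fi, loc in enumerate(_TET_FACES):
                if neighbors[t, fi] < 0:
                    key = tuple(sorted(tet_mesh.tets[t][loc]))
                    table[t, fi] = lookup.get(key, -1)
        return table

    endo_tri = _trace_all(
        tet_mesh.vertices, tet_mesh.tets, grads, neighbors,
        face_tri_table(endo_surface), True, hops,
    )
    epi_tri = _trace_all(
        tet_mesh.vertices, tet_mesh.tets, grads, neighbors,
        face_tri_table(epi_surface), False, hops,
    )
    flags = np.zeros(n, dtype=np.int8)

    centers = tet_mesh.tet_centers()
    for surf, arr in ((endo_surface, endo_tri), (epi_surface, epi_tri)):
        missing = np.flatnonzero(arr < 0)
        if missing.size:
            tree = cKDTree(surf.triangle_centers())
            _, nearest = tree.query(centers[missing])
            arr[missing] = nearest
            flags[missing] = FLAG_NEAREST_FALLBACK
    return TransmuralMap(
        phi=phi,
        endo_triangle=endo_tri,
        epi_triangle=epi_tri,
        fieldline_dir=fieldline,
        flags=flags,
    )


def interpolation_weight(phi: np.ndarray | float, scheme: str) -> np.ndarray | float:
    """Transmural interpolation weight.

    ``two_layer``: step at 0.5; ``five_layer``: {0, .25, .5, .75, 1} on the
    intervals (0.2, 0.4, 0.6, 0.8); ``linear``: identity; ``sigmoid``:
    0.5*(1 + tanh(5*(phi - 0.5))) — the tanh form normalized to [0, 1] so it
    is a valid convex-combination weight.
    """
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0) or np.any(phi_arr > 1):
        raise ValueError("phi must lie in [0, 1]")
    if scheme == "two_layer":
        w = np.where(phi_arr <= 0.5, 0.0, 1.0)
    elif scheme == "five_layer":
        w = np.select(
            [phi_arr <= 0.2, phi_arr <= 0.4, phi_arr <= 0.6, phi_arr <= 0.8],
            [0.0, 0.25, 0.5, 0.75],
            default=1.0,
        )
    elif scheme == "linear":
        w = phi_arr.copy()
    elif scheme == "sigmoid":
        w = 0.5 * (1.0 + np.tanh(5.0 * (phi_arr - 0.5)))
    else:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    return float(w) if np.isscalar(phi) else w


def blend_fibers(f_ed: np.ndarray, f_ep: np.ndarray, w: np.ndarray | float) -> np.ndarray:
    """Normalized convex combination of endo/epi axes with sign alignment.

    f_ep is flipped into the f_ed hemisphere first (axes are directionless),
    which makes the combination nonzero for every w in [0, 1].
    """
    single = np.ndim(f_ed) == 1
    f_ed = np.atleast_2d(np.asarray(f_ed, dtype=float))
    f_ep = np.atleast_2d(np.asarray(f_ep, dtype=float))
    w_arr = np.broadcast_to(np.asarray(w, dtype=float), f_ed.shape[:1]).copy()
    dots = np.einsum("ij,ij->i", f_ed, f_ep)
    f_ep = np.where(dots[:, None] < 0, -f_ep, f_ep)
    out = (1 - w_arr)[:, None] * f_ed + w_arr[:, None] * f_ep
    nrm = np.linalg.norm(out, axis=1)
    # with sign alignment the norm vanishes only for exactly orthogonal
    # axes at the degenerate w; guard anyway
    tiny = nrm < 1e-12
    out[tiny] = f_ed[tiny]
    nrm[tiny] = 1.0
    out = out / nrm[:, None]
    return out[0] if single else out


def assign_volume_fibers(
    tet_mesh: TetMesh,
    corr: TransmuralMap,
    endo_fibers: np.ndarray,
    epi_fibers: np.ndarray,
    scheme: str = "linear",
) -> TetMesh:
    """Blend surface fibers transmurally and project off the field line."""
    w = interpolation_weight(corr.phi, scheme)
    f = blend_fibers(endo_fibers[corr.endo_triangle], epi_fibers[corr.epi_triangle], w)
    fl = corr.fieldline_dir
    proj = f - np.einsum("ij,ij->i", f, fl)[:, None] * fl
    nrm = np.linalg.norm(proj, axis=1)
    good = nrm > 1e-8
    proj[good] /= nrm[good, None]
    if not good.all():
        proj = _fill_degenerate(tet_mesh, proj, good, fl)
    return TetMesh(
        vertices=tet_mesh.vertices,
        tets=tet_mesh.tets,
        element_tags=tet_mesh.element_tags,
        fibers=proj,
    )


def _fill_degenerate(
    mesh: TetMesh, fibers: np.ndarray, good: np.ndarray, fieldline: np.ndarray
) -> np.ndarray:
    """Replace degenerate projections by sign-aligned neighbor averages."""
    neighbors = _face_neighbors(mesh)
    pending = np.flatnonzero(~good)
    good = good.copy()
    while pending.size:
        progressed = False
        still = []
        for t in pending:
            nb = [n for n in neighbors[t] if n >= 0 and good[n]]
            if not nb:
                still.append(t)
                continue
            ref = fibers[nb[0]]
            acc = np.zeros(3)
            for n in nb:
                v = fibers[n]
                acc += v if v @ ref >= 0 else -v
            fl = fieldline[t]
            acc = acc - (acc @ fl) * fl
            n = np.linalg.norm(acc)
            if n < 1e-12:
                still.append(t)
                continue
            fibers[t] = acc / n
            good[t] = True
            progressed = True
        if not progressed:
            raise RuntimeError("cannot fill degenerate volume fibers from neighbors")
        pending = np.asarray(still, dtype=np.int64)
    return fibers
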