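"""Topology queries: adjacency, boundary extraction, rim loops.

Boundary faces of a tet mesh are faces that belong to exactly one
tetrahedron.  They are grouped into connected components by breadth-first
search over shared edges, which separates the endo- and epicardial sides
of a shell as long as rim faces (lateral faces bridging the two sides at
open orifices) are excluded via ``exclude_faces``.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass

import numpy as np

from atriofiber.mesh_io.types import MeshValidationError, SurfaceMesh, TetMesh

__all__ = [
    "BoundaryComponent",
    "element_adjacency",
    "boundary_faces",
    "extract_boundary_surfaces",
    "trace_edge_loops",
    "enclosed_volume",
]

# Local faces of a positively oriented tet, wound to point outward.
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


class TopologyError(MeshValidationError):
    pass


@dataclass
class BoundaryComponent:
    """One connected boundary surface plus back-references to the volume mesh.

    ``parent_tets[i]`` is the tet owning triangle ``i``; ``parent_faces[i]``
    its local face index.  ``enclosed_volume`` uses the divergence theorem on
    the outward-wound faces, so the outermost component of a shell has the
    largest absolute value.
    """

    surface: SurfaceMesh
    parent_tets: np.ndarray
    parent_faces: np.ndarray
    enclosed_volume: float


def element_adjacency(mesh: SurfaceMesh | TetMesh) -> list[list[int]]:
    """Neighbor lists: face-adjacent for tets, edge-adjacent for triangles.

    Symmetric and irreflexive; each tet has <= 4 neighbors, triangle <= 3.
    """
    if isinstance(mesh, TetMesh):
        elems, simplex_faces = mesh.tets, _TET_FACES
    else:
        elems = mesh.triangles
        simplex_faces = np.array([[0, 1], [1, 2], [2, 0]])
    key_owner: dict[tuple, int] = {}
    neighbors: list[list[int]] = [[] for _ in range(len(elems))]
    for ei, elem in enumerate(elems):
        for loc in simplex_faces:
            key = tuple(sorted(elem[loc]))
            other = key_owner.get(key)
            if other is None:
                key_owner[key] = ei
            else:
                neighbors[ei].append(other)
                neighbors[other].append(ei)
    return [sorted(set(n)) for n in neighbors]


def boundary_faces(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All outward-wound boundary triangles of a tet mesh.

    Returns ``(faces, parent_tets, parent_local_faces)``.
    """
    count: dict[tuple, int] = defaultdict(int)
    wound: dict[tuple, tuple] = {}
    for ti, tet in enumerate(mesh.tets):
        for fi, loc in enumerate(_TET_FACES):
            tri = tet[loc]
            key = tuple(sorted(tri))
            count[key] += 1
            wound[key] = (tuple(tri), ti, fi)
    faces, parents, locals_ = [], [], []
    for key, c in count.items():
        if c == 1:
            tri, ti, fi = wound[key]
            faces.append(tri)
            parents.append(ti)
            locals_.append(fi)
        elif c > 2:
            raise TopologyError(f"face {key} shared by {c} tets (non-manifold)")
    return (
        np.asarray(faces, dtype=np.int64).reshape(-1, 3),
        np.asarray(parents, dtype=np.int64),
        np.asarray(locals_, dtype=np.int64),
    )


def _face_components(faces: np.ndarray) -> list[np.ndarray]:
    """BFS over shared edges; errors on edges shared by > 2 faces."""
    edge_faces: dict[tuple, list[int]] = defaultdict(list)
    for i, tri in enumerate(faces):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            edge_faces[tuple(sorted((tri[a], tri[b])))].append(i)
    for edge, owners in edge_faces.items():
        if len(owners) > 2:
            raise TopologyError(
                f"boundary edge {edge} shared by {len(owners)} faces (non-manifold)"
            )
    visited = np.full(len(faces), -1, dtype=np.int64)
    comps: list[np.ndarray] = []
    for seed in range(len(faces)):
        if visited[seed] >= 0:
            continue
        label = len(comps)
        queue = deque([seed])
        visited[seed] = label
        members = [seed]
        while queue:
            f = queue.popleft()
            tri = faces[f]
            for a, b in ((0, 1), (1, 2), (2, 0)):
                for g in edge_faces[tuple(sorted((tri[a], tri[b])))]:
                    if visited[g] < 0:
                        visited[g] = label
                        members.append(g)
                        queue.append(g)
        comps.append(np.asarray(sorted(members), dtype=np.int64))
    return comps


def extract_boundary_surfaces(
    mesh: TetMesh,
    exclude_faces: np.ndarray | None = None,
) -> list[BoundaryComponent]:
    """Split the boundary into connected components, largest |volume| first.

    ``exclude_faces`` is a boolean mask over the boundary-face array (in the
    order returned by :func:`boundary_faces`) removing e.g. tagged rim strips
    so that endo and epi separate at open orifices.
    """
    faces, parents, locals_ = boundary_faces(mesh)
    keep = np.ones(len(faces), dtype=bool)
    if exclude_faces is not None:
        keep &= ~np.asarray(exclude_faces, dtype=bool)
    idx = np.flatnonzero(keep)
    comps = _face_components(faces[idx])
    out = []
    for members in comps:
        sel = idx[members]
        tris = faces[sel]
        vol = _signed_volume_of_faces(mesh.vertices, tris)
        out.append(
            BoundaryComponent(
                surface=SurfaceMesh(vertices=mesh.vertices, triangles=tris),
                parent_tets=parents[sel],
                parent_faces=locals_[sel],
                enclosed_volume=vol,
            )
        )
    out.sort(key=lambda c: -abs(c.enclosed_volume))
    return out


def _signed_volume_of_faces(vertices: np.ndarray, tris: np.ndarray) -> float:
    v = vertices[tris]
    return float(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6)


def trace_edge_loops(triangles: np.ndarray) -> list[list[int]]:
    """Closed vertex loops of edges used by exactly one triangle."""
    edge_count: dict[tuple, int] = defaultdict(int)
    for tri in triangles:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            edge_count[tuple(sorted((tri[a], tri[b])))] += 1
    border = [e for e, c in edge_count.items() if c == 1]
    adj: dict[int, list[int]] = defaultdict(list)
    for a, b in border:
        adj[a].append(b)
        adj[b].append(a)
    unused = {tuple(sorted(e)) for e in border}
    loops = []
    while unused:
        a0, b0 = min(unused)
        unused.discard((a0, b0))
        loop = [a0, b0]
        prev, cur = a0, b0
        while cur != a0:
            nxt = [v for v in adj[cur] if tuple(sorted((cur, v))) in unused]
            if not nxt:
                break
            nx = min(nxt)
            unused.discard(tuple(sorted((cur, nx))))
            loop.append(nx)
            prev, cur = cur, nx
        if loop[-1] == loop[0]:
            loop.pop()
        loops.append(loop)
    return loops


def enclosed_volume(surface: SurfaceMesh) -> float:
    """Signed volume enclosed by a closed, consistently wound surface."""
    return _signed_volume_of_faces(surface.vertices, surface.triangles)
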