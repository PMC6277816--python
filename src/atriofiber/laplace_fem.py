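"""P1 finite-element Laplace solver on triangle and tetrahedral meshes.

Dirichlet conditions are imposed by system reduction; any boundary not
listed is a natural (zero-flux) boundary. Triangle meshes may be embedded
in 3-D: basis gradients are intrinsic to each triangle plane, so solutions
and gradients need no global parametrization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from atriofiber.mesh_io import SurfaceMesh, TetMesh

__all__ = [
    "BoundaryConditionSpec",
    "LaplaceError",
    "assemble_stiffness",
    "solve_laplace",
    "element_gradient",
    "element_basis_gradients",
]

_DEGENERATE_MEASURE = 1e-12
# above this many unknowns switch from direct factorization to CG
_DIRECT_SOLVE_LIMIT = 200_000


class LaplaceError(RuntimeError):
    pass


@dataclass
class BoundaryConditionSpec:
    """u=0 on ``dirichlet0``, u=1 on ``dirichlet1``, zero-flux elsewhere."""

    dirichlet0: np.ndarray
    dirichlet1: np.ndarray

    def __post_init__(self) -> None:
        self.dirichlet0 = np.unique(np.asarray(self.dirichlet0, dtype=np.int64))
        self.dirichlet1 = np.unique(np.asarray(self.dirichlet1, dtype=np.int64))
        if len(self.dirichlet0) == 0 or len(self.dirichlet1) == 0:
            raise LaplaceError("both Dirichlet sets must be nonempty")
        if np.intersect1d(self.dirichlet0, self.dirichlet1).size:
            raise LaplaceError("Dirichlet sets overlap")


def _elements(mesh: SurfaceMesh | TetMesh) -> np.ndarray:
    return mesh.triangles if isinstance(mesh, SurfaceMesh) else mesh.tets


def element_basis_gradients(mesh: SurfaceMesh | TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element P1 basis gradients and measures.

    Returns ``(grads, measure)`` with ``grads[e, i]`` the 3-D gradient of the
    hat function of local node i (constant on the element) and ``measure``
    the area/volume. Triangle gradients lie in the triangle plane.
    """
    elems = _elements(mesh)
    v = mesh.vertices[elems]  # (n, k, 3)
    n, k, _ = v.shape
    edges = v[:, 1:, :] - v[:, :1, :]  # (n, k-1, 3)
    if k == 4:
        measure = np.einsum(
            "ij,ij->i", edges[:, 0], np.cross(edges[:, 1], edges[:, 2])
        ) / 6.0
        bad = np.flatnonzero(np.abs(measure) < _DEGENERATE_MEASURE)
        if bad.size:
            raise LaplaceError(f"degenerate tetrahedra: {bad[:10].tolist()}")
        # barycentric coords: lam = inv(E)(x - v0) with E columns the edges,
        # so the gradient of node i (i=1..3) is row i-1 of inv(E)
        E = edges.transpose(0, 2, 1)  # (n, 3, 3), columns = edges
        G = np.linalg.inv(E)
        grads = np.empty((n, 4, 3))
        grads[:, 1:, :] = G
        grads[:, 0, :] = -G.sum(axis=1)
        return grads, np.abs(measure)
    # triangles (possibly embedded in 3-D)
    e1, e2 = edges[:, 0], edges[:, 1]
    normal = np.cross(e1, e2)
    area2 = np.linalg.norm(normal, axis=1)
    bad = np.flatnonzero(area2 / 2 < _DEGENERATE_MEASURE)
    if bad.size:
        raise LaplaceError(f"degenerate triangles: {bad[:10].tolist()}")
    nhat = normal / area2[:, None]
    # gradient of hat_i is the inward normal of the opposite edge / height
    grads = np.empty((n, 3, 3))
    for i in range(3):
        a = v[:, (i + 1) % 3]
        b = v[:, (i + 2) % 3]
        edge = b - a
        g = np.cross(nhat, edge)  # in-plane, perpendicular to opposite edge
        # scale so that grad . (v_i - a) == 1
        denom = np.einsum("ij,ij->i", g, v[:, i] - a)
        grads[:, i, :] = g / denom[:, None]
    return grads, area2 / 2


def assemble_stiffness(
    mesh: SurfaceMesh | TetMesh,
    tensors: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Galerkin stiffness ``K[i,j] = sum_e |e| g_i . D_e . g_j``.

    With ``tensors=None`` D is the identity (pure Laplace); symmetric with
    zero row sums either way.
    """
    elems = _elements(mesh)
    grads, measure = element_basis_gradients(mesh)
    n, k, _ = grads.shape
    if tensors is None:
        Dg = grads
    else:
        Dg = np.einsum("eab,eib->eia", tensors, grads)
    ke = np.einsum("eia,eja,e->eij", grads, Dg, measure)
    rows = np.repeat(elems, k, axis=1).reshape(n, k, k)
    cols = rows.transpose(0, 2, 1)
    K = sp.coo_matrix(
        (ke.ravel(), (rows.ravel(), cols.ravel())),
        shape=(mesh.n_vertices, mesh.n_vertices),
    ).tocsr()
    return K


def solve_laplace(
    mesh: SurfaceMesh | TetMesh,
    bc: BoundaryConditionSpec,
    stiffness: sp.csr_matrix | None = None,
) -> np.ndarray:
    """Discrete harmonic field with the given mixed boundary conditions."""
    K = stiffness if stiffness is not None else assemble_stiffness(mesh)
    nv = mesh.n_vertices
    fixed = np.zeros(nv, dtype=bool)
    fixed[bc.dirichlet0] = True
    fixed[bc.dirichlet1] = True
    uvals = np.zeros(nv)
    uvals[bc.dirichlet1] = 1.0
    free = np.flatnonzero(~fixed)
    if free.size == 0:
        return uvals
    Kff = K[free][:, free].tocsc()
    rhs = -K[free][:, np.flatnonzero(fixed)] @ uvals[fixed]
    if free.size <= _DIRECT_SOLVE_LIMIT:
        try:
            sol = spla.spsolve(Kff, rhs)
        except RuntimeError as exc:  # singular factorization
            raise LaplaceError(f"singular reduced system: {exc}") from exc
    else:
        M = spla.LinearOperator(
            Kff.shape, matvec=lambda x: x / Kff.diagonal()
        )
        sol, info = spla.cg(Kff, rhs, rtol=1e-12, atol=0.0, maxiter=10_000, M=M)
        if info != 0:
            raise LaplaceError(f"CG failed to converge (info={info})")
    if not np.all(np.isfinite(sol)):
        raise LaplaceError(
            "singular system: Dirichlet sets likely disconnected from part of the mesh"
        )
    res = np.linalg.norm(Kff @ sol - rhs)
    scale = np.linalg.norm(rhs)
    if scale > 0 and res / scale > 1e-8:
        raise LaplaceError(f"relative residual {res / scale:.2e} too large")
    uvals[free] = sol
    return uvals


def element_gradient(
    mesh: SurfaceMesh | TetMesh, values: np.ndarray
) -> np.ndarray:
    """Exact P1 gradient, constant per element (3-vector each)."""
    elems = _elements(mesh)
    grads, _ = element_basis_gradients(mesh)
    return np.einsum("eik,ei->ek", grads, np.asarray(values)[elems])
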