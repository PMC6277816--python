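"""Structured slab and ellipsoidal shell-atrium tetrahedral meshes.

Both generators split hexahedral cells into 6 positively oriented
tetrahedra (Kuhn subdivision), so element counts follow closed-form
formulas: ``6 * nx * ny * nz`` tets on ``(nx+1)(ny+1)(nz+1)`` vertices
for the slab.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from atriofiber.mesh_io.types import SurfaceMesh, TetMesh

__all__ = ["make_slab_mesh", "make_shell_atrium", "ShellAtriumSpec", "ShellAtrium"]

# Kuhn subdivision: each tet walks corner 000 -> 111 adding one axis at a
# time; one permutation of (x, y, z) per tet. Corner ids are bit codes
# b = x + 2y + 4z.
_KUHN_PERMS = [
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
]
_AXIS_BIT = (1, 2, 4)


def _kuhn_tets() -> np.ndarray:
    corner_xyz = np.array([[b & 1, (b >> 1) & 1, (b >> 2) & 1] for b in range(8)], float)
    tets = []
    for perm in _KUHN_PERMS:
        corners = [0]
        b = 0
        for ax in perm:
            b += _AXIS_BIT[ax]
            corners.append(b)
        v = corner_xyz[corners]
        vol = np.linalg.det(v[1:] - v[0])
        if vol < 0:  # enforce positive orientation on the reference cube
            corners[1], corners[2] = corners[2], corners[1]
        tets.append(corners)
    return np.asarray(tets)


_KUHN = _kuhn_tets()


def _hex_to_tets(corner_ids: np.ndarray) -> np.ndarray:
    """corner_ids: (n_cells, 8) global vertex ids in bit-code order."""
    return corner_ids[:, _KUHN].reshape(-1, 4)


def make_slab_mesh(
    extent: tuple[float, float, float],
    h: float,
    endo_tag: int = 1,
    epi_tag: int = 2,
) -> TetMesh:
    """Structured slab covering [0, extent] with cell size ~h.

    Vertices on z=0 are the "endo" side, z=extent[2] the "epi" side; use
    :func:`slab_face_vertices` to retrieve them.
    """
    nx, ny, nz = (max(2, int(round(e / h))) for e in extent)
    xs = np.linspace(0, extent[0], nx + 1)
    ys = np.linspace(0, extent[1], ny + 1)
    zs = np.linspace(0, extent[2], nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corners = np.stack(
        [vid(I + (b & 1), J + ((b >> 1) & 1), K + ((b >> 2) & 1)) for b in range(8)],
        axis=1,
    )
    tets = _hex_to_tets(corners)
    mesh = TetMesh(vertices=verts, tets=tets)
    mesh.validate_orientation()
    return mesh


def slab_face_vertices(mesh: TetMesh, axis: int = 2, tol: float = 1e-9):
    """(low-face, high-face) vertex index arrays of an axis-aligned slab."""
    coord = mesh.vertices[:, axis]
    lo, hi = coord.min(), coord.max()
    return (
        np.flatnonzero(np.abs(coord - lo) < tol),
        np.flatnonzero(np.abs(coord - hi) < tol),
    )


@dataclass
class ShellAtriumSpec:
    """Parametric ellipsoidal shell with open orifices.

    The shell spans colatitude [theta_top, theta_mv]; the north opening
    stands in for the LAA orifice and the south opening for the MV. Four
    PV holes are punched through the wall in the upper band. Wall
    thickness varies linearly in colatitude from ``thickness_top`` to
    ``thickness_bottom`` (exercises heterogeneous wall thickness).
    """

    radii: tuple[float, float, float] = (15.0, 13.0, 12.0)
    thickness_top: float = 1.0
    thickness_bottom: float = 3.0
    n_theta: int = 16
    n_phi: int = 32
    n_layers: int = 2
    theta_top: float = 0.35
    theta_mv: float = 2.60
    # index-space layout (rows of theta cells); None scales with n_theta
    laa_band_rows: int | None = None
    pv_band_rows: int | None = None
    body_band_rows: int | None = None
    pv_hole_phi_cells: int = 2

    def __post_init__(self) -> None:
        if self.n_theta < 12 or self.n_phi < 16 or self.n_phi % 4:
            raise ValueError("need n_theta >= 12 and n_phi >= 16 divisible by 4")
        if not (0 < self.theta_top < self.theta_mv < np.pi):
            raise ValueError("theta range must satisfy 0 < top < mv < pi")
        if min(self.thickness_top, self.thickness_bottom) <= 0:
            raise ValueError("wall thickness must be positive")


@dataclass
class ShellAtrium:
    """Generated shell with surfaces, ground-truth labels, and features."""

    volume: TetMesh
    endo: SurfaceMesh  # element_tags = ground-truth region labels
    epi: SurfaceMesh
    region_names: dict[int, str]
    rim_vertex_groups: dict[str, np.ndarray]  # opening name -> rim vertices
    vertex_layer: np.ndarray  # radial layer index per vertex (0=endo)
    landmarks: dict[str, int] = field(default_factory=dict)
    grid_vertex_ids: np.ndarray | None = None  # (n_theta+1, n_phi, n_layers+1)


def _shell_bands(spec: ShellAtriumSpec):
    nt = spec.n_theta
    laa = spec.laa_band_rows if spec.laa_band_rows is not None else max(1, nt * 2 // 16)
    # pv band >= 5 rows: the PV rectangle needs a row above and below its hole
    pv = spec.pv_band_rows if spec.pv_band_rows is not None else max(5, nt * 5 // 16)
    body = spec.body_band_rows if spec.body_band_rows is not None else max(2, nt * 5 // 16)
    a, b, c = laa, laa + pv, laa + pv + body
    if c >= nt:
        raise ValueError("band rows exceed n_theta")
    return a, b, c  # boundaries: laa|pv at a, pv|body at b, body|mv at c


def _pv_layout(spec: ShellAtriumSpec):
    """Per PV: (phi cell window of the rectangle, of the hole, theta rows)."""
    a, b, _ = _shell_bands(spec)
    q = spec.n_phi // 4
    rect_t0, rect_t1 = a + 1, b - 1          # rect rows (inside pv band)
    mid = (rect_t0 + rect_t1) // 2
    hole_rows = (mid, mid + 1)
    names = ["rspv", "ripv", "lipv", "lspv"]
    out = {}
    for i, name in enumerate(names):
        center = i * q + q // 2
        hw_rect = max(2, q // 2 - 2)
        rect = [(center + d) % spec.n_phi for d in range(-hw_rect, hw_rect)]
        hw_hole = spec.pv_hole_phi_cells // 2
        hole = [
            (center + d) % spec.n_phi
            for d in range(-hw_hole, spec.pv_hole_phi_cells - hw_hole)
        ]
        out[name] = dict(
            rect_phi=set(rect), hole_phi=set(hole),
            rect_rows=(rect_t0, rect_t1), hole_rows=hole_rows,
        )
    return out


def make_shell_atrium(spec: ShellAtriumSpec | None = None) -> ShellAtrium:
    """Build the shell-atrium phantom with constructive ground truth."""
    spec = spec or ShellAtriumSpec()
    nt, np_, nr = spec.n_theta, spec.n_phi, spec.n_layers
    thetas = np.linspace(spec.theta_top, spec.theta_mv, nt + 1)
    phis = np.arange(np_) * (2 * np.pi / np_)
    layers = np.linspace(0.0, 1.0, nr + 1)
    rx, ry, rz = spec.radii

    # vertex grid (it, ip, ir) -> id
    vid = np.arange((nt + 1) * np_ * (nr + 1)).reshape(nt + 1, np_, nr + 1)
    verts = np.empty(((nt + 1) * np_ * (nr + 1), 3))
    layer_of = np.empty(len(verts), dtype=np.int64)
    for it, th in enumerate(thetas):
        t_here = spec.thickness_top + (spec.thickness_bottom - spec.thickness_top) * (
            (th - spec.theta_top) / (spec.theta_mv - spec.theta_top)
        )
        base = np.column_stack(
            [
                rx * np.sin(th) * np.cos(phis),
                ry * np.sin(th) * np.sin(phis),
                np.full(np_, rz * np.cos(th)),
            ]
        )
        nrm = base / np.linalg.norm(base, axis=1, keepdims=True)
        for ir, lam in enumerate(layers):
            ids = vid[it, :, ir]
            verts[ids] = base + lam * t_here * nrm
            layer_of[ids] = ir

    pvs = _pv_layout(spec)

    def cell_removed(it: int, ip: int) -> bool:
        for pv in pvs.values():
            r0, r1 = pv["hole_rows"]
            if r0 <= it < r1 and ip in pv["hole_phi"]:
                return True
        return False

    corners = []
    cell_idx = []
    for it in range(nt):
        for ip in range(np_):
            if cell_removed(it, ip):
                continue
            ipn = (ip + 1) % np_
            for ir in range(nr):
                c = [
                    vid[it, ip, ir], vid[it + 1, ip, ir],
                    vid[it, ipn, ir], vid[it + 1, ipn, ir],
                    vid[it, ip, ir + 1], vid[it + 1, ip, ir + 1],
                    vid[it, ipn, ir + 1], vid[it + 1, ipn, ir + 1],
                ]
                corners.append(c)
                cell_idx.append((it, ip, ir))
    corners = np.asarray(corners)
    tets = _hex_to_tets(corners)
    # fix inverted tets caused by the curved geometry mapping
    mesh = TetMesh(vertices=verts, tets=tets)
    vol = mesh.signed_volumes()
    flip = vol < 0
    tets[flip, 0], tets[flip, 1] = tets[flip, 1].copy(), tets[flip, 0].copy()
    mesh = TetMesh(vertices=verts, tets=tets)
    mesh.validate_orientation()

    region_ids, region_names = _region_labeler(spec, pvs)
    endo = _surface_from_quads(spec, verts, vid, 0, region_ids, flip_out=True)
    epi = _surface_from_quads(spec, verts, vid, nr, region_ids, flip_out=False)

    rims = {
        "laa": vid[0, :, :].ravel(),
        "mv": vid[nt, :, :].ravel(),
    }
    for name, pv in pvs.items():
        r0, r1 = pv["hole_rows"]
        hole = sorted(pv["hole_phi"])
        ids = []
        for it in (r0, r1):
            for ip in hole:
                ids.append(vid[it, ip, :])
                ids.append(vid[it, (ip + 1) % np_, :])
        for it in range(r0, r1 + 1):
            for ip in hole:
                ids.append(vid[it, ip, :])
                ids.append(vid[it, (ip + 1) % np_, :])
        rims[name] = (
            np.unique(np.concatenate(ids)) if ids else np.empty(0, dtype=np.int64)
        )

    landmarks = _shell_landmarks(spec, vid, pvs)
    return ShellAtrium(
        volume=mesh,
        endo=endo,
        epi=epi,
        region_names=region_names,
        rim_vertex_groups={k: np.asarray(v) for k, v in rims.items()},
        vertex_layer=layer_of,
        landmarks=landmarks,
        grid_vertex_ids=vid,
    )


def _region_labeler(spec: ShellAtriumSpec, pvs):
    """Label function over (theta row, phi cell) plus id->name table."""
    a, b, c = _shell_bands(spec)
    q = spec.n_phi // 4
    names = {0: "laa_ring", 1: "pv_interstitial", 10: "mv_vestibule"}
    pv_ids = {}
    for i, name in enumerate(pvs):
        pv_ids[name] = 2 + i
        names[2 + i] = f"pv_{name}"
    body = ["body_anterior", "body_septal", "body_posterior", "body_lateral"]
    for i, nm in enumerate(body):
        names[6 + i] = nm

    def label(it: int, ip: int) -> int:
        if it < a:
            return 0
        if it < b:
            for name, pv in pvs.items():
                r0, r1 = pv["rect_rows"]
                if r0 <= it < r1 and ip in pv["rect_phi"]:
                    return pv_ids[name]
            return 1
        if it < c:
            return 6 + (ip // q)
        return 10

    return label, names


def _surface_from_quads(spec, verts, vid, ir, label, flip_out):
    """Triangulate one radial layer into a tagged SurfaceMesh.

    Quad diagonals match the Kuhn tet faces (diagonal from bit-code 00 to
    11 corner in (theta, phi)), so surface triangles coincide with
    boundary faces of the volume mesh.
    """
    nt, np_ = spec.n_theta, spec.n_phi
    pvs = _pv_layout(spec)
    tris, tags = [], []
    for it in range(nt):
        for ip in range(np_):
            hole = False
            for pv in pvs.values():
                r0, r1 = pv["hole_rows"]
                if r0 <= it < r1 and ip in pv["hole_phi"]:
                    hole = True
            if hole:
                continue
            ipn = (ip + 1) % np_
            v00, v10 = vid[it, ip, ir], vid[it + 1, ip, ir]
            v01, v11 = vid[it, ipn, ir], vid[it + 1, ipn, ir]
            # Kuhn faces on constant-z layer: split along v00-v11 diagonal
            t1, t2 = [v00, v10, v11], [v00, v11, v01]
            if flip_out:
                t1, t2 = t1[::-1], t2[::-1]
            tris += [t1, t2]
            tags += [label(it, ip)] * 2
    return SurfaceMesh(
        vertices=verts,
        triangles=np.asarray(tris),
        element_tags=np.asarray(tags),
    )


def _shell_landmarks(spec, vid, pvs) -> dict[str, int]:
    a, b, c = _shell_bands(spec)
    nt, np_, nr = spec.n_theta, spec.n_phi, spec.n_layers
    q = spec.n_phi // 4
    lm: dict[str, int] = {}
    for i, (name, pv) in enumerate(pvs.items()):
        if pv["hole_phi"]:
            ip0 = min(pv["hole_phi"])
            lm[f"{name}_rim"] = int(vid[pv["hole_rows"][0], ip0, nr])
    for i in range(4):
        lm[f"mv_{i}"] = int(vid[nt, i * q, nr])
        lm[f"laa_{i}"] = int(vid[0, i * q, nr])
        lm[f"body_top_{i}"] = int(vid[b, i * q, nr])
        lm[f"body_bottom_{i}"] = int(vid[c, i * q, nr])
    return lm
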