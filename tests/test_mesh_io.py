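import numpy as np
import pytest

from atriofiber.mesh_io import (
    CarpParseError,
    MeshValidationError,
    SurfaceMesh,
    TetMesh,
    TopologyError,
    boundary_faces,
    element_adjacency,
    extract_boundary_surfaces,
    read_carp,
    read_image,
    read_vtk,
    trace_edge_loops,
    write_carp,
    write_image,
    write_vtk,
)
from atriofiber.mesh_io.types import VoxelImage
from atriofiber.synthetic import make_slab_mesh


def single_tet():
    return TetMesh(
        vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        tets=[[0, 1, 2, 3]],
        element_tags=[7],
    )


class TestCarp:
    def test_roundtrip_identity(self, tmp_path):
        mesh = single_tet()
        base = str(tmp_path / "tet")
        write_carp(mesh, base)
        back = read_carp(base)
        assert isinstance(back, TetMesh)
        np.testing.assert_array_equal(back.vertices, mesh.vertices)
        np.testing.assert_array_equal(back.tets, mesh.tets)
        np.testing.assert_array_equal(back.element_tags, mesh.element_tags)
        assert back.fibers is None

    def test_lon_constant_axis(self, tmp_path):
        mesh = single_tet()
        mesh.fibers = np.array([[1.0, 0.0, 0.0]])
        base = str(tmp_path / "tet")
        write_carp(mesh, base)
        back = read_carp(base)
        np.testing.assert_allclose(back.fibers, [[1, 0, 0]])

    def test_no_lon_without_fibers(self, tmp_path):
        base = str(tmp_path / "tet")
        write_carp(single_tet(), base)
        assert not (tmp_path / "tet.lon").exists()

    def test_elem_tag_in_last_column(self, tmp_path):
        base = str(tmp_path / "tet")
        write_carp(single_tet(), base)
        line = (tmp_path / "tet.elem").read_text().splitlines()[1]
        assert line.split()[0] == "Tt"
        assert line.split()[-1] == "7"

    def test_slab_element_counts(self, tmp_path):
        # 5x5x2 cells at 6 tets per cell; vertices by brute-force uniqueness
        mesh = make_slab_mesh((5 * 0.4, 5 * 0.4, 2 * 0.4), 0.4)
        assert mesh.n_elements == 6 * 5 * 5 * 2 == 300
        assert len(np.unique(mesh.tets)) == 108
        assert mesh.n_vertices == 108
        base = str(tmp_path / "slab")
        write_carp(mesh, base)
        back = read_carp(base)
        np.testing.assert_array_equal(back.tets, mesh.tets)

    def test_malformed_header_names_line(self, tmp_path):
        (tmp_path / "bad.pts").write_text("not_a_number\n")
        (tmp_path / "bad.elem").write_text("0\n")
        with pytest.raises(CarpParseError, match=r"bad\.pts:1"):
            read_carp(str(tmp_path / "bad"))

    def test_unsupported_element_type(self, tmp_path):
        (tmp_path / "bad.pts").write_text("1\n0 0 0\n")
        (tmp_path / "bad.elem").write_text("1\nQd 0 0 0 0 1\n")
        with pytest.raises(CarpParseError, match="Qd"):
            read_carp(str(tmp_path / "bad"))

    def test_nonunit_fiber_refused(self, tmp_path):
        mesh = single_tet()
        mesh.fibers = np.array([[1.0, 0.0, 0.0]])
        mesh.fibers[0, 0] = 2.0  # corrupt after validation
        with pytest.raises(MeshValidationError):
            write_carp(mesh, str(tmp_path / "t"))

    def test_units_conversion(self, tmp_path):
        mesh = single_tet()
        base = str(tmp_path / "um")
        write_carp(mesh, base, units="um")
        raw = read_carp(base)  # read as mm: values were written in um
        np.testing.assert_allclose(raw.vertices, mesh.vertices * 1000)
        back = read_carp(base, units="um")
        np.testing.assert_allclose(back.vertices, mesh.vertices)


class TestDispatch:
    def test_read_write_mesh_by_extension(self, tmp_path):
        from atriofiber.mesh_io import read_mesh, write_mesh

        mesh = single_tet()
        write_mesh(mesh, str(tmp_path / "m.pts"))  # carp via extension
        back = read_mesh(str(tmp_path / "m.elem"))
        np.testing.assert_array_equal(back.tets, mesh.tets)
        write_mesh(mesh, str(tmp_path / "m.vtk"))
        back = read_mesh(str(tmp_path / "m.vtk"))
        np.testing.assert_array_equal(back.tets, mesh.tets)

    def test_unknown_format_rejected(self, tmp_path):
        from atriofiber.mesh_io import write_mesh

        with pytest.raises(ValueError, match="unknown mesh format"):
            write_mesh(single_tet(), str(tmp_path / "m.x"), format="obj")


class TestVtk:
    def test_roundtrip_with_fibers_and_tags(self, tmp_path):
        mesh = SurfaceMesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
            triangles=[[0, 1, 2], [1, 3, 2]],
            element_tags=[1, 2],
            fibers=[[1, 0, 0], [0, 1, 0]],
        )
        path = str(tmp_path / "s.vtk")
        write_vtk(mesh, path)
        back = read_vtk(path)
        np.testing.assert_allclose(back.vertices, mesh.vertices)
        np.testing.assert_array_equal(back.triangles, mesh.triangles)
        np.testing.assert_array_equal(back.element_tags, mesh.element_tags)
        np.testing.assert_allclose(back.fibers, mesh.fibers)

    def test_vector_array_one_triple_per_triangle(self, tmp_path):
        mesh = SurfaceMesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
            triangles=[[0, 1, 2]],
            fibers=[[0, 0, 1]],
        )
        path = str(tmp_path / "s.vtk")
        write_vtk(mesh, path)
        text = (tmp_path / "s.vtk").read_text()
        assert "VECTORS fiber double" in text
        vec_block = text.split("VECTORS fiber double\n")[1].strip().splitlines()
        assert len(vec_block) == mesh.n_elements


class TestImages:
    def test_mha_roundtrip(self, tmp_path):
        img = VoxelImage(
            data=np.arange(24, dtype=np.float32).reshape(2, 3, 4),
            spacing=[0.5, 1.0, 2.0],
            origin=[1, 2, 3],
        )
        path = str(tmp_path / "img.mha")
        write_image(img, path)
        back = read_image(path)
        np.testing.assert_allclose(back.data, img.data)
        np.testing.assert_allclose(back.spacing, img.spacing)
        np.testing.assert_allclose(back.origin, img.origin)

    def test_nifti_roundtrip(self, tmp_path):
        img = VoxelImage(
            data=np.random.default_rng(0).normal(size=(4, 5, 6)),
            spacing=[1, 1, 2.0],
        )
        path = str(tmp_path / "img.nii")
        write_image(img, path)
        back = read_image(path)
        np.testing.assert_allclose(back.data, img.data)
        np.testing.assert_allclose(back.spacing, img.spacing)


class TestAdjacency:
    def test_two_tets_sharing_face(self):
        mesh = TetMesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]],
            tets=[[0, 1, 2, 3], [1, 2, 3, 4]],
        )
        adj = element_adjacency(mesh)
        assert adj == [[1], [0]]

    def test_isolated_triangle(self):
        mesh = SurfaceMesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], triangles=[[0, 1, 2]]
        )
        assert element_adjacency(mesh) == [[]]

    def test_grid_interior_triangle_has_three_neighbors(self):
        n = 10
        xs, ys = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros((n + 1) ** 2)])
        tris = []
        for i in range(n):
            for j in range(n):
                a = i * (n + 1) + j
                b = a + 1
                c = a + n + 1
                d = c + 1
                tris += [[a, b, d], [a, d, c]]
        mesh = SurfaceMesh(vertices=verts, triangles=tris)
        adj = element_adjacency(mesh)
        # independent oracle: pairwise shared-edge scan
        tris = np.asarray(tris)
        for t in (2 * (4 * n + 4) + 1,):  # an interior triangle
            brute = [
                o
                for o in range(len(tris))
                if o != t and len(set(tris[t]) & set(tris[o])) == 2
            ]
            assert sorted(adj[t]) == sorted(brute)
            assert len(adj[t]) == 3

    def test_symmetric_irreflexive(self, shell):
        adj = element_adjacency(shell.endo)
        for t, nbs in enumerate(adj):
            assert t not in nbs
            for n in nbs:
                assert t in adj[n]
            assert len(nbs) <= 3


def cube_shell_mesh():
    """10^3-cell slab with a hollowed 4^3 interior: a thick closed shell."""
    mesh = make_slab_mesh((10, 10, 10), 1.0)
    centers = mesh.tet_centers()
    inside = np.all((centers > 3.0) & (centers < 7.0), axis=1)
    return TetMesh(vertices=mesh.vertices, tets=mesh.tets[~inside])


class TestBoundary:
    def test_solid_slab_single_component(self, small_slab):
        comps = extract_boundary_surfaces(small_slab)
        assert len(comps) == 1

    def test_thick_shell_two_components_outer_larger(self):
        comps = extract_boundary_surfaces(cube_shell_mesh())
        assert len(comps) == 2
        outer, inner = comps
        assert abs(outer.enclosed_volume) > abs(inner.enclosed_volume)
        assert abs(abs(outer.enclosed_volume) - 1000) < 1e-6

    def test_components_partition_boundary(self):
        mesh = cube_shell_mesh()
        faces, _, _ = boundary_faces(mesh)
        comps = extract_boundary_surfaces(mesh)
        total = sum(len(c.surface.triangles) for c in comps)
        assert total == len(faces)

    def test_shell_atrium_components_and_rims(self, shell):
        faces, _, _ = boundary_faces(shell.volume)
        lay = shell.vertex_layer[faces]
        rim_f = ~(np.all(lay == 0, axis=1) | np.all(lay == lay.max(), axis=1))
        comps = extract_boundary_surfaces(shell.volume, exclude_faces=rim_f)
        assert len(comps) == 2
        # brute-force edge-loop tracing on each surface: LAA + MV + 4 PVs
        assert len(trace_edge_loops(shell.endo.triangles)) == 6
        assert len(trace_edge_loops(shell.epi.triangles)) == 6

    def test_nonmanifold_face_raises(self):
        mesh = TetMesh(
            vertices=[
                [0, 0, 0], [1, 0, 0], [0, 1, 0],
                [0, 0, 1], [0.4, 0.4, -1], [1, 1, 1],
            ],
            tets=[[0, 1, 2, 3], [0, 2, 1, 4], [0, 1, 2, 5]],
        )
        with pytest.raises(TopologyError, match="non-manifold"):
            boundary_faces(mesh)


class TestValidation:
    def test_index_out_of_range(self):
        with pytest.raises(MeshValidationError):
            SurfaceMesh(vertices=[[0, 0, 0]], triangles=[[0, 1, 2]])

    def test_negative_volume_detected(self):
        mesh = TetMesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
            tets=[[1, 0, 2, 3]],
        )
        with pytest.raises(MeshValidationError, match="signed volume"):
            mesh.validate_orientation()

    def test_bad_spacing(self):
        with pytest.raises(MeshValidationError):
            VoxelImage(data=np.zeros((2, 2, 2)), spacing=[1, 0, 1])
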