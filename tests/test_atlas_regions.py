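import itertools

import numpy as np
import pytest

from atriofiber.atlas_regions import (
    AtlasError,
    LandmarkSet,
    RegionSpec,
    auxiliary_line,
    derive_landmarks,
    load_atlas,
    partition_regions,
    save_atlas,
    transfer_landmarks,
)
from atriofiber.mesh_io import SurfaceMesh


def grid_surface(nx, ny, h=1.0):
    xs, ys = np.meshgrid(np.arange(nx + 1) * h, np.arange(ny + 1) * h, indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(xs.size)])
    tris = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = a + ny + 1
            tris += [[a, b, b + 1], [a, b + 1, a + 1]]
    return SurfaceMesh(vertices=verts, triangles=tris)


def disk_surface(n_ring=24, n_r=4, radius=4.0):
    """Fan-triangulated disk; boundary rim is the outer circle."""
    verts = [[0.0, 0.0, 0.0]]
    for ir in range(1, n_r + 1):
        r = radius * ir / n_r
        for k in range(n_ring):
            a = 2 * np.pi * k / n_ring
            verts.append([r * np.cos(a), r * np.sin(a), 0.0])
    tris = []
    for k in range(n_ring):
        tris.append([0, 1 + k, 1 + (k + 1) % n_ring])
    for ir in range(1, n_r):
        base0 = 1 + (ir - 1) * n_ring
        base1 = 1 + ir * n_ring
        for k in range(n_ring):
            kn = (k + 1) % n_ring
            tris += [
                [base0 + k, base1 + k, base1 + kn],
                [base0 + k, base1 + kn, base0 + kn],
            ]
    return SurfaceMesh(vertices=verts, triangles=tris)


class TestTransfer:
    def test_identity_zero_error(self, shell):
        surf = shell.epi
        lms = {f"p{i}": surf.vertices[v] for i, v in enumerate([3, 50, 400])}
        out = transfer_landmarks(lms, surf, surf)
        assert out.mapping_error == 0.0
        assert out.vertex_ids == {"p0": 3, "p1": 50, "p2": 400}

    def test_tie_breaks_to_lowest_index(self):
        surf = grid_surface(1, 1)
        # point equidistant to vertices 0 and 3
        mid = 0.5 * (surf.vertices[0] + surf.vertices[3])
        out = transfer_landmarks({"m": mid}, surf, surf)
        assert out.vertex_ids["m"] == 0

    def test_shell_mini_atlas_brute_force(self, shell):
        surf = shell.epi
        lms = {name: surf.vertices[v] for name, v in shell.landmarks.items()}
        out = transfer_landmarks(lms, surf, surf)
        for name, vid in shell.landmarks.items():
            d = np.linalg.norm(surf.vertices - lms[name], axis=1)
            assert out.vertex_ids[name] == int(np.argmin(d)) == vid

    def test_topology_mismatch_rejected(self, shell):
        other = SurfaceMesh(
            vertices=shell.epi.vertices, triangles=shell.epi.triangles[:-1]
        )
        with pytest.raises(AtlasError, match="topology"):
            transfer_landmarks({"a": [0, 0, 0]}, shell.epi, other)

    def test_idempotent_and_deterministic(self, shell):
        surf = shell.endo
        lms = {"a": surf.vertices[10] + 0.01, "b": surf.vertices[99]}
        r1 = transfer_landmarks(lms, surf, surf)
        r2 = transfer_landmarks(lms, surf, surf)
        assert r1.vertex_ids == r2.vertex_ids
        # snapping again from the snapped coordinates is a fixed point
        snapped = {k: surf.vertices[v] for k, v in r1.vertex_ids.items()}
        r3 = transfer_landmarks(snapped, surf, surf)
        assert r3.vertex_ids == r1.vertex_ids


class TestDerive:
    def test_rim_subdivision_antipodal(self):
        surf = disk_surface(n_ring=24)
        rim0 = 1 + 3 * 24  # outer-ring start vertex (angle 0)
        lm = LandmarkSet(vertex_ids={"A": rim0, "B": rim0 + 12})
        out = derive_landmarks(
            lm, surf,
            [{"type": "rim_subdivide", "between": ["A", "B"], "n_arcs": 2,
              "names": ["E", "W"]}],
        )
        angles = {
            n: np.degrees(np.arctan2(*surf.vertices[v][1::-1]))
            for n, v in out.vertex_ids.items() if n in ("E", "W")
        }
        # +/-90 degrees within one vertex spacing (15 deg)
        assert min(abs(abs(a) - 90.0) for a in angles.values()) < 15.0
        vals = sorted(round(a) for a in angles.values())
        assert vals[0] == -vals[1]

    def test_midpoint_of_coincident_landmarks(self, shell):
        lm = LandmarkSet(vertex_ids={"a": 5, "b": 5})
        out = derive_landmarks(
            lm, shell.epi, [{"type": "midpoint", "of": ["a", "b"], "name": "m"}]
        )
        assert out.vertex_ids["m"] == 5

    def test_unique_names_enforced(self, shell):
        v = int(shell.epi.triangles[0, 0])
        lm = LandmarkSet(vertex_ids={"m": v, "a": v, "b": v})
        with pytest.raises(AtlasError, match="duplicate"):
            derive_landmarks(
                lm, shell.epi, [{"type": "midpoint", "of": ["a", "b"], "name": "m"}]
            )


class TestAuxiliaryLine:
    def test_straight_strip_near_optimal(self):
        surf = grid_surface(10, 2)
        a, b = 0, 10 * 3  # (0,0) to (10,0)
        path = auxiliary_line(surf, a, b)
        length = np.linalg.norm(np.diff(surf.vertices[path], axis=0), axis=1).sum()
        assert length <= 10.0 + 1.0 + 1e-9

    def test_single_vertex_when_endpoints_equal(self, shell):
        path = auxiliary_line(shell.epi, 17, 17)
        assert path.tolist() == [17]

    def test_corridor_detour_and_membership(self):
        surf = grid_surface(4, 4)
        # corridor omits every triangle touching the lower central column,
        # so its vertices are unusable and the path must detour upward
        blocked = (surf.vertices[:, 0] == 2.0) & (surf.vertices[:, 1] <= 3.0)
        keep = ~blocked[surf.triangles].any(axis=1)
        corridor = np.flatnonzero(keep)
        allowed = set(surf.triangles[corridor].ravel().tolist())
        a, b = 1 * 5 + 0, 3 * 5 + 0  # (1,0) -> (3,0) across the blocked column
        path = auxiliary_line(surf, a, b, corridor=corridor)
        assert all(int(v) in allowed for v in path)
        length = np.linalg.norm(np.diff(surf.vertices[path], axis=0), axis=1).sum()
        assert length > 2.0 + 1e-9  # forced detour

    def test_optimal_vs_bruteforce_enumeration(self):
        surf = grid_surface(3, 2)
        a, b = 0, surf.n_vertices - 1
        path = auxiliary_line(surf, a, b)
        dijkstra_len = np.linalg.norm(
            np.diff(surf.vertices[path], axis=0), axis=1
        ).sum()
        # exhaustive enumeration of simple paths on the small edge graph
        edges = {}
        for tri in surf.triangles:
            for i, j in ((0, 1), (1, 2), (2, 0)):
                u, v = int(tri[i]), int(tri[j])
                w = float(np.linalg.norm(surf.vertices[u] - surf.vertices[v]))
                edges.setdefault(u, {})[v] = w
                edges.setdefault(v, {})[u] = w
        best = [np.inf]

        def dfs(u, seen, acc):
            if acc >= best[0]:
                return
            if u == b:
                best[0] = acc
                return
            for v, w in edges[u].items():
                if v not in seen:
                    dfs(v, seen | {v}, acc + w)

        dfs(a, {a}, 0.0)
        assert dijkstra_len == pytest.approx(best[0])

    def test_no_path_raises(self):
        surf = grid_surface(4, 1)
        corridor = np.array([0, 1])  # a corner patch
        with pytest.raises(AtlasError):
            auxiliary_line(surf, 0, surf.n_vertices - 1, corridor=corridor)


class TestPartition:
    def test_slab_no_lines_single_region(self):
        surf = grid_surface(5, 5)
        atlas = partition_regions(surf, {}, {"all": 0})
        assert np.all(atlas.triangle_region == 0)

    def test_closed_line_two_regions_conserve_triangles(self, shell, shell_atlases):
        surf = shell.endo
        ring = shell_atlases["endo"].lines["ring_b"]
        atlas = partition_regions(
            surf, {"ring_b": ring}, {"upper": 0, "lower": surf.n_elements - 1}
        )
        counts = np.bincount(atlas.triangle_region)
        assert counts.sum() == surf.n_elements
        assert len(counts) == 2 and np.all(counts > 0)

    def test_leak_raises_with_line_name(self):
        surf = grid_surface(4, 4)
        # an unsealed partial line: fills collide around its end
        line = np.array([1 * 5 + 0, 1 * 5 + 1, 1 * 5 + 2])
        with pytest.raises(AtlasError, match="leak"):
            partition_regions(surf, {"stub": line}, {"left": 0, "right": 30})

    def test_shell_partition_matches_generator_labels(self, shell, shell_atlases):
        for which in ("endo", "epi"):
            surf = shell.endo if which == "endo" else shell.epi
            atlas = shell_atlases[which]
            names = list(atlas.regions)
            for t in range(surf.n_elements):
                assert (
                    names[atlas.triangle_region[t]]
                    == shell.region_names[int(surf.element_tags[t])]
                )

    def test_partition_complete(self, shell_atlases):
        for atlas in shell_atlases.values():
            assert np.all(atlas.triangle_region >= 0)


class TestAtlasIO:
    def test_json_roundtrip(self, tmp_path, shell_atlases):
        atlas = shell_atlases["epi"]
        path = str(tmp_path / "atlas.json")
        save_atlas(atlas, path)
        back = load_atlas(path)
        assert set(back.lines) == set(atlas.lines)
        assert set(back.regions) == set(atlas.regions)
        np.testing.assert_array_equal(back.triangle_region, atlas.triangle_region)
        for name in atlas.regions:
            assert back.regions[name].orthogonal == atlas.regions[name].orthogonal
            assert back.regions[name].gamma0_lines == atlas.regions[name].gamma0_lines

    def test_yaml_roundtrip(self, tmp_path, shell_atlases):
        atlas = shell_atlases["endo"]
        path = str(tmp_path / "atlas.yaml")
        save_atlas(atlas, path)
        back = load_atlas(path)
        assert set(back.lines) == set(atlas.lines)

    def test_unknown_line_reference_rejected(self):
        with pytest.raises(AtlasError, match="unknown line"):
            spec = RegionSpec("r", 0, gamma0_lines=["ghost"], gamma1_lines=[])
            from atriofiber.atlas_regions import RegionAtlas

            RegionAtlas(lines={}, regions={"r": spec}).validate()
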