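"""Landmarks, auxiliary lines, and region partitions on atrial surfaces.

A :class:`RegionAtlas` names a set of auxiliary lines (vertex paths on the
surface) and regions (triangle sets grown from seeds without crossing the
lines). Each region carries the boundary assignment for its Laplace solve:
lines in ``gamma0`` get u=0, lines in ``gamma1`` get u=1, everything else
is zero-flux. ``orthogonal`` rotates the resulting fiber axis by 90 degrees
in the triangle plane (used for encircling patterns around orifices).
"""

from __future__ import annotations

import heapq
import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from atriofiber.mesh_io import SurfaceMesh, element_adjacency, trace_edge_loops

__all__ = [
    "AtlasError",
    "LandmarkSet",
    "RegionSpec",
    "RegionAtlas",
    "transfer_landmarks",
    "derive_landmarks",
    "auxiliary_line",
    "partition_regions",
    "load_atlas",
    "save_atlas",
]


class AtlasError(ValueError):
    pass


@dataclass
class LandmarkSet:
    """Named landmarks snapped to surface vertices."""

    vertex_ids: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    mapping_error: float = 0.0

    def coords(self, surface: SurfaceMesh) -> dict[str, np.ndarray]:
        return {k: surface.vertices[v] for k, v in self.vertex_ids.items()}

    def merged_with(self, other: "LandmarkSet") -> "LandmarkSet":
        dup = set(self.vertex_ids) & set(other.vertex_ids)
        if dup:
            raise AtlasError(f"duplicate landmark names: {sorted(dup)}")
        return LandmarkSet(
            vertex_ids={**self.vertex_ids, **other.vertex_ids},
            provenance={**self.provenance, **other.provenance},
            mapping_error=self.mapping_error,
        )


@dataclass
class RegionSpec:
    name: str
    seed_triangle: int
    gamma0_lines: list[str] = field(default_factory=list)  # u = 0
    gamma1_lines: list[str] = field(default_factory=list)  # u = 1
    orthogonal: bool = False


@dataclass
class RegionAtlas:
    lines: dict[str, np.ndarray] = field(default_factory=dict)
    regions: dict[str, RegionSpec] = field(default_factory=dict)
    # per-triangle region id in the order of RegionAtlas.region_ids(); -1 unset
    triangle_region: np.ndarray | None = None

    def region_ids(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.regions)}

    def validate(self) -> None:
        for name, path in self.lines.items():
            if len(path) < 1:
                raise AtlasError(f"line {name!r} is empty")
        for name, reg in self.regions.items():
            for ln in reg.gamma0_lines + reg.gamma1_lines:
                if ln not in self.lines:
                    raise AtlasError(f"region {name!r} references unknown line {ln!r}")
            both = set(reg.gamma0_lines) & set(reg.gamma1_lines)
            if both:
                raise AtlasError(f"region {name!r}: lines {both} in both gammas")


def _nearest_vertices(points: np.ndarray, vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive nearest-vertex search; ties break to the lowest index."""
    ids = np.empty(len(points), dtype=np.int64)
    dists = np.empty(len(points))
    for i, p in enumerate(points):
        d2 = np.einsum("ij,ij->i", vertices - p, vertices - p)
        ids[i] = int(np.argmin(d2))  # argmin returns first (lowest) index on ties
        dists[i] = np.sqrt(d2[ids[i]])
    return ids, dists


def transfer_landmarks(
    atlas_landmarks: dict[str, np.ndarray],
    registered_surface: SurfaceMesh,
    target_surface: SurfaceMesh,
) -> LandmarkSet:
    """Nearest-neighbor transfer via a topology-preserving registration.

    Each landmark maps to the nearest vertex of the registered surface; the
    same vertex index is then read on the target surface (registration is
    assumed to preserve vertex numbering). ``mapping_error`` reports the
    mean landmark-to-nearest-vertex distance.
    """
    if registered_surface.n_vertices != target_surface.n_vertices or not np.array_equal(
        registered_surface.triangles, target_surface.triangles
    ):
        raise AtlasError("registered and target surfaces must share topology")
    names = list(atlas_landmarks)
    pts = np.asarray([atlas_landmarks[n] for n in names], dtype=float)
    ids, dists = _nearest_vertices(pts, registered_surface.vertices)
    return LandmarkSet(
        vertex_ids={n: int(v) for n, v in zip(names, ids)},
        provenance={n: "transferred" for n in names},
        mapping_error=float(dists.mean()) if len(dists) else 0.0,
    )


def _loop_containing(surface: SurfaceMesh, a: int, b: int) -> list[int]:
    for loop in trace_edge_loops(surface.triangles):
        if a in loop and b in loop:
            return loop
    raise AtlasError(f"no boundary rim loop contains landmarks {a} and {b}")


def derive_landmarks(
    landmarks: LandmarkSet,
    surface: SurfaceMesh,
    rules: list[dict],
) -> LandmarkSet:
    """Compute additional landmarks from transferred ones.

    Supported rules::

        {"type": "rim_subdivide", "between": [A, B], "n_arcs": k,
         "names": [... 2*(k-1) names, side-1 then side-2 ...]}
        {"type": "midpoint", "of": [A, B], "name": N}
    """
    out = LandmarkSet()
    for rule in rules:
        kind = rule["type"]
        if kind == "rim_subdivide":
            a = landmarks.vertex_ids[rule["between"][0]]
            b = landmarks.vertex_ids[rule["between"][1]]
            loop = _loop_containing(surface, a, b)
            ia, ib = loop.index(a), loop.index(b)
            arc1 = loop[ia : ib + 1] if ia <= ib else loop[ia:] + loop[: ib + 1]
            arc2 = loop[ib:] + loop[: ia + 1] if ia <= ib else loop[ib : ia + 1]
            k = int(rule["n_arcs"])
            names = iter(rule["names"])
            for arc in (arc1, arc2):
                for v in _equal_arc_points(surface.vertices, arc, k):
                    name = next(names)
                    out.vertex_ids[name] = int(v)
                    out.provenance[name] = "derived"
        elif kind == "midpoint":
            a = landmarks.vertex_ids[rule["of"][0]]
            b = landmarks.vertex_ids[rule["of"][1]]
            if a == b:
                v = a
            else:
                path = _dijkstra_path(surface, a, b, None)
                lens = np.linalg.norm(
                    np.diff(surface.vertices[path], axis=0), axis=1
                )
                cum = np.concatenate([[0.0], np.cumsum(lens)])
                v = path[int(np.argmin(np.abs(cum - cum[-1] / 2)))]
            out.vertex_ids[rule["name"]] = int(v)
            out.provenance[rule["name"]] = "derived"
        else:
            raise AtlasError(f"unknown landmark rule {kind!r}")
    return landmarks.merged_with(out)


def _equal_arc_points(vertices: np.ndarray, arc: list[int], n_arcs: int) -> list[int]:
    """Vertices splitting an open arc into n_arcs pieces of equal length."""
    lens = np.linalg.norm(np.diff(vertices[arc], axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    total = cum[-1]
    pts = []
    for k in range(1, n_arcs):
        target = total * k / n_arcs
        pts.append(arc[int(np.argmin(np.abs(cum - target)))])
    return pts


def _surface_edges(surface: SurfaceMesh) -> dict[int, list[tuple[int, float]]]:
    adj: dict[int, list[tuple[int, float]]] = {}
    seen = set()
    for tri in surface.triangles:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            u, v = int(tri[a]), int(tri[b])
            key = (u, v) if u < v else (v, u)
            if key in seen:
                continue
            seen.add(key)
            w = float(np.linalg.norm(surface.vertices[u] - surface.vertices[v]))
            adj.setdefault(u, []).append((v, w))
            adj.setdefault(v, []).append((u, w))
    return adj


def _dijkstra_path(
    surface: SurfaceMesh,
    a: int,
    b: int,
    allowed: set[int] | None,
) -> list[int]:
    adj = _surface_edges(surface)
    dist: dict[int, float] = {a: 0.0}
    pred: dict[int, int] = {a: -1}
    heap: list[tuple[float, int]] = [(0.0, a)]
    done: set[int] = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == b:
            break
        for v, w in adj.get(u, []):
            if allowed is not None and v not in allowed:
                continue
            nd = d + w
            old = dist.get(v)
            # deterministic tie-break: lexicographically smallest predecessor
            if old is None or nd < old - 1e-12 or (abs(nd - old) <= 1e-12 and u < pred[v]):
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    if b not in pred:
        raise AtlasError(f"no path from {a} to {b} within corridor")
    path = [b]
    while path[-1] != a:
        path.append(pred[path[-1]])
    return path[::-1]


def auxiliary_line(
    surface: SurfaceMesh,
    a: int,
    b: int,
    corridor: np.ndarray | None = None,
) -> np.ndarray:
    """Shortest edge path from a to b restricted to a corridor triangle set."""
    allowed = None
    if corridor is not None:
        allowed = set(int(v) for v in surface.triangles[np.asarray(corridor)].ravel())
        if a not in allowed or b not in allowed:
            raise AtlasError("endpoints must lie inside the corridor")
    if a == b:
        return np.asarray([a], dtype=np.int64)
    return np.asarray(_dijkstra_path(surface, a, b, allowed), dtype=np.int64)


def _barrier_edges(lines: dict[str, np.ndarray]) -> dict[tuple[int, int], str]:
    barrier: dict[tuple[int, int], str] = {}
    for name, path in lines.items():
        p = np.asarray(path)
        for u, v in zip(p[:-1], p[1:]):
            key = (int(u), int(v)) if u < v else (int(v), int(u))
            barrier[key] = name
    return barrier


def partition_regions(
    surface: SurfaceMesh,
    lines: dict[str, np.ndarray],
    seeds: dict[str, int],
    region_specs: dict[str, RegionSpec] | None = None,
) -> RegionAtlas:
    """Flood-fill triangles from seeds without crossing auxiliary-line edges."""
    barrier = _barrier_edges(lines)
    adjacency = element_adjacency(surface)
    # shared edge between adjacent triangles
    labels = np.full(surface.n_elements, -1, dtype=np.int64)
    names = list(seeds)
    for rid, name in enumerate(names):
        seed = seeds[name]
        if labels[seed] >= 0:
            raise AtlasError(
                f"regions {name!r} and {names[labels[seed]]!r} leak into each "
                f"other: seed triangle {seed} already flooded"
            )
        labels[seed] = rid
        queue = deque([seed])
        while queue:
            t = queue.popleft()
            tri_t = set(surface.triangles[t].tolist())
            for nb in adjacency[t]:
                shared = tuple(sorted(tri_t & set(surface.triangles[nb].tolist())))
                if len(shared) == 2 and shared in barrier:
                    continue
                if labels[nb] == rid:
                    continue
                if labels[nb] >= 0:
                    edge_name = barrier.get(shared, "<none>")
                    raise AtlasError(
                        f"regions {name!r} and {names[labels[nb]]!r} leak into each "
                        f"other (unsealed near line {edge_name!r})"
                    )
                labels[nb] = rid
                queue.append(nb)
    if np.any(labels < 0):
        n_bad = int((labels < 0).sum())
        raise AtlasError(f"{n_bad} triangles not reached by any seed")
    regions = {}
    for rid, name in enumerate(names):
        spec = (region_specs or {}).get(name)
        regions[name] = RegionSpec(
            name=name,
            seed_triangle=int(seeds[name]),
            gamma0_lines=spec.gamma0_lines if spec else [],
            gamma1_lines=spec.gamma1_lines if spec else [],
            orthogonal=spec.orthogonal if spec else False,
        )
    atlas = RegionAtlas(lines=dict(lines), regions=regions, triangle_region=labels)
    atlas.validate()
    return atlas


def save_atlas(atlas: RegionAtlas, path: str) -> None:
    doc = {
        "lines": {k: np.asarray(v).tolist() for k, v in atlas.lines.items()},
        "regions": {
            k: {
                "seed": r.seed_triangle,
                "gamma0": r.gamma0_lines,
                "gamma1": r.gamma1_lines,
                "orthogonal": r.orthogonal,
            }
            for k, r in atlas.regions.items()
        },
    }
    if atlas.triangle_region is not None:
        doc["triangle_region"] = atlas.triangle_region.tolist()
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)
    else:
        with open(path, "w") as fh:
            json.dump(doc, fh)


def load_atlas(path: str) -> RegionAtlas:
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            doc = json.load(fh)
    lines = {k: np.asarray(v, dtype=np.int64) for k, v in doc["lines"].items()}
    regions = {
        k: RegionSpec(
            name=k,
            seed_triangle=int(r["seed"]),
            gamma0_lines=list(r.get("gamma0", [])),
            gamma1_lines=list(r.get("gamma1", [])),
            orthogonal=bool(r.get("orthogonal", False)),
        )
        for k, r in doc["regions"].items()
    }
    tr = doc.get("triangle_region")
    atlas = RegionAtlas(
        lines=lines,
        regions=regions,
        triangle_region=None if tr is None else np.asarray(tr, dtype=np.int64),
    )
    atlas.validate()
    return atlas
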