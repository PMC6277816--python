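"""Simplified region atlas for the shell-atrium phantom.

Builds, per surface (endo/epi), the auxiliary-line network and the
11-region partition matching the generator's constructive labels:
an LAA ring, four PV rectangles with punched holes, the interstitial PV
band, four body quadrants and the MV vestibule. Orifice-ring regions use
the ``orthogonal`` flag so their fiber axes encircle the openings.
"""

from __future__ import annotations

import numpy as np

from atriofiber.atlas_regions import LandmarkSet, RegionAtlas, RegionSpec, partition_regions
from atriofiber.synthetic.meshes import ShellAtrium, ShellAtriumSpec, _pv_layout, _shell_bands

__all__ = ["build_shell_atlas", "shell_landmark_set"]


def _ring_path(vid: np.ndarray, it: int, ir: int) -> np.ndarray:
    n_phi = vid.shape[1]
    path = [vid[it, ip, ir] for ip in range(n_phi)]
    path.append(path[0])  # closed loop
    return np.asarray(path, dtype=np.int64)


def _meridian_path(vid: np.ndarray, ip: int, it0: int, it1: int, ir: int) -> np.ndarray:
    return np.asarray([vid[it, ip, ir] for it in range(it0, it1 + 1)], dtype=np.int64)


def _rect_path(vid, rows, phis, ir) -> np.ndarray:
    """Closed rectangle it in [rows], phi cells `phis` (contiguous mod n_phi)."""
    n_phi = vid.shape[1]
    phis = sorted(phis)
    # detect wrap-around windows and order columns contiguously
    cols = _contiguous_columns(phis, n_phi)
    cols_closed = cols + [(cols[-1] + 1) % n_phi]
    r0, r1 = rows
    path = [vid[r0, ip, ir] for ip in cols_closed]
    path += [vid[it, cols_closed[-1], ir] for it in range(r0 + 1, r1 + 1)]
    path += [vid[r1, ip, ir] for ip in cols_closed[-2::-1]]
    path += [vid[it, cols_closed[0], ir] for it in range(r1 - 1, r0 - 1, -1)]
    return np.asarray(path, dtype=np.int64)


def _contiguous_columns(phis: list[int], n_phi: int) -> list[int]:
    s = set(phis)
    if 0 in s and (n_phi - 1) in s and len(s) < n_phi:
        start = max(ip for ip in range(n_phi) if ip not in s) + 1
    else:
        start = min(s)
    cols = []
    ip = start % n_phi
    for _ in range(len(s)):
        cols.append(ip)
        ip = (ip + 1) % n_phi
    return cols


def build_shell_atlas(
    shell: ShellAtrium, spec: ShellAtriumSpec, which: str = "epi"
) -> RegionAtlas:
    """Auxiliary lines + region specs for one surface; partition verified
    against the generator's constructive triangle labels by the caller."""
    vid = shell.grid_vertex_ids
    assert vid is not None
    ir = 0 if which == "endo" else spec.n_layers
    surface = shell.endo if which == "endo" else shell.epi
    a, b, c = _shell_bands(spec)
    q = spec.n_phi // 4
    pvs = _pv_layout(spec)

    lines: dict[str, np.ndarray] = {
        "laa_rim": _ring_path(vid, 0, ir),
        "mv_rim": _ring_path(vid, spec.n_theta, ir),
        "ring_a": _ring_path(vid, a, ir),
        "ring_b": _ring_path(vid, b, ir),
        "ring_c": _ring_path(vid, c, ir),
    }
    for i in range(4):
        lines[f"meridian_{i}"] = _meridian_path(vid, i * q, b, c, ir)
    for name, pv in pvs.items():
        lines[f"{name}_rect"] = _rect_path(vid, pv["rect_rows"], pv["rect_phi"], ir)
        r0, r1 = pv["hole_rows"]
        lines[f"{name}_rim"] = _rect_path(vid, (r0, r1), pv["hole_phi"], ir)

    specs = {
        "laa_ring": RegionSpec("laa_ring", 0, ["laa_rim"], ["ring_a"], orthogonal=True),
        "pv_interstitial": RegionSpec("pv_interstitial", 0, ["ring_a"], ["ring_b"]),
        "mv_vestibule": RegionSpec("mv_vestibule", 0, ["mv_rim"], ["ring_c"], orthogonal=True),
    }
    for name in pvs:
        specs[f"pv_{name}"] = RegionSpec(
            f"pv_{name}", 0, [f"{name}_rim"], [f"{name}_rect"], orthogonal=True
        )
    for nm in ("body_anterior", "body_septal", "body_posterior", "body_lateral"):
        specs[nm] = RegionSpec(nm, 0, ["ring_b"], ["ring_c"])

    # seeds from constructive ground-truth labels
    name_of = shell.region_names
    seeds: dict[str, int] = {}
    for tid, lab in enumerate(surface.element_tags):
        nm = name_of[int(lab)]
        if nm not in seeds:
            seeds[nm] = tid
    missing = set(specs) - set(seeds)
    if missing:
        raise ValueError(f"regions without any triangle: {sorted(missing)}")

    # rim lines run along the surface boundary, so they are inert as barriers
    return partition_regions(surface, lines, seeds, specs)


def shell_landmark_set(shell: ShellAtrium) -> LandmarkSet:
    return LandmarkSet(
        vertex_ids=dict(shell.landmarks),
        provenance={k: "manual" for k in shell.landmarks},
    )
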