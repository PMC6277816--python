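"""End-to-end benchmark measurements used by the acceptance suite.

Each function recomputes its quantity from scratch by running the package
pipeline pieces, so results reflect the code as shipped rather than cached
numbers.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from atriofiber.ep import (
    MonodomainModel,
    fit_conductivity,
    make_cable,
    measure_cv,
    pace_to_steady_state,
    simulate_monodomain,
)
from atriofiber.segmentation import (
    build_wall,
    compute_thresholds,
    smooth_and_resample,
    _signed_distance,
)
from atriofiber.synthetic import VoxelPhantomSpec, make_voxel_phantom

__all__ = [
    "cv_fit_and_remeasure",
    "wall_thickness_cap",
    "smoothing_displacement_pct",
    "resampled_spacing_um",
    "sheet_isochrone_ratio",
]


def cv_fit_and_remeasure(
    target_cv_l: float = 1.2,
    target_cv_t: float = 0.4,
    resolution: float = 0.2,
    dt: float = 0.01,
    n_beats: int = 50,
    bcl: float = 1000.0,
    length: float = 20.0,
) -> dict:
    """Fit conductivities on a 1-D cable, then re-measure both CVs in fresh
    planar-wave simulations between the 25%/75% cable positions."""
    state, pacing_delta = pace_to_steady_state(n_beats, bcl=bcl, dt=dt)
    sigma_l, sigma_t, report = fit_conductivity(
        target_cv_l, target_cv_t, resolution=resolution, dt=dt,
        state=state, length=length,
    )
    verts, elems = make_cable(length, resolution)
    fibers = np.tile([1.0, 0.0, 0.0], (len(elems), 1))
    stim = np.flatnonzero(verts[:, 0] <= max(resolution, 0.5))
    out = {}
    for name, sigma in (("l", sigma_l), ("t", sigma_t)):
        model = MonodomainModel(sigma_l=sigma, sigma_t=sigma, dt=dt)
        res = simulate_monodomain(
            verts, elems, fibers, model,
            t_end=model.stim_duration + length / 0.1,
            initial_state=state, stim_vertices=stim,
        )
        out[name] = measure_cv(res.lat, verts, [1.0, 0.0, 0.0])
    return {
        "cv_l": out["l"],
        "cv_t": out["t"],
        "ratio": out["l"] / out["t"],
        "sigma_l": sigma_l,
        "sigma_t": sigma_t,
        "n_nodes": len(verts),
        "pacing_delta": pacing_delta,
        "state": state,
        "fit_report": report,
    }


def wall_thickness_cap(seed: int = 0, max_thickness: float = 3.0) -> dict:
    """Max Euclidean distance (mm) from tagged wall voxels to the blood-pool
    boundary on a phantom whose intensity wall band is 5 mm thick."""
    spec = VoxelPhantomSpec(wall_thickness=5.0, spacing=0.4, seed=seed)
    ph = make_voxel_phantom(spec)
    _, thr = compute_thresholds(ph.image, ph.wall_samples, ph.cavity_samples)
    seg = build_wall(ph.image, thr, ph.seed_point, max_thickness=max_thickness)
    dist = ndimage.distance_transform_edt(~seg.blood_mask, sampling=seg.spacing)
    return {
        "max_distance_mm": float(dist[seg.wall_mask].max()),
        "n_wall_voxels": int(seg.wall_mask.sum()),
    }


def _staircase_sphere_segmentation(seed: int = 0):
    spec = VoxelPhantomSpec(
        cavity_radius=8.0, wall_thickness=4.0, spacing=2.0,
        sd_wall=5.0, sd_cavity=5.0, sd_background=5.0, seed=seed,
    )
    ph = make_voxel_phantom(spec)
    _, thr = compute_thresholds(ph.image, ph.wall_samples, ph.cavity_samples)
    return build_wall(ph.image, thr, ph.seed_point, max_thickness=4.0)


def smoothing_displacement_pct(seed: int = 0) -> dict:
    """Max vertex displacement of the smoothed isosurface as % of voxel size
    on a staircase sphere voxelized at 2 mm."""
    seg = _staircase_sphere_segmentation(seed)
    _, surf = smooth_and_resample(seg, target_spacing=1.0)
    sdf0 = _signed_distance(seg.wall_mask, seg.spacing)
    idx = ((surf.vertices - seg.origin) / seg.spacing).T
    disp = np.abs(ndimage.map_coordinates(sdf0, idx, order=1))
    voxel = float(np.min(seg.spacing))
    return {
        "max_displacement_pct": float(disp.max() / voxel * 100.0),
        "n_vertices": surf.n_vertices,
    }


def resampled_spacing_um(seed: int = 0, target_spacing_mm: float = 0.1) -> dict:
    """Spacing metadata (um) of the smoothed + resampled segmentation."""
    spec = VoxelPhantomSpec(
        cavity_radius=2.0, wall_thickness=1.0, spacing=0.4, margin=1.2, seed=seed
    )
    ph = make_voxel_phantom(spec)
    _, thr = compute_thresholds(ph.image, ph.wall_samples, ph.cavity_samples)
    seg = build_wall(ph.image, thr, ph.seed_point)
    out, _ = smooth_and_resample(seg, target_spacing=target_spacing_mm)
    spac = np.asarray(out.spacing) * 1000.0
    assert spac.min() == spac.max()
    return {"spacing_um": float(spac[0]), "n_voxels": int(out.labels.size)}


def sheet_isochrone_ratio(
    sigma_l: float,
    sigma_t: float,
    state: np.ndarray,
    h: float = 0.2,
    extent: float = 30.0,
    t_end: float = 13.0,
    iso_times: tuple[float, float] = (6.0, 11.0),
    dt: float = 0.01,
) -> dict:
    """Long/short axis ratio of the point-stimulus isochrone on a uniform
    2-D sheet with fibers along x.

    The ratio is taken between two isochrones (front displacement between
    ``iso_times``), which cancels the finite stimulus-patch radius and the
    launch delay; crossing positions are interpolated along the axis rays.
    """
    n = int(extent / h) + 1
    xs, ys = np.meshgrid(np.arange(n) * h, np.arange(n) * h, indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + n
            tris += [[a, b, b + 1], [a, b + 1, a + 1]]
    tris = np.asarray(tris)
    fibers = np.tile([1.0, 0.0, 0.0], (len(tris), 1))
    # strong patch stimulus: a point source into a 2-D anisotropic load
    # needs margin against source-sink mismatch
    model = MonodomainModel(
        sigma_l=sigma_l, sigma_t=sigma_t, dt=dt, stim_amplitude=100.0
    )
    center = np.array([extent / 2, extent / 2, 0.0])
    stim = np.flatnonzero(
        np.linalg.norm(verts - center, axis=1) <= max(1.0, 2.5 * h)
    )
    res = simulate_monodomain(
        verts, tris, fibers, model, t_end, initial_state=state, stim_vertices=stim
    )
    lat = res.lat.reshape(n, n)
    ic = n // 2

    def crossing(ray: np.ndarray, iso: float) -> float:
        for k in range(1, len(ray)):
            if not np.isfinite(ray[k]):
                return np.nan
            if ray[k] > iso:
                frac = (iso - ray[k - 1]) / (ray[k] - ray[k - 1])
                return (k - 1 + frac) * h
        return np.nan

    # axis i of the (i, j) grid is x: the fiber (fast) direction
    def extent_at(iso: float) -> tuple[float, float]:
        along = np.mean([crossing(lat[ic:, ic], iso), crossing(lat[ic::-1, ic], iso)])
        across = np.mean([crossing(lat[ic, ic:], iso), crossing(lat[ic, ic::-1], iso)])
        return along, across

    a1, c1 = extent_at(iso_times[0])
    a2, c2 = extent_at(iso_times[1])
    return {
        "ratio": float((a2 - a1) / (c2 - c1)),
        "along_mm": float(a2),
        "across_mm": float(c2),
        "n_nodes": n * n,
    }
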