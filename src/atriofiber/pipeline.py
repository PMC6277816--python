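"""Two-phase pipeline orchestration on the synthetic shell-atrium phantom.

Stage order: phantom -> segment -> smooth -> regions -> fibers-surface ->
fibers-volume -> fit-cv -> simulate. Every stage writes its artifacts under
the output directory and registers them (with SHA-256 hashes) in a
manifest, making reruns comparable byte-for-byte for deterministic stages.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
from typing import Any

import numpy as np

from atriofiber import __version__
from atriofiber.atlas_regions import save_atlas
from atriofiber.config import validate_config
from atriofiber.ep import (
    MonodomainModel,
    fit_conductivity,
    pace_to_steady_state,
    simulate_monodomain,
)
from atriofiber.fiber_surface import generate_surface_fibers
from atriofiber.fiber_transmural import (
    assign_volume_fibers,
    build_correspondence,
    transmural_laplace,
)
from atriofiber.mesh_io import SurfaceMesh, write_carp, write_image, write_vtk
from atriofiber.mesh_io.types import VoxelImage
from atriofiber.segmentation import (
    build_wall,
    compute_thresholds,
    median_prefilter,
    smooth_and_resample,
)
from atriofiber.synthetic import (
    ShellAtriumSpec,
    VoxelPhantomSpec,
    build_shell_atlas,
    make_shell_atrium,
    make_voxel_phantom,
)

__all__ = ["run_pipeline", "STAGES"]

STAGES = (
    "phantom",
    "segment",
    "smooth",
    "regions",
    "fibers-surface",
    "fibers-volume",
    "fit-cv",
    "simulate",
)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: str, config: dict):
        self.doc: dict[str, Any] = {
            "version": __version__,
            "seed": config["seed"],
            "units": config["units"],
            "stages": {},
        }
        self.out_dir = out_dir

    def record(self, stage: str, outputs: list[str], **info) -> None:
        self.doc["stages"][stage] = {
            "outputs": {
                os.path.relpath(p, self.out_dir): _sha256(p) for p in outputs
            },
            **info,
        }

    def save(self) -> str:
        path = os.path.join(self.out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(self.doc, fh, indent=1, sort_keys=True)
        return path


def run_pipeline(
    config: dict | None = None,
    out_dir: str = "atriofiber_out",
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the requested stages in order; returns the manifest document."""
    cfg = validate_config(config)
    os.makedirs(out_dir, exist_ok=True)
    manifest = _Manifest(out_dir, cfg)
    ctx: dict[str, Any] = {}

    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            _STAGE_FUNCS[stage](cfg, out_dir, ctx, manifest)
        except KeyError as exc:
            missing = str(exc).strip("'")
            upstream = _PRODUCERS.get(missing)
            if upstream:
                raise RuntimeError(
                    f"stage {stage!r} needs artifact {missing!r}; run stage "
                    f"{upstream!r} first"
                ) from exc
            raise

    manifest.save()
    return manifest.doc


def _stage_phantom(cfg, out_dir, ctx, manifest):
    p = cfg["phantom"]
    spec = VoxelPhantomSpec(
        cavity_radius=p["cavity_radius"],
        wall_thickness=p["wall_thickness"],
        spacing=p["spacing"],
        mean_wall=p["mean_wall"],
        sd_wall=p["sd_wall"],
        mean_cavity=p["mean_cavity"],
        sd_cavity=p["sd_cavity"],
        seed=cfg["seed"],
    )
    phantom = make_voxel_phantom(spec)
    s = cfg["shell"]
    shell_spec = ShellAtriumSpec(
        radii=tuple(s["radii"]),
        n_theta=s["n_theta"],
        n_phi=s["n_phi"],
        n_layers=s["n_layers"],
        thickness_top=s["thickness_top"],
        thickness_bottom=s["thickness_bottom"],
    )
    shell = make_shell_atrium(shell_spec)
    ctx["phantom"], ctx["shell"], ctx["shell_spec"] = phantom, shell, shell_spec

    img_path = os.path.join(out_dir, "phantom.mha")
    write_image(phantom.image, img_path)
    mesh_base = os.path.join(out_dir, "shell")
    write_carp(shell.volume, mesh_base)
    lm_path = os.path.join(out_dir, "landmarks.json")
    with open(lm_path, "w") as fh:
        json.dump(shell.landmarks, fh, indent=0, sort_keys=True)
    manifest.record(
        "phantom",
        [img_path, mesh_base + ".pts", mesh_base + ".elem", lm_path],
        seed=cfg["seed"],
    )


def _stage_segment(cfg, out_dir, ctx, manifest):
    phantom = ctx["phantom"]
    filtered = median_prefilter(
        phantom.image, radius=cfg["segmentation"]["median_radius"]
    )
    stats, thr = compute_thresholds(
        filtered, phantom.wall_samples, phantom.cavity_samples
    )
    seg = build_wall(
        filtered,
        thr,
        phantom.seed_point,
        max_thickness=cfg["segmentation"]["max_thickness"],
        min_dilations=cfg["segmentation"]["min_dilations"],
    )
    ctx["segmentation"] = seg
    lab_path = os.path.join(out_dir, "segmentation.mha")
    write_image(
        VoxelImage(seg.labels, seg.spacing, seg.origin), lab_path
    )
    stat_path = os.path.join(out_dir, "thresholds.json")
    with open(stat_path, "w") as fh:
        json.dump(
            {
                "lt": thr.lt, "mt": thr.mt, "ut": thr.ut,
                "mean_myo": stats.mean_myo, "sd_myo": stats.sd_myo,
                "mean_blood": stats.mean_blood, "sd_blood": stats.sd_blood,
            },
            fh, indent=1, sort_keys=True,
        )
    manifest.record("segment", [lab_path, stat_path], thresholds=[thr.lt, thr.mt, thr.ut])


def _stage_smooth(cfg, out_dir, ctx, manifest):
    seg = ctx["segmentation"]
    sm = cfg["smoothing"]
    out, surface = smooth_and_resample(
        seg,
        target_spacing=sm["target_spacing"],
        max_displacement_fraction=sm["max_displacement_fraction"],
        iterations=sm["iterations"],
    )
    ctx["smoothed"] = out
    surf_path = os.path.join(out_dir, "smoothed_surface.vtk")
    write_vtk(surface, surf_path)
    meta_path = os.path.join(out_dir, "smoothed_meta.json")
    with open(meta_path, "w") as fh:
        json.dump(
            {"spacing": out.spacing.tolist(), "shape": list(out.labels.shape)}, fh
        )
    manifest.record("smooth", [surf_path, meta_path], spacing=out.spacing.tolist())


def _stage_regions(cfg, out_dir, ctx, manifest):
    shell, spec = ctx["shell"], ctx["shell_spec"]
    paths = []
    for which in ("endo", "epi"):
        atlas = build_shell_atlas(shell, spec, which)
        ctx[f"atlas_{which}"] = atlas
        path = os.path.join(out_dir, f"atlas_{which}.json")
        save_atlas(atlas, path)
        paths.append(path)
    manifest.record("regions", paths, regions=len(ctx["atlas_endo"].regions))


def _stage_fibers_surface(cfg, out_dir, ctx, manifest):
    shell = ctx["shell"]
    fs = cfg["fibers_surface"]
    paths = []
    for which in ("endo", "epi"):
        surface = shell.endo if which == "endo" else shell.epi
        field = generate_surface_fibers(
            surface, ctx[f"atlas_{which}"], fs["band_width"], fs["passes"]
        )
        ctx[f"fibers_{which}"] = field
        out = SurfaceMesh(
            vertices=surface.vertices,
            triangles=surface.triangles,
            element_tags=surface.element_tags,
            fibers=field.axes,
        )
        base = os.path.join(out_dir, f"fibers_{which}")
        write_carp(out, base)
        write_vtk(out, base + ".vtk")
        paths += [base + ".lon", base + ".vtk"]
    manifest.record("fibers-surface", paths)


def _stage_fibers_volume(cfg, out_dir, ctx, manifest):
    shell = ctx["shell"]
    scheme = cfg["fibers_volume"]["scheme"]
    # endo/epi vertex sets are disjoint (different radial layers); lateral
    # rim faces at open orifices get the natural zero-flux condition
    endo_v = np.unique(shell.endo.triangles)
    epi_v = np.unique(shell.epi.triangles)
    u = transmural_laplace(shell.volume, endo_v, epi_v)
    corr = build_correspondence(shell.volume, u, shell.endo, shell.epi)
    fibered = assign_volume_fibers(
        shell.volume,
        corr,
        ctx["fibers_endo"].axes,
        ctx["fibers_epi"].axes,
        scheme,
    )
    ctx["fibered_volume"] = fibered
    ctx["correspondence"] = corr
    base = os.path.join(out_dir, "volume_fibers")
    write_carp(fibered, base)
    write_vtk(fibered, base + ".vtk")
    prov = os.path.join(out_dir, "volume_fibers_provenance.csv")
    with open(prov, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tet", "phi", "scheme", "flag"])
        for t in range(fibered.n_elements):
            w.writerow([t, f"{corr.phi[t]:.6f}", scheme, int(corr.flags[t])])
    manifest.record(
        "fibers-volume", [base + ".lon", base + ".vtk", prov], scheme=scheme
    )


def _stage_fit_cv(cfg, out_dir, ctx, manifest):
    f = cfg["cv_fit"]
    state, delta = pace_to_steady_state(f["n_beats"], bcl=f["bcl"], dt=f["dt"])
    sigma_l, sigma_t, report = fit_conductivity(
        f["cv_l"],
        f["cv_t"],
        resolution=f["resolution"],
        dt=f["dt"],
        state=state,
        length=f["cable_length"],
        tol=f["tolerance"],
        max_iter=f["max_iter"],
    )
    ctx["paced_state"] = state
    ctx["sigma"] = (sigma_l, sigma_t)
    path = os.path.join(out_dir, "conductivity.json")
    with open(path, "w") as fh:
        json.dump(
            {
                "sigma_l": sigma_l,
                "sigma_t": sigma_t,
                "cv_measured": report["cv"],
                "pacing_convergence": delta,
            },
            fh, indent=1, sort_keys=True,
        )
    manifest.record("fit-cv", [path], cv=report["cv"])


def _stage_simulate(cfg, out_dir, ctx, manifest):
    shell = ctx["shell"]
    fibered = ctx["fibered_volume"]
    sim = cfg["simulate"]
    sigma_l, sigma_t = ctx.get("sigma", (8e-3, 1.06e-3))
    model = MonodomainModel(
        sigma_l=sigma_l,
        sigma_t=sigma_t,
        dt=sim["dt"],
        stim_amplitude=sim["stim_amplitude"],
        stim_duration=sim["stim_duration"],
        lat_threshold=sim["lat_threshold"],
    )
    center = shell.volume.vertices[shell.landmarks[sim["stim_landmark"]]]
    d = np.linalg.norm(shell.volume.vertices - center, axis=1)
    stim = np.flatnonzero(d <= sim["stim_radius"])
    state = ctx.get("paced_state")
    res = simulate_monodomain(
        shell.volume.vertices,
        shell.volume.tets,
        fibered.fibers,
        model,
        sim["t_end"],
        initial_state=state,
        stim_vertices=stim,
    )
    ctx["lat"] = res.lat
    lat_path = os.path.join(out_dir, "lat.csv")
    with open(lat_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex", "lat_ms"])
        for i, t in enumerate(res.lat):
            w.writerow([i, "" if np.isnan(t) else f"{t:.4f}"])
    manifest.record(
        "simulate",
        [lat_path],
        activated_fraction=float(np.isfinite(res.lat).mean()),
        max_lat=float(np.nanmax(res.lat)),
    )


_PRODUCERS = {
    "phantom": "phantom",
    "shell": "phantom",
    "shell_spec": "phantom",
    "segmentation": "segment",
    "smoothed": "smooth",
    "atlas_endo": "regions",
    "atlas_epi": "regions",
    "fibers_endo": "fibers-surface",
    "fibers_epi": "fibers-surface",
    "fibered_volume": "fibers-volume",
    "correspondence": "fibers-volume",
    "paced_state": "fit-cv",
}

_STAGE_FUNCS = {
    "phantom": _stage_phantom,
    "segment": _stage_segment,
    "smooth": _stage_smooth,
    "regions": _stage_regions,
    "fibers-surface": _stage_fibers_surface,
    "fibers-volume": _stage_fibers_volume,
    "fit-cv": _stage_fit_cv,
    "simulate": _stage_simulate,
}
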