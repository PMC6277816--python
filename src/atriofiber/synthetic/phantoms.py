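"""Two-compartment voxel phantoms for the segmentation stage.

Contrast-enhanced convention: the cavity (blood pool) is brighter than
the wall. Each phantom ships ground-truth masks and three sample-region
masks per tissue class mimicking the manual sampling protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from atriofiber.mesh_io.types import VoxelImage

__all__ = ["VoxelPhantomSpec", "VoxelPhantom", "make_voxel_phantom"]


@dataclass
class VoxelPhantomSpec:
    geometry: str = "spherical_shell"  # or "slab"
    cavity_radius: float = 8.0  # mm (shell); slab uses extent instead
    wall_thickness: float = 1.5  # mm
    spacing: float = 0.4  # mm isotropic
    mean_wall: float = 250.0
    sd_wall: float = 30.0
    mean_cavity: float = 450.0
    sd_cavity: float = 40.0
    mean_background: float = 50.0
    sd_background: float = 20.0
    margin: float = 3.0  # mm of background around the structure
    seed: int = 0
    slab_extent: tuple[float, float, float] = (20.0, 20.0, 12.0)

    def __post_init__(self) -> None:
        if self.wall_thickness <= 0 or self.spacing <= 0:
            raise ValueError("thickness and spacing must be positive")
        if self.wall_thickness < self.spacing:
            raise ValueError(
                f"wall thickness {self.wall_thickness} mm is thinner than one voxel "
                f"({self.spacing} mm); decrease spacing"
            )
        if not self.mean_wall < self.mean_cavity:
            raise ValueError("contrast convention requires mean_wall < mean_cavity")


@dataclass
class VoxelPhantom:
    image: VoxelImage
    cavity_mask: np.ndarray  # ground-truth blood pool
    wall_mask: np.ndarray  # ground-truth wall
    wall_samples: np.ndarray  # 3 labeled sample regions (values 1..3)
    cavity_samples: np.ndarray
    seed_point: np.ndarray  # physical coordinate inside the cavity
    spec: VoxelPhantomSpec


def _ball_mask(shape, center, radius, spacing):
    grid = np.indices(shape).astype(float)
    d2 = sum(((grid[i] - center[i]) * spacing[i]) ** 2 for i in range(3))
    return d2 <= radius**2


def make_voxel_phantom(spec: VoxelPhantomSpec | None = None) -> VoxelPhantom:
    spec = spec or VoxelPhantomSpec()
    rng = np.random.default_rng(spec.seed)
    sp = spec.spacing
    if spec.geometry == "spherical_shell":
        half = spec.cavity_radius + spec.wall_thickness + spec.margin
        n = int(np.ceil(2 * half / sp)) + 1
        shape = (n, n, n)
        center = np.array([(n - 1) / 2.0] * 3)
        grid = np.indices(shape).astype(float)
        r = np.sqrt(sum(((grid[i] - center[i]) * sp) ** 2 for i in range(3)))
        cavity = r <= spec.cavity_radius
        wall = (r > spec.cavity_radius) & (r <= spec.cavity_radius + spec.wall_thickness)
        seed_idx = center
        # sample balls: 3 inside the cavity, 3 inside the wall
        rs = spec.cavity_radius
        ball_r = min(2.0, rs / 3)
        cav_centers = [
            center + np.array(d) * (rs * 0.45 / sp)
            for d in ((1, 0, 0), (-0.5, 0.8, 0), (0, -0.6, -0.7))
        ]
        mid_r = spec.cavity_radius + spec.wall_thickness / 2
        wall_ball_r = spec.wall_thickness * 0.45
        wall_centers = [
            center + np.array(d) / np.linalg.norm(d) * (mid_r / sp)
            for d in ((0.0, 0.0, 1.0), (1.0, 1.0, 0.0), (-1.0, 0.5, -0.5))
        ]
    elif spec.geometry == "slab":
        ext = spec.slab_extent
        shape = tuple(int(np.ceil(e / sp)) + 1 for e in ext)
        grid = np.indices(shape).astype(float)
        z = grid[2] * sp
        z_cav = ext[2] * 0.5
        cavity = z <= z_cav
        wall = (z > z_cav) & (z <= z_cav + spec.wall_thickness)
        center = np.array([(s - 1) / 2.0 for s in shape])
        seed_idx = np.array([center[0], center[1], (z_cav / 2) / sp])
        ball_r = min(2.0, ext[0] / 6)
        cav_centers = [
            np.array([shape[0] * f, shape[1] * g, (z_cav / 2) / sp])
            for f, g in ((0.3, 0.3), (0.7, 0.4), (0.5, 0.7))
        ]
        wall_ball_r = spec.wall_thickness * 0.45
        zc = (z_cav + spec.wall_thickness / 2) / sp
        wall_centers = [
            np.array([shape[0] * f, shape[1] * g, zc])
            for f, g in ((0.3, 0.3), (0.7, 0.4), (0.5, 0.7))
        ]
    else:
        raise ValueError(f"unknown phantom geometry {spec.geometry!r}")

    data = rng.normal(spec.mean_background, spec.sd_background, size=shape)
    data[wall] = rng.normal(spec.mean_wall, spec.sd_wall, size=int(wall.sum()))
    data[cavity] = rng.normal(spec.mean_cavity, spec.sd_cavity, size=int(cavity.sum()))

    cav_samples = np.zeros(shape, dtype=np.int8)
    wall_samples = np.zeros(shape, dtype=np.int8)
    for i, c in enumerate(cav_centers, start=1):
        m = _ball_mask(shape, c, ball_r, (sp, sp, sp)) & cavity
        cav_samples[m] = i
    for i, c in enumerate(wall_centers, start=1):
        m = _ball_mask(shape, c, wall_ball_r, (sp, sp, sp)) & wall
        wall_samples[m] = i
    if min(int((cav_samples == i).sum()) for i in (1, 2, 3)) == 0:
        raise ValueError("empty cavity sample region; enlarge phantom")
    if min(int((wall_samples == i).sum()) for i in (1, 2, 3)) == 0:
        raise ValueError("empty wall sample region; thicken wall or refine spacing")

    image = VoxelImage(data=data, spacing=np.full(3, sp), origin=np.zeros(3))
    return VoxelPhantom(
        image=image,
        cavity_mask=cavity,
        wall_mask=wall,
        wall_samples=wall_samples,
        cavity_samples=cav_samples,
        seed_point=image.index_to_physical(seed_idx),
        spec=spec,
    )
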