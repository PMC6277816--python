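"""Statistics-based tagged segmentation of the atrial wall.

Thresholds come from pooled sample statistics: the wall band is
[mean_myo - 3 sd_myo, mid] and the blood band [mid, mean_blood + 3 sd_blood]
with the mid threshold the average of the two sample means. The wall is
grown from the blood pool by iterative 6-connected dilations intersected
with the viable-myocardium band, capped at a maximum physical thickness,
with a one-voxel minimum ring. Orifices (MV, PVs) are tagged by simple
3-point geometric cutting bodies; the wall label algebra keeps
{aw, mv, pv} an exact partition of the wall class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from atriofiber.mesh_io.types import SurfaceMesh, VoxelImage

__all__ = [
    "ThresholdSet",
    "SampleStats",
    "TaggedSegmentation",
    "SegmentationError",
    "compute_thresholds",
    "median_prefilter",
    "build_wall",
    "tag_orifices",
    "smooth_and_resample",
    "LABEL_BACKGROUND",
    "LABEL_BLOOD",
    "LABEL_AW",
    "LABEL_MV",
    "LABEL_PV",
]

LABEL_BACKGROUND = 0
LABEL_BLOOD = 1
LABEL_AW = 2  # atrial wall proper
LABEL_MV = 3  # mitral-valve annulus tag
LABEL_PV = 4  # pulmonary-vein end tag
_WALL_LABELS = (LABEL_AW, LABEL_MV, LABEL_PV)

_CONN6 = ndimage.generate_binary_structure(3, 1)


class SegmentationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ThresholdSet:
    lt: float  # lower (wall) threshold
    mt: float  # mid threshold separating wall from blood
    ut: float  # upper (blood) threshold

    def __post_init__(self) -> None:
        if not (self.lt < self.mt < self.ut):
            raise SegmentationError(
                f"thresholds must be ordered LT < MT < UT, got "
                f"({self.lt}, {self.mt}, {self.ut})"
            )


@dataclass(frozen=True)
class SampleStats:
    mean_myo: float
    sd_myo: float
    mean_blood: float
    sd_blood: float


@dataclass
class TaggedSegmentation:
    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def blood_mask(self) -> np.ndarray:
        return self.labels == LABEL_BLOOD

    @property
    def wall_mask(self) -> np.ndarray:
        """Omega_MC: the full muscular-continuum wall class (aw | mv | pv)."""
        return np.isin(self.labels, _WALL_LABELS)

    @property
    def aw_mask(self) -> np.ndarray:
        return self.labels == LABEL_AW

    @property
    def mv_mask(self) -> np.ndarray:
        return self.labels == LABEL_MV

    @property
    def pv_mask(self) -> np.ndarray:
        return self.labels == LABEL_PV

    def physical_to_index(self, xyz) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing


def compute_thresholds(
    image: VoxelImage,
    myo_samples: np.ndarray,
    blood_samples: np.ndarray,
) -> tuple[SampleStats, ThresholdSet]:
    """Pooled statistics over the sample-region voxels (combined, not
    per-region averages) and the derived threshold triple."""
    myo_samples = np.asarray(myo_samples) > 0
    blood_samples = np.asarray(blood_samples) > 0
    if not myo_samples.any() or not blood_samples.any():
        raise SegmentationError("sample masks must be nonempty")
    if np.any(myo_samples & blood_samples):
        raise SegmentationError("sample masks overlap")
    mv = image.data[myo_samples].astype(float)
    bv = image.data[blood_samples].astype(float)
    stats = SampleStats(
        mean_myo=float(mv.mean()),
        sd_myo=float(mv.std()),
        mean_blood=float(bv.mean()),
        sd_blood=float(bv.std()),
    )
    lt = stats.mean_myo - 3.0 * stats.sd_myo
    ut = stats.mean_blood + 3.0 * stats.sd_blood
    mt = 0.5 * (stats.mean_myo + stats.mean_blood)
    if lt >= mt:
        raise SegmentationError(
            f"degenerate statistics: wall N({stats.mean_myo:.1f}, {stats.sd_myo:.1f}) "
            f"overlaps blood N({stats.mean_blood:.1f}, {stats.sd_blood:.1f}) "
            f"(LT={lt:.1f} >= MT={mt:.1f})"
        )
    return stats, ThresholdSet(lt=lt, mt=mt, ut=ut)


def median_prefilter(image: VoxelImage, radius: int = 1) -> VoxelImage:
    """Median filter with a 6-connected-plus-center footprint (radius 1 by
    default); stands in for the vendor '4-point' median filter."""
    footprint = ndimage.iterate_structure(_CONN6, radius) if radius > 1 else _CONN6
    data = ndimage.median_filter(image.data, footprint=footprint, mode="nearest")
    return VoxelImage(data=data, spacing=image.spacing.copy(), origin=image.origin.copy())


def build_wall(
    image: VoxelImage,
    thresholds: ThresholdSet,
    seed_point: np.ndarray,
    max_thickness: float = 3.0,
    min_dilations: int = 1,
) -> TaggedSegmentation:
    """Blood pool + wall segmentation (labels blood and aw only).

    The blood pool is the [MT, UT] component containing ``seed_point``;
    viable wall voxels are in [LT, MT). The wall is the union of the
    K-fold dilated blood pool intersected with the viable band (K chosen
    so the dilation distance does not exceed ``max_thickness``) and a
    ``min_dilations``-voxel ring guaranteeing minimum thickness.
    """
    data = image.data
    blood_band = (data >= thresholds.mt) & (data <= thresholds.ut)
    if not blood_band.any():
        raise SegmentationError("no voxels in the blood intensity band")
    labeled, _ = ndimage.label(blood_band, structure=_CONN6)
    seed_idx = np.round(image.physical_to_index(seed_point)).astype(int)
    if np.any(seed_idx < 0) or np.any(seed_idx >= data.shape):
        raise SegmentationError(f"seed point {seed_point} outside the image")
    seed_label = labeled[tuple(seed_idx)]
    if seed_label == 0:
        raise SegmentationError("seed point is not inside the blood intensity band")
    blood = labeled == seed_label
    viable = (data >= thresholds.lt) & (data < thresholds.mt)

    k_max = int(np.floor(max_thickness / float(np.min(image.spacing))))
    ring = ndimage.binary_dilation(blood, _CONN6, iterations=min_dilations) & ~blood
    if k_max >= 1:
        grown = ndimage.binary_dilation(blood, _CONN6, iterations=k_max)
        wall = (grown & viable & ~blood) | ring
    else:
        wall = ring
    labels = np.zeros(data.shape, dtype=np.uint8)
    labels[blood] = LABEL_BLOOD
    labels[wall] = LABEL_AW
    return TaggedSegmentation(
        labels=labels, spacing=image.spacing.copy(), origin=image.origin.copy()
    )


def _circumcircle(points: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Center, radius, and unit plane normal of the circle through 3 points."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in points)
    a, b = p2 - p1, p3 - p1
    n = np.cross(a, b)
    nn = np.linalg.norm(n)
    if nn < 1e-9 * max(np.linalg.norm(a), np.linalg.norm(b), 1e-12):
        raise SegmentationError(f"points {points} are collinear")
    c = p1 + (
        np.dot(a, a) * np.cross(b, n) + np.dot(b, b) * np.cross(n, a)
    ) / (2.0 * nn**2)
    r = float(np.linalg.norm(c - p1))
    return c, r, n / nn


def _physical_grid(seg: TaggedSegmentation) -> tuple[np.ndarray, ...]:
    idx = np.indices(seg.labels.shape).astype(float)
    return tuple(seg.origin[i] + idx[i] * seg.spacing[i] for i in range(3))


def tag_orifices(
    seg: TaggedSegmentation,
    mv_points: np.ndarray,
    pv_points: list[np.ndarray],
    seed_point: np.ndarray,
    shell_thickness: float = 1.0,
    sphere_radius_factor: float = 1.0,
    cylinder_margin: float = 1.2,
    cylinder_half_length: float = 2.0,
) -> TaggedSegmentation:
    """Tag MV annulus (spherical shell) and PV ends (cylindrical disks);
    remove wall/blood distal to the cutting bodies; recompute the wall
    partition. Three non-collinear points define each body."""
    X, Y, Z = _physical_grid(seg)
    wall = seg.wall_mask
    blood = seg.blood_mask

    c, r, n = _circumcircle(mv_points)
    r_s = r * sphere_radius_factor
    dist = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
    ss = np.abs(dist - r_s) <= shell_thickness / 2.0
    cut = ss.copy()
    pv_mask_all = np.zeros_like(cut)
    for pts in pv_points:
        c, r, n = _circumcircle(pts)
        dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
        axial = dx * n[0] + dy * n[1] + dz * n[2]
        rad2 = dx * dx + dy * dy + dz * dz - axial * axial
        cd = (np.abs(axial) <= cylinder_half_length) & (
            rad2 <= (r * cylinder_margin) ** 2
        )
        pv_mask_all |= cd
        cut |= cd

    mv_tag = wall & ss
    pv_tag = wall & pv_mask_all & ~mv_tag

    # connectivity to the blood-pool seed decides what is distal
    keep_domain = (wall | blood) & ~cut
    labeled, _ = ndimage.label(keep_domain, structure=_CONN6)
    seed_idx = tuple(np.round(seg.physical_to_index(seed_point)).astype(int))
    seed_label = labeled[seed_idx]
    if seed_label == 0:
        raise SegmentationError("seed point was removed by a cutting body")
    keep = labeled == seed_label

    labels = np.zeros_like(seg.labels)
    labels[blood & keep] = LABEL_BLOOD
    labels[wall & keep] = LABEL_AW
    labels[mv_tag] = LABEL_MV
    labels[pv_tag] = LABEL_PV
    return TaggedSegmentation(
        labels=labels, spacing=seg.spacing.copy(), origin=seg.origin.copy()
    )


def _signed_distance(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Negative inside the mask, positive outside (physical units)."""
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return outside - inside


def smooth_and_resample(
    seg: TaggedSegmentation,
    target_spacing: float = 0.1,
    max_displacement_fraction: float = 0.5,
    iterations: int = 50,
    smooth_sigma_vox: float = 0.6,
) -> tuple[TaggedSegmentation, SurfaceMesh]:
    """Constrained level-set smoothing of the wall surface + isotropic
    upsampling.

    The signed-distance field of the wall is smoothed iteratively and
    clamped each iteration to within ``max_displacement_fraction`` x voxel
    size of the original field; because signed distance is 1-Lipschitz,
    every point of the smoothed isosurface then lies within that cap of
    the original surface. Tags transfer by nearest original voxel.
    """
    if target_spacing > float(np.min(seg.spacing)) + 1e-12:
        raise SegmentationError(
            f"refusing to downsample: target {target_spacing} mm coarser than "
            f"original spacing {seg.spacing}"
        )
    from skimage import measure

    voxel = float(np.min(seg.spacing))
    cap = max_displacement_fraction * voxel
    wall = seg.wall_mask
    if not wall.any():
        raise SegmentationError("empty wall; nothing to smooth")
    sdf0 = _signed_distance(wall, seg.spacing)
    sdf = sdf0.copy()
    sigma = smooth_sigma_vox
    for _ in range(iterations):
        sdf = ndimage.gaussian_filter(sdf, sigma=sigma)
        np.clip(sdf, sdf0 - cap, sdf0 + cap, out=sdf)

    verts_idx, faces, _, _ = measure.marching_cubes(sdf, level=0.0)
    verts = seg.origin + verts_idx * seg.spacing
    surface = SurfaceMesh(vertices=verts, triangles=faces)

    # --- resample to isotropic target spacing -----------------------------
    shape = seg.labels.shape
    extent = (np.asarray(shape) - 1) * seg.spacing
    new_shape = np.floor(extent / target_spacing).astype(int) + 1
    grids = [
        np.arange(new_shape[i]) * target_spacing / seg.spacing[i] for i in range(3)
    ]
    ci, cj, ck = np.meshgrid(*grids, indexing="ij", sparse=True)
    coords = np.broadcast_arrays(ci, cj, ck)
    coords = np.stack([c.ravel() for c in coords])
    sdf_new = ndimage.map_coordinates(sdf, coords, order=1).reshape(tuple(new_shape))
    labels_nn = (
        ndimage.map_coordinates(seg.labels, coords, order=0).reshape(tuple(new_shape))
    )
    # nearest *wall* label for tag transfer inside the new wall mask
    _, idx = ndimage.distance_transform_edt(
        ~wall, sampling=seg.spacing, return_indices=True
    )
    wall_label_map = seg.labels[tuple(idx)]
    wall_nn = (
        ndimage.map_coordinates(wall_label_map, coords, order=0).reshape(tuple(new_shape))
    )
    new_wall = sdf_new <= 0.0
    labels_new = labels_nn.copy()
    labels_new[new_wall] = wall_nn[new_wall]
    outside_wall_label = ~new_wall & np.isin(labels_nn, _WALL_LABELS)
    labels_new[outside_wall_label] = LABEL_BACKGROUND
    out = TaggedSegmentation(
        labels=labels_new,
        spacing=np.full(3, float(target_spacing)),
        origin=seg.origin.copy(),
    )
    return out, surface
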