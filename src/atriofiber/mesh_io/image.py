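"""Voxel-image I/O: NIfTI-1 (via nibabel) and uncompressed MetaImage (.mha)."""

from __future__ import annotations

import os

import numpy as np

from atriofiber.mesh_io.types import VoxelImage

__all__ = ["read_image", "write_image"]

_MHA_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MHA_NAMES = {np.dtype(v): k for k, v in _MHA_TYPES.items()}


def read_image(path: str) -> VoxelImage:
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        affine = img.affine
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        origin = affine[:3, 3]
        return VoxelImage(data=data, spacing=spacing, origin=origin)
    if path.endswith(".mha"):
        return _read_mha(path)
    raise ValueError(f"unsupported image format: {path}")


def write_image(image: VoxelImage, path: str) -> None:
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        affine[0, 0], affine[1, 1], affine[2, 2] = image.spacing
        affine[:3, 3] = image.origin
        nib.save(nib.Nifti1Image(np.asarray(image.data), affine), path)
        return
    if path.endswith(".mha"):
        _write_mha(image, path)
        return
    raise ValueError(f"unsupported image format: {path}")


def _read_mha(path: str) -> VoxelImage:
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline().decode("ascii")
            if not line:
                raise ValueError(f"{path}: truncated MetaImage header")
            key, _, value = line.partition("=")
            header[key.strip()] = value.strip()
            if key.strip() == "ElementDataFile":
                break
        if header.get("ElementDataFile", "LOCAL") != "LOCAL":
            raise ValueError("only LOCAL-data .mha supported")
        if header.get("CompressedData", "False").lower() == "true":
            raise ValueError("compressed .mha not supported")
        dims = [int(v) for v in header["DimSize"].split()]
        dtype = _MHA_TYPES[header.get("ElementType", "MET_FLOAT")]
        raw = fh.read()
    data = np.frombuffer(raw, dtype=dtype, count=int(np.prod(dims)))
    # MetaImage data is x-fastest; our arrays index (x, y, z) C-order
    data = data.reshape(dims[::-1]).transpose(2, 1, 0)
    spacing = [float(v) for v in header.get("ElementSpacing", "1 1 1").split()]
    origin = [float(v) for v in header.get("Offset", "0 0 0").split()]
    return VoxelImage(data=data.copy(), spacing=spacing, origin=origin)


def _write_mha(image: VoxelImage, path: str) -> None:
    data = np.asarray(image.data)
    try:
        etype = _MHA_NAMES[data.dtype]
    except KeyError:
        data = data.astype(np.float64)
        etype = "MET_DOUBLE"
    dims = data.shape
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {dims[0]} {dims[1]} {dims[2]}\n"
        f"ElementSpacing = {image.spacing[0]:.9g} {image.spacing[1]:.9g} {image.spacing[2]:.9g}\n"
        f"Offset = {image.origin[0]:.9g} {image.origin[1]:.9g} {image.origin[2]:.9g}\n"
        f"ElementType = {etype}\n"
        "ElementDataFile = LOCAL\n"
    )
    tmp = path + ".tmp"
    with open(tmp, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(data.transpose(2, 1, 0).tobytes())
    os.replace(tmp, path)
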