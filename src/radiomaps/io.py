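"""NRRD (and optional DICOM) reading and writing through SimpleITK.

Images travel as 2D NRRD with pixel spacing in the ``space directions`` header
field; the slice thickness, which has no natural home in a 2D header, is kept
in the custom key ``slice_thickness_mm``.  Masks are written as 0/1 unsigned
char grids with identical geometry.
"""

from __future__ import annotations

import os

import numpy as np
import SimpleITK as sitk

from .core import ImageSlice, SegmentationMask

THICKNESS_KEY = "slice_thickness_mm"


def _to_sitk(pixels: np.ndarray, spacing_mm, origin_mm, thickness_mm) -> sitk.Image:
    # SimpleITK axis order is (x, y) = (col, row); numpy arrays are (row, col).
    img = sitk.GetImageFromArray(pixels)
    img.SetSpacing((float(spacing_mm[1]), float(spacing_mm[0])))
    img.SetOrigin((float(origin_mm[1]), float(origin_mm[0])))
    img.SetMetaData(THICKNESS_KEY, repr(float(thickness_mm)))
    return img


def write_image(image: ImageSlice, path: str | os.PathLike) -> None:
    img = _to_sitk(
        image.pixels.astype(np.float64),
        image.spacing_mm,
        image.origin_mm,
        image.slice_thickness_mm,
    )
    sitk.WriteImage(img, os.fspath(path))


def read_image(path: str | os.PathLike, slice_thickness_mm: float | None = None) -> ImageSlice:
    """Read a 2D NRRD/DICOM file into an :class:`ImageSlice`.

    ``slice_thickness_mm`` overrides the header value; files written by this
    package carry the thickness in the ``slice_thickness_mm`` NRRD key.
    """
    img = sitk.ReadImage(os.fspath(path))
    if img.GetDimension() != 2:
        raise ValueError(f"{path}: expected a 2D slice, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img).astype(np.float64)
    sx, sy = img.GetSpacing()  # (col, row)
    ox, oy = img.GetOrigin()
    thickness = slice_thickness_mm
    if thickness is None:
        if img.HasMetaDataKey(THICKNESS_KEY):
            thickness = float(img.GetMetaData(THICKNESS_KEY))
        else:
            thickness = 8.0
    return ImageSlice(
        pixels=arr,
        spacing_mm=(sy, sx),
        origin_mm=(oy, ox),
        slice_thickness_mm=float(thickness),
    )


def write_mask(mask: SegmentationMask, path: str | os.PathLike) -> None:
    img = _to_sitk(
        mask.mask.astype(np.uint8),
        mask.spacing_mm,
        mask.origin_mm,
        mask.slice_thickness_mm,
    )
    sitk.WriteImage(img, os.fspath(path))


def read_mask(path: str | os.PathLike) -> SegmentationMask:
    img = sitk.ReadImage(os.fspath(path))
    if img.GetDimension() != 2:
        raise ValueError(f"{path}: expected a 2D mask, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img)
    sx, sy = img.GetSpacing()
    ox, oy = img.GetOrigin()
    thickness = 8.0
    if img.HasMetaDataKey(THICKNESS_KEY):
        thickness = float(img.GetMetaData(THICKNESS_KEY))
    return SegmentationMask(
        mask=arr > 0,
        spacing_mm=(sy, sx),
        origin_mm=(oy, ox),
        slice_thickness_mm=thickness,
    )
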