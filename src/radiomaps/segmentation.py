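"""Semi-automated LV myocardium segmentation.

Mirrors the two-step clinical workflow: a coarse circular region around the
left ventricle (the manual ROI surrogate), then an intensity window —
default 0–170, interval closed on both ends — that separates myocardium from
the bright blood pool, keeping the largest 8-connected component.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import ImageSlice, SegmentationMask

__all__ = ["SegmentationError", "circle_region", "threshold_segment"]

DEFAULT_THRESHOLD = (0.0, 170.0)


class SegmentationError(ValueError):
    """Segmentation produced no usable region."""


def circle_region(
    image: ImageSlice, center_mm: tuple[float, float], radius_mm: float
) -> SegmentationMask:
    """Pixels whose centers lie within ``radius_mm`` of ``center_mm``.

    Coordinates are physical (mm), so the pixel count of the same circle
    varies with the pixel spacing.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    rr, cc = image.pixel_centers_mm()
    d2 = (rr - center_mm[0]) ** 2 + (cc - center_mm[1]) ** 2
    mask = d2 <= radius_mm**2
    if not mask.any():
        raise SegmentationError(
            "circle does not intersect the image; check center/radius"
        )
    return SegmentationMask.like(image, mask)


def threshold_segment(
    image: ImageSlice,
    region: SegmentationMask,
    lo: float = DEFAULT_THRESHOLD[0],
    hi: float = DEFAULT_THRESHOLD[1],
) -> SegmentationMask:
    """Intensity window inside ``region``, then largest 8-connected component."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    if not region.matches_geometry(image):
        raise ValueError("region geometry does not match the image")
    raw = region.mask & (image.pixels >= lo) & (image.pixels <= hi)
    if not raw.any():
        raise SegmentationError(
            "threshold produced an empty mask; review the intensity window "
            f"[{lo}, {hi}] and the region placement"
        )
    structure = np.ones((3, 3), dtype=int)
    lab, nlab = ndimage.label(raw, structure=structure)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = int(sizes.argmax())
    return SegmentationMask.like(image, lab == keep)
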