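"""Core in-memory containers shared by every pipeline stage.

All geometry is physical: a 2D pixel grid plus an in-plane pixel spacing in
millimetres and a slice thickness.  Pixel (r, c) has its *center* at

    origin_mm + (r + 0.5, c + 0.5) * spacing_mm

so physical coordinates are (row-axis mm, column-axis mm) pairs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageSlice", "SegmentationMask"]


@dataclass(frozen=True)
class ImageSlice:
    """A single 2D intensity slice with physical pixel geometry.

    Parameters
    ----------
    pixels
        2D float array of intensities (arbitrary units), shape (rows, cols).
    spacing_mm
        Pixel spacing per axis (row spacing, column spacing) in mm/pixel.
    slice_thickness_mm
        Through-plane extent of the slice, in mm.  Only volume-bearing
        features (total energy) consume it.
    origin_mm
        Physical position of the corner of pixel (0, 0).
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float]
    slice_thickness_mm: float = 8.0
    origin_mm: tuple[float, float] = (0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        sp = (float(self.spacing_mm[0]), float(self.spacing_mm[1]))
        if sp[0] <= 0 or sp[1] <= 0:
            raise ValueError("spacing_mm entries must be positive")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be positive")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing_mm", sp)
        object.__setattr__(
            self, "origin_mm", (float(self.origin_mm[0]), float(self.origin_mm[1]))
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_mm[0] * self.spacing_mm[1]

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (row_mm, col_mm) center coordinate grids, each (rows, cols)."""
        h, w = self.pixels.shape
        r = self.origin_mm[0] + (np.arange(h) + 0.5) * self.spacing_mm[0]
        c = self.origin_mm[1] + (np.arange(w) + 0.5) * self.spacing_mm[1]
        return np.meshgrid(r, c, indexing="ij")

    def with_pixels(self, pixels: np.ndarray) -> "ImageSlice":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class SegmentationMask:
    """Boolean mask aligned pixel-for-pixel with a source :class:`ImageSlice`."""

    mask: np.ndarray
    spacing_mm: tuple[float, float]
    origin_mm: tuple[float, float] = (0.0, 0.0)
    slice_thickness_mm: float = 8.0

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("mask must be a non-empty 2D array")
        object.__setattr__(self, "mask", m)
        object.__setattr__(
            self, "spacing_mm", (float(self.spacing_mm[0]), float(self.spacing_mm[1]))
        )
        object.__setattr__(
            self, "origin_mm", (float(self.origin_mm[0]), float(self.origin_mm[1]))
        )

    @classmethod
    def like(cls, image: ImageSlice, mask: np.ndarray) -> "SegmentationMask":
        m = np.asarray(mask, dtype=bool)
        if m.shape != image.shape:
            raise ValueError(
                f"mask shape {m.shape} does not match image shape {image.shape}"
            )
        return cls(
            mask=m,
            spacing_mm=image.spacing_mm,
            origin_mm=image.origin_mm,
            slice_thickness_mm=image.slice_thickness_mm,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def matches_geometry(self, image: ImageSlice, atol: float = 1e-9) -> bool:
        return (
            self.mask.shape == image.shape
            and np.allclose(self.spacing_mm, image.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, image.origin_mm, atol=atol)
        )
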