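"""Single-region feature extraction API.

These functions are thin wrappers that feed one masked region through the
batched kernels in :mod:`radiomaps.features.engine`, so conventional ROI
extraction and the parametric-map engine share one implementation.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np

from ..core import ImageSlice, SegmentationMask
from . import engine
from .catalog import ALL_FEATURES, CLASS_FEATURES, N_FEATURES
from .settings import ExtractionSettings

__all__ = [
    "DiscretizedRegion",
    "FeatureVector",
    "discretize",
    "first_order",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "extract_all",
]


@dataclass(frozen=True)
class DiscretizedRegion:
    """Gray-level discretized masked region (levels 1..Ng, 0 outside)."""

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    n_pixels: int
    pixel_area_mm2: float
    slice_thickness_mm: float

    def _as_stack(self) -> engine.DiscretizedStack:
        return engine.DiscretizedStack(
            levels=self.levels[None],
            mask=self.mask[None],
            ng=np.array([self.ng]),
            counts=np.array([self.n_pixels]),
        )


@dataclass(frozen=True)
class FeatureVector:
    """Ordered mapping of the 93 canonical feature names to scalar values.

    Undefined (degenerate) features hold NaN and carry ``valid=False``; they
    are excluded from downstream coefficient-of-variation statistics rather
    than silently filled.
    """

    values: "OrderedDict[str, float]"
    valid: "OrderedDict[str, bool]"

    def __post_init__(self):
        if len(self.values) != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {len(self.values)}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)

    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def is_valid(self, name: str) -> bool:
        return self.valid[name]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for name in self.values:
            cls = name.split("_", 1)[0]
            counts[cls] = counts.get(cls, 0) + 1
        return counts

    def to_series(self):
        import pandas as pd

        return pd.Series(
            {k: (v if self.valid[k] else np.nan) for k, v in self.values.items()}
        )


def _check_inputs(image: ImageSlice, mask: SegmentationMask):
    if not mask.matches_geometry(image):
        raise ValueError("mask geometry does not match the image")
    if mask.n_pixels == 0:
        raise ValueError("mask is empty; nothing to extract")


def discretize(
    image: ImageSlice,
    mask: SegmentationMask,
    settings: ExtractionSettings | None = None,
) -> DiscretizedRegion:
    """Fixed-bin-width discretization anchored at the masked minimum."""
    settings = settings or ExtractionSettings()
    _check_inputs(image, mask)
    disc = engine.discretize_stack(
        image.pixels[None], mask.mask[None], settings.bin_width
    )
    return DiscretizedRegion(
        levels=disc.levels[0],
        mask=disc.mask[0],
        ng=int(disc.ng[0]),
        n_pixels=int(disc.counts[0]),
        pixel_area_mm2=image.pixel_area_mm2,
        slice_thickness_mm=image.slice_thickness_mm,
    )


def _select_class(result: engine.BatchResult, cls: str) -> "OrderedDict[str, float]":
    out: "OrderedDict[str, float]" = OrderedDict()
    for name in CLASS_FEATURES[cls]:
        full = f"{cls}_{name}"
        v = float(result.values[full][0])
        out[full] = v if result.valid[full][0] else float("nan")
    return out


def first_order(
    image: ImageSlice,
    mask: SegmentationMask,
    settings: ExtractionSettings | None = None,
) -> "OrderedDict[str, float]":
    """The 18 first-order intensity statistics (undefined entries are NaN)."""
    settings = settings or ExtractionSettings()
    _check_inputs(image, mask)
    disc = engine.discretize_stack(image.pixels[None], mask.mask[None], settings.bin_width)
    feats = engine._firstorder_batch(
        image.pixels[None].astype(np.float64),
        disc,
        image.pixel_area_mm2,
        image.slice_thickness_mm,
    )
    out: "OrderedDict[str, float]" = OrderedDict()
    for name in CLASS_FEATURES["firstorder"]:
        full = f"firstorder_{name}"
        v, ok = feats[full]
        out[full] = float(v[0]) if ok[0] and np.isfinite(v[0]) else float("nan")
    return out


def _matrix_class(region: DiscretizedRegion, settings, batch_fn, cls: str):
    settings = settings or ExtractionSettings()
    feats = batch_fn(region._as_stack(), settings)
    out: "OrderedDict[str, float]" = OrderedDict()
    for name in CLASS_FEATURES[cls]:
        full = f"{cls}_{name}"
        v, ok = feats[full]
        out[full] = float(v[0]) if ok[0] and np.isfinite(v[0]) else float("nan")
    return out


def glcm_features(region: DiscretizedRegion, settings: ExtractionSettings | None = None):
    """24 gray level co-occurrence features, averaged over in-plane angles."""
    return _matrix_class(region, settings, engine._glcm_batch, "glcm")


def glrlm_features(region: DiscretizedRegion, settings: ExtractionSettings | None = None):
    """16 gray level run-length features, averaged over in-plane angles."""
    return _matrix_class(region, settings, engine._glrlm_batch, "glrlm")


def glszm_features(region: DiscretizedRegion, settings: ExtractionSettings | None = None):
    """16 gray level size-zone features (orientation-free)."""
    return _matrix_class(region, settings, engine._glszm_batch, "glszm")


def gldm_features(region: DiscretizedRegion, settings: ExtractionSettings | None = None):
    """14 gray level dependence features."""
    return _matrix_class(region, settings, engine._gldm_batch, "gldm")


def ngtdm_features(region: DiscretizedRegion, settings: ExtractionSettings | None = None):
    """5 neighboring gray tone difference features."""
    return _matrix_class(region, settings, engine._ngtdm_batch, "ngtdm")


def extract_all(
    image: ImageSlice,
    mask: SegmentationMask,
    settings: ExtractionSettings | None = None,
) -> FeatureVector:
    """Extract the full 93-feature vector from one masked region."""
    settings = settings or ExtractionSettings()
    _check_inputs(image, mask)
    result = engine.extract_stack(
        image.pixels[None],
        mask.mask[None],
        image.pixel_area_mm2,
        image.slice_thickness_mm,
        settings,
    )
    values: "OrderedDict[str, float]" = OrderedDict()
    valid: "OrderedDict[str, bool]" = OrderedDict()
    for name in ALL_FEATURES:
        values[name] = float(result.values[name][0])
        valid[name] = bool(result.valid[name][0])
    return FeatureVector(values=values, valid=valid)
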