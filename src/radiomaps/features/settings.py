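"""Extraction settings shared by conventional extraction and feature maps."""

from __future__ import annotations

from dataclasses import dataclass

#: Unit direction offsets (row, col) for the four in-plane angles
#: 0°, 45°, 90°, 135° (sign is irrelevant for symmetric co-occurrence).
ANGLES_2D = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass(frozen=True)
class ExtractionSettings:
    """Settings of the gray-level discretization and texture matrices.

    bin_width
        Fixed intensity bin width for discretization, anchored at the masked
        minimum.  Default 25 intensity units.
    glcm_distance
        Pixel offset distance for co-occurrence pairs (default 1).
    angles_2d
        In-plane unit direction offsets; co-occurrence and run-length
        statistics are computed per angle and averaged.
    connectivity
        Neighborhood for zone/dependence/gray-tone statistics: 8
        (Chebyshev distance 1, default) or 4 (edge-sharing only).
    symmetric_glcm
        Count each co-occurrence pair in both directions (default True).
    gldm_alpha
        Gray-level difference tolerance for dependence counting (default 0:
        neighbors must share the exact discretized level).
    """

    bin_width: float = 25.0
    glcm_distance: int = 1
    angles_2d: tuple[tuple[int, int], ...] = ANGLES_2D
    connectivity: int = 8
    symmetric_glcm: bool = True
    gldm_alpha: float = 0.0

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")
        if len(self.angles_2d) == 0:
            raise ValueError("angle set must be non-empty")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.gldm_alpha < 0:
            raise ValueError("gldm_alpha must be >= 0")

    @property
    def neighbor_offsets(self) -> tuple[tuple[int, int], ...]:
        if self.connectivity == 8:
            return tuple(
                (dr, dc)
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)
            )
        return ((-1, 0), (1, 0), (0, -1), (0, 1))
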