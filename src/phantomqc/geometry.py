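"""Pixel-space geometry primitives.

Convention: 0-based (row, col) indices, origin at the top-left corner,
row index increases downward.  Physical lengths are converted to pixels
through the image pixel spacing (mm/px).  Angles are in degrees,
clockwise-positive when looking at the image with rows running down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

Segment = tuple[tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangular pixel region, half-open [row0, row0+height)."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise GeometryError(f"Rect must have positive extent, got {self}")

    @property
    def row1(self) -> int:
        return self.row0 + self.height

    @property
    def col1(self) -> int:
        return self.col0 + self.width

    @property
    def center(self) -> tuple[float, float]:
        return (self.row0 + (self.height - 1) / 2.0, self.col0 + (self.width - 1) / 2.0)

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        if not self.inside((pixels.shape[0], pixels.shape[1])):
            raise GeometryError(f"{self} is outside image of shape {pixels.shape}")
        rs, cs = self.slices()
        return pixels[rs, cs]

    def inside(self, shape: tuple[int, int]) -> bool:
        return self.row0 >= 0 and self.col0 >= 0 and self.row1 <= shape[0] and self.col1 <= shape[1]

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.row1 <= other.row0
            or other.row1 <= self.row0
            or self.col1 <= other.col0
            or other.col1 <= self.col0
        )

    def translated(self, drow: int, dcol: int) -> "Rect":
        return Rect(self.row0 + drow, self.col0 + dcol, self.height, self.width)

    @staticmethod
    def centered_at(center_rc: tuple[float, float], height: int, width: int) -> "Rect":
        r0 = int(round(center_rc[0] - (height - 1) / 2.0))
        c0 = int(round(center_rc[1] - (width - 1) / 2.0))
        return Rect(r0, c0, height, width)


@dataclass(frozen=True)
class OrientedSquare:
    """Square of side ``side_px`` centred at ``center_rc``, rotated by
    ``angle_deg`` (clockwise positive) relative to the pixel rows/cols."""

    center_rc: tuple[float, float]
    side_px: float
    angle_deg: float

    def corners(self) -> np.ndarray:
        """4x2 array of (row, col) corners in order TL, TR, BR, BL (pre-rotation)."""
        h = self.side_px / 2.0
        base = np.array([[-h, -h], [-h, h], [h, h], [h, -h]], dtype=float)
        th = math.radians(self.angle_deg)
        # clockwise rotation in (row, col) with row pointing down
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        return base @ rot.T + np.asarray(self.center_rc, dtype=float)

    def edge_segments(self) -> dict[str, Segment]:
        """Four edges keyed by their nominal orientation on the plate."""
        tl, tr, br, bl = self.corners()
        return {
            "top": (tuple(tl), tuple(tr)),
            "right": (tuple(tr), tuple(br)),
            "bottom": (tuple(bl), tuple(br)),
            "left": (tuple(tl), tuple(bl)),
        }

    def bounding_rect(self, margin_px: int = 0) -> Rect:
        c = self.corners()
        r0 = int(math.floor(c[:, 0].min())) - margin_px
        c0 = int(math.floor(c[:, 1].min())) - margin_px
        r1 = int(math.ceil(c[:, 0].max())) + margin_px
        c1 = int(math.ceil(c[:, 1].max())) + margin_px
        return Rect(r0, c0, r1 - r0, c1 - c0)

    def translated(self, drow: float, dcol: float) -> "OrientedSquare":
        return OrientedSquare(
            (self.center_rc[0] + drow, self.center_rc[1] + dcol), self.side_px, self.angle_deg
        )


def mm_to_px(length_mm: float, pixel_spacing_mm: float) -> float:
    return length_mm / pixel_spacing_mm


def px_to_mm(length_px: float, pixel_spacing_mm: float) -> float:
    return length_px * pixel_spacing_mm
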