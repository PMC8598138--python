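"""Normalized local-variance map for artifact and nonuniformity detection.

The image is tiled (non-overlapping) into kernel-sized blocks of nominally
2 x 2 mm; each block's sample variance is divided by the variance of the
detrended homogeneous (NNPS) region.  On artifact-free noise the map sits
at ~1; dead pixels/lines and blobs stand out as connected groups of
elevated blocks.  Rendering uses a green -> red ramp clipped to a
user-set display range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import MetricDomainError
from .geometry import Rect
from .image_io import PhantomImage
from .roi_locator import RoiSet
from .spatial_frequency import detrend_region

KERNEL_MM = 2.0
DEFAULT_DEFECT_THRESHOLD = 5.0


@dataclass(frozen=True)
class VarianceMap:
    values: np.ndarray          # block grid of variance ratios; NaN where masked
    kernel_px: int
    kernel_mm: tuple[float, float]
    normalization_variance: float
    display_range: tuple[float, float] = (0.0, 3.0)
    mask: np.ndarray = field(default=None, repr=False)  # True where excluded

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class DefectRegion:
    centroid_block: tuple[float, float]
    centroid_px: tuple[float, float]
    n_blocks: int
    peak_value: float
    bbox_blocks: tuple[int, int, int, int]  # row0, col0, row1, col1 (exclusive)


def compute_variance_map(image: PhantomImage, roiset: RoiSet | None = None,
                         normalization_variance: float | None = None,
                         display_range: tuple[float, float] = (0.0, 3.0)
                         ) -> VarianceMap:
    """Tile the image into ~2 mm blocks of per-block variance over the
    detrended-NNPS-region variance; blocks touching the targets are masked."""
    px = np.asarray(image.pixels, dtype=float)
    p = float(image.pixel_spacing_mm[0])
    k = max(2, int(round(KERNEL_MM / p)))

    if normalization_variance is None:
        if roiset is None:
            raise ValueError("either roiset or normalization_variance is required")
        region = roiset.nnps_region.extract(px)
        normalization_variance = float(detrend_region(region).std(ddof=1) ** 2)
    if normalization_variance <= 0:
        raise MetricDomainError(
            "variance map undefined: normalization variance is zero (constant image)")

    n_rows, n_cols = px.shape[0] // k, px.shape[1] // k
    trimmed = px[: n_rows * k, : n_cols * k]
    blocks = trimmed.reshape(n_rows, k, n_cols, k)
    # sample variance (ddof=1) per block
    mean = blocks.mean(axis=(1, 3), keepdims=True)
    var = ((blocks - mean) ** 2).sum(axis=(1, 3)) / (k * k - 1)
    values = var / normalization_variance

    mask = np.zeros(values.shape, dtype=bool)
    if roiset is not None:
        for rect in (roiset.cu_square.bounding_rect(margin_px=k),
                     _inflate(roiset.al_roi, 3 * k),
                     _inflate(roiset.background_roi, k)):
            b_r0 = max(rect.row0 // k, 0)
            b_c0 = max(rect.col0 // k, 0)
            b_r1 = min(-(-rect.row1 // k), n_rows)
            b_c1 = min(-(-rect.col1 // k), n_cols)
            if b_r1 > b_r0 and b_c1 > b_c0:
                mask[b_r0:b_r1, b_c0:b_c1] = True
    values = values.copy()
    values[mask] = np.nan
    return VarianceMap(values=values, kernel_px=k, kernel_mm=(k * p, k * p),
                       normalization_variance=normalization_variance,
                       display_range=display_range, mask=mask)


def _inflate(rect: Rect, margin: int) -> Rect:
    return Rect(rect.row0 - margin, rect.col0 - margin,
                rect.height + 2 * margin, rect.width + 2 * margin)


def flag_defects(vmap: VarianceMap,
                 threshold: float = DEFAULT_DEFECT_THRESHOLD) -> list[DefectRegion]:
    """Connected components of unmasked blocks above threshold, ranked by
    peak value (descending)."""
    above = np.nan_to_num(vmap.values, nan=-np.inf) > threshold
    labels, n = ndimage.label(above)
    defects: list[DefectRegion] = []
    for idx in range(1, n + 1):
        component = labels == idx
        peak = float(np.nanmax(np.where(component, vmap.values, -np.inf)))
        centroid = ndimage.center_of_mass(component)
        rows, cols = np.nonzero(component)
        defects.append(DefectRegion(
            centroid_block=(float(centroid[0]), float(centroid[1])),
            centroid_px=((centroid[0] + 0.5) * vmap.kernel_px,
                         (centroid[1] + 0.5) * vmap.kernel_px),
            n_blocks=int(component.sum()),
            peak_value=peak,
            bbox_blocks=(int(rows.min()), int(cols.min()),
                         int(rows.max()) + 1, int(cols.max()) + 1)))
    defects.sort(key=lambda d: (-d.peak_value, d.centroid_block))
    return defects


def match_defects(previous: list[DefectRegion], current: list[DefectRegion],
                  max_distance_blocks: float = 1.0
                  ) -> list[tuple[DefectRegion, DefectRegion]]:
    """Pair defects across two sessions by centroid distance (persistence
    check: the same flaw shows up in the same place)."""
    matched: list[tuple[DefectRegion, DefectRegion]] = []
    used: set[int] = set()
    for prev in previous:
        best_j, best_d = None, max_distance_blocks
        for j, cur in enumerate(current):
            if j in used:
                continue
            d = float(np.hypot(prev.centroid_block[0] - cur.centroid_block[0],
                               prev.centroid_block[1] - cur.centroid_block[1]))
            if d <= best_d:
                best_j, best_d = j, d
        if best_j is not None:
            used.add(best_j)
            matched.append((prev, current[best_j]))
    return matched


def render_variance_map(vmap: VarianceMap, path,
                        display_range: tuple[float, float] | None = None,
                        upscale: int = 4) -> None:
    """Write a green (minimum) -> red (maximum) PNG, values clipped to the
    display range; deterministic byte-for-byte for fixed input."""
    lo, hi = display_range if display_range is not None else vmap.display_range
    if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
        raise ValueError(f"display range must be finite with hi > lo, got ({lo}, {hi})")
    vals = np.nan_to_num(vmap.values, nan=lo)
    t = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    # green -> yellow -> red ramp
    r = np.clip(2.0 * t, 0.0, 1.0)
    g = np.clip(2.0 * (1.0 - t), 0.0, 1.0)
    rgb = np.stack([np.rint(255 * r), np.rint(255 * g), np.zeros_like(t)],
                   axis=-1).astype(np.uint8)
    if vmap.mask is not None:
        rgb[vmap.mask] = (80, 80, 80)  # masked target blocks in grey
    if upscale > 1:
        rgb = np.repeat(np.repeat(rgb, upscale, axis=0), upscale, axis=1)
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")


def write_defect_csv(defects: list[DefectRegion], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["block_row", "block_col", "centroid_row_px",
                         "centroid_col_px", "n_blocks", "peak_value"])
        for d in defects:
            writer.writerow([f"{d.centroid_block[0]:.2f}", f"{d.centroid_block[1]:.2f}",
                             f"{d.centroid_px[0]:.1f}", f"{d.centroid_px[1]:.1f}",
                             d.n_blocks, repr(d.peak_value)])
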