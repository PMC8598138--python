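"""Automatic placement of analysis regions on a phantom image.

The copper square is segmented by Otsu thresholding and connected-component
analysis, the aluminium square by a matched box filter in a window placed
relative to the found copper square, the noise (NNPS) region greedily at
maximal distance from both targets.  Everything is deterministic and
translation-equivariant; a failed search raises
:class:`~phantomqc.errors.LocalizationError` so the caller can fall back to
manual coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import GeometryError, LocalizationError
from .geometry import OrientedSquare, Rect, Segment, mm_to_px
from .image_io import PhantomImage

ROI_SIDE_MM = 5.0          # analysis ROI size used for SDNR / SNR
BACKGROUND_OFFSET_MM = 10.0  # background ROI centre distance from the Al square edge
NNPS_SIDE_PX = 512
NNPS_MIN_SIDE_PX = 256
NNPS_TARGET_MARGIN_MM = 5.0
ANGLE_RANGE_DEG = (1.0, 7.0)  # outside -> MTF reliability warning


@dataclass(frozen=True)
class RoiSet:
    """Located analysis regions for one phantom image."""

    cu_square: OrientedSquare
    al_roi: Rect
    background_roi: Rect
    nnps_region: Rect
    edge_segments: dict[str, Segment]
    warnings: tuple[str, ...] = field(default=())

    def translated(self, drow: int, dcol: int) -> "RoiSet":
        segs = {k: ((a[0] + drow, a[1] + dcol), (b[0] + drow, b[1] + dcol))
                for k, (a, b) in self.edge_segments.items()}
        return RoiSet(
            cu_square=self.cu_square.translated(drow, dcol),
            al_roi=self.al_roi.translated(drow, dcol),
            background_roi=self.background_roi.translated(drow, dcol),
            nnps_region=self.nnps_region.translated(drow, dcol),
            edge_segments=segs,
            warnings=self.warnings,
        )


def validate_roiset(roiset: RoiSet, image_shape: tuple[int, int],
                    pixel_spacing_mm: float) -> None:
    """Enforce the geometric invariants; raises :class:`GeometryError`."""
    shape = image_shape
    for name, rect in (("al_roi", roiset.al_roi),
                       ("background_roi", roiset.background_roi),
                       ("nnps_region", roiset.nnps_region)):
        if not rect.inside(shape):
            raise GeometryError(f"{name} {rect} lies outside image of shape {shape}")
    if roiset.al_roi.n_pixels != roiset.background_roi.n_pixels:
        raise GeometryError("al_roi and background_roi must have equal pixel counts")
    cu_rect = roiset.cu_square.bounding_rect()
    margin_px = int(math.ceil(mm_to_px(NNPS_TARGET_MARGIN_MM, pixel_spacing_mm)))
    pairs = [("al_roi", roiset.al_roi), ("background_roi", roiset.background_roi)]
    for name, rect in pairs:
        if rect.overlaps(cu_rect):
            raise GeometryError(f"{name} overlaps the Cu square")
    if roiset.al_roi.overlaps(roiset.background_roi):
        raise GeometryError("al_roi overlaps background_roi")
    inflated = [Rect(r.row0 - margin_px, r.col0 - margin_px,
                     r.height + 2 * margin_px, r.width + 2 * margin_px)
                for r in (cu_rect, _al_square_rect(roiset, pixel_spacing_mm))]
    for r in inflated:
        if roiset.nnps_region.overlaps(r):
            raise GeometryError(
                f"nnps_region must keep a {NNPS_TARGET_MARGIN_MM} mm margin from targets")


def _al_square_rect(roiset: RoiSet, pixel_spacing_mm: float) -> Rect:
    # the al_roi sits centred on the Al square; inflate to a conservative
    # square-target footprint (2x the ROI) for margin checks
    c = roiset.al_roi.center
    side = roiset.al_roi.height * 2
    return Rect.centered_at(c, side, side)


# ---------------------------------------------------------------------------
# construction shared by the simulator's ground truth and the locator


def build_roiset(image_shape: tuple[int, int], pixel_spacing_mm: float,
                 cu_square: OrientedSquare, al_center_rc: tuple[float, float],
                 al_side_px: float, warnings: tuple[str, ...] = ()) -> RoiSet:
    """Derive the analysis regions from the two target positions."""
    roi_px = max(5, int(round(mm_to_px(ROI_SIDE_MM, pixel_spacing_mm))))
    al_roi = Rect.centered_at(al_center_rc, roi_px, roi_px)

    offset_px = mm_to_px(BACKGROUND_OFFSET_MM, pixel_spacing_mm) + al_side_px / 2.0
    cu_rect = cu_square.bounding_rect(margin_px=2)
    bg_roi = None
    for direction in (+1, -1):  # prefer to the right of the Al square
        cand = Rect.centered_at((al_center_rc[0], al_center_rc[1] + direction * offset_px),
                                roi_px, roi_px)
        if cand.inside(image_shape) and not cand.overlaps(cu_rect):
            bg_roi = cand
            break
    if bg_roi is None:
        raise LocalizationError("no valid background ROI position beside the Al square")

    nnps, nnps_warnings = _place_nnps_region(image_shape, pixel_spacing_mm, cu_square,
                                             al_center_rc, al_side_px)
    roiset = RoiSet(cu_square=cu_square, al_roi=al_roi, background_roi=bg_roi,
                    nnps_region=nnps, edge_segments=cu_square.edge_segments(),
                    warnings=tuple(warnings) + nnps_warnings)
    validate_roiset(roiset, image_shape, pixel_spacing_mm)
    return roiset


def _place_nnps_region(image_shape, pixel_spacing_mm, cu_square, al_center_rc,
                       al_side_px) -> tuple[Rect, tuple[str, ...]]:
    margin_px = int(math.ceil(mm_to_px(NNPS_TARGET_MARGIN_MM, pixel_spacing_mm)))
    cu_rect = cu_square.bounding_rect(margin_px=margin_px)
    al_half = int(math.ceil(al_side_px / 2.0)) + margin_px
    al_rect = Rect.centered_at(al_center_rc, 2 * al_half, 2 * al_half)
    warnings: list[str] = []

    sizes = [NNPS_SIDE_PX]
    side = 1 << (max(min(image_shape) - 2, 2).bit_length() - 1)
    while side >= NNPS_MIN_SIDE_PX:
        if side < NNPS_SIDE_PX and side not in sizes:
            sizes.append(side)
        side //= 2

    targets = [np.asarray(cu_square.center_rc), np.asarray(al_center_rc)]
    for size in sizes:
        best: tuple[float, int, int] | None = None
        max_r0 = image_shape[0] - size
        max_c0 = image_shape[1] - size
        if max_r0 < 0 or max_c0 < 0:
            continue
        stride = max(8, size // 32)
        rows = sorted(set(list(range(0, max_r0 + 1, stride)) + [max_r0]))
        cols = sorted(set(list(range(0, max_c0 + 1, stride)) + [max_c0]))
        for r0 in rows:
            for c0 in cols:
                cand = Rect(r0, c0, size, size)
                if cand.overlaps(cu_rect) or cand.overlaps(al_rect):
                    continue
                center = np.asarray(cand.center)
                score = min(float(np.hypot(*(center - t))) for t in targets)
                key = (-score, r0, c0)
                if best is None or key < (-best[0], best[1], best[2]):
                    best = (score, r0, c0)
        if best is not None:
            if size < NNPS_SIDE_PX:
                warnings.append(
                    f"nnps_region shrunk to {size}x{size} px (image too small for "
                    f"{NNPS_SIDE_PX}x{NNPS_SIDE_PX})")
            return Rect(best[1], best[2], size, size), tuple(warnings)
    raise LocalizationError(
        "no homogeneous region of at least "
        f"{NNPS_MIN_SIDE_PX}x{NNPS_MIN_SIDE_PX} px clears the targets")


# ---------------------------------------------------------------------------
# automatic localization


def _fit_left_edge_angle(mask: np.ndarray) -> float:
    """Angle (deg, clockwise positive) of the left edge of a filled square mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    trim = max(2, int(0.1 * len(rows)))
    rows = rows[trim:-trim]
    cols = np.array([np.flatnonzero(mask[r])[0] for r in rows], dtype=float)
    coef = np.polyfit(rows, cols, 1)
    resid = cols - np.polyval(coef, rows)
    keep = np.abs(resid) <= max(3.0, 3 * resid.std())
    if keep.sum() >= 10:
        coef = np.polyfit(rows[keep], cols[keep], 1)
    return math.degrees(math.atan(coef[0]))


def locate_rois(image: PhantomImage, spec) -> RoiSet:
    """Locate Cu square, Al square, background ROI and NNPS region.

    ``spec`` is a :class:`~phantomqc.phantom_sim.PhantomSpec`-like object
    providing the expected geometry (sides in mm, fractional positions).
    """
    px = np.asarray(image.pixels, dtype=float)
    spacing = float(image.pixel_spacing_mm[0])
    shape = px.shape
    warnings: list[str] = []

    cu_side_px = mm_to_px(spec.cu_square_side_mm, spacing)
    al_side_px = mm_to_px(spec.al_square_side_mm, spacing)
    expected_area = cu_side_px ** 2

    try:
        thresh = threshold_otsu(px)
    except ValueError as exc:
        raise LocalizationError(f"cannot threshold image: {exc}") from exc
    dark = px < thresh
    labels, n_labels = ndimage.label(dark)
    if n_labels == 0:
        raise LocalizationError("no high-contrast target candidate found")

    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_labels + 1))
    candidates = [i + 1 for i, a in enumerate(areas)
                  if 0.25 * expected_area <= a <= 4.0 * expected_area]
    if not candidates:
        raise LocalizationError(
            "no connected component matches the expected Cu square size; "
            "place ROIs manually")
    centroids = ndimage.center_of_mass(dark, labels, candidates)
    expected_cu = (spec.cu_center_frac[0] * shape[0], spec.cu_center_frac[1] * shape[1])
    order = sorted(range(len(candidates)),
                   key=lambda i: float(np.hypot(centroids[i][0] - expected_cu[0],
                                                centroids[i][1] - expected_cu[1])))
    label_id = candidates[order[0]]
    cu_mask = labels == label_id
    cu_center = ndimage.center_of_mass(cu_mask)
    side_est = math.sqrt(float(cu_mask.sum()))
    angle = _fit_left_edge_angle(cu_mask)
    if not (ANGLE_RANGE_DEG[0] <= abs(angle) <= ANGLE_RANGE_DEG[1]):
        warnings.append(
            f"Cu edge angle {angle:.2f} deg outside [{ANGLE_RANGE_DEG[0]:g}, "
            f"{ANGLE_RANGE_DEG[1]:g}] deg; MTF reliability reduced")
    cu_square = OrientedSquare(center_rc=(float(cu_center[0]), float(cu_center[1])),
                               side_px=side_est, angle_deg=angle)

    # Al square: matched box filter in a window placed relative to the found
    # Cu centre, preserving translation equivariance.
    rel = ((spec.al_center_frac[0] - spec.cu_center_frac[0]) * shape[0],
           (spec.al_center_frac[1] - spec.cu_center_frac[1]) * shape[1])
    al_expected = (cu_square.center_rc[0] + rel[0], cu_square.center_rc[1] + rel[1])
    box = max(3, int(round(al_side_px)))
    half_win = int(round(max(mm_to_px(15.0, spacing), 1.5 * al_side_px)))
    r0 = max(box, int(al_expected[0]) - half_win)
    r1 = min(shape[0] - box, int(al_expected[0]) + half_win)
    c0 = max(box, int(al_expected[1]) - half_win)
    c1 = min(shape[1] - box, int(al_expected[1]) + half_win)
    if r1 <= r0 or c1 <= c0:
        raise LocalizationError("Al search window lies outside the image")
    means = ndimage.uniform_filter(px, size=box, mode="nearest")
    window = means[r0:r1, c0:c1].copy()
    win_cu = cu_square.bounding_rect(margin_px=2)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside_cu = ((rr >= win_cu.row0) & (rr < win_cu.row1)
                 & (cc >= win_cu.col0) & (cc < win_cu.col1))
    window[inside_cu] = np.inf
    flat = int(np.argmin(window))
    al_center = (r0 + flat // window.shape[1], c0 + flat % window.shape[1])
    # local background reference: the window median is robust to both the
    # Al square itself and any planar gradient across the image
    bg_level = np.median(window[np.isfinite(window)])
    depth = bg_level - window.flat[flat]
    noise_sd = float(px[max(0, r0 - box):r0 + box, c0:c1].std()) if r0 >= box else float(px.std())
    if depth <= 4.0 * noise_sd / box:
        raise LocalizationError("no low-contrast Al square found in the search window")

    return build_roiset(shape, spacing, cu_square,
                        (float(al_center[0]), float(al_center[1])),
                        al_side_px, warnings=tuple(warnings))


def override_rois(roiset: RoiSet, image_shape: tuple[int, int],
                  pixel_spacing_mm: float, **edits) -> RoiSet:
    """Return a copy with the given fields replaced, revalidated.

    Accepted keys: ``cu_square``, ``al_roi``, ``background_roi``,
    ``nnps_region``.  An edit that breaks an invariant raises
    :class:`GeometryError` and leaves the input untouched.
    """
    allowed = {"cu_square", "al_roi", "background_roi", "nnps_region"}
    unknown = set(edits) - allowed
    if unknown:
        raise ValueError(f"unknown ROI fields: {sorted(unknown)}")
    if not edits:
        return roiset
    merged = replace(roiset, **edits)
    if "cu_square" in edits:
        merged = replace(merged, edge_segments=merged.cu_square.edge_segments())
    validate_roiset(merged, image_shape, pixel_spacing_mm)
    return merged
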