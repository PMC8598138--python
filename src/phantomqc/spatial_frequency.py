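"""Slanted-edge presampled MTF and detrended NNPS on a common frequency grid.

MTF pipeline: per-line subpixel edge crossings -> least-squares edge angle
-> projection of a pixel band onto the edge normal -> 0.1-pixel binned
oversampled ESF -> centred finite-difference LSF -> Hann window centred on
the LSF peak -> DFT magnitude normalised at zero frequency.

NNPS pipeline: 3x3 half-overlapping square ROIs taken from the homogeneous
region after two-pass linear detrending; NPS(u,v) = p_x p_y / (N_x N_y) *
<|DFT(ROI - mean)|^2>; NNPS = NPS / large-area-mean^2.  One-dimensional
cuts average the three lines adjacent to (but excluding) each
zero-frequency axis; a radial average is also provided.  The NNPS grid is
the common grid onto which MTF curves are interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, MetricDomainError
from .geometry import Segment
from .image_io import PhantomImage

ESF_BIN_PITCH_PX = 0.1
DEFAULT_BAND_HALFWIDTH_PX = 40
ANGLE_VALID_RANGE_DEG = (1.0, 7.0)
EDGE_FIT_RESIDUAL_WARN_PX = 1.0


@dataclass(frozen=True)
class MtfCurve:
    frequencies: np.ndarray  # cycles/mm, ascending from 0
    values: np.ndarray
    direction: str  # horizontal | vertical | averaged
    edge_angle_deg: float | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.frequencies.shape != self.values.shape:
            raise ValueError("frequencies and values must have equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def at(self, frequencies: np.ndarray) -> np.ndarray:
        return np.interp(frequencies, self.frequencies, self.values)


@dataclass(frozen=True)
class NnpsCurve:
    frequencies: np.ndarray  # cycles/mm
    values: np.ndarray       # mm^2
    direction: str           # horizontal | vertical | radial | averaged
    large_area_mean: float
    large_area_variance: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))


@dataclass(frozen=True)
class NnpsResult:
    """Directional and radial NNPS cuts plus the full 2-D spectrum."""

    horizontal: NnpsCurve
    vertical: NnpsCurve
    radial: NnpsCurve
    averaged: NnpsCurve
    nnps_2d: np.ndarray = field(repr=False)
    freq_step: float = 0.0


@dataclass(frozen=True)
class CharacteristicFrequencies:
    """First downward crossings of the 50/20/10 % MTF levels (cycles/mm),
    absent (None) when the level is not crossed below Nyquist."""

    f50: float | None
    f20: float | None
    f10: float | None


@dataclass(frozen=True)
class EdgeAngleEstimate:
    degrees: float
    residual_rms_px: float
    n_lines: int
    warnings: tuple[str, ...] = ()

    def __float__(self) -> float:
        return self.degrees


@dataclass(frozen=True)
class EsfProfile:
    """Oversampled edge spread function, ordered low -> high signal."""

    positions_px: np.ndarray  # distance along the edge normal, native px
    values: np.ndarray
    sample_pitch_px: float = ESF_BIN_PITCH_PX


def _edge_orientation(segment: Segment) -> str:
    (r0, c0), (r1, c1) = segment
    return "vertical" if abs(r1 - r0) >= abs(c1 - c0) else "horizontal"


def _crossings(profile: np.ndarray, lo: float, hi: float) -> float | None:
    """Subpixel index of the 50 % threshold crossing nearest the profile centre."""
    mid = 0.5 * (lo + hi)
    d = profile - mid
    sign_change = np.nonzero(d[:-1] * d[1:] <= 0)[0]
    sign_change = sign_change[d[sign_change] != d[sign_change + 1]]
    if sign_change.size == 0:
        return None
    centre = (len(profile) - 1) / 2.0
    i = sign_change[np.argmin(np.abs(sign_change - centre))]
    frac = d[i] / (d[i] - d[i + 1])
    return float(i + frac)


def estimate_edge_angle(image: PhantomImage, edge_segment: Segment,
                        band_halfwidth_px: int = 12) -> EdgeAngleEstimate:
    """Edge angle from a least-squares line through per-line 50 % crossings.

    Clockwise-positive relative to the pixel rows; mirroring the image flips
    the sign.
    """
    px = np.asarray(image.pixels, dtype=float)
    orient = _edge_orientation(edge_segment)
    if orient == "horizontal":
        (r0, c0), (r1, c1) = edge_segment
        flipped = estimate_edge_angle(
            PhantomImage(pixels=px.T, pixel_spacing_mm=image.pixel_spacing_mm[::-1],
                         modality=image.modality,
                         presentation_state=image.presentation_state,
                         metadata=image.metadata),
            ((c0, r0), (c1, r1)), band_halfwidth_px)
        return replace(flipped, degrees=-flipped.degrees)

    (r0, c0), (r1, c1) = edge_segment
    if r1 < r0:
        r0, c0, r1, c1 = r1, c1, r0, c0
    length = r1 - r0
    margin = max(2.0, 0.05 * length)
    rows = np.arange(int(math.ceil(r0 + margin)), int(math.floor(r1 - margin)) + 1)
    if rows.size < 8:
        raise GeometryError("edge segment too short for an angle fit")
    w = band_halfwidth_px
    crossings = np.full(rows.size, np.nan)
    for k, r in enumerate(rows):
        t = (r - r0) / length if length else 0.5
        c_nom = c0 + t * (c1 - c0)
        lo_c, hi_c = int(round(c_nom)) - w, int(round(c_nom)) + w + 1
        if lo_c < 0 or hi_c > px.shape[1] or r < 0 or r >= px.shape[0]:
            continue
        prof = px[r, lo_c:hi_c]
        a, b = prof[:3].mean(), prof[-3:].mean()
        cross = _crossings(prof, a, b)
        if cross is not None:
            crossings[k] = lo_c + cross
    ok = np.isfinite(crossings)
    if ok.sum() < 8:
        raise GeometryError("too few edge crossings found for an angle fit")
    coef = np.polyfit(rows[ok], crossings[ok], 1)
    resid = crossings[ok] - np.polyval(coef, rows[ok])
    rms = float(np.sqrt(np.mean(resid ** 2)))
    angle = math.degrees(math.atan(coef[0]))
    warnings: list[str] = []
    if rms > EDGE_FIT_RESIDUAL_WARN_PX:
        warnings.append(f"ragged edge: crossing fit residual {rms:.2f} px")
    if not (ANGLE_VALID_RANGE_DEG[0] <= abs(angle) <= ANGLE_VALID_RANGE_DEG[1]):
        warnings.append(
            f"edge angle {angle:.2f} deg outside "
            f"[{ANGLE_VALID_RANGE_DEG[0]:g}, {ANGLE_VALID_RANGE_DEG[1]:g}] deg; "
            "presampled MTF may be unreliable")
    return EdgeAngleEstimate(degrees=angle, residual_rms_px=rms, n_lines=int(ok.sum()),
                             warnings=tuple(warnings))


def build_oversampled_esf(image: PhantomImage, edge_segment: Segment,
                          angle_deg: float,
                          band_halfwidth_px: int = DEFAULT_BAND_HALFWIDTH_PX,
                          bin_pitch_px: float = ESF_BIN_PITCH_PX) -> EsfProfile:
    """Project a band of pixels onto the edge normal and bin at subpixel pitch.

    Empty bins are filled by linear interpolation; the profile is oriented
    to run from the low-signal side to the high-signal side.
    """
    px = np.asarray(image.pixels, dtype=float)
    orient = _edge_orientation(edge_segment)
    if orient == "horizontal":
        (r0, c0), (r1, c1) = edge_segment
        transposed = PhantomImage(
            pixels=px.T, pixel_spacing_mm=image.pixel_spacing_mm[::-1],
            modality=image.modality, presentation_state=image.presentation_state,
            metadata=image.metadata)
        return build_oversampled_esf(transposed, ((c0, r0), (c1, r1)), -angle_deg,
                                     band_halfwidth_px, bin_pitch_px)

    (r0, c0), (r1, c1) = edge_segment
    if r1 < r0:
        r0, c0, r1, c1 = r1, c1, r0, c0
    # trim enough of the segment ends that blur bleeding around the square's
    # corners cannot contaminate the ESF tails (scales with the band width)
    margin = max(2.0, 0.05 * (r1 - r0), 0.5 * band_halfwidth_px)
    row_lo = int(math.ceil(r0 + margin))
    row_hi = int(math.floor(r1 - margin))
    if row_hi - row_lo < 8:
        raise GeometryError("edge segment too short to build an ESF")
    tan_th = math.tan(math.radians(angle_deg))
    cos_th = math.cos(math.radians(angle_deg))
    r_mid = 0.5 * (r0 + r1)
    c_mid = 0.5 * (c0 + c1)

    rows = np.arange(row_lo, row_hi + 1)
    c_line = c_mid + tan_th * (rows - r_mid)
    col_lo = int(math.floor(c_line.min() - band_halfwidth_px / cos_th)) - 1
    col_hi = int(math.ceil(c_line.max() + band_halfwidth_px / cos_th)) + 2
    if row_lo < 0 or row_hi >= px.shape[0] or col_lo < 0 or col_hi > px.shape[1]:
        raise GeometryError("ESF band is clipped by the image border")

    patch = px[row_lo:row_hi + 1, col_lo:col_hi]
    cols = np.arange(col_lo, col_hi)
    s = (cols[None, :] - c_line[:, None]) * cos_th  # signed normal distance, px
    keep = np.abs(s) <= band_halfwidth_px
    s_flat = s[keep]
    v_flat = patch[keep]

    bins = np.rint(s_flat / bin_pitch_px).astype(int)
    b0 = bins.min()
    counts = np.bincount(bins - b0)
    sums = np.bincount(bins - b0, weights=v_flat)
    positions = (np.arange(counts.size) + b0) * bin_pitch_px
    filled = counts > 0
    values = np.empty_like(positions)
    values[filled] = sums[filled] / counts[filled]
    if not filled.all():
        values[~filled] = np.interp(positions[~filled], positions[filled], values[filled])

    head = values[: max(3, values.size // 20)].mean()
    tail = values[-max(3, values.size // 20):].mean()
    if head > tail:  # orient low -> high signal
        values = values[::-1]
        positions = -positions[::-1]
    return EsfProfile(positions_px=positions, values=values, sample_pitch_px=bin_pitch_px)


def compute_presampled_mtf(esf: EsfProfile, pixel_spacing_mm: float,
                           direction: str = "horizontal",
                           edge_angle_deg: float | None = None,
                           warnings: tuple[str, ...] = ()) -> MtfCurve:
    """LSF by centred finite difference, Hann window on the LSF peak, DFT
    magnitude normalised at zero frequency, truncated at Nyquist."""
    v = np.asarray(esf.values, dtype=float)
    contrast = abs(v[-5:].mean() - v[:5].mean())
    scale = max(abs(v).max(), 1.0)
    if contrast < 1e-9 * scale:
        raise MetricDomainError("zero-contrast edge: no edge signal to transform")
    ds_mm = esf.sample_pitch_px * pixel_spacing_mm
    lsf = np.gradient(v, ds_mm)
    # locate the peak on a one-native-pixel boxcar smooth so a noisy tail bin
    # cannot hijack the window centre; the window is applied to the raw LSF
    k = max(1, int(round(1.0 / esf.sample_pitch_px)))
    smooth = np.convolve(np.abs(lsf), np.ones(k) / k, mode="same")
    peak = int(np.argmax(smooth))
    halfw = min(peak, lsf.size - 1 - peak)
    if halfw < 8:
        raise MetricDomainError("LSF peak too close to the profile end")
    window = np.zeros_like(lsf)
    idx = np.arange(peak - halfw, peak + halfw + 1)
    window[idx] = 0.5 * (1.0 + np.cos(math.pi * (idx - peak) / halfw))
    spectrum = np.abs(np.fft.rfft(lsf * window))
    if spectrum[0] == 0:
        raise MetricDomainError("zero-contrast edge: no edge signal to transform")
    freqs = np.fft.rfftfreq(lsf.size, d=ds_mm)
    values = spectrum / spectrum[0]
    nyquist = 1.0 / (2.0 * pixel_spacing_mm)
    keep = freqs <= nyquist * (1 + 1e-12)
    return MtfCurve(frequencies=freqs[keep], values=values[keep], direction=direction,
                    edge_angle_deg=edge_angle_deg, warnings=tuple(warnings))


def characteristic_frequencies(mtf: MtfCurve,
                               levels: tuple[float, ...] = (0.5, 0.2, 0.1)
                               ) -> CharacteristicFrequencies:
    out: list[float | None] = []
    f, v = mtf.frequencies, mtf.values
    for level in levels:
        below = np.nonzero(v < level)[0]
        below = below[below > 0]
        crossing: float | None = None
        for i in below:
            if v[i - 1] >= level:
                frac = (v[i - 1] - level) / (v[i - 1] - v[i])
                crossing = float(f[i - 1] + frac * (f[i] - f[i - 1]))
                break
        out.append(crossing)
    return CharacteristicFrequencies(f50=out[0], f20=out[1], f10=out[2])


def detrend_region(region: np.ndarray) -> np.ndarray:
    """Remove a least-squares linear ramp along columns, then along rows,
    restoring the original mean (level is kept, gradient removed)."""
    z = np.asarray(region, dtype=float)
    mean0 = z.mean()
    cols = np.arange(z.shape[1], dtype=float)
    slope, intercept = np.polyfit(cols, z.mean(axis=0), 1)
    z = z - (slope * cols + intercept)[None, :]
    rows = np.arange(z.shape[0], dtype=float)
    slope, intercept = np.polyfit(rows, z.mean(axis=1), 1)
    z = z - (slope * rows + intercept)[:, None]
    return z + mean0


def compute_nnps(region: np.ndarray, pixel_spacing_mm: float,
                 detrend: bool = True, n_cut_lines: int = 3) -> NnpsResult:
    """NNPS from 3x3 half-overlapping ROIs of a square homogeneous region."""
    z = np.asarray(region, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("NNPS region must be a square 2-D array")
    n_region = z.shape[0]
    roi = n_region // 2
    if roi < 32:
        raise ValueError(f"region of {n_region} px is too small for NNPS")
    mean = float(z.mean())
    if mean <= 0:
        raise MetricDomainError("NNPS undefined: region mean is not positive")
    work = detrend_region(z) if detrend else z
    variance = float(work.std(ddof=1) ** 2)

    p = pixel_spacing_mm
    step = roi // 2
    acc = np.zeros((roi, roi))
    for i in range(3):
        for j in range(3):
            tile = work[i * step:i * step + roi, j * step:j * step + roi]
            tile = tile - tile.mean()
            acc += np.abs(np.fft.fft2(tile)) ** 2
    nps_2d = (p * p / (roi * roi)) * acc / 9.0
    nnps_2d = nps_2d / mean ** 2

    df = 1.0 / (roi * p)
    n_half = roi // 2
    freqs = np.arange(n_half + 1) * df

    lines = np.concatenate([np.arange(1, n_cut_lines + 1),
                            np.arange(-n_cut_lines, 0)])
    horiz = nnps_2d[lines, :][:, :n_half + 1].mean(axis=0)
    vert = nnps_2d[:, lines][:n_half + 1, :].mean(axis=1)

    fu = np.fft.fftfreq(roi, d=p)
    radius = np.hypot(fu[:, None], fu[None, :])
    rbin = np.rint(radius / df).astype(int)
    keep = rbin <= n_half
    sums = np.bincount(rbin[keep], weights=nnps_2d[keep], minlength=n_half + 1)
    counts = np.bincount(rbin[keep], minlength=n_half + 1)
    radial = sums / np.maximum(counts, 1)

    def curve(vals, direction):
        return NnpsCurve(frequencies=freqs, values=vals, direction=direction,
                         large_area_mean=mean, large_area_variance=variance)

    return NnpsResult(horizontal=curve(horiz, "horizontal"),
                      vertical=curve(vert, "vertical"),
                      radial=curve(radial, "radial"),
                      averaged=curve(0.5 * (horiz + vert), "averaged"),
                      nnps_2d=nnps_2d, freq_step=df)


def common_grid(mtf: MtfCurve, nnps: NnpsCurve) -> tuple[MtfCurve, NnpsCurve]:
    """Evaluate the MTF on the NNPS frequency grid (the common grid)."""
    values = np.interp(nnps.frequencies, mtf.frequencies, mtf.values)
    resampled = MtfCurve(frequencies=nnps.frequencies.copy(), values=values,
                         direction=mtf.direction, edge_angle_deg=mtf.edge_angle_deg,
                         warnings=mtf.warnings)
    return resampled, nnps


def average_curves(a: MtfCurve, b: MtfCurve) -> MtfCurve:
    """Average two directional MTFs sampled on the same grid."""
    if not np.allclose(a.frequencies, b.frequencies):
        raise ValueError("curves must share a frequency grid; use common_grid first")
    return MtfCurve(frequencies=a.frequencies.copy(),
                    values=0.5 * (a.values + b.values), direction="averaged",
                    edge_angle_deg=None, warnings=a.warnings + b.warnings)
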