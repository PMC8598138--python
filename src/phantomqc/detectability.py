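"""Non-prewhitening-with-eye-filter (NPWE) detectability index.

d' = 2*pi*C * I1 / sqrt(I2) with
  I1 = int S^2(u) MTF^2(u) VTF^2(u) u du
  I2 = int S^2(u) MTF^2(u) VTF^4(u) NNPS(u) u du,
integrated by the trapezoid rule on [0, Nyquist] over the common frequency
grid.  S is the 2-D Fourier transform of a disk of diameter D; the VTF is a
band-pass eye filter peaking at 4 cycles/degree for the stated viewing
distance.  The eye-filter functional form is isolated in
:func:`visual_transfer_function` so an alternative model is a one-point
change; the ``two_pi_inside_sqrt`` switch covers the alternative reading of
the constant placement in the printed formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import j1

from .errors import MetricDomainError
from .spatial_frequency import MtfCurve, NnpsCurve

VTF_PEAK_CYC_PER_DEG = 4.0
DEFAULT_VIEWING_DISTANCE_MM = 400.0

RADIOGRAPHY_DISK_DIAMETERS_MM = (0.3, 4.0)
MAMMOGRAPHY_DISK_DIAMETERS_MM = (0.1, 0.25)


@dataclass(frozen=True)
class DetectionTask:
    """A disk-detection task: nominal contrast, disk diameter, viewing distance."""

    contrast: float
    disk_diameter_mm: float
    viewing_distance_mm: float = DEFAULT_VIEWING_DISTANCE_MM

    def __post_init__(self) -> None:
        if self.disk_diameter_mm <= 0:
            raise ValueError("disk_diameter_mm must be positive")
        if self.viewing_distance_mm <= 0:
            raise ValueError("viewing_distance_mm must be positive")


def default_disk_diameters(modality: str) -> tuple[float, float]:
    if modality == "mammography":
        return MAMMOGRAPHY_DISK_DIAMETERS_MM
    return RADIOGRAPHY_DISK_DIAMETERS_MM


def disk_shape_function(diameter_mm: float, frequencies: np.ndarray) -> np.ndarray:
    """S(u) = (pi D^2 / 4) * 2 J1(pi D u) / (pi D u), S(0) = disk area."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    u = np.asarray(frequencies, dtype=float)
    area = math.pi * diameter_mm ** 2 / 4.0
    x = math.pi * diameter_mm * u
    out = np.full_like(u, area)
    nz = x != 0
    out[nz] = area * 2.0 * j1(x[nz]) / x[nz]
    return out


def visual_transfer_function(frequencies_cyc_mm: np.ndarray,
                             viewing_distance_mm: float = DEFAULT_VIEWING_DISTANCE_MM
                             ) -> np.ndarray:
    """Band-pass eye filter, unit peak at 4 cycles/degree.

    Spatial frequency u (cycles/mm) maps to angular frequency
    f = u * distance * pi/180 (cycles/degree); VTF(f) = f^1.5 exp(-c f)
    with c = 1.5/4 so the maximum sits at 4 cycles/degree, normalised
    analytically to 1 at the peak.
    """
    if viewing_distance_mm <= 0:
        raise ValueError("viewing distance must be positive")
    u = np.asarray(frequencies_cyc_mm, dtype=float)
    f_deg = u * viewing_distance_mm * math.pi / 180.0
    c = 1.5 / VTF_PEAK_CYC_PER_DEG
    peak = VTF_PEAK_CYC_PER_DEG ** 1.5 * math.exp(-1.5)
    return np.where(f_deg > 0, f_deg ** 1.5 * np.exp(-c * f_deg), 0.0) / peak


def compute_dprime(mtf: MtfCurve, nnps: NnpsCurve, task: DetectionTask,
                   two_pi_inside_sqrt: bool = False) -> float:
    """Evaluate the NPWE detectability index on the curves' common grid."""
    if not np.allclose(mtf.frequencies, nnps.frequencies):
        raise ValueError("MTF and NNPS must be evaluated on the common grid")
    u = mtf.frequencies
    if np.all(nnps.values <= 0):
        raise MetricDomainError("NNPS is identically zero: d' would be infinite")
    s2 = disk_shape_function(task.disk_diameter_mm, u) ** 2
    m2 = mtf.values ** 2
    vtf = visual_transfer_function(u, task.viewing_distance_mm)
    num = np.trapezoid(s2 * m2 * vtf ** 2 * u, u)
    den = np.trapezoid(s2 * m2 * vtf ** 4 * nnps.values * u, u)
    if den <= 0:
        raise MetricDomainError("noise integral is zero: d' would be infinite")
    if two_pi_inside_sqrt:
        return float(2.0 * math.pi * task.contrast * num / math.sqrt(2.0 * math.pi * den))
    return float(2.0 * math.pi * task.contrast * num / math.sqrt(den))
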