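"""ROI statistics, SNR and SDNR.

SDNR = (S_background - S_target) / sigma_background.  SNR is the
conventional large-area ratio S_background / sigma_background (the metric
list names SNR without defining it; the background ROI is used so the
denominator matches the SDNR's).  Sample standard deviations use the n-1
denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MetricDomainError
from .geometry import Rect
from .image_io import PhantomImage


@dataclass(frozen=True)
class RoiStats:
    mean_signal: float
    sd_signal: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.sd_signal < 0:
            raise ValueError("sd_signal must be non-negative")


def roi_stats(image: PhantomImage, region: Rect) -> RoiStats:
    """Arithmetic mean and sample SD (ddof=1) of the region's pixels."""
    values = region.extract(np.asarray(image.pixels, dtype=float))
    return RoiStats(mean_signal=float(values.mean()),
                    sd_signal=float(values.std(ddof=1)),
                    n_pixels=values.size)


def compute_sdnr(background: RoiStats, target: RoiStats) -> float:
    if background.sd_signal <= 0:
        raise MetricDomainError("SDNR undefined: background SD is zero")
    return (background.mean_signal - target.mean_signal) / background.sd_signal


def compute_snr(background: RoiStats) -> float:
    if background.sd_signal <= 0:
        raise MetricDomainError("SNR undefined: background SD is zero")
    return background.mean_signal / background.sd_signal
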