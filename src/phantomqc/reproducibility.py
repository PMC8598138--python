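"""Reproducibility experiments: repeat-analysis and movement-jitter harness.

Mirrors the two desk-scale experiments used to characterise the method:
analysing the same image repeatedly (which must show zero variability), and
re-imaging with small random shifts/rotations between exposures (which shows
which metrics are robust to phantom placement).  The jittered acquisition
includes a per-exposure planar gradient (tube-heel variation with position)
and a serrated Cu edge, the two physical effects that make the simple
metrics placement-sensitive while the detectability index, computed with a
nominal task contrast, stays comparatively stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .image_io import QcRecord
from .phantom_sim import SimulationConfig, desk_config, device_config_for, \
    simulate_phantom_image
from .pipeline import analyze_image

JITTER_METRICS = ["sdnr", "snr", "mtf50_h", "mtf20_h", "mtf10_h",
                  "mtf50_v", "mtf20_v", "mtf10_v", "dprime_small", "dprime_large"]

DEFAULT_EDGE_ROUGHNESS_MM = 0.4
DEFAULT_EDGE_ROUGHNESS_CORR_MM = 0.5
DEFAULT_SHIFT_FRAC = 0.02
DEFAULT_GRADIENT_RANGE = 25.0  # detector units per mm


@dataclass
class JitterResult:
    records: list[QcRecord]
    metric_values: dict[str, list[float]] = field(default_factory=dict)

    def cv_percent(self, metric: str) -> float:
        v = np.asarray(self.metric_values[metric], dtype=float)
        return float(100.0 * v.std(ddof=1) / v.mean())


def repeat_analysis_records(config: SimulationConfig | None = None,
                            n_repeats: int = 5) -> list[QcRecord]:
    """Analyze one fixed simulated image ``n_repeats`` times."""
    config = config if config is not None else desk_config(seed=11)
    image, _ = simulate_phantom_image(config)
    device_cfg = device_config_for(config)
    return [analyze_image(image, device_cfg).record for _ in range(n_repeats)]


def repeat_analysis_cv_percent(records: list[QcRecord],
                               metrics: list[str] | None = None) -> float:
    """Largest coefficient of variation over the exported metrics (percent)."""
    metrics = metrics or JITTER_METRICS
    worst = 0.0
    for metric in metrics:
        values = np.asarray([r.metric(metric) for r in records], dtype=float)
        if np.all(values == values[0]):
            continue  # exactly reproduced: CV is 0 by definition
        if values.mean() != 0:
            worst = max(worst, float(100.0 * values.std(ddof=1)
                                     / abs(values.mean())))
    return worst


def movement_jitter_experiment(n_placements: int = 10, master_seed: int = 1,
                               base_config: SimulationConfig | None = None,
                               shift_frac: float = DEFAULT_SHIFT_FRAC,
                               gradient_range: float = DEFAULT_GRADIENT_RANGE
                               ) -> JitterResult:
    """Simulate ``n_placements`` exposures with small random placement
    changes and analyse each one with the full pipeline."""
    rng = np.random.default_rng(master_seed)
    cfg0 = base_config if base_config is not None else desk_config(
        cu_edge_roughness_mm=DEFAULT_EDGE_ROUGHNESS_MM,
        cu_edge_roughness_corr_mm=DEFAULT_EDGE_ROUGHNESS_CORR_MM)
    records: list[QcRecord] = []
    for _ in range(n_placements):
        dr, dc = rng.uniform(-shift_frac, shift_frac, 2)
        angle = rng.uniform(2.0, 5.0)
        gradient = tuple(rng.uniform(-gradient_range, gradient_range, 2))
        spec = replace(cfg0.spec,
                       cu_center_frac=(cfg0.spec.cu_center_frac[0] + dr,
                                       cfg0.spec.cu_center_frac[1] + dc),
                       al_center_frac=(cfg0.spec.al_center_frac[0] + dr,
                                       cfg0.spec.al_center_frac[1] + dc),
                       cu_edge_angle_deg=angle)
        cfg = replace(cfg0, spec=spec, seed=int(rng.integers(1 << 31)),
                      gradient_slope=gradient)
        image, _ = simulate_phantom_image(cfg)
        # nominal task contrast of the Al square, not the measured one: the
        # object's contrast is a property of the phantom, not of one exposure
        device_cfg = device_config_for(cfg,
                                       nominal_contrast=1.0 - cfg0.al_transmission)
        records.append(analyze_image(image, device_cfg).record)
    values = {m: [r.metric(m) for r in records] for m in JITTER_METRICS}
    return JitterResult(records=records, metric_values=values)


def summarize_cvs(result: JitterResult) -> dict[str, float]:
    return {m: result.cv_percent(m) for m in JITTER_METRICS
            if not math.isnan(result.cv_percent(m))}
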