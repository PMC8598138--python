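"""End-to-end analysis: image file -> QcRecord -> history -> control status.

The analysis path contains no random number usage, so re-running on the
same input reproduces identical metric values bit for bit.
"""

from __future__ import annotations

import csv
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from . import __version__
from .basic_metrics import compute_sdnr, compute_snr, roi_stats
from .detectability import DetectionTask, compute_dprime, default_disk_diameters
from .errors import PhantomQcError
from .image_io import (PhantomImage, QcRecord, read_phantom_image, read_qc_csv,
                       validate_acquisition, write_qc_csv)
from .phantom_sim import PhantomSpec
from .roi_locator import RoiSet, locate_rois
from .spatial_frequency import (MtfCurve, NnpsResult, average_curves,
                                build_oversampled_esf, characteristic_frequencies,
                                common_grid, compute_nnps, compute_presampled_mtf,
                                estimate_edge_angle)
from .trending import (CHART_METRICS, DEFAULT_N_BASELINE, build_chart, detect_trend,
                       render_charts)
from .uniformity import (DEFAULT_DEFECT_THRESHOLD, DefectRegion, VarianceMap,
                         compute_variance_map, flag_defects, render_variance_map,
                         write_defect_csv)

EXIT_OK = 0
EXIT_LIMIT_VIOLATION = 2
EXIT_TREND = 3


class StageError(PhantomQcError):
    """Wraps a stage failure with the stage name for actionable CLI errors."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisReport:
    record: QcRecord
    roiset: RoiSet
    mtf_horizontal: MtfCurve
    mtf_vertical: MtfCurve
    mtf_averaged: MtfCurve
    nnps: NnpsResult
    variance_map: VarianceMap
    defects: list[DefectRegion]
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_qc_csv([self.record], out / "record.csv")
        with open(out / "curves.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frequency_cyc_mm", "value", "curve"])
            for curve, name in ((self.mtf_horizontal, "mtf_horizontal"),
                                (self.mtf_vertical, "mtf_vertical"),
                                (self.mtf_averaged, "mtf_averaged"),
                                (self.nnps.horizontal, "nnps_horizontal"),
                                (self.nnps.vertical, "nnps_vertical"),
                                (self.nnps.radial, "nnps_radial")):
                for f, v in zip(curve.frequencies, curve.values):
                    writer.writerow([repr(float(f)), repr(float(v)), name])
        render_variance_map(self.variance_map, out / "variance_map.png")
        write_defect_csv(self.defects, out / "defects.csv")
        with open(out / "report.txt", "w", encoding="utf-8") as fh:
            fh.write(f"software_version={__version__}\n")
            fh.write("violations:\n")
            for v in self.violations:
                fh.write(f"  - {v}\n")
            fh.write("warnings:\n")
            for w in self.warnings:
                fh.write(f"  - {w}\n")


def _spec_from_config(cfg: dict, modality: str) -> PhantomSpec:
    spec_cfg = dict(cfg.get("phantom_spec", {}))
    spec_cfg.setdefault("modality", modality)
    for key in ("plate_size_mm", "cu_center_frac", "al_center_frac"):
        if key in spec_cfg:
            spec_cfg[key] = tuple(spec_cfg[key])
    return PhantomSpec(**spec_cfg)


def _mtf_for_edge(image: PhantomImage, roiset: RoiSet, edge_name: str,
                  direction: str, warnings: list[str]) -> MtfCurve:
    segment = roiset.edge_segments[edge_name]
    estimate = estimate_edge_angle(image, segment)
    warnings.extend(estimate.warnings)
    band = _band_halfwidth(image, roiset)
    esf = build_oversampled_esf(image, segment, estimate.degrees,
                                band_halfwidth_px=band)
    return compute_presampled_mtf(esf, image.pixel_spacing_mm[0], direction=direction,
                                  edge_angle_deg=estimate.degrees,
                                  warnings=estimate.warnings)


def _band_halfwidth(image: PhantomImage, roiset: RoiSet) -> int:
    # at most 40 px, but never deeper than 40 % of the Cu square half-side
    return int(min(40, max(16, 0.4 * roiset.cu_square.side_px / 2)))


def analyze_image(source, device_config: dict | None = None) -> AnalysisReport:
    """Run the full pipeline on an image file (or an in-memory PhantomImage).

    Stages: read -> validate -> locate ROIs -> SDNR/SNR -> MTF (h, v) ->
    NNPS -> common grid -> d' (both disk sizes) -> variance map -> record.
    """
    cfg = device_config or {}
    warnings: list[str] = []

    if isinstance(source, PhantomImage):
        image = source
    else:
        try:
            image = read_phantom_image(source, cfg)
        except Exception as exc:
            raise StageError("read", exc) from exc

    violations = validate_acquisition(image, cfg.get("protocol", {}))

    spec = _spec_from_config(cfg, image.modality)
    try:
        roiset = locate_rois(image, spec)
    except Exception as exc:
        raise StageError("locate-rois", exc) from exc
    warnings.extend(roiset.warnings)

    try:
        bg = roi_stats(image, roiset.background_roi)
        al = roi_stats(image, roiset.al_roi)
        sdnr = compute_sdnr(bg, al)
        snr = compute_snr(bg)
        if sdnr < 0:
            warnings.append("negative SDNR: target brighter than background")
    except Exception as exc:
        raise StageError("basic-metrics", exc) from exc

    try:
        mtf_h = _mtf_for_edge(image, roiset, "left", "horizontal", warnings)
        mtf_v = _mtf_for_edge(image, roiset, "top", "vertical", warnings)
    except Exception as exc:
        raise StageError("mtf", exc) from exc

    try:
        region = roiset.nnps_region.extract(np.asarray(image.pixels, dtype=float))
        nnps = compute_nnps(region, image.pixel_spacing_mm[0])
    except Exception as exc:
        raise StageError("nnps", exc) from exc

    try:
        mtf_h_c, _ = common_grid(mtf_h, nnps.averaged)
        mtf_v_c, _ = common_grid(mtf_v, nnps.averaged)
        mtf_avg = average_curves(mtf_h_c, mtf_v_c)
        contrast = cfg.get("nominal_contrast")
        if contrast is None:
            contrast = abs(bg.mean_signal - al.mean_signal) / bg.mean_signal
        d_small_d, d_large_d = default_disk_diameters(image.modality)
        dprime_small = compute_dprime(mtf_avg, nnps.averaged,
                                      DetectionTask(contrast, d_small_d))
        dprime_large = compute_dprime(mtf_avg, nnps.averaged,
                                      DetectionTask(contrast, d_large_d))
    except Exception as exc:
        raise StageError("detectability", exc) from exc

    try:
        vmap = compute_variance_map(image, roiset)
        defects = flag_defects(vmap, cfg.get("defect_threshold",
                                             DEFAULT_DEFECT_THRESHOLD))
    except Exception as exc:
        raise StageError("variance-map", exc) from exc

    ch = characteristic_frequencies(mtf_h)
    cv = characteristic_frequencies(mtf_v)
    md = image.metadata
    record = QcRecord(
        device_key=cfg.get("device_key")
        or f"{md.station_name or 'unknown'}/{md.detector_id or 'unknown'}",
        acquisition_datetime=md.acquisition_datetime or datetime(1970, 1, 1),
        kvp=md.kvp, mas=md.tube_load_mas, exposure_index=md.exposure_index,
        organ_dose=md.organ_dose, entrance_dose=md.entrance_dose,
        snr=snr, sdnr=sdnr,
        mtf50_h=ch.f50, mtf20_h=ch.f20, mtf10_h=ch.f10,
        mtf50_v=cv.f50, mtf20_v=cv.f20, mtf10_v=cv.f10,
        dprime_small=dprime_small, dprime_large=dprime_large,
        uniformity_flag=bool(defects), software_version=__version__)
    return AnalysisReport(record=record, roiset=roiset,
                          mtf_horizontal=mtf_h, mtf_vertical=mtf_v,
                          mtf_averaged=mtf_avg, nnps=nnps, variance_map=vmap,
                          defects=defects, violations=violations, warnings=warnings)


def run_session(source, history_csv, policy: str = "pct10",
                device_config: dict | None = None,
                n_baseline: int = DEFAULT_N_BASELINE,
                charts_dir=None) -> tuple[int, AnalysisReport]:
    """Analyze, append to history, apply limits and trend rules.

    Returns (exit_status, report): 0 in control, 2 limit violation,
    3 trend flag.  A failed analysis leaves the history file unmodified.
    """
    report = analyze_image(source, device_config)

    history_csv = Path(history_csv)
    records = read_qc_csv(history_csv) if history_csv.exists() else []
    records = records + [report.record]
    # atomic append: write to a temp file then replace
    fd, tmp = tempfile.mkstemp(dir=history_csv.parent or Path("."), suffix=".csv")
    os.close(fd)
    try:
        write_qc_csv(records, tmp)
        os.replace(tmp, history_csv)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)

    status = EXIT_OK
    if len(records) >= n_baseline:
        for metric in CHART_METRICS:
            if all(r.metric(metric) is None for r in records):
                continue
            try:
                chart = build_chart(records, metric, policy, n_baseline)
            except PhantomQcError:
                continue
            if chart.flags and chart.flags[-1] != "ok":
                status = EXIT_LIMIT_VIOLATION
                break
            if status == EXIT_OK and detect_trend(chart).any_trend:
                status = EXIT_TREND
    if charts_dir is not None:
        render_charts(records, charts_dir, policy, n_baseline)
    return status, report
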