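"""Phantom image reading/writing, acquisition validation, QC record CSV.

Absent metadata is always represented as ``None`` — never as zero — so a
missing header value can be distinguished from a measured zero.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import tifffile

from . import dicomlite
from .errors import CsvFormatError, ImageReadError

logger = logging.getLogger(__name__)

MODALITIES = ("radiography", "mammography")
_DICOM_MODALITY = {"radiography": "DX", "mammography": "MG"}
_MODALITY_FROM_DICOM = {"DX": "radiography", "CR": "radiography", "MG": "mammography",
                        "OT": "radiography"}
_DT_FORMAT = "%Y%m%d%H%M%S"


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Exposure-related header values recorded for stability tracking."""

    kvp: float | None = None
    tube_load_mas: float | None = None
    exposure_index: float | None = None
    organ_dose: float | None = None
    entrance_dose: float | None = None
    anode_filter: str | None = None
    detector_id: str | None = None
    station_name: str | None = None
    acquisition_datetime: datetime | None = None

    def __post_init__(self) -> None:
        if self.kvp is not None and self.kvp <= 0:
            raise ValueError(f"kvp must be positive when present, got {self.kvp}")


@dataclass
class PhantomImage:
    """A single phantom exposure: pixels plus acquisition context."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    modality: str = "radiography"
    presentation_state: str = "unknown"  # for_processing | for_presentation | unknown
    metadata: AcquisitionMetadata = field(default_factory=AcquisitionMetadata)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ValueError("pixels must be finite")
        if min(self.pixel_spacing_mm) <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing_mm}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def nyquist_cyc_mm(self) -> float:
        return 1.0 / (2.0 * self.pixel_spacing_mm[0])


# ---------------------------------------------------------------------------
# DICOM / TIFF reading and writing


def write_phantom_dicom(path, image: PhantomImage) -> None:
    """Write the image as a monochrome Explicit-VR-LE DICOM file."""
    px = image.pixels
    if px.dtype != np.uint16:
        if px.min() < 0 or px.max() > 0xFFFF:
            raise ValueError("pixel values outside the uint16 range; rescale first")
        px = np.rint(px).astype(np.uint16)
    md = image.metadata
    spacing = f"{image.pixel_spacing_mm[0]:.6g}\\{image.pixel_spacing_mm[1]:.6g}"
    intent = {"for_processing": "FOR PROCESSING",
              "for_presentation": "FOR PRESENTATION"}.get(image.presentation_state)
    attrs: dict[str, object] = {
        "Modality": _DICOM_MODALITY[image.modality],
        "ImagerPixelSpacing": spacing,
        "PixelSpacing": spacing,
    }
    if intent:
        attrs["PresentationIntentType"] = intent
    if md.kvp is not None:
        attrs["KVP"] = f"{md.kvp:.6g}"
    if md.tube_load_mas is not None:
        attrs["ExposureInuAs"] = str(int(round(md.tube_load_mas * 1000)))
        attrs["Exposure"] = str(int(round(md.tube_load_mas)))
    if md.exposure_index is not None:
        attrs["ExposureIndex"] = f"{md.exposure_index:.6g}"
    if md.organ_dose is not None:
        attrs["OrganDose"] = f"{md.organ_dose:.6g}"
    if md.entrance_dose is not None:
        attrs["EntranceDoseInmGy"] = f"{md.entrance_dose:.6g}"
    if md.anode_filter is not None:
        attrs["FilterMaterial"] = md.anode_filter
    if md.detector_id is not None:
        attrs["DetectorID"] = md.detector_id
    if md.station_name is not None:
        attrs["StationName"] = md.station_name
    if md.acquisition_datetime is not None:
        attrs["AcquisitionDateTime"] = md.acquisition_datetime.strftime(_DT_FORMAT)
    dicomlite.write_dicom(path, px, attrs)


def write_phantom_tiff(path, image: PhantomImage) -> None:
    px = image.pixels
    if px.dtype != np.uint16:
        if px.min() < 0 or px.max() > 0xFFFF:
            raise ValueError("pixel values outside the uint16 range; rescale first")
        px = np.rint(px).astype(np.uint16)
    # TIFF resolution is pixels per cm (RESUNIT=CENTIMETER)
    res = (10.0 / image.pixel_spacing_mm[1], 10.0 / image.pixel_spacing_mm[0])
    tifffile.imwrite(path, px, resolution=res, resolutionunit="CENTIMETER")


def _metadata_from_dicom(ds: dicomlite.DicomFile, tag_map: dict[str, str]) -> AcquisitionMetadata:
    def num(keyword: str, default_source: str) -> float | None:
        return ds.number(tag_map.get(keyword, default_source))

    mas = None
    uas = num("tube_load_mas", "ExposureInuAs")
    if uas is not None and "tube_load_mas" not in tag_map:
        mas = uas / 1000.0
    elif uas is not None:
        mas = uas
    else:
        mas = ds.number("Exposure")

    dt = None
    raw_dt = ds.string("AcquisitionDateTime")
    if raw_dt:
        for fmt in (_DT_FORMAT, "%Y%m%d%H%M%S.%f", "%Y%m%d"):
            try:
                dt = datetime.strptime(raw_dt.split("+")[0].split("-")[0], fmt)
                break
            except ValueError:
                continue
    return AcquisitionMetadata(
        kvp=num("kvp", "KVP"),
        tube_load_mas=mas,
        exposure_index=num("exposure_index", "ExposureIndex"),
        organ_dose=num("organ_dose", "OrganDose"),
        entrance_dose=num("entrance_dose", "EntranceDoseInmGy"),
        anode_filter=ds.string(tag_map.get("anode_filter", "FilterMaterial")),
        detector_id=ds.string(tag_map.get("detector_id", "DetectorID")),
        station_name=ds.string(tag_map.get("station_name", "StationName")),
        acquisition_datetime=dt,
    )


def read_phantom_image(path, device_config: dict | None = None) -> PhantomImage:
    """Read a DICOM or 16-bit TIFF phantom image.

    ``device_config`` keys used here: ``pixel_spacing_mm`` (override/fallback),
    ``modality``, and ``tag_map`` (metadata field -> DICOM keyword or
    ``"GGGG,EEEE"`` hex tag) for vendor-specific headers.
    """
    cfg = device_config or {}
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such file: {path}")
    if dicomlite.is_dicom(path):
        return _read_dicom_image(path, cfg)
    return _read_tiff_image(path, cfg)


def _read_dicom_image(path: Path, cfg: dict) -> PhantomImage:
    ds = dicomlite.read_dicom(path)
    pixels = ds.pixel_array()
    provenance = [f"read from DICOM {path.name}"]

    photometric = ds.string("PhotometricInterpretation") or "MONOCHROME2"
    if photometric == "MONOCHROME1":
        # flip so that higher value always means more detector signal
        pixels = pixels.max() - pixels
        provenance.append("MONOCHROME1 polarity inverted on read")

    spacing = ds.pixel_spacing_mm()
    if "pixel_spacing_mm" in cfg:
        ov = cfg["pixel_spacing_mm"]
        spacing = (ov, ov) if np.isscalar(ov) else tuple(ov)
        provenance.append("pixel spacing taken from device config")
    if spacing is None:
        raise ImageReadError(
            f"{path}: no pixel spacing in header and no device-config override; "
            "spatial-frequency metrics would be meaningless"
        )

    intent = ds.string("PresentationIntentType")
    if intent is None:
        state = "unknown"
        logger.warning("%s: presentation intent absent; treating as unknown", path)
    elif "FOR PROCESSING" in intent.upper():
        state = "for_processing"
    else:
        state = "for_presentation"
        warnings.warn(
            f"{path.name}: image is '{intent}', not a for-processing image; "
            "results may be affected by display processing",
            stacklevel=3,
        )

    modality = cfg.get("modality") or _MODALITY_FROM_DICOM.get(
        ds.string("Modality") or "", "radiography")
    metadata = _metadata_from_dicom(ds, cfg.get("tag_map", {}))
    return PhantomImage(pixels=pixels, pixel_spacing_mm=spacing, modality=modality,
                        presentation_state=state, metadata=metadata, provenance=provenance)


def _read_tiff_image(path: Path, cfg: dict) -> PhantomImage:
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            pixels = page.asarray()
            spacing = None
            if "pixel_spacing_mm" in cfg:
                ov = cfg["pixel_spacing_mm"]
                spacing = (ov, ov) if np.isscalar(ov) else tuple(ov)
            else:
                tags = page.tags
                if ("XResolution" in tags and "YResolution" in tags
                        and tags.get("ResolutionUnit") is not None):
                    unit = tags["ResolutionUnit"].value
                    mm_per_unit = {2: 25.4, 3: 10.0}.get(int(unit))
                    if mm_per_unit:
                        xr = tags["XResolution"].value
                        yr = tags["YResolution"].value
                        xr = xr[0] / xr[1] if isinstance(xr, tuple) else float(xr)
                        yr = yr[0] / yr[1] if isinstance(yr, tuple) else float(yr)
                        if xr > 0 and yr > 0:
                            spacing = (mm_per_unit / yr, mm_per_unit / xr)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ImageReadError(f"{path} is neither DICOM nor readable TIFF: {exc}") from exc
    if pixels.ndim != 2:
        raise ImageReadError(f"{path}: expected a single-channel 2-D TIFF")
    if spacing is None:
        raise ImageReadError(
            f"{path}: TIFF carries no resolution and device config gives no "
            "pixel_spacing_mm override"
        )
    logger.warning("%s: TIFF input has no presentation intent; treating as unknown", path)
    return PhantomImage(pixels=pixels, pixel_spacing_mm=spacing,
                        modality=cfg.get("modality", "radiography"),
                        presentation_state="unknown",
                        provenance=[f"read from TIFF {path.name}"])


# ---------------------------------------------------------------------------
# Acquisition protocol validation


def validate_acquisition(image: PhantomImage, protocol: dict) -> list[str]:
    """Check header consistency against the site protocol; returns human-readable
    violation strings and never raises on a mismatch."""
    violations: list[str] = []
    md = image.metadata
    if "kvp" in protocol:
        if md.kvp is None:
            violations.append("kVp not recorded in the image header; must be recorded")
        else:
            tol = protocol.get("kvp_tolerance", 0.5)
            if abs(md.kvp - protocol["kvp"]) > tol:
                violations.append(
                    f"kVp mismatch: header {md.kvp:g}, protocol expects {protocol['kvp']:g}")
    if "modality" in protocol and image.modality != protocol["modality"]:
        violations.append(
            f"modality mismatch: image is {image.modality}, protocol expects "
            f"{protocol['modality']}")
    if "detector_id" in protocol:
        if md.detector_id is None:
            violations.append("detector ID not recorded in the image header")
        elif md.detector_id != protocol["detector_id"]:
            violations.append(
                f"wrong detector: header {md.detector_id!r}, protocol expects "
                f"{protocol['detector_id']!r}")
    if image.presentation_state == "for_presentation":
        violations.append("image is 'for presentation' (processed); for-processing "
                          "images are required")
    return violations


# ---------------------------------------------------------------------------
# QC record CSV exchange


@dataclass(frozen=True)
class QcRecord:
    """One QC session's metric vector; the row exchanged with the remote centre."""

    device_key: str
    acquisition_datetime: datetime
    kvp: float | None = None
    mas: float | None = None
    exposure_index: float | None = None
    organ_dose: float | None = None
    entrance_dose: float | None = None
    snr: float | None = None
    sdnr: float | None = None
    mtf50_h: float | None = None
    mtf20_h: float | None = None
    mtf10_h: float | None = None
    mtf50_v: float | None = None
    mtf20_v: float | None = None
    mtf10_v: float | None = None
    dprime_small: float | None = None
    dprime_large: float | None = None
    uniformity_flag: bool = False
    software_version: str = ""

    def metric(self, name: str) -> float | None:
        return getattr(self, name)


QC_CSV_COLUMNS = [f.name for f in fields(QcRecord)]
_FLOAT_FIELDS = {f.name for f in fields(QcRecord)
                 if f.name not in ("device_key", "acquisition_datetime",
                                   "uniformity_flag", "software_version")}


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, datetime):
        return value.isoformat()
    if isinstance(value, float):
        return repr(value)  # shortest round-trippable representation
    return str(value)


def write_qc_csv(records: list[QcRecord], path) -> None:
    """Write records with the fixed, documented header row (UTF-8, comma,
    '.' decimal, ISO-8601 datetimes; absent values are empty cells)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(QC_CSV_COLUMNS)
        for rec in records:
            writer.writerow([_cell(getattr(rec, name)) for name in QC_CSV_COLUMNS])


def read_qc_csv(path) -> list[QcRecord]:
    records: list[QcRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CsvFormatError(f"{path}: empty file, expected a header row") from None
        if header != QC_CSV_COLUMNS:
            raise CsvFormatError(
                f"{path}: unexpected header {header!r}; expected {QC_CSV_COLUMNS!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(QC_CSV_COLUMNS):
                raise CsvFormatError(
                    f"{path}: row {lineno} has {len(row)} cells, expected "
                    f"{len(QC_CSV_COLUMNS)}")
            kwargs: dict[str, object] = {}
            for name, cell in zip(QC_CSV_COLUMNS, row):
                try:
                    if name == "device_key" or name == "software_version":
                        kwargs[name] = cell
                    elif name == "acquisition_datetime":
                        kwargs[name] = datetime.fromisoformat(cell)
                    elif name == "uniformity_flag":
                        kwargs[name] = cell == "true"
                    elif name in _FLOAT_FIELDS:
                        kwargs[name] = float(cell) if cell != "" else None
                except ValueError as exc:
                    raise CsvFormatError(
                        f"{path}: row {lineno}, column {name!r}: {exc}") from exc
            records.append(QcRecord(**kwargs))  # type: ignore[arg-type]
    return records


def record_with(record: QcRecord, **updates) -> QcRecord:
    return replace(record, **updates)
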