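"""Minimal DICOM part-10 reader/writer.

Supports exactly what this package needs: single-frame 16-bit monochrome
images with the acquisition tags used for QC trending, encoded as Explicit
VR Little Endian (written) and Explicit or Implicit VR Little Endian
(read).  It is not a general DICOM implementation; unknown elements are
retained as raw bytes and exposed to the caller so device-specific tag
maps can resolve vendor fields.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field

import numpy as np

from .errors import ImageReadError

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
IMPLICIT_VR_LE = "1.2.840.10008.1.2"
SECONDARY_CAPTURE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"
_IMPLEMENTATION_UID = "1.2.826.0.1.3680043.10.1456.1"
_UID_ROOT = "1.2.826.0.1.3680043.10.1456.2"

# VRs carrying a 2-byte reserved field and 4-byte length in explicit encoding
_LONG_VRS = {"OB", "OW", "OF", "OL", "OD", "SQ", "UC", "UR", "UT", "UN"}

Tag = tuple[int, int]

# tag -> (VR, keyword); the subset this package reads/writes by name
DICT: dict[Tag, tuple[str, str]] = {
    (0x0002, 0x0001): ("OB", "FileMetaInformationVersion"),
    (0x0002, 0x0002): ("UI", "MediaStorageSOPClassUID"),
    (0x0002, 0x0003): ("UI", "MediaStorageSOPInstanceUID"),
    (0x0002, 0x0010): ("UI", "TransferSyntaxUID"),
    (0x0002, 0x0012): ("UI", "ImplementationClassUID"),
    (0x0008, 0x0008): ("CS", "ImageType"),
    (0x0008, 0x0016): ("UI", "SOPClassUID"),
    (0x0008, 0x0018): ("UI", "SOPInstanceUID"),
    (0x0008, 0x002A): ("DT", "AcquisitionDateTime"),
    (0x0008, 0x0060): ("CS", "Modality"),
    (0x0008, 0x0068): ("CS", "PresentationIntentType"),
    (0x0008, 0x1010): ("SH", "StationName"),
    (0x0018, 0x0060): ("DS", "KVP"),
    (0x0018, 0x1152): ("IS", "Exposure"),
    (0x0018, 0x1153): ("IS", "ExposureInuAs"),
    (0x0018, 0x1411): ("DS", "ExposureIndex"),
    (0x0018, 0x700A): ("SH", "DetectorID"),
    (0x0018, 0x7050): ("LO", "FilterMaterial"),
    (0x0018, 0x1164): ("DS", "ImagerPixelSpacing"),
    (0x0028, 0x0002): ("US", "SamplesPerPixel"),
    (0x0028, 0x0004): ("CS", "PhotometricInterpretation"),
    (0x0028, 0x0010): ("US", "Rows"),
    (0x0028, 0x0011): ("US", "Columns"),
    (0x0028, 0x0030): ("DS", "PixelSpacing"),
    (0x0028, 0x0100): ("US", "BitsAllocated"),
    (0x0028, 0x0101): ("US", "BitsStored"),
    (0x0028, 0x0102): ("US", "HighBit"),
    (0x0028, 0x0103): ("US", "PixelRepresentation"),
    (0x0040, 0x0316): ("DS", "OrganDose"),
    (0x0040, 0x8302): ("DS", "EntranceDoseInmGy"),
    (0x7FE0, 0x0010): ("OW", "PixelData"),
}
_KEYWORD_TO_TAG = {kw: tag for tag, (_vr, kw) in DICT.items()}


@dataclass
class DicomFile:
    """Parsed dataset: decoded string/number access plus raw elements."""

    elements: dict[Tag, bytes] = field(default_factory=dict)
    transfer_syntax: str = EXPLICIT_VR_LE

    def raw(self, tag: Tag) -> bytes | None:
        return self.elements.get(tag)

    def string(self, keyword_or_tag: str | Tag) -> str | None:
        tag = self._resolve(keyword_or_tag)
        raw = self.elements.get(tag)
        if raw is None:
            return None
        return raw.decode("ascii", errors="replace").rstrip(" \x00")

    def number(self, keyword_or_tag: str | Tag) -> float | None:
        s = self.string(keyword_or_tag)
        if s is None or s == "":
            return None
        try:
            return float(s.split("\\")[0])
        except ValueError:
            return None

    def ushort(self, keyword: str) -> int | None:
        raw = self.elements.get(self._resolve(keyword))
        if raw is None or len(raw) < 2:
            return None
        return struct.unpack("<H", raw[:2])[0]

    def pixel_array(self) -> np.ndarray:
        rows, cols = self.ushort("Rows"), self.ushort("Columns")
        raw = self.elements.get(_KEYWORD_TO_TAG["PixelData"])
        if rows is None or cols is None or raw is None:
            raise ImageReadError("DICOM file has no usable pixel data")
        bits = self.ushort("BitsAllocated") or 16
        signed = (self.ushort("PixelRepresentation") or 0) == 1
        dtype = {(8, False): np.uint8, (8, True): np.int8,
                 (16, False): np.uint16, (16, True): np.int16}.get((bits, signed))
        if dtype is None:
            raise ImageReadError(f"unsupported BitsAllocated={bits}")
        arr = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<"), count=rows * cols)
        return arr.reshape(rows, cols).astype(dtype)

    def pixel_spacing_mm(self) -> tuple[float, float] | None:
        for kw in ("ImagerPixelSpacing", "PixelSpacing"):
            s = self.string(kw)
            if s:
                parts = s.split("\\")
                try:
                    if len(parts) == 1:
                        v = float(parts[0])
                        return (v, v)
                    return (float(parts[0]), float(parts[1]))
                except ValueError:
                    continue
        return None

    @staticmethod
    def _resolve(keyword_or_tag: str | Tag) -> Tag:
        if isinstance(keyword_or_tag, tuple):
            return keyword_or_tag
        if keyword_or_tag in _KEYWORD_TO_TAG:
            return _KEYWORD_TO_TAG[keyword_or_tag]
        # "GGGG,EEEE" hex form used by device tag maps
        g, e = keyword_or_tag.split(",")
        return (int(g, 16), int(e, 16))


def _pad(value: bytes, vr: str) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in ("UI", "OB") else b" "
    return value


def _encode_element(tag: Tag, vr: str, value: bytes) -> bytes:
    value = _pad(value, vr)
    head = struct.pack("<HH", tag[0], tag[1])
    if vr in _LONG_VRS:
        return head + vr.encode() + b"\x00\x00" + struct.pack("<I", len(value)) + value
    if len(value) > 0xFFFF:
        raise ValueError(f"value too long for short-form VR {vr}")
    return head + vr.encode() + struct.pack("<H", len(value)) + value


def _str_bytes(v: object) -> bytes:
    return str(v).encode("ascii")


def deterministic_uid(seed_material: bytes) -> str:
    digest = int.from_bytes(hashlib.sha256(seed_material).digest()[:12], "big")
    return f"{_UID_ROOT}.{digest}"


def write_dicom(path, pixels: np.ndarray, attributes: dict[str, object]) -> None:
    """Write a part-10 Explicit VR LE file.

    ``attributes`` maps DICOM keywords from :data:`DICT` to python values;
    Rows/Columns/BitsAllocated/PixelData are derived from ``pixels``.
    """
    if pixels.dtype != np.uint16:
        raise ValueError("pixels must be uint16")
    attrs = dict(attributes)
    attrs.setdefault("ImageType", "ORIGINAL\\PRIMARY")
    attrs.setdefault("SOPClassUID", SECONDARY_CAPTURE_SOP_CLASS)
    attrs.setdefault("PhotometricInterpretation", "MONOCHROME2")
    if "SOPInstanceUID" not in attrs:
        h = hashlib.sha256(pixels.tobytes())
        for k in sorted(attrs):
            h.update(f"{k}={attrs[k]}".encode("ascii", "replace"))
        attrs["SOPInstanceUID"] = deterministic_uid(h.digest())

    body = bytearray()
    dataset: dict[Tag, tuple[str, bytes]] = {}
    for keyword, value in attrs.items():
        if value is None:
            continue
        tag = _KEYWORD_TO_TAG[keyword]
        vr = DICT[tag][0]
        dataset[tag] = (vr, _str_bytes(value))
    rows, cols = pixels.shape
    for kw, v in (("SamplesPerPixel", 1), ("Rows", rows), ("Columns", cols),
                  ("BitsAllocated", 16), ("BitsStored", 16), ("HighBit", 15),
                  ("PixelRepresentation", 0)):
        dataset[_KEYWORD_TO_TAG[kw]] = ("US", struct.pack("<H", v))
    dataset[_KEYWORD_TO_TAG["PixelData"]] = ("OW", pixels.astype("<u2").tobytes())
    for tag in sorted(dataset):
        vr, value = dataset[tag]
        body += _encode_element(tag, vr, value)

    meta = bytearray()
    meta += _encode_element((0x0002, 0x0001), "OB", b"\x00\x01")
    meta += _encode_element((0x0002, 0x0002), "UI", _str_bytes(attrs["SOPClassUID"]))
    meta += _encode_element((0x0002, 0x0003), "UI", _str_bytes(attrs["SOPInstanceUID"]))
    meta += _encode_element((0x0002, 0x0010), "UI", EXPLICIT_VR_LE.encode())
    meta += _encode_element((0x0002, 0x0012), "UI", _IMPLEMENTATION_UID.encode())
    group_len = _encode_element((0x0002, 0x0000), "UL", struct.pack("<I", len(meta)))

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(group_len)
        fh.write(meta)
        fh.write(body)


def is_dicom(path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _parse_elements(buf: bytes, offset: int, explicit: bool,
                    stop_before: Tag | None = None) -> tuple[dict[Tag, bytes], int]:
    out: dict[Tag, bytes] = {}
    n = len(buf)
    while offset + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, offset)
        tag = (group, elem)
        if stop_before is not None and tag >= stop_before:
            break
        if explicit:
            vr = buf[offset + 4:offset + 6].decode("ascii", errors="replace")
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", buf, offset + 8)
                value_off = offset + 12
            else:
                (length,) = struct.unpack_from("<H", buf, offset + 6)
                value_off = offset + 8
        else:
            (length,) = struct.unpack_from("<I", buf, offset + 4)
            value_off = offset + 8
        if length == 0xFFFFFFFF:
            raise ImageReadError("undefined-length DICOM elements are not supported")
        if value_off + length > n:
            raise ImageReadError(f"truncated DICOM element at tag {tag}")
        out[tag] = buf[value_off:value_off + length]
        offset = value_off + length
    return out, offset


def read_dicom(path) -> DicomFile:
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 140 or buf[128:132] != b"DICM":
        raise ImageReadError(f"{path} is not a DICOM part-10 file")
    meta, offset = _parse_elements(buf, 132, explicit=True, stop_before=(0x0003, 0x0000))
    ts_raw = meta.get((0x0002, 0x0010), EXPLICIT_VR_LE.encode())
    ts = ts_raw.decode("ascii").rstrip(" \x00")
    if ts not in (EXPLICIT_VR_LE, IMPLICIT_VR_LE):
        raise ImageReadError(f"unsupported transfer syntax {ts!r}")
    elements, _ = _parse_elements(buf, offset, explicit=(ts == EXPLICIT_VR_LE))
    elements.update(meta)
    return DicomFile(elements=elements, transfer_syntax=ts)
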