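import numpy as np
import pytest
from datetime import datetime

from hypothesis import given, settings, strategies as st

from phantomqc import dicomlite
from phantomqc.errors import CsvFormatError, ImageReadError
from phantomqc.image_io import (AcquisitionMetadata, PhantomImage, QcRecord,
                                read_phantom_image, read_qc_csv,
                                validate_acquisition, write_phantom_dicom,
                                write_phantom_tiff, write_qc_csv)


@pytest.fixture
def small_image():
    rng = np.random.default_rng(7)
    pixels = rng.integers(500, 1500, size=(64, 80), dtype=np.uint16)
    md = AcquisitionMetadata(kvp=80.0, tube_load_mas=10.0, exposure_index=400.0,
                             detector_id="DET-1", station_name="RM-1",
                             acquisition_datetime=datetime(2021, 3, 4, 9, 30))
    return PhantomImage(pixels=pixels, pixel_spacing_mm=(0.1, 0.1),
                        modality="radiography", presentation_state="for_processing",
                        metadata=md)


class TestDicomRoundTrip:
    def test_pixels_and_header_identity(self, small_image, tmp_path):
        path = tmp_path / "img.dcm"
        write_phantom_dicom(path, small_image)
        back = read_phantom_image(path)
        assert np.array_equal(back.pixels, small_image.pixels)
        assert back.metadata.kvp == small_image.metadata.kvp
        assert back.metadata.tube_load_mas == small_image.metadata.tube_load_mas
        assert back.metadata.exposure_index == small_image.metadata.exposure_index
        assert back.metadata.detector_id == "DET-1"
        assert back.pixel_spacing_mm == (0.1, 0.1)
        assert back.presentation_state == "for_processing"
        assert back.metadata.acquisition_datetime == datetime(2021, 3, 4, 9, 30)

    def test_for_presentation_warns(self, small_image, tmp_path):
        img = PhantomImage(pixels=small_image.pixels, pixel_spacing_mm=(0.1, 0.1),
                           presentation_state="for_presentation",
                           metadata=small_image.metadata)
        path = tmp_path / "proc.dcm"
        write_phantom_dicom(path, img)
        with pytest.warns(UserWarning, match="for-processing"):
            back = read_phantom_image(path)
        assert back.presentation_state == "for_presentation"

    def test_missing_spacing_is_hard_error(self, tmp_path):
        path = tmp_path / "nospacing.dcm"
        dicomlite.write_dicom(path, np.zeros((8, 8), dtype=np.uint16),
                              {"Modality": "DX"})
        with pytest.raises(ImageReadError, match="spacing"):
            read_phantom_image(path)

    def test_missing_spacing_with_override(self, tmp_path):
        path = tmp_path / "nospacing.dcm"
        dicomlite.write_dicom(path, np.zeros((8, 8), dtype=np.uint16),
                              {"Modality": "DX"})
        back = read_phantom_image(path, {"pixel_spacing_mm": 0.2})
        assert back.pixel_spacing_mm == (0.2, 0.2)

    def test_monochrome1_polarity_flip(self, tmp_path):
        pixels = np.arange(64, dtype=np.uint16).reshape(8, 8)
        path = tmp_path / "mono1.dcm"
        dicomlite.write_dicom(path, pixels, {
            "Modality": "DX", "PhotometricInterpretation": "MONOCHROME1",
            "ImagerPixelSpacing": "0.1\\0.1"})
        back = read_phantom_image(path)
        assert np.array_equal(back.pixels, pixels.max() - pixels)
        assert any("polarity" in p for p in back.provenance)

    def test_absent_metadata_stays_absent(self, tmp_path):
        path = tmp_path / "bare.dcm"
        dicomlite.write_dicom(path, np.zeros((8, 8), dtype=np.uint16),
                              {"Modality": "DX", "ImagerPixelSpacing": "0.1\\0.1"})
        back = read_phantom_image(path)
        assert back.metadata.kvp is None
        assert back.metadata.exposure_index is None
        assert back.metadata.organ_dose is None

    def test_unreadable_file(self, tmp_path):
        path = tmp_path / "garbage.dcm"
        path.write_bytes(b"not a dicom file at all")
        with pytest.raises(ImageReadError):
            read_phantom_image(path)


class TestTiff:
    def test_roundtrip_with_resolution(self, small_image, tmp_path):
        path = tmp_path / "img.tif"
        write_phantom_tiff(path, small_image)
        back = read_phantom_image(path)
        assert np.array_equal(back.pixels, small_image.pixels)
        assert back.pixel_spacing_mm[0] == pytest.approx(0.1)

    def test_config_override_precedence(self, small_image, tmp_path):
        import tifffile
        path = tmp_path / "nospacing.tif"
        tifffile.imwrite(path, small_image.pixels)  # no resolution tags
        back = read_phantom_image(path, {"pixel_spacing_mm": 0.1})
        assert back.pixel_spacing_mm == (0.1, 0.1)

    def test_no_spacing_anywhere_errors(self, small_image, tmp_path):
        import tifffile
        path = tmp_path / "nospacing.tif"
        tifffile.imwrite(path, small_image.pixels)
        with pytest.raises(ImageReadError, match="spacing"):
            read_phantom_image(path)


class TestValidateAcquisition:
    def test_matching_protocol_empty(self, small_image):
        assert validate_acquisition(small_image, {"kvp": 80}) == []

    def test_kvp_mismatch(self, small_image):
        violations = validate_acquisition(small_image, {"kvp": 90})
        assert len(violations) == 1 and "kVp" in violations[0]

    def test_absent_kvp_reported(self):
        img = PhantomImage(pixels=np.ones((4, 4)), pixel_spacing_mm=(0.1, 0.1))
        violations = validate_acquisition(img, {"kvp": 80})
        assert any("not recorded" in v for v in violations)

    def test_wrong_detector(self, small_image):
        violations = validate_acquisition(small_image, {"detector_id": "DET-9"})
        assert any("detector" in v for v in violations)

    def test_processed_image_flagged(self, small_image):
        img = PhantomImage(pixels=small_image.pixels, pixel_spacing_mm=(0.1, 0.1),
                           presentation_state="for_presentation")
        violations = validate_acquisition(img, {})
        assert any("for presentation" in v for v in violations)

    def test_never_raises_on_mismatch(self, small_image):
        validate_acquisition(small_image, {"kvp": 999, "detector_id": "X",
                                           "modality": "mammography"})


def _record(**overrides):
    base = dict(device_key="RM-1/DET-1",
                acquisition_datetime=datetime(2020, 5, 6, 7, 8, 9),
                kvp=80.0, mas=10.0, exposure_index=400.0, organ_dose=None,
                entrance_dose=2.5, snr=101.5, sdnr=9.87,
                mtf50_h=1.1, mtf20_h=2.2, mtf10_h=2.9,
                mtf50_v=1.15, mtf20_v=2.25, mtf10_v=2.95,
                dprime_small=14.2, dprime_large=480.0,
                uniformity_flag=False, software_version="0.1.0")
    base.update(overrides)
    return QcRecord(**base)


class TestQcCsv:
    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "qc.csv"
        write_qc_csv([], path)
        assert len(path.read_text().strip().splitlines()) == 1
        assert read_qc_csv(path) == []

    def test_three_records_roundtrip(self, tmp_path):
        records = [_record(), _record(sdnr=10.01), _record(kvp=None)]
        path = tmp_path / "qc.csv"
        write_qc_csv(records, path)
        assert read_qc_csv(path) == records

    def test_absent_is_empty_cell(self, tmp_path):
        path = tmp_path / "qc.csv"
        write_qc_csv([_record(organ_dose=None)], path)
        row = path.read_text().splitlines()[1]
        cells = row.split(",")
        assert cells[5] == ""  # organ_dose column
        assert read_qc_csv(path)[0].organ_dose is None

    def test_malformed_row_names_row_number(self, tmp_path):
        path = tmp_path / "qc.csv"
        write_qc_csv([_record()], path)
        with open(path, "a", encoding="utf-8") as fh:
            fh.write("only,three,cells\n")
        with pytest.raises(CsvFormatError, match="row 3"):
            read_qc_csv(path)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "qc.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(CsvFormatError, match="header"):
            read_qc_csv(path)

    @given(
        kvp=st.one_of(st.none(), st.floats(1e-3, 1e3, allow_nan=False)),
        sdnr=st.one_of(st.none(), st.floats(-1e6, 1e6, allow_nan=False)),
        ei=st.one_of(st.none(), st.floats(0, 1e5, allow_nan=False)),
        flag=st.booleans(),
        device=st.text(
            alphabet=st.characters(codec="utf-8", exclude_characters=",\r\n\"'"),
            max_size=12),
    )
    @settings(max_examples=60, deadline=None)
    def test_roundtrip_property(self, tmp_path_factory, kvp, sdnr, ei, flag, device):
        record = _record(kvp=kvp, sdnr=sdnr, exposure_index=ei,
                         uniformity_flag=flag, device_key=device)
        path = tmp_path_factory.mktemp("csv") / "qc.csv"
        write_qc_csv([record], path)
        assert read_qc_csv(path) == [record]
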