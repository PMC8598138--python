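# phantomqc

Automated quality control for radiographic and mammographic phantom images.
Given an unprocessed ("for processing") exposure of a two-target QC plate —
a copper square with slightly slanted edges and a small low-contrast
aluminium square on a uniform attenuator — the package locates the targets
automatically and computes the full objective image-quality metric set:

- **SNR / SDNR** from automatically placed 5×5 mm ROIs,
- **presampled MTF** (horizontal and vertical) from the slanted Cu edges,
  with characteristic frequencies at 50/20/10 %,
- **NNPS** from 3×3 half-overlapping 256×256 px ROIs of a homogeneous
  512×512 px region, after two-pass linear detrending,
- **NPWE detectability index d′** for two disk-detection tasks
  (0.3/4.0 mm disks for radiography, 0.1/0.25 mm for mammography) with a
  band-pass eye filter at 400 mm viewing distance,
- **variance maps** (2×2 mm kernel, normalized to the homogeneous-region
  variance) with dead-pixel/line defect flagging and session-to-session
  persistence matching,
- **control charts** per device and metric with configurable limit
  policies (±10 %, ±15 %, or ±2 SD), monotone-run and moving-average trend
  rules.

A synthetic phantom simulator with analytic ground truth (known blur,
noise, contrast, geometry, gradients, edge roughness, and injected
detector defects) makes the entire pipeline testable without hardware.

## CLI

```sh
# generate a synthetic phantom image (DICOM or TIFF by extension)
phantomqc simulate --config sim.yaml --seed 3 --out image.dcm --truth-out truth.txt

# print header metadata and acquisition-protocol validation
phantomqc inspect image.dcm --config device.yaml

# full analysis of one image; optional report archive directory
phantomqc analyze image.dcm --config device.yaml --out-dir report/

# one QC session: analyze, append to history, apply limits + trend rules.
# exit code 0 = in control, 2 = limit violation, 3 = trend flag
phantomqc session image.dcm --history dev1.csv --policy pct10 --config device.yaml

# render control charts for an existing history CSV
phantomqc trend --history dev1.csv --policy pct10 --out charts/
```

The device config (YAML) may contain `phantom_spec` (plate geometry),
`pixel_spacing_mm` (override/fallback), `protocol` (expected kVp,
detector_id, modality), `tag_map` (vendor-specific DICOM tags for
exposure index / dose fields, as keyword or `"GGGG,EEEE"`),
`nominal_contrast` (task contrast for d′; defaults to the measured Al
contrast), and `device_key`.

The report archive written by `analyze --out-dir` contains `record.csv`
(one QC record), `curves.csv` (MTF/NNPS curves), `variance_map.png`,
`defects.csv` and `report.txt` (violations and warnings).

## Python API

```python
import phantomqc as pq
from phantomqc.phantom_sim import desk_config, device_config_for

cfg = desk_config(seed=1)                      # compact 1024x1024 test phantom
image, truth = pq.simulate_phantom_image(cfg)  # with analytic ground truth
report = pq.analyze_image(image, device_config_for(cfg))
print(report.record.sdnr, report.record.mtf50_h, report.record.dprime_small)
```

Module map: `phantom_sim` (simulator + ground truth), `image_io`
(DICOM/TIFF + QC-record CSV), `roi_locator`, `basic_metrics`,
`spatial_frequency` (MTF/NNPS), `detectability`, `uniformity`
(variance map), `trending` (control charts), `reproducibility`
(repeat-analysis and movement-jitter experiments), `pipeline` + `cli`.

## Conventions

Pixel coordinates are 0-based (row, col) with the origin at the top-left;
lengths convert to mm through the pixel spacing. Edge angles are
clockwise-positive relative to the pixel rows. Images are treated as
"higher value = more signal"; MONOCHROME1 DICOM inputs are inverted on
read. QC record CSVs use comma separation, `.` decimals, ISO-8601
datetimes and empty cells for absent values; absent header values are
never silently replaced by zero.
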