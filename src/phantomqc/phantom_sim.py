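"""Synthetic phantom-image generator with known ground truth.

Renders the two-target QC plate (high-contrast copper square with slanted
edges, low-contrast aluminium square) on a uniform attenuator, applies a
Gaussian system blur, Poisson quantum noise with configurable gain plus
Gaussian electronic noise, and optional detector artifacts.  The physical
noise/blur model is a stand-in chosen to make every analysis stage testable
against closed-form expectations — it is not a beam-spectrum simulation.

Coordinate convention: 0-based (row, col), origin top-left, lengths in mm
through ``pixel_spacing_mm``.  Identical config + seed gives bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .errors import ConfigurationError, MetricDomainError
from .geometry import OrientedSquare, mm_to_px
from .image_io import AcquisitionMetadata, PhantomImage
from .roi_locator import RoiSet, build_roiset

SUPERSAMPLE = 8  # subpixel rendering factor for area-weighted edge coverage


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the target plate."""

    modality: str = "radiography"
    plate_size_mm: tuple[float, float] = (280.0, 280.0)
    cu_square_side_mm: float = 50.0
    al_square_side_mm: float = 10.0
    cu_edge_angle_deg: float = 3.0
    cu_center_frac: tuple[float, float] = (0.30, 0.30)
    al_center_frac: tuple[float, float] = (0.72, 0.28)

    @staticmethod
    def radiography(**overrides) -> "PhantomSpec":
        return replace(PhantomSpec(), **overrides)

    @staticmethod
    def mammography(**overrides) -> "PhantomSpec":
        base = PhantomSpec(modality="mammography", plate_size_mm=(300.0, 240.0),
                           cu_square_side_mm=50.0, al_square_side_mm=10.0)
        return replace(base, **overrides)

    def validate(self) -> None:
        if self.modality not in ("radiography", "mammography"):
            raise ConfigurationError(f"modality: unknown value {self.modality!r}")
        for name, side, frac in (("cu", self.cu_square_side_mm, self.cu_center_frac),
                                 ("al", self.al_square_side_mm, self.al_center_frac)):
            if side <= 0:
                raise ConfigurationError(f"{name}_square_side_mm must be positive")
            # allow for rotation: the square's circumradius must stay inside
            half_diag = side / math.sqrt(2.0)
            for axis, plate in zip(frac, self.plate_size_mm):
                lo, hi = axis * plate - half_diag, axis * plate + half_diag
                if lo < 0 or hi > plate:
                    raise ConfigurationError(
                        f"{name}_center_frac: square of side {side} mm does not fit "
                        f"inside the {self.plate_size_mm} mm plate at {frac}")


@dataclass(frozen=True)
class ArtifactSpec:
    """An injected detector defect."""

    kind: str  # dead_pixel | dead_row | dead_column | blob
    location_px: tuple[int, int]
    magnitude: float = 0.0
    radius_px: int = 4  # blob only

    def validate(self, shape: tuple[int, int]) -> None:
        if self.kind not in ("dead_pixel", "dead_row", "dead_column", "blob"):
            raise ConfigurationError(f"artifacts: unknown kind {self.kind!r}")
        r, c = self.location_px
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ConfigurationError(
                f"artifacts: location {self.location_px} outside image {shape}")


@dataclass(frozen=True)
class SimulationConfig:
    spec: PhantomSpec = field(default_factory=PhantomSpec)
    pixel_spacing_mm: float = 0.1
    image_size_px: tuple[int, int] | None = None  # default: plate size / spacing
    mean_background_signal: float = 10000.0
    cu_transmission: float = 0.4
    al_transmission: float = 0.9
    blur_sigma_mm: float = 0.3
    poisson_gain: float = 1.0
    electronic_noise_sd: float = 0.0
    gradient_slope: tuple[float, float] = (0.0, 0.0)  # detector units per mm (row, col)
    # RMS perpendicular deviation of the Cu square's edges (hand-cut edges are
    # not perfectly straight); 0 renders ideal edges
    cu_edge_roughness_mm: float = 0.0
    cu_edge_roughness_corr_mm: float = 2.0
    artifacts: tuple[ArtifactSpec, ...] = ()
    seed: int = 0
    metadata: AcquisitionMetadata = field(default_factory=lambda: AcquisitionMetadata(
        kvp=80.0, tube_load_mas=10.0, exposure_index=400.0, anode_filter="W/Al",
        detector_id="SIM-DET-1", station_name="SIM-STATION",
        acquisition_datetime=datetime(2020, 1, 1, 8, 0, 0)))

    @property
    def shape(self) -> tuple[int, int]:
        if self.image_size_px is not None:
            return tuple(self.image_size_px)  # type: ignore[return-value]
        return (int(round(self.spec.plate_size_mm[0] / self.pixel_spacing_mm)),
                int(round(self.spec.plate_size_mm[1] / self.pixel_spacing_mm)))

    def validate(self) -> None:
        self.spec.validate()
        if self.pixel_spacing_mm <= 0:
            raise ConfigurationError("pixel_spacing_mm must be positive")
        if self.mean_background_signal <= 0:
            raise ConfigurationError("mean_background_signal must be positive")
        for name, t in (("cu_transmission", self.cu_transmission),
                        ("al_transmission", self.al_transmission)):
            if not (0 < t <= 1):
                raise ConfigurationError(f"{name} must lie in (0, 1], got {t}")
        for name, v in (("blur_sigma_mm", self.blur_sigma_mm),
                        ("poisson_gain", self.poisson_gain),
                        ("electronic_noise_sd", self.electronic_noise_sd),
                        ("cu_edge_roughness_mm", self.cu_edge_roughness_mm)):
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        shape = self.shape
        for name, frac, side in (("cu_center_frac", self.spec.cu_center_frac,
                                  self.spec.cu_square_side_mm),
                                 ("al_center_frac", self.spec.al_center_frac,
                                  self.spec.al_square_side_mm)):
            half = mm_to_px(side, self.pixel_spacing_mm) / math.sqrt(2.0)
            for axis in range(2):
                c = frac[axis] * shape[axis]
                if c - half < 0 or c + half > shape[axis]:
                    raise ConfigurationError(
                        f"{name}: target extends outside the image along axis {axis}")
        for art in self.artifacts:
            art.validate(shape)


@dataclass(frozen=True)
class AnalyticMtf:
    """Closed-form system MTF: Gaussian blur times pixel-aperture sinc."""

    blur_sigma_mm: float
    pixel_spacing_mm: float

    def __call__(self, u_cyc_mm) -> np.ndarray:
        u = np.asarray(u_cyc_mm, dtype=float)
        gauss = np.exp(-2.0 * math.pi ** 2 * self.blur_sigma_mm ** 2 * u ** 2)
        aperture = np.abs(np.sinc(self.pixel_spacing_mm * u))
        return gauss * aperture


@dataclass(frozen=True)
class GroundTruth:
    analytic_mtf: AnalyticMtf
    expected_sdnr: float
    expected_nnps_level: float  # mm^2
    roi_truth: RoiSet
    cu_center_px: tuple[float, float]
    al_center_px: tuple[float, float]
    cu_angle_deg: float


def expected_sdnr(config: SimulationConfig) -> float:
    """Analytic SDNR oracle: (M - M*t_al) / sqrt(g*M + sigma_e^2)."""
    m = config.mean_background_signal
    noise_var = config.poisson_gain * m + config.electronic_noise_sd ** 2
    if noise_var <= 0:
        raise MetricDomainError("SDNR undefined for a noise-free configuration")
    return m * (1.0 - config.al_transmission) / math.sqrt(noise_var)


def expected_noise_variance(config: SimulationConfig) -> float:
    return (config.poisson_gain * config.mean_background_signal
            + config.electronic_noise_sd ** 2)


def _edge_displacement(rng: np.random.Generator, coords: np.ndarray,
                       rms_px: float, corr_px: float) -> np.ndarray:
    """Smooth random perpendicular displacement sampled at ``coords`` (px)."""
    lo, hi = float(coords.min()), float(coords.max())
    step = 0.25
    grid = np.arange(lo - 4 * corr_px, hi + 4 * corr_px + step, step)
    noise = gaussian_filter1d(rng.normal(0.0, 1.0, grid.size), corr_px / step,
                              mode="reflect")
    sd = noise.std()
    if sd > 0:
        noise *= rms_px / sd
    return np.interp(coords, grid, noise)


def _square_coverage(shape: tuple[int, int], square: OrientedSquare,
                     roughness_px: float = 0.0, roughness_corr_px: float = 20.0,
                     rng: np.random.Generator | None = None) -> tuple:
    """Area-weighted coverage of the square, supersampled then box-averaged.

    Returns (row0, col0, coverage_patch) for the square's bounding box.
    """
    rect = square.bounding_rect(margin_px=2)
    r0, c0 = max(rect.row0, 0), max(rect.col0, 0)
    r1, c1 = min(rect.row1, shape[0]), min(rect.col1, shape[1])
    h, w = r1 - r0, c1 - c0
    s = SUPERSAMPLE
    rr = r0 + (np.arange(h * s) + 0.5) / s - 0.5
    cc = c0 + (np.arange(w * s) + 0.5) / s - 0.5
    dr = rr[:, None] - square.center_rc[0]
    dc = cc[None, :] - square.center_rc[1]
    th = math.radians(square.angle_deg)
    u = math.cos(th) * dr + math.sin(th) * dc
    v = -math.sin(th) * dr + math.cos(th) * dc
    half = square.side_px / 2.0
    if roughness_px > 0 and rng is not None:
        axis = np.arange(-half - 2, half + 2, 0.25)
        disp = [_edge_displacement(rng, axis, roughness_px, roughness_corr_px)
                for _ in range(4)]
        inside = ((u >= -half + np.interp(v, axis, disp[0]))
                  & (u <= half + np.interp(v, axis, disp[1]))
                  & (v >= -half + np.interp(u, axis, disp[2]))
                  & (v <= half + np.interp(u, axis, disp[3])))
    else:
        inside = (np.abs(u) <= half) & (np.abs(v) <= half)
    coverage = inside.reshape(h, s, w, s).mean(axis=(1, 3))
    return r0, c0, coverage


def _apply_artifacts(img: np.ndarray, artifacts: tuple[ArtifactSpec, ...]) -> None:
    for art in artifacts:
        r, c = art.location_px
        if art.kind == "dead_pixel":
            img[r, c] = art.magnitude
        elif art.kind == "dead_row":
            img[r, :] = art.magnitude
        elif art.kind == "dead_column":
            img[:, c] = art.magnitude
        elif art.kind == "blob":
            rr, cc = np.ogrid[:img.shape[0], :img.shape[1]]
            disk = (rr - r) ** 2 + (cc - c) ** 2 <= art.radius_px ** 2
            img[disk] += art.magnitude


def simulate_phantom_image(config: SimulationConfig) -> tuple[PhantomImage, GroundTruth]:
    """Render one phantom exposure plus its analytic ground truth."""
    config.validate()
    shape = config.shape
    p = config.pixel_spacing_mm
    spec = config.spec

    cu_center = (spec.cu_center_frac[0] * shape[0], spec.cu_center_frac[1] * shape[1])
    al_center = (spec.al_center_frac[0] * shape[0], spec.al_center_frac[1] * shape[1])
    cu_side_px = mm_to_px(spec.cu_square_side_mm, p)
    al_side_px = mm_to_px(spec.al_square_side_mm, p)
    cu_square = OrientedSquare(cu_center, cu_side_px, spec.cu_edge_angle_deg)
    al_square = OrientedSquare(al_center, al_side_px, 0.0)

    # background with optional planar gradient, centred so the mean is preserved
    m = config.mean_background_signal
    gr, gc = config.gradient_slope
    rows_mm = (np.arange(shape[0]) - (shape[0] - 1) / 2.0) * p
    cols_mm = (np.arange(shape[1]) - (shape[1] - 1) / 2.0) * p
    scene = np.full(shape, m, dtype=float)
    if gr != 0.0:
        scene += gr * rows_mm[:, None]
    if gc != 0.0:
        scene += gc * cols_mm[None, :]

    rough_px = config.cu_edge_roughness_mm / p
    rough_rng = np.random.default_rng((config.seed, 0xE0))
    transmission = np.ones(shape, dtype=float)
    for square, t, rough in ((cu_square, config.cu_transmission, rough_px),
                             (al_square, config.al_transmission, 0.0)):
        r0, c0, cov = _square_coverage(
            shape, square, roughness_px=rough,
            roughness_corr_px=config.cu_edge_roughness_corr_mm / p, rng=rough_rng)
        transmission[r0:r0 + cov.shape[0], c0:c0 + cov.shape[1]] -= (1.0 - t) * cov
    scene *= transmission

    if config.blur_sigma_mm > 0:
        scene = gaussian_filter(scene, sigma=config.blur_sigma_mm / p, mode="nearest")

    rng = np.random.default_rng(config.seed)
    if config.poisson_gain > 0:
        img = rng.poisson(scene / config.poisson_gain).astype(float) * config.poisson_gain
    else:
        img = scene
    if config.electronic_noise_sd > 0:
        img = img + rng.normal(0.0, config.electronic_noise_sd, size=shape)

    _apply_artifacts(img, config.artifacts)

    img = np.rint(img)
    if img.min() < 0 or img.max() > 0xFFFF:
        raise ConfigurationError(
            f"rendered signal range [{img.min():g}, {img.max():g}] clips the 16-bit "
            "output; lower mean_background_signal or the noise parameters")
    pixels = img.astype(np.uint16)

    roi_truth = build_roiset(shape, p, cu_square, al_center, al_side_px)
    try:
        sdnr = expected_sdnr(config)
    except MetricDomainError:
        sdnr = math.inf
    truth = GroundTruth(
        analytic_mtf=AnalyticMtf(config.blur_sigma_mm, p),
        expected_sdnr=sdnr,
        expected_nnps_level=expected_noise_variance(config) * p * p / (m * m),
        roi_truth=roi_truth,
        cu_center_px=cu_center,
        al_center_px=al_center,
        cu_angle_deg=spec.cu_edge_angle_deg,
    )
    image = PhantomImage(pixels=pixels, pixel_spacing_mm=(p, p), modality=spec.modality,
                         presentation_state="for_processing", metadata=config.metadata,
                         provenance=[f"simulated (seed={config.seed})"])
    return image, truth


def desk_config(modality: str = "radiography", seed: int = 0, **overrides) -> SimulationConfig:
    """A compact 1024x1024, 0.1 mm/px configuration used for desk-scale tests.

    The plate is scaled down from the physical design so a full analysis runs
    in seconds; all geometric relationships (slanted Cu square, low-contrast
    Al square, homogeneous noise region) are preserved.
    """
    if modality == "radiography":
        spec = PhantomSpec.radiography(
            plate_size_mm=(102.4, 102.4), cu_square_side_mm=25.0,
            al_square_side_mm=8.0, cu_edge_angle_deg=3.0,
            cu_center_frac=(0.28, 0.28), al_center_frac=(0.72, 0.25))
        transmissions = {"cu_transmission": 0.4, "al_transmission": 0.9}
    elif modality == "mammography":
        spec = PhantomSpec.mammography(
            plate_size_mm=(102.4, 102.4), cu_square_side_mm=25.0,
            al_square_side_mm=8.0, cu_edge_angle_deg=3.0,
            cu_center_frac=(0.28, 0.28), al_center_frac=(0.72, 0.25))
        transmissions = {"cu_transmission": 0.3, "al_transmission": 0.95}
    else:
        raise ConfigurationError(f"unknown modality {modality!r}")
    base = SimulationConfig(spec=spec, pixel_spacing_mm=0.1, image_size_px=(1024, 1024),
                            mean_background_signal=10000.0, blur_sigma_mm=0.3,
                            poisson_gain=1.0, electronic_noise_sd=20.0, seed=seed,
                            **transmissions)
    return replace(base, **overrides)


def device_config_for(config: SimulationConfig, **extra) -> dict:
    """Device-config mapping matching a simulation's phantom geometry, for
    feeding simulated images straight into the analysis pipeline."""
    s = config.spec
    cfg = {
        "phantom_spec": {
            "modality": s.modality,
            "plate_size_mm": list(s.plate_size_mm),
            "cu_square_side_mm": s.cu_square_side_mm,
            "al_square_side_mm": s.al_square_side_mm,
            "cu_edge_angle_deg": s.cu_edge_angle_deg,
            "cu_center_frac": list(s.cu_center_frac),
            "al_center_frac": list(s.al_center_frac),
        },
        "pixel_spacing_mm": config.pixel_spacing_mm,
    }
    cfg.update(extra)
    return cfg


# ---------------------------------------------------------------------------
# config file / sidecar I/O


def config_from_mapping(data: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain (YAML-loaded) mapping."""
    data = dict(data)
    spec_data = dict(data.pop("spec", {}))
    for key in ("plate_size_mm", "cu_center_frac", "al_center_frac"):
        if key in spec_data:
            spec_data[key] = tuple(spec_data[key])
    spec = PhantomSpec(**spec_data)
    artifacts = tuple(
        ArtifactSpec(kind=a["kind"], location_px=tuple(a["location_px"]),
                     magnitude=a.get("magnitude", 0.0),
                     radius_px=a.get("radius_px", 4))
        for a in data.pop("artifacts", []))
    md = dict(data.pop("metadata", {}))
    if isinstance(md.get("acquisition_datetime"), str):
        md["acquisition_datetime"] = datetime.fromisoformat(md["acquisition_datetime"])
    metadata = AcquisitionMetadata(**md)
    for key in ("image_size_px", "gradient_slope"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return SimulationConfig(spec=spec, artifacts=artifacts, metadata=metadata, **data)


def write_ground_truth(path, truth: GroundTruth) -> None:
    """Plain-text key=value sidecar describing the simulated ground truth."""
    lines = [
        f"blur_sigma_mm={truth.analytic_mtf.blur_sigma_mm!r}",
        f"pixel_spacing_mm={truth.analytic_mtf.pixel_spacing_mm!r}",
        f"expected_sdnr={truth.expected_sdnr!r}",
        f"expected_nnps_level={truth.expected_nnps_level!r}",
        f"cu_center_px={truth.cu_center_px[0]!r},{truth.cu_center_px[1]!r}",
        f"al_center_px={truth.al_center_px[0]!r},{truth.al_center_px[1]!r}",
        f"cu_angle_deg={truth.cu_angle_deg!r}",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
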