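import math

import numpy as np
import pytest
from dataclasses import replace
from scipy.optimize import brentq
from scipy.stats import norm

from conftest import MTF_BAND_PX, mtf_config
from phantomqc import (build_oversampled_esf, characteristic_frequencies,
                       common_grid, compute_nnps, compute_presampled_mtf,
                       desk_config, detrend_region, estimate_edge_angle,
                       locate_rois, simulate_phantom_image)
from phantomqc.errors import MetricDomainError
from phantomqc.image_io import PhantomImage
from phantomqc.spatial_frequency import (EsfProfile, MtfCurve, NnpsCurve,
                                         average_curves)


@pytest.fixture(scope="module")
def sharp_sim():
    cfg = mtf_config(sigma_mm=0.5)
    image, truth = simulate_phantom_image(cfg)
    rs = locate_rois(image, cfg.spec)
    return cfg, image, truth, rs


class TestEdgeAngle:
    def test_recovers_three_degrees(self, sharp_sim):
        _, image, truth, rs = sharp_sim
        est = estimate_edge_angle(image, rs.edge_segments["left"])
        assert est.degrees == pytest.approx(3.0, abs=0.1)
        assert est.warnings == ()

    def test_mirrored_image_negates_angle(self, sharp_sim):
        _, image, _, rs = sharp_sim
        mirrored = PhantomImage(pixels=np.fliplr(np.asarray(image.pixels)),
                                pixel_spacing_mm=image.pixel_spacing_mm)
        w = image.shape[1]
        (r0, c0), (r1, c1) = rs.edge_segments["left"]
        seg = ((r0, w - 1 - c0), (r1, w - 1 - c1))
        est = estimate_edge_angle(image, rs.edge_segments["left"])
        est_m = estimate_edge_angle(mirrored, seg)
        assert est_m.degrees == pytest.approx(-est.degrees, abs=0.05)

    def test_zero_degree_edge_warns(self):
        cfg = mtf_config(sigma_mm=0.2)
        cfg = replace(cfg, spec=replace(cfg.spec, cu_edge_angle_deg=0.0))
        image, _ = simulate_phantom_image(cfg)
        rs_truth = _truth_roiset(cfg)
        est = estimate_edge_angle(image, rs_truth.edge_segments["left"])
        assert abs(est.degrees) < 0.05
        assert any("outside" in w for w in est.warnings)

    def test_top_edge_angle_sign_matches(self, sharp_sim):
        _, image, truth, rs = sharp_sim
        est_left = estimate_edge_angle(image, rs.edge_segments["left"])
        est_top = estimate_edge_angle(image, rs.edge_segments["top"])
        assert est_top.degrees == pytest.approx(est_left.degrees, abs=0.1)


def _truth_roiset(cfg):
    _, truth = simulate_phantom_image(cfg)
    return truth.roi_truth


class TestEsf:
    def test_ideal_step_preserved(self):
        cfg = mtf_config(sigma_mm=0.0)
        image, truth = simulate_phantom_image(cfg)
        seg = truth.roi_truth.edge_segments["left"]
        est = estimate_edge_angle(image, seg)
        esf = build_oversampled_esf(image, seg, est.degrees, band_halfwidth_px=30)
        v = esf.values
        lo, hi = v[:20].mean(), v[-20:].mean()
        inside_lo = esf.positions_px < -0.8
        inside_hi = esf.positions_px > 0.8
        assert np.all(np.abs(v[inside_lo] - lo) < 0.01 * (hi - lo))
        assert np.all(np.abs(v[inside_hi] - hi) < 0.01 * (hi - lo))

    def test_gaussian_cdf_match(self, sharp_sim):
        cfg, image, truth, rs = sharp_sim
        seg = truth.roi_truth.edge_segments["left"]
        est = estimate_edge_angle(image, seg)
        esf = build_oversampled_esf(image, seg, est.degrees,
                                    band_halfwidth_px=MTF_BAND_PX)
        sigma_px = cfg.blur_sigma_mm / cfg.pixel_spacing_mm
        v = esf.values
        lo, hi = v[:50].mean(), v[-50:].mean()
        # centre the model on the fitted 50 % point
        mid_pos = np.interp(0.5 * (lo + hi), v, esf.positions_px)
        model = lo + (hi - lo) * norm.cdf((esf.positions_px - mid_pos) / sigma_px)
        rms = np.sqrt(np.mean((v - model) ** 2)) / (hi - lo)
        assert rms < 0.01

    def test_band_width_stability(self, sharp_sim):
        _, image, truth, rs = sharp_sim
        seg = truth.roi_truth.edge_segments["left"]
        est = estimate_edge_angle(image, seg)
        narrow = build_oversampled_esf(image, seg, est.degrees, band_halfwidth_px=60)
        wide = build_oversampled_esf(image, seg, est.degrees, band_halfwidth_px=120)
        v_wide = np.interp(narrow.positions_px, wide.positions_px, wide.values)
        contrast = abs(narrow.values[-5:].mean() - narrow.values[:5].mean())
        rms = np.sqrt(np.mean((narrow.values - v_wide) ** 2)) / contrast
        assert rms < 0.005


class TestMtf:
    @pytest.mark.parametrize("sigma", [0.2, 0.5])
    def test_gaussian_aperture_oracle(self, sigma):
        cfg = mtf_config(sigma_mm=sigma)
        image, truth = simulate_phantom_image(cfg)
        seg = truth.roi_truth.edge_segments["left"]
        est = estimate_edge_angle(image, seg)
        esf = build_oversampled_esf(image, seg, est.degrees,
                                    band_halfwidth_px=MTF_BAND_PX)
        mtf = compute_presampled_mtf(esf, cfg.pixel_spacing_mm)
        expected = truth.analytic_mtf(mtf.frequencies)
        keep = mtf.frequencies <= 5.0
        assert np.max(np.abs(mtf.values[keep] - expected[keep])) < 0.02

    def test_zero_blur_is_aperture_only(self):
        cfg = mtf_config(sigma_mm=0.0)
        image, truth = simulate_phantom_image(cfg)
        seg = truth.roi_truth.edge_segments["left"]
        est = estimate_edge_angle(image, seg)
        esf = build_oversampled_esf(image, seg, est.degrees,
                                    band_halfwidth_px=MTF_BAND_PX)
        mtf = compute_presampled_mtf(esf, cfg.pixel_spacing_mm)
        aperture = np.abs(np.sinc(cfg.pixel_spacing_mm * mtf.frequencies))
        assert np.max(np.abs(mtf.values - aperture)) < 0.02

    def test_normalised_at_zero(self, sharp_sim):
        cfg, image, truth, rs = sharp_sim
        seg = truth.roi_truth.edge_segments["left"]
        est = estimate_edge_angle(image, seg)
        esf = build_oversampled_esf(image, seg, est.degrees)
        mtf = compute_presampled_mtf(esf, cfg.pixel_spacing_mm)
        assert mtf.values[0] == 1.0
        assert mtf.frequencies[0] == 0.0
        assert mtf.frequencies[-1] <= 1 / (2 * cfg.pixel_spacing_mm) * (1 + 1e-9)

    def test_zero_contrast_edge_raises(self):
        flat = EsfProfile(positions_px=np.arange(-400, 400) * 0.1,
                          values=np.full(800, 1000.0))
        with pytest.raises(MetricDomainError):
            compute_presampled_mtf(flat, 0.1)

    def test_angle_insensitivity_2_vs_5_deg(self):
        curves = []
        for angle in (2.0, 5.0):
            cfg = mtf_config(sigma_mm=0.5)
            cfg = replace(cfg, spec=replace(cfg.spec, cu_edge_angle_deg=angle))
            image, truth = simulate_phantom_image(cfg)
            seg = truth.roi_truth.edge_segments["left"]
            est = estimate_edge_angle(image, seg)
            esf = build_oversampled_esf(image, seg, est.degrees,
                                        band_halfwidth_px=120)
            curves.append(compute_presampled_mtf(esf, cfg.pixel_spacing_mm))
        u = np.linspace(0, 5.0, 200)
        diff = curves[0].at(u) - curves[1].at(u)
        assert np.sqrt(np.mean(diff ** 2)) < 0.02


class TestCharacteristicFrequencies:
    def test_gaussian_closed_form_ratio(self):
        a = 2 * math.pi ** 2 * 0.5 ** 2
        u = np.linspace(0, 5, 2000)
        mtf = MtfCurve(u, np.exp(-a * u ** 2), "averaged")
        cf = characteristic_frequencies(mtf)
        assert cf.f50 / cf.f10 == pytest.approx(math.sqrt(math.log(2) / math.log(10)),
                                                rel=0.01)
        f50_true = brentq(lambda x: math.exp(-a * x * x) - 0.5, 1e-9, 5)
        assert cf.f50 == pytest.approx(f50_true, rel=0.01)

    def test_uncrossed_level_absent(self):
        u = np.linspace(0, 5, 100)
        mtf = MtfCurve(u, np.linspace(1.0, 0.65, 100), "averaged")
        cf = characteristic_frequencies(mtf)
        assert cf.f50 is None and cf.f20 is None and cf.f10 is None

    def test_ordering_on_monotone_curve(self):
        u = np.linspace(0, 5, 500)
        mtf = MtfCurve(u, np.exp(-1.5 * u), "averaged")
        cf = characteristic_frequencies(mtf)
        assert cf.f50 < cf.f20 < cf.f10


class TestDetrend:
    def test_exact_ramp_removal(self):
        rows = np.arange(64)[:, None]
        cols = np.arange(64)[None, :]
        ramp = 100.0 + 0.5 * rows + 1.5 * cols
        out = detrend_region(ramp)
        assert out.std() < 1e-6 * (ramp.max() - ramp.min())
        assert out.mean() == pytest.approx(ramp.mean())

    def test_white_noise_nearly_unchanged(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(1000, 50, (256, 256))
        out = detrend_region(noise)
        assert out.var() == pytest.approx(noise.var(), rel=0.01)
        assert out.mean() == pytest.approx(noise.mean(), rel=1e-9)


class TestNnps:
    def test_white_noise_level_and_parseval(self):
        rng = np.random.default_rng(0)
        m, sd, p = 1e4, 100.0, 0.1
        region = rng.normal(m, sd, (512, 512))
        res = compute_nnps(region, p)
        expected = sd * sd * p * p / (m * m)
        # band-averaged flatness
        assert res.averaged.values[3:].mean() == pytest.approx(expected, rel=0.05)
        total = res.nnps_2d.sum() * res.freq_step ** 2
        assert total == pytest.approx(sd * sd / (m * m), rel=0.02)

    def test_constant_region_zero(self):
        res = compute_nnps(np.full((512, 512), 500.0), 0.1)
        assert np.all(np.abs(res.averaged.values) < 1e-20)
        assert np.all(np.abs(res.radial.values) < 1e-20)

    def test_nonpositive_mean_raises(self):
        with pytest.raises(MetricDomainError):
            compute_nnps(np.full((512, 512), -1.0), 0.1)

    def test_two_seeds_agree(self):
        levels = []
        for seed in (1, 2):
            rng = np.random.default_rng(seed)
            region = rng.normal(1e4, 100.0, (512, 512))
            res = compute_nnps(region, 0.1)
            levels.append(res.averaged.values[3:].mean())
        assert levels[0] == pytest.approx(levels[1], rel=0.05)

    def test_curve_metadata(self):
        rng = np.random.default_rng(5)
        region = rng.normal(2e4, 80.0, (512, 512))
        res = compute_nnps(region, 0.05)
        assert res.horizontal.large_area_mean == pytest.approx(2e4, rel=1e-3)
        assert res.horizontal.large_area_variance == pytest.approx(80.0 ** 2, rel=0.05)
        assert res.horizontal.frequencies[-1] == pytest.approx(1 / (2 * 0.05))


class TestCommonGrid:
    def test_exact_at_shared_points(self):
        u_fine = np.linspace(0, 5, 501)
        mtf = MtfCurve(u_fine, np.exp(-u_fine), "horizontal")
        u_coarse = u_fine[::4]
        nnps = NnpsCurve(u_coarse, np.ones_like(u_coarse), "averaged", 1e4, 1e4)
        mtf_c, nnps_c = common_grid(mtf, nnps)
        assert np.allclose(mtf_c.values, np.exp(-u_coarse))
        assert np.array_equal(mtf_c.frequencies, nnps_c.frequencies)

    def test_linear_segment_interpolated_exactly(self):
        mtf = MtfCurve(np.array([0.0, 1.0]), np.array([1.0, 0.0]), "horizontal")
        nnps = NnpsCurve(np.array([0.0, 0.25, 0.5, 1.0]), np.ones(4), "averaged",
                         1e4, 1e4)
        mtf_c, _ = common_grid(mtf, nnps)
        assert np.allclose(mtf_c.values, [1.0, 0.75, 0.5, 0.0])

    def test_average_of_identical_curves(self):
        u = np.linspace(0, 5, 64)
        mtf = MtfCurve(u, np.exp(-u), "horizontal")
        avg = average_curves(mtf, MtfCurve(u, np.exp(-u), "vertical"))
        assert np.allclose(avg.values, mtf.values)
        assert avg.direction == "averaged"
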