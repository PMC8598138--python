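import hashlib
import math
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phantomqc.errors import ConfigurationError
from phantomqc.image_io import QcRecord
from phantomqc.trending import (ControlChart, apply_limits, build_chart,
                                detect_trend, establish_baseline, render_charts)


def _records(values, metric="sdnr", device="dev1"):
    t0 = datetime(2020, 1, 1)
    return [QcRecord(device_key=device, acquisition_datetime=t0 + timedelta(days=i),
                     **{metric: v}) for i, v in enumerate(values)]


def _chart(values, policy="pct10", baseline_mean=None, baseline_sd=None,
           n_baseline=5):
    if baseline_mean is None:
        baseline_mean, baseline_sd = establish_baseline(
            _records(values), "sdnr", n_baseline)
    chart = ControlChart(device_key="dev1", metric_name="sdnr",
                         timestamps=list(range(len(values))),
                         values=list(values), baseline_mean=baseline_mean,
                         baseline_sd=baseline_sd, limit_policy=policy,
                         n_baseline=n_baseline)
    chart.flags = apply_limits(chart)
    return chart


class TestBaseline:
    def test_hand_arithmetic(self):
        mean, sd = establish_baseline(_records([98, 100, 102, 100, 100]), "sdnr", 5)
        assert mean == 100.0
        assert sd == pytest.approx(math.sqrt(2.0))

    def test_too_few_records(self):
        with pytest.raises(ConfigurationError):
            establish_baseline(_records([1, 2, 3]), "sdnr", 5)

    def test_n_baseline_exceeds_available(self):
        with pytest.raises(ConfigurationError):
            establish_baseline(_records([1, 2, 3, 4, 5, 6]), "sdnr", 10)

    def test_constant_baseline_sd_zero(self):
        mean, sd = establish_baseline(_records([5.0] * 6), "sdnr", 5)
        assert mean == 5.0 and sd == 0.0

    def test_baseline_immutable_under_append(self):
        values = [100, 101, 99, 100, 100]
        chart = _chart(values)
        extended = _chart(values + [500, 600], baseline_mean=chart.baseline_mean,
                          baseline_sd=chart.baseline_sd)
        assert extended.baseline_mean == chart.baseline_mean
        assert extended.baseline_sd == chart.baseline_sd


class TestLimits:
    def test_pct10_flags_high(self):
        chart = _chart([100, 100, 100, 100, 100, 111])
        assert chart.flags == ["ok"] * 5 + ["high"]

    def test_sd2_inside(self):
        chart = _chart([100, 105, 95, 100, 100, 109], policy="sd2",
                       baseline_mean=100.0, baseline_sd=5.0)
        assert chart.flags[-1] == "ok"

    def test_exactly_on_limit_is_ok(self):
        chart = _chart([100, 100, 100, 100, 100, 110.0],
                       baseline_mean=100.0, baseline_sd=1.0)
        assert chart.flags[-1] == "ok"

    def test_low_flag(self):
        chart = _chart([100, 100, 100, 100, 100, 80])
        assert chart.flags[-1] == "low"

    def test_sd2_with_zero_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            _chart([100.0] * 6, policy="sd2", baseline_mean=100.0,
                   baseline_sd=0.0)

    def test_pct15_wider_than_pct10(self):
        values = [100, 100, 100, 100, 100, 112]
        assert _chart(values, "pct10").flags[-1] == "high"
        assert _chart(values, "pct15").flags[-1] == "ok"

    @given(st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=5, max_size=40),
           st.sampled_from(["pct10", "pct15", "sd2"]))
    @settings(max_examples=100, deadline=None)
    def test_flags_match_brute_force(self, values, policy):
        baseline_mean, baseline_sd = 100.0, 7.5
        chart = _chart(values, policy, baseline_mean, baseline_sd)
        half = {"pct10": 10.0, "pct15": 15.0, "sd2": 15.0}[policy]
        for v, flag in zip(values, chart.flags):
            if v > baseline_mean + half:
                assert flag == "high"
            elif v < baseline_mean - half:
                assert flag == "low"
            else:
                assert flag == "ok"


class TestTrend:
    def test_decreasing_run_flagged(self):
        chart = _chart([100, 100, 100, 100, 100, 99, 98, 97, 96, 95, 94],
                       baseline_mean=100.0, baseline_sd=10.0)
        report = detect_trend(chart, window=6)
        assert report.monotone_run and report.run_direction == "down"

    def test_no_false_positive_rate_on_iid_noise(self):
        rng = np.random.default_rng(0)
        n_flagged = 0
        n_sim = 300
        for _ in range(n_sim):
            values = list(rng.normal(100, 5, 20))
            chart = _chart(values, baseline_mean=100.0, baseline_sd=5.0)
            if detect_trend(chart, window=6).monotone_run:
                n_flagged += 1
        # run-length null: P(6-point strict monotone run in 20 points) << 5 %
        assert n_flagged / n_sim < 0.05

    def test_slow_drift_detected_before_limit(self):
        # decay slow enough that pct10 never fires in the window shown
        values = [100.0] * 10 + [100 - 0.8 * i for i in range(1, 11)]
        chart = _chart(values, baseline_mean=100.0, baseline_sd=1.5,
                       n_baseline=10)
        report = detect_trend(chart, window=6)
        assert report.any_trend
        assert all(f == "ok" for f in chart.flags)

    def test_short_series_no_trend(self):
        chart = _chart([100, 99, 98, 97, 96], baseline_mean=100.0, baseline_sd=5.0)
        assert not detect_trend(chart, window=6).monotone_run


class TestRenderCharts:
    def _history(self):
        rng = np.random.default_rng(4)
        t0 = datetime(2020, 1, 1)
        records = []
        for i in range(15):
            records.append(QcRecord(
                device_key="dev1", acquisition_datetime=t0 + timedelta(days=7 * i),
                kvp=80.0, mas=10.0, exposure_index=float(rng.normal(400, 10)),
                snr=float(rng.normal(100, 2)), sdnr=float(rng.normal(10, 0.2)),
                mtf50_h=0.62, dprime_small=15.0))
        return records

    def test_charts_written(self, tmp_path):
        written = render_charts(self._history(), tmp_path, "pct10", 10)
        assert "sdnr" in written and "overview" in written
        assert (tmp_path / "chart_sdnr.png").exists()
        assert (tmp_path / "overview.png").exists()

    def test_single_record_charts(self, tmp_path):
        # too few points for a baseline: metrics skipped, no crash
        written = render_charts(self._history()[:1], tmp_path, "pct10", 10)
        assert written == {}

    def test_outlier_flagged_in_chart_data(self):
        records = self._history()
        records[12] = QcRecord(device_key="dev1",
                               acquisition_datetime=records[12].acquisition_datetime,
                               exposure_index=40.0)
        chart = build_chart(records, "exposure_index", "pct10", 10)
        assert chart.flags[12] == "low"

    def test_rerender_identical_bytes(self, tmp_path):
        records = self._history()
        render_charts(records, tmp_path / "a", "pct10", 10)
        render_charts(records, tmp_path / "b", "pct10", 10)
        for name in ("chart_sdnr.png", "overview.png"):
            assert hashlib.sha256((tmp_path / "a" / name).read_bytes()).digest() == \
                hashlib.sha256((tmp_path / "b" / name).read_bytes()).digest()
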