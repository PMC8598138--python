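"""Per-device QC history: baselines, control limits, trend rules, charts.

Limit policies: ``pct10``/``pct15`` (baseline +/- 10/15 %) or ``sd2``
(baseline +/- 2 baseline SDs).  A point exactly on a limit is in control
(strict inequality).  Trend detection combines two configurable rules: a
strictly monotone run of at least ``window`` points, and a moving-average
drift of more than one baseline SD; the rules and the default baseline
length (10 sessions) are package choices, not mandated values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime

from .errors import ConfigurationError, MetricDomainError
from .image_io import QcRecord

LIMIT_POLICIES = ("pct10", "pct15", "sd2")
DEFAULT_N_BASELINE = 10
MIN_N_BASELINE = 5
DEFAULT_TREND_WINDOW = 6

CHART_METRICS = ["mas", "kvp", "organ_dose", "entrance_dose", "exposure_index",
                 "snr", "sdnr", "mtf50_h", "mtf20_h", "mtf10_h",
                 "mtf50_v", "mtf20_v", "mtf10_v", "dprime_small", "dprime_large"]


def establish_baseline(records: list[QcRecord], metric_name: str,
                       n_baseline: int = DEFAULT_N_BASELINE) -> tuple[float, float]:
    """Mean and sample SD of the first ``n_baseline`` values of the metric."""
    values = [r.metric(metric_name) for r in records[:n_baseline]]
    values = [v for v in values if v is not None]
    if n_baseline > len(records):
        raise ConfigurationError(
            f"baseline needs {n_baseline} records but only {len(records)} exist")
    if len(values) < MIN_N_BASELINE:
        raise ConfigurationError(
            f"baseline needs at least {MIN_N_BASELINE} recorded values of "
            f"{metric_name!r}, got {len(values)}")
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return mean, sd


@dataclass
class ControlChart:
    device_key: str
    metric_name: str
    timestamps: list[datetime]
    values: list[float | None]
    baseline_mean: float
    baseline_sd: float
    limit_policy: str = "pct10"
    n_baseline: int = DEFAULT_N_BASELINE
    flags: list[str] = field(default_factory=list)  # ok | high | low per point
    moving_average_window: int = DEFAULT_TREND_WINDOW

    def limits(self) -> tuple[float, float]:
        if self.limit_policy == "pct10":
            half = 0.10 * abs(self.baseline_mean)
        elif self.limit_policy == "pct15":
            half = 0.15 * abs(self.baseline_mean)
        elif self.limit_policy == "sd2":
            if self.baseline_sd <= 0:
                raise ConfigurationError(
                    "sd2 limit policy is unusable: baseline SD is zero")
            half = 2.0 * self.baseline_sd
        else:
            raise ConfigurationError(f"unknown limit policy {self.limit_policy!r}")
        return self.baseline_mean - half, self.baseline_mean + half

    def moving_average(self) -> list[float | None]:
        w = self.moving_average_window
        out: list[float | None] = []
        for i in range(len(self.values)):
            window = [v for v in self.values[max(0, i - w + 1):i + 1] if v is not None]
            out.append(sum(window) / len(window) if len(window) == w else None)
        return out


def build_chart(records: list[QcRecord], metric_name: str,
                policy: str = "pct10",
                n_baseline: int = DEFAULT_N_BASELINE) -> ControlChart:
    if policy not in LIMIT_POLICIES:
        raise ConfigurationError(f"unknown limit policy {policy!r}")
    mean, sd = establish_baseline(records, metric_name, n_baseline)
    chart = ControlChart(
        device_key=records[0].device_key if records else "",
        metric_name=metric_name,
        timestamps=[r.acquisition_datetime for r in records],
        values=[r.metric(metric_name) for r in records],
        baseline_mean=mean, baseline_sd=sd, limit_policy=policy,
        n_baseline=n_baseline)
    chart.flags = apply_limits(chart)
    return chart


def apply_limits(chart: ControlChart) -> list[str]:
    """Per-point flags; strictly outside the limits -> high/low, else ok.
    Appending records never changes the stored baseline."""
    lo, hi = chart.limits()
    flags: list[str] = []
    for v in chart.values:
        if v is None:
            flags.append("ok")
        elif v > hi:
            flags.append("high")
        elif v < lo:
            flags.append("low")
        else:
            flags.append("ok")
    return flags


@dataclass(frozen=True)
class TrendReport:
    monotone_run: bool
    run_direction: str | None  # "up" | "down" | None
    run_end_index: int | None
    ma_drift: bool
    drift_index: int | None

    @property
    def any_trend(self) -> bool:
        return self.monotone_run or self.ma_drift


def detect_trend(chart: ControlChart, window: int = DEFAULT_TREND_WINDOW) -> TrendReport:
    """Flag a strictly monotone run of >= window points and a moving-average
    drift of more than one baseline SD from the baseline mean."""
    values = [v for v in chart.values if v is not None]
    monotone, direction, end_idx = False, None, None
    if len(values) >= window:
        run_up = run_down = 1
        for i in range(1, len(values)):
            run_up = run_up + 1 if values[i] > values[i - 1] else 1
            run_down = run_down + 1 if values[i] < values[i - 1] else 1
            if run_up >= window:
                monotone, direction, end_idx = True, "up", i
                break
            if run_down >= window:
                monotone, direction, end_idx = True, "down", i
                break

    drift, drift_idx = False, None
    if chart.baseline_sd > 0:
        ma = chart.moving_average()
        for i, m in enumerate(ma):
            if m is not None and abs(m - chart.baseline_mean) > chart.baseline_sd:
                drift, drift_idx = True, i
                break
    return TrendReport(monotone_run=monotone, run_direction=direction,
                       run_end_index=end_idx, ma_drift=drift, drift_index=drift_idx)


# ---------------------------------------------------------------------------
# chart rendering (matplotlib, Agg, deterministic output)


def render_charts(records: list[QcRecord], out_dir, policy: str = "pct10",
                  n_baseline: int = DEFAULT_N_BASELINE,
                  metrics: list[str] | None = None) -> dict[str, str]:
    """One PNG per metric plus an overview grid; returns {metric: filename}.

    Metrics without enough baseline data are skipped silently (charts exist
    to be looked at; hard errors live in the analysis path).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from pathlib import Path

    if not records:
        raise ConfigurationError("no records to chart")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics = metrics if metrics is not None else CHART_METRICS

    charts: dict[str, ControlChart] = {}
    for metric in metrics:
        values = [r.metric(metric) for r in records]
        if all(v is None for v in values):
            continue
        try:
            charts[metric] = build_chart(records, metric, policy, n_baseline)
        except (ConfigurationError, MetricDomainError):
            continue

    written: dict[str, str] = {}
    for metric, chart in charts.items():
        fig, ax = plt.subplots(figsize=(7, 3.2), dpi=100)
        _draw(ax, chart)
        fig.tight_layout()
        fname = f"chart_{metric}.png"
        fig.savefig(out / fname, metadata={"Software": None})
        plt.close(fig)
        written[metric] = fname

    if charts:
        n = len(charts)
        ncols = 3
        nrows = -(-n // ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(4.0 * ncols, 2.2 * nrows),
                                 dpi=90, squeeze=False)
        for ax in axes.flat:
            ax.set_visible(False)
        for ax, (metric, chart) in zip(axes.flat, charts.items()):
            ax.set_visible(True)
            _draw(ax, chart, compact=True)
        fig.tight_layout()
        fig.savefig(out / "overview.png", metadata={"Software": None})
        plt.close(fig)
        written["overview"] = "overview.png"
    return written


def _draw(ax, chart: ControlChart, compact: bool = False) -> None:
    xs = list(range(len(chart.values)))
    ys = [v if v is not None else float("nan") for v in chart.values]
    ax.plot(xs, ys, "-o", color="#1f77b4", markersize=3 if compact else 5)
    try:
        lo, hi = chart.limits()
        ax.axhline(lo, color="#d62728", linestyle="--", linewidth=0.8)
        ax.axhline(hi, color="#d62728", linestyle="--", linewidth=0.8)
    except ConfigurationError:
        pass
    ax.axhline(chart.baseline_mean, color="#2ca02c", linewidth=0.8)
    bad = [i for i, f in enumerate(chart.flags) if f != "ok"]
    if bad:
        ax.plot([xs[i] for i in bad], [ys[i] for i in bad], "o", color="#d62728",
                markersize=4 if compact else 7, fillstyle="none", markeredgewidth=1.5)
    ax.set_title(chart.metric_name, fontsize=8 if compact else 10)
    if not compact:
        ax.set_xlabel("session")
        ax.set_ylabel(chart.metric_name)
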