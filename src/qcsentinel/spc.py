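"""Statistical-process-control charts over longitudinal QC metric series.

A guide set of initial in-control runs fixes a baseline (mean, sample SD).
Against that baseline the suite provides:

* Levey-Jennings — per-point z-scores with Westgard-style rules
  (default: 1_3s FAIL at |z|>3, 2_2s WARN for two consecutive same-side |z|>2);
* tabular CUSUM — S+/S- recursions with slack k and decision interval h in SD
  units, sensitive to small sustained shifts;
* moving range — |x_i - x_{i-1}| against the individuals-chart limit
  3.267 × mean(MR);
* trailing mean / trailing CV — statistics of the most recent `window` runs.

All charts operate on one metric of one analyte; extraction from the
measurement table happens in :func:`extract_metric`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .analytes import expected_envelope
from .errors import InsufficientDataError, UndefinedScoreError, ValidationError
from .ingest import MeasurementTable, RunLog, RunType
from .isotope import idotp

__all__ = [
    "Metric",
    "Chart",
    "Flag",
    "MetricSeries",
    "Baseline",
    "ChartResult",
    "extract_metric",
    "establish_baseline",
    "levey_jennings",
    "cusum",
    "moving_range",
    "trailing_stats",
    "MOVING_RANGE_D4",
]


class Metric(str, Enum):
    PRECURSOR_AREA = "PRECURSOR_AREA"
    TRANSITION_AREA = "TRANSITION_AREA"
    AREA_RATIO = "AREA_RATIO"
    RT_MIN = "RT_MIN"
    MASS_ERROR_PPM = "MASS_ERROR_PPM"
    IDOTP = "IDOTP"


class Chart(str, Enum):
    LEVEY_JENNINGS = "LEVEY_JENNINGS"
    CUSUM = "CUSUM"
    MOVING_RANGE = "MOVING_RANGE"
    TRAILING_MEAN = "TRAILING_MEAN"
    TRAILING_CV = "TRAILING_CV"


class Flag(str, Enum):
    PASS = "PASS"
    WARN = "WARN"
    FAIL = "FAIL"


#: n=2 individuals-chart upper control constant for the moving-range chart.
MOVING_RANGE_D4 = 3.267


@dataclass
class MetricSeries:
    """Ordered per-run values of one metric for one analyte."""

    metric: Metric
    analyte_id: str
    points: pd.DataFrame  # columns: run_id, acquired_at, value
    n_omitted: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.points["value"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Baseline:
    """Guide-set mean and sample SD (n-1 denominator)."""

    mean: float
    sd: float
    n: int
    guide_run_ids: list[str] = field(default_factory=list)


@dataclass
class ChartResult:
    chart: Chart
    metric: Metric
    analyte_id: str
    data: pd.DataFrame  # per-run records incl. flag, rule_fired
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.data.copy()
        df.insert(0, "analyte_id", self.analyte_id)
        df.insert(0, "metric", self.metric.value)
        df.insert(0, "chart", self.chart.value)
        return df

    @property
    def n_fail(self) -> int:
        return int((self.data["flag"] == Flag.FAIL.value).sum())


def extract_metric(
    table: MeasurementTable,
    runlog: RunLog,
    metric: Metric,
    analyte_id: str,
    run_types: set[RunType] = frozenset({RunType.SYSTEM_SUITABILITY}),
) -> MetricSeries:
    """Pull one analyte's metric from the selected run types, in run order.

    AREA_RATIO (precursor/transition) points with a zero denominator are
    omitted and counted in ``n_omitted``. IDOTP is computed against the
    analyte's theoretical envelope; rows without isotope areas are omitted.
    """
    metric = Metric(metric)
    wanted = {RunType(t).value for t in run_types}
    runs = runlog.data[runlog.data["run_type"].isin(wanted)]["run_id"]
    df = table.data
    df = df[(df["analyte_id"] == analyte_id) & (df["run_id"].isin(set(runs)))]
    if df.empty:
        raise InsufficientDataError(
            f"analyte {analyte_id!r} absent from all selected runs"
        )
    n_omitted = 0
    if metric is Metric.PRECURSOR_AREA:
        values = df["precursor_area"]
    elif metric is Metric.TRANSITION_AREA:
        values = df["transition_area"]
    elif metric is Metric.RT_MIN:
        values = df["rt_min"]
    elif metric is Metric.MASS_ERROR_PPM:
        values = df["mass_error_ppm"]
    elif metric is Metric.AREA_RATIO:
        ok = df["transition_area"] > 0
        n_omitted = int((~ok).sum())
        df = df[ok]
        values = df["precursor_area"] / df["transition_area"]
    else:  # IDOTP
        ok = df["iso_m0"].notna()
        n_omitted = int((~ok).sum())
        df = df[ok]
        env = expected_envelope(analyte_id)
        iso = df[["iso_m0", "iso_m1", "iso_m2"]].to_numpy(dtype=float)
        norm = np.linalg.norm(iso, axis=1) * np.linalg.norm(env)
        if np.any(norm == 0):
            raise UndefinedScoreError("all-zero isotope areas in series")
        values = pd.Series(np.clip(iso @ env / norm, 0.0, 1.0), index=df.index)
    points = pd.DataFrame(
        {
            "run_id": df["run_id"].to_numpy(),
            "acquired_at": df["acquired_at"].to_numpy(),
            "value": np.asarray(values, dtype=float),
        }
    )
    dropna = points["value"].notna()
    n_omitted += int((~dropna).sum())
    points = points[dropna].reset_index(drop=True)
    if not np.isfinite(points["value"]).all():
        raise ValidationError("non-finite metric values")
    return MetricSeries(metric, analyte_id, points, n_omitted)


def establish_baseline(
    series: MetricSeries,
    guide: list[str] | None = None,
    first_k: int = 10,
    min_guide: int = 5,
) -> Baseline:
    """Baseline from an explicit guide run list or the first ``first_k`` runs."""
    if guide is not None:
        sel = series.points[series.points["run_id"].isin(set(guide))]
    else:
        sel = series.points.iloc[:first_k]
        if len(series.points) < first_k:
            sel = series.points.iloc[0:0]  # not enough runs to fill the guide window
    if len(sel) < min_guide:
        raise InsufficientDataError(
            f"baseline needs >= {min_guide} guide points, got {len(sel)}"
        )
    v = sel["value"].to_numpy(dtype=float)
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd < abs(mean) * 1e-12:  # numerically constant guide set
        sd = 0.0
    return Baseline(mean, sd, len(v), sel["run_id"].tolist())


def _base_frame(series: MetricSeries) -> pd.DataFrame:
    return series.points[["run_id", "value"]].copy()


def levey_jennings(
    series: MetricSeries,
    baseline: Baseline,
    z_fail: float = 3.0,
    z_warn: float = 2.0,
    enable_2_2s: bool = True,
) -> ChartResult:
    """Per-point z chart. 1_3s: FAIL at |z| > z_fail. 2_2s: WARN when this and
    the previous point sit on the same side beyond z_warn.

    A zero-SD baseline degenerates to "any deviation from the mean FAILs"
    (rule "exact").
    """
    df = _base_frame(series)
    v = df["value"].to_numpy(dtype=float)
    flags = np.full(len(v), Flag.PASS.value, dtype=object)
    rules = np.full(len(v), None, dtype=object)
    if baseline.sd > 0:
        z = (v - baseline.mean) / baseline.sd
        fail = np.abs(z) > z_fail
        flags[fail] = Flag.FAIL.value
        rules[fail] = "1_3s"
        if enable_2_2s:
            same_side = (z[1:] > z_warn) & (z[:-1] > z_warn) | (z[1:] < -z_warn) & (
                z[:-1] < -z_warn
            )
            warn = np.concatenate(([False], same_side)) & ~fail
            flags[warn] = Flag.WARN.value
            rules[warn] = "2_2s"
    else:
        # degenerate baseline: any deviation beyond serialization precision fails
        same = np.isclose(v, baseline.mean, rtol=1e-9, atol=0.0)
        z = np.zeros(len(v))
        z[~same] = np.sign(v[~same] - baseline.mean) * np.inf
        fail = ~same
        flags[fail] = Flag.FAIL.value
        rules[fail] = "exact"
    df["z"] = z
    df["flag"] = flags
    df["rule_fired"] = rules
    return ChartResult(
        Chart.LEVEY_JENNINGS, series.metric, series.analyte_id, df,
        {"mean": baseline.mean, "sd": baseline.sd, "z_fail": z_fail, "z_warn": z_warn},
    )


def cusum(series: MetricSeries, baseline: Baseline, k: float = 0.5, h: float = 5.0) -> ChartResult:
    """Tabular CUSUM on standardized values.

    S+_i = max(0, S+_{i-1} + z_i - k); S-_i = max(0, S-_{i-1} - z_i - k);
    S+_0 = S-_0 = 0. FAIL when either statistic exceeds h.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if h <= 0:
        raise ValueError("h must be > 0")
    if baseline.sd <= 0:
        raise ValidationError("cusum requires baseline.sd > 0")
    df = _base_frame(series)
    z = (df["value"].to_numpy(dtype=float) - baseline.mean) / baseline.sd
    s_hi = np.empty(len(z))
    s_lo = np.empty(len(z))
    hi = lo = 0.0
    for i, zi in enumerate(z):
        hi = max(0.0, hi + zi - k)
        lo = max(0.0, lo - zi - k)
        s_hi[i] = hi
        s_lo[i] = lo
    fail = (s_hi > h) | (s_lo > h)
    df["z"] = z
    df["s_hi"] = s_hi
    df["s_lo"] = s_lo
    df["flag"] = np.where(fail, Flag.FAIL.value, Flag.PASS.value)
    df["rule_fired"] = np.where(fail, f"cusum_h{h:g}", None)
    return ChartResult(
        Chart.CUSUM, series.metric, series.analyte_id, df,
        {"k": k, "h": h, "mean": baseline.mean, "sd": baseline.sd},
    )


def moving_range(series: MetricSeries, baseline: Baseline | None = None) -> ChartResult:
    """Moving range MR_i = |x_i - x_{i-1}|; FAIL above D4 × mean(MR).

    mean(MR) is taken over the guide-set region when a baseline is supplied,
    else over the whole series. The first point has no MR and is flagged PASS.
    """
    if len(series) < 2:
        raise InsufficientDataError("moving range needs >= 2 points")
    df = _base_frame(series)
    v = df["value"].to_numpy(dtype=float)
    mr = np.abs(np.diff(v))
    mr_full = np.concatenate(([np.nan], mr))
    if baseline is not None and baseline.guide_run_ids:
        in_guide = df["run_id"].isin(set(baseline.guide_run_ids)).to_numpy()
        sel = mr_full[1:][in_guide[1:] & in_guide[:-1]]
        if len(sel) == 0:
            sel = mr
    else:
        sel = mr
    mr_bar = float(np.mean(sel))
    limit = MOVING_RANGE_D4 * mr_bar
    fail = np.nan_to_num(mr_full, nan=-np.inf) > limit
    df["moving_range"] = mr_full
    df["flag"] = np.where(fail, Flag.FAIL.value, Flag.PASS.value)
    df["rule_fired"] = np.where(fail, "mr_d4", None)
    return ChartResult(
        Chart.MOVING_RANGE, series.metric, series.analyte_id, df,
        {"mr_bar": mr_bar, "limit": limit, "d4": MOVING_RANGE_D4},
    )


def trailing_stats(
    series: MetricSeries, window: int = 5, cv_fail_pct: float = 20.0
) -> tuple[ChartResult, ChartResult]:
    """Trailing mean and trailing CV% over the most recent ``window`` runs.

    CV% = 100 × sample SD / mean of the window ending at the current run.
    Runs earlier than the first full window carry no statistic. The CV chart
    FAILs above ``cv_fail_pct``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    df_mean = _base_frame(series)
    df_cv = _base_frame(series)
    n = len(series)
    if n < window:
        warnings.warn(
            f"series of length {n} has no complete window of {window}; empty trailing charts",
            stacklevel=2,
        )
    roll = df_mean["value"].rolling(window)
    t_mean = roll.mean()
    t_sd = roll.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_cv = 100.0 * t_sd / t_mean
    df_mean["trailing_mean"] = t_mean
    df_mean["flag"] = Flag.PASS.value
    df_mean["rule_fired"] = None
    fail = t_cv.to_numpy() > cv_fail_pct
    df_cv["trailing_cv_pct"] = t_cv
    df_cv["flag"] = np.where(np.nan_to_num(t_cv, nan=-1) > cv_fail_pct, Flag.FAIL.value, Flag.PASS.value)
    df_cv["rule_fired"] = np.where(fail, "trailing_cv", None)
    params = {"window": window, "cv_fail_pct": cv_fail_pct}
    return (
        ChartResult(Chart.TRAILING_MEAN, series.metric, series.analyte_id, df_mean, params),
        ChartResult(Chart.TRAILING_CV, series.metric, series.analyte_id, df_cv, params),
    )
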