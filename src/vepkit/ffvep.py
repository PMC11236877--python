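"""Full-field VEP analysis: array averaging, P100 measurement, interocular /
interhemispheric metrics, normative statistics, and green/yellow/red
classification.

Kept trials are averaged per electrode, then electrodes are pooled into three
scalp arrays: LA = mean(E1, E2) over O1, CA = mean(E3..E6) over Oz, RA =
mean(E7, E8) over O2.  The P100 is the maximum positive deflection inside a
search window (default 70–160 ms) of the baseline-removed array response.

Classification against a normative table (mean, std per metric):

* latencies and latency differences — normal < m+2s, borderline in
  [m+2s, m+3s], abnormal > m+3s;
* amplitudes on the ln(1+amp) scale — abnormal if the P100 is absent/negative
  or the value < m−3s, borderline in [m−3s, m−2s), normal >= m−2s;
* amplitude ratios (larger/smaller) — normal < 2, borderline in [2, 2.5],
  abnormal > 2.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import TrialSet

__all__ = [
    "ArrayResponse",
    "P100Measure",
    "FfvepMetrics",
    "NormativeStats",
    "FfvepReport",
    "ARRAYS",
    "average_and_aggregate",
    "detect_p100",
    "compute_ffvep_metrics",
    "fit_normative_stats",
    "classify_ffvep",
    "default_normative_stats",
    "normative_stats_to_csv",
    "normative_stats_from_csv",
]

# array label -> member channel indices (0-based into E1..E8)
ARRAYS = {"LA": (0, 1), "CA": (2, 3, 4, 5), "RA": (6, 7)}
ARRAY_SITE = {"LA": "O1", "CA": "Oz", "RA": "O2"}


@dataclass
class ArrayResponse:
    array: str  # "LA" | "CA" | "RA"
    eye: str
    waveform: np.ndarray  # 500 samples @ 1 kHz
    n_trials_kept: int
    rate_hz: float = 1000.0


@dataclass
class P100Measure:
    present: bool
    peak_time_ms: float | None
    amplitude_uv: float | None
    search_window_ms: tuple = (70, 160)


@dataclass
class FfvepMetrics:
    """Per array x eye P100 measures plus the four comparison metrics.

    ``io_pt_diff``/``io_amp_ratio`` are keyed by array (left vs right eye at
    that array); ``ih_pt_diff``/``ih_amp_ratio`` are keyed by eye (LA vs RA
    for that eye).  NaN marks a comparison with an absent P100 (reported NA).
    """

    p100: dict = field(default_factory=dict)  # (array, eye) -> P100Measure
    io_pt_diff: dict = field(default_factory=dict)
    io_amp_ratio: dict = field(default_factory=dict)
    ih_pt_diff: dict = field(default_factory=dict)
    ih_amp_ratio: dict = field(default_factory=dict)


@dataclass
class NormativeStats:
    """Per-metric mean/std/n; amplitude entries are stored on the ln(1+amp)
    scale (``scale`` column "log1p" vs "linear")."""

    table: pd.DataFrame  # index: metric name; columns: mean, std, n, scale


@dataclass
class FfvepReport:
    values: dict  # metric -> float (NaN = NA)
    classes: dict  # metric -> "normal" | "borderline" | "abnormal" | "na" | "unclassified"


def average_and_aggregate(trials: TrialSet) -> list[ArrayResponse]:
    """Average kept trials per channel and pool channels into LA/CA/RA per
    eye.  An eye with zero kept trials yields no responses for that eye."""
    out: list[ArrayResponse] = []
    for eye in ("L", "R"):
        sel = (trials.eye == eye) & trials.kept
        n = int(sel.sum())
        if n == 0:
            continue
        mean_by_channel = trials.trials[sel].mean(axis=0)  # (channel, time)
        for arr, members in ARRAYS.items():
            out.append(
                ArrayResponse(
                    array=arr,
                    eye=eye,
                    waveform=mean_by_channel[list(members)].mean(axis=0),
                    n_trials_kept=n,
                    rate_hz=trials.rate_hz,
                )
            )
    return out


def detect_p100(
    response: ArrayResponse, search_window_ms: tuple = (70, 160)
) -> P100Measure:
    """Maximum positive deflection inside the search window; absent when the
    window holds no positive value.  Ties break toward the earlier time."""
    w = response.waveform
    i0 = int(round(search_window_ms[0] / 1000.0 * response.rate_hz))
    i1 = int(round(search_window_ms[1] / 1000.0 * response.rate_hz)) + 1
    if i1 > len(w):
        raise ValueError("waveform does not cover the search window")
    seg = w[i0:i1]
    k = int(np.argmax(seg))  # argmax returns the first index on ties
    if seg[k] <= 0:
        return P100Measure(False, None, None, search_window_ms)
    peak_ms = (i0 + k) / response.rate_hz * 1000.0
    return P100Measure(True, peak_ms, float(seg[k]), search_window_ms)


def _pair_diff(a: P100Measure, b: P100Measure) -> float:
    if not (a.present and b.present):
        return math.nan
    return abs(a.peak_time_ms - b.peak_time_ms)


def _pair_ratio(a: P100Measure, b: P100Measure) -> float:
    if not (a.present and b.present) or a.amplitude_uv <= 0 or b.amplitude_uv <= 0:
        return math.nan
    hi, lo = max(a.amplitude_uv, b.amplitude_uv), min(a.amplitude_uv, b.amplitude_uv)
    return hi / lo


def compute_ffvep_metrics(measures: dict) -> FfvepMetrics:
    """Interocular (per array) and interhemispheric (per eye, LA vs RA)
    absolute peak-time differences and larger/smaller amplitude ratios.
    ``measures`` maps (array, eye) -> P100Measure; absent measures propagate
    NA (NaN)."""
    m = FfvepMetrics(p100=dict(measures))
    absent = P100Measure(False, None, None)
    for arr in ARRAYS:
        l = measures.get((arr, "L"), absent)
        r = measures.get((arr, "R"), absent)
        m.io_pt_diff[arr] = _pair_diff(l, r)
        m.io_amp_ratio[arr] = _pair_ratio(l, r)
    for eye in ("L", "R"):
        la = measures.get(("LA", eye), absent)
        ra = measures.get(("RA", eye), absent)
        m.ih_pt_diff[eye] = _pair_diff(la, ra)
        m.ih_amp_ratio[eye] = _pair_ratio(la, ra)
    return m


# canonical scalar metric names used in normative tables and reports
def _metric_rows(metrics: FfvepMetrics) -> dict:
    rows = {}
    for (arr, eye), p in metrics.p100.items():
        rows[f"{arr}_peak_time_{eye}"] = p.peak_time_ms if p.present else math.nan
        rows[f"{arr}_amplitude_{eye}"] = p.amplitude_uv if p.present else math.nan
    for arr in ARRAYS:
        rows[f"{arr}_io_pt_diff"] = metrics.io_pt_diff.get(arr, math.nan)
        rows[f"{arr}_io_amp_ratio"] = metrics.io_amp_ratio.get(arr, math.nan)
    for eye in ("L", "R"):
        rows[f"ih_pt_diff_{eye}"] = metrics.ih_pt_diff.get(eye, math.nan)
        rows[f"ih_amp_ratio_{eye}"] = metrics.ih_amp_ratio.get(eye, math.nan)
    return rows


def _metric_kind(name: str) -> str:
    if "amp_ratio" in name:
        return "ratio"
    if "amplitude" in name:
        return "amplitude"
    return "latency"


def fit_normative_stats(cohort_metrics: list[FfvepMetrics]) -> NormativeStats:
    """Mean/std/n per metric over a normative cohort.  Amplitudes are
    transformed to ln(1+amp) before the statistics; eyes are pooled (each eye
    contributes one observation, as in a 13-subject / 26-eye cohort)."""
    if len(cohort_metrics) < 2:
        raise ValueError("need at least 2 cohort entries")
    per_metric: dict[str, list[float]] = {}
    for m in cohort_metrics:
        for name, val in _metric_rows(m).items():
            per_metric.setdefault(_pool_eye(name), []).append(val)
    recs = []
    for name, vals in per_metric.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        kind = _metric_kind(name)
        scale = "linear"
        if kind == "amplitude":
            v = np.log1p(v)
            scale = "log1p"
        if len(v) < 2:
            continue
        recs.append(
            {"metric": name, "mean": v.mean(), "std": v.std(ddof=1), "n": len(v), "scale": scale}
        )
    return NormativeStats(pd.DataFrame(recs).set_index("metric"))


def _pool_eye(name: str) -> str:
    # normative tables pool the two eyes for per-eye metrics
    for suffix in ("_L", "_R"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def classify_ffvep(metrics: FfvepMetrics, norms: NormativeStats) -> FfvepReport:
    """Classify every scalar metric normal/borderline/abnormal against the
    normative table.  A metric with no normative entry is flagged
    "unclassified"; NA values classify as "na" except absent amplitudes,
    which are abnormal."""
    values = _metric_rows(metrics)
    classes = {}
    tab = norms.table
    for name, val in values.items():
        kind = _metric_kind(name)
        if kind == "ratio":
            if not math.isfinite(val):
                classes[name] = "na"
            elif val > 2.5:
                classes[name] = "abnormal"
            elif val >= 2.0:
                classes[name] = "borderline"
            else:
                classes[name] = "normal"
            continue
        key = _pool_eye(name)
        if key not in tab.index:
            classes[name] = "unclassified"
            continue
        mean, std = float(tab.loc[key, "mean"]), float(tab.loc[key, "std"])
        if kind == "latency":
            if not math.isfinite(val):
                classes[name] = "na"
            elif val > mean + 3 * std:
                classes[name] = "abnormal"
            elif val >= mean + 2 * std:
                classes[name] = "borderline"
            else:
                classes[name] = "normal"
        else:  # amplitude: absent/negative P100 is abnormal outright
            if not math.isfinite(val) or val < 0:
                classes[name] = "abnormal"
            else:
                x = math.log1p(val)
                if x < mean - 3 * std:
                    classes[name] = "abnormal"
                elif x < mean - 2 * std:
                    classes[name] = "borderline"
                else:
                    classes[name] = "normal"
    return FfvepReport(values=values, classes=classes)


def default_normative_stats() -> NormativeStats:
    """Normative statistics from a 13-subject (26-eye) normally sighted
    cohort on the three scalp arrays.  Amplitude rows are on the ln(1+amp)
    scale.  Interhemispheric peak-time differences were not part of the
    published table and are absent (such metrics classify "unclassified")."""
    rows = [
        ("LA_peak_time", 110.0, 10.34),
        ("LA_io_pt_diff", 5.08, 5.44),
        ("LA_amplitude", 1.36, 0.44),
        ("CA_peak_time", 105.0, 7.43),
        ("CA_io_pt_diff", 3.31, 2.72),
        ("CA_amplitude", 1.61, 0.42),
        ("RA_peak_time", 107.0, 10.91),
        ("RA_io_pt_diff", 4.77, 3.94),
        ("RA_amplitude", 1.36, 0.44),
    ]
    df = pd.DataFrame(
        [
            {
                "metric": name,
                "mean": mean,
                "std": std,
                "n": 26,
                "scale": "log1p" if "amplitude" in name else "linear",
            }
            for name, mean, std in rows
        ]
    ).set_index("metric")
    return NormativeStats(df)


def normative_stats_to_csv(norms: NormativeStats, path) -> None:
    norms.table.to_csv(path)


def normative_stats_from_csv(path) -> NormativeStats:
    return NormativeStats(pd.read_csv(path, index_col="metric"))
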