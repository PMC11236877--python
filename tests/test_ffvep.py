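"""Array aggregation, P100 detection, comparison metrics, normative
statistics, and green/yellow/red classification."""

import math

import numpy as np
import pytest

from vepkit.ffvep import (
    ArrayResponse,
    FfvepMetrics,
    P100Measure,
    average_and_aggregate,
    classify_ffvep,
    compute_ffvep_metrics,
    default_normative_stats,
    detect_p100,
    fit_normative_stats,
    normative_stats_from_csv,
    normative_stats_to_csv,
)
from vepkit.preprocess import TrialSet


def _trials(per_channel_values, n_trials=4, eye="L"):
    """Trials whose 8 channels are constant at the given values."""
    vals = np.asarray(per_channel_values, dtype=float)
    trials = np.tile(vals[None, :, None], (n_trials, 1, 500))
    return TrialSet(
        trials=trials,
        eye=np.array([eye] * n_trials),
        onsets_s=np.arange(n_trials, dtype=float),
    )


class TestAggregation:
    def test_identical_channels_give_equal_arrays(self):
        res = average_and_aggregate(_trials([3.0] * 8))
        w = {r.array: r.waveform for r in res}
        assert np.array_equal(w["LA"], w["CA"]) and np.array_equal(w["CA"], w["RA"])

    def test_central_array_is_mean_of_e3_to_e6(self):
        res = average_and_aggregate(_trials([0, 0, 1, 2, 3, 4, 0, 0]))
        ca = next(r for r in res if r.array == "CA")
        assert np.allclose(ca.waveform, 2.5)

    def test_aggregate_equals_brute_force_mean(self):
        rng = np.random.default_rng(2)
        trials = rng.normal(size=(10, 8, 500))
        ts = TrialSet(
            trials=trials,
            eye=np.array(["L"] * 6 + ["R"] * 4),
            onsets_s=np.arange(10, dtype=float),
        )
        ts.variance_outlier[1] = True
        res = average_and_aggregate(ts)
        la_L = next(r for r in res if r.array == "LA" and r.eye == "L")
        sel = (ts.eye == "L") & ts.kept
        brute = trials[sel][:, [0, 1], :].mean(axis=(0, 1))
        assert np.allclose(la_L.waveform, brute)
        assert la_L.n_trials_kept == 5

    def test_eye_without_kept_trials_absent(self):
        ts = _trials([1.0] * 8, eye="L")
        res = average_and_aggregate(ts)
        assert {r.eye for r in res} == {"L"}


def _resp(waveform):
    return ArrayResponse("CA", "L", np.asarray(waveform, dtype=float), 10)


class TestP100Detection:
    def test_gaussian_bump_detected_at_construction(self):
        t = np.arange(500)
        w = 5.0 * np.exp(-0.5 * ((t - 100) / 15.0) ** 2)
        m = detect_p100(_resp(w))
        assert m.present and m.peak_time_ms == 100.0 and m.amplitude_uv == pytest.approx(5.0)

    def test_strictly_negative_waveform_absent(self):
        m = detect_p100(_resp(-np.ones(500)))
        assert not m.present and m.peak_time_ms is None

    def test_tie_breaks_toward_earlier_time(self):
        w = np.zeros(500)
        w[95] = w[140] = 2.0
        assert detect_p100(_resp(w)).peak_time_ms == 95.0

    def test_peak_outside_window_ignored(self):
        w = np.zeros(500)
        w[30] = 9.0
        w[120] = 1.0
        m = detect_p100(_resp(w))
        assert m.peak_time_ms == 120.0 and m.amplitude_uv == 1.0


def _measure(pt, amp):
    return P100Measure(True, pt, amp)


class TestMetrics:
    def test_identical_eyes_give_zero_diff_unit_ratio(self):
        meas = {(a, e): _measure(100.0, 4.0) for a in ("LA", "CA", "RA") for e in "LR"}
        m = compute_ffvep_metrics(meas)
        assert m.io_pt_diff["CA"] == 0.0
        assert m.io_amp_ratio["CA"] == 1.0

    def test_peak_time_difference_arithmetic(self):
        meas = {("CA", "L"): _measure(100.0, 4.0), ("CA", "R"): _measure(112.0, 4.0)}
        assert compute_ffvep_metrics(meas).io_pt_diff["CA"] == pytest.approx(12.0)

    @pytest.mark.parametrize("a,b", [(2.0, 5.0), (5.0, 2.0)])
    def test_amplitude_ratio_is_larger_over_smaller(self, a, b):
        meas = {("CA", "L"): _measure(100.0, a), ("CA", "R"): _measure(100.0, b)}
        assert compute_ffvep_metrics(meas).io_amp_ratio["CA"] == pytest.approx(2.5)

    def test_absent_p100_propagates_na(self):
        meas = {("CA", "L"): _measure(100.0, 4.0), ("CA", "R"): P100Measure(False, None, None)}
        m = compute_ffvep_metrics(meas)
        assert math.isnan(m.io_pt_diff["CA"]) and math.isnan(m.io_amp_ratio["CA"])


def _cohort_entry(pt=100.0, amp=4.0):
    meas = {(a, e): _measure(pt, amp) for a in ("LA", "CA", "RA") for e in "LR"}
    return compute_ffvep_metrics(meas)


class TestNormativeStats:
    def test_identical_entries_give_zero_std(self):
        norms = fit_normative_stats([_cohort_entry(), _cohort_entry()])
        assert norms.table.loc["CA_peak_time", "std"] == 0.0

    def test_amplitude_stored_on_log1p_scale(self):
        norms = fit_normative_stats([_cohort_entry(amp=1.718), _cohort_entry(amp=1.718)])
        assert norms.table.loc["CA_amplitude", "mean"] == pytest.approx(1.0, abs=1e-3)
        assert norms.table.loc["CA_amplitude", "scale"] == "log1p"

    def test_mean_std_match_two_pass_oracle(self):
        pts = [95.0, 100.0, 104.0, 111.0]
        norms = fit_normative_stats([_cohort_entry(pt=p) for p in pts])
        vals = np.repeat(pts, 2).astype(float)  # both eyes pooled
        assert norms.table.loc["CA_peak_time", "mean"] == pytest.approx(vals.mean())
        assert norms.table.loc["CA_peak_time", "std"] == pytest.approx(vals.std(ddof=1))

    def test_single_entry_rejected(self):
        with pytest.raises(ValueError):
            fit_normative_stats([_cohort_entry()])

    def test_csv_round_trip(self, tmp_path):
        norms = default_normative_stats()
        p = tmp_path / "norms.csv"
        normative_stats_to_csv(norms, p)
        back = normative_stats_from_csv(p)
        assert np.allclose(back.table["mean"], norms.table["mean"])


def _metrics_with_ca(pt=None, amp=None, ratio=None):
    m = FfvepMetrics()
    if pt is not None or amp is not None:
        m.p100[("CA", "L")] = P100Measure(pt is not None, pt, amp)
    if ratio is not None:
        m.ih_amp_ratio["L"] = ratio
    return m


class TestClassification:
    norms = default_normative_stats()  # CA peak time: mean 105, std 7.43

    def classify_pt(self, pt):
        rep = classify_ffvep(_metrics_with_ca(pt=pt, amp=3.0), self.norms)
        return rep.classes["CA_peak_time_L"]

    def test_normal_borderline_abnormal_latency(self):
        assert self.classify_pt(115.0) == "normal"  # < 119.86
        assert self.classify_pt(125.0) == "borderline"  # in [119.86, 127.29]
        assert self.classify_pt(130.0) == "abnormal"  # > 127.29

    def test_exact_latency_boundaries(self):
        assert self.classify_pt(105.0 + 2 * 7.43) == "borderline"
        assert self.classify_pt(105.0 + 3 * 7.43) == "borderline"
        assert self.classify_pt(105.0 + 3 * 7.43 + 1e-9) == "abnormal"

    @pytest.mark.parametrize(
        "ratio,expect",
        [(1.9, "normal"), (2.0, "borderline"), (2.2, "borderline"), (2.5, "borderline"), (2.51, "abnormal")],
    )
    def test_ratio_thresholds(self, ratio, expect):
        rep = classify_ffvep(_metrics_with_ca(ratio=ratio), self.norms)
        assert rep.classes["ih_amp_ratio_L"] == expect

    def test_absent_p100_amplitude_abnormal(self):
        m = FfvepMetrics()
        m.p100[("CA", "L")] = P100Measure(False, None, None)
        rep = classify_ffvep(m, self.norms)
        assert rep.classes["CA_amplitude_L"] == "abnormal"

    def test_amplitude_boundaries_on_log_scale(self):
        mean, std = 1.61, 0.42
        just_normal = math.expm1(mean - 2 * std)
        rep = classify_ffvep(_metrics_with_ca(pt=105.0, amp=just_normal), self.norms)
        assert rep.classes["CA_amplitude_L"] == "normal"
        low = math.expm1(mean - 3 * std) * 0.9
        rep = classify_ffvep(_metrics_with_ca(pt=105.0, amp=low), self.norms)
        assert rep.classes["CA_amplitude_L"] == "abnormal"

    def test_missing_normative_entry_flagged(self):
        m = FfvepMetrics()
        m.ih_pt_diff["L"] = 5.0
        rep = classify_ffvep(m, self.norms)
        assert rep.classes["ih_pt_diff_L"] == "unclassified"

    def test_latency_classification_monotone(self):
        """Increasing a latency never moves its class toward normal."""
        order = {"normal": 0, "borderline": 1, "abnormal": 2}
        grades = [order[self.classify_pt(pt)] for pt in np.linspace(80, 150, 141)]
        assert all(b >= a for a, b in zip(grades, grades[1:]))

    def test_amplitude_classification_monotone(self):
        """Decreasing an amplitude never moves its class toward normal."""
        order = {"normal": 0, "borderline": 1, "abnormal": 2}
        amps = np.linspace(6.0, 0.01, 120)
        grades = [
            order[
                classify_ffvep(_metrics_with_ca(pt=105.0, amp=a), self.norms).classes[
                    "CA_amplitude_L"
                ]
            ]
            for a in amps
        ]
        assert all(b >= a for a, b in zip(grades, grades[1:]))
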