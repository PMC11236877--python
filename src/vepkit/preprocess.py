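"""Shared EEG conditioning: baseline removal, band limiting, epoching, and the
two per-trial rejection screens.

The fixed processing order is: SWT baseline removal (0.5 Hz effective cutoff)
-> band limiting to 3–13 Hz (Bessel high-pass + SWT low-pass) -> epoching into
500 ms trials -> variance-outlier screen (isolation forest on per-trial
variance, catching movement artifacts) -> alpha screen (FFT peak comparison,
catching trials dominated by intrinsic 9–12 Hz rhythm).  Rejection marks
flags; it never mutates waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.ensemble import IsolationForest

from ._wavelets import swt_approximation, swt_depth_for_cutoff
from .stimulus import StimulusSchedule

__all__ = [
    "Recording",
    "TrialSet",
    "swt_baseline_remove",
    "band_limit",
    "epoch",
    "reject_variance_outliers",
    "reject_alpha_trials",
    "preprocess_recording",
]

RATE_HZ = 1000.0
EPOCH_MS = 500
CHANNEL_LABELS = tuple(f"E{i}" for i in range(1, 9))


@dataclass
class Recording:
    """Continuous multichannel EEG plus its stimulation schedule.

    ``samples`` is (n_channels, n_samples) in microvolts at ``rate_hz``;
    channels are scalp electrodes E1..E8 referenced to the left ear lobe.
    """

    samples: np.ndarray
    rate_hz: float = RATE_HZ
    channel_labels: tuple = CHANNEL_LABELS
    schedule: StimulusSchedule | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.rate_hz


@dataclass
class TrialSet:
    """Epoched trials (trial x channel x time) with per-trial rejection flags.

    ``kept``, ``variance_outlier`` and ``alpha_reject`` are disjoint boolean
    masks whose union covers every trial.  ``eye`` labels each trial "L"/"R".
    """

    trials: np.ndarray
    eye: np.ndarray
    onsets_s: np.ndarray
    rate_hz: float = RATE_HZ
    variance_outlier: np.ndarray = None
    alpha_reject: np.ndarray = None
    n_dropped_out_of_range: int = 0

    def __post_init__(self):
        n = self.trials.shape[0]
        if self.variance_outlier is None:
            self.variance_outlier = np.zeros(n, dtype=bool)
        if self.alpha_reject is None:
            self.alpha_reject = np.zeros(n, dtype=bool)

    @property
    def kept(self) -> np.ndarray:
        return ~(self.variance_outlier | self.alpha_reject)

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def counts(self) -> dict:
        return {
            "total": int(self.n_trials),
            "kept": int(self.kept.sum()),
            "variance_outlier": int(self.variance_outlier.sum()),
            "alpha_reject": int(self.alpha_reject.sum()),
            "dropped_out_of_range": int(self.n_dropped_out_of_range),
        }


def swt_baseline_remove(
    signal: np.ndarray, cutoff_hz: float = 0.5, rate_hz: float = RATE_HZ
) -> np.ndarray:
    """Subtract the stationary-wavelet baseline (approximation at the depth
    whose band edge sits at ``cutoff_hz``).  Strongly attenuates sub-cutoff
    drift while leaving the passband essentially untouched; zero phase."""
    x = np.asarray(signal, dtype=float)
    min_len = int(2 * rate_hz / cutoff_hz)
    if x.shape[-1] < min_len:
        raise ValueError(
            f"signal too short for cutoff {cutoff_hz} Hz: need >= {min_len} samples, got {x.shape[-1]}"
        )
    depth = swt_depth_for_cutoff(rate_hz, cutoff_hz)
    return x - swt_approximation(x, depth)


def band_limit(
    signal: np.ndarray,
    low_hz: float = 3.0,
    high_hz: float = 13.0,
    rate_hz: float = RATE_HZ,
    hp_order: int = 4,
) -> np.ndarray:
    """Band limit with a Bessel high-pass IIR (forward-backward, zero phase)
    and the SWT approximation as the low-pass."""
    if not 0 < low_hz < high_hz < rate_hz / 2:
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) at rate {rate_hz}")
    x = np.asarray(signal, dtype=float)
    sos = sps.bessel(hp_order, low_hz, btype="highpass", fs=rate_hz, output="sos", norm="mag")
    y = sps.sosfiltfilt(sos, x, axis=-1)
    depth = swt_depth_for_cutoff(rate_hz, high_hz)
    return swt_approximation(y, depth)


def epoch(
    recording: Recording,
    events=None,
    window_ms: tuple = (0, EPOCH_MS),
) -> TrialSet:
    """Cut one trial per usable event: samples [t, t + 0.5 s) at 1 kHz.

    Events inside a segment's onset/offset discard window are excluded;
    events whose window would run past the recording are dropped and counted.
    """
    sched = recording.schedule
    if events is None:
        if sched is None:
            raise ValueError("no events: recording has no schedule and none were passed")
        events = sched.usable_events()
    if not events:
        raise ValueError("no usable events: all events fell in discard windows or none exist")
    n0 = int(round(window_ms[0] / 1000.0 * recording.rate_hz))
    n1 = int(round(window_ms[1] / 1000.0 * recording.rate_hz))
    width = n1 - n0
    total = recording.samples.shape[1]
    trials, eyes, onsets = [], [], []
    dropped = 0
    for ev in events:
        i = int(round(ev.time_s * recording.rate_hz)) + n0
        if i < 0 or i + width > total:
            dropped += 1
            continue
        trials.append(recording.samples[:, i : i + width])
        eyes.append(ev.eye)
        onsets.append(ev.time_s)
    if not trials:
        raise ValueError("no usable events: every event window exceeded the recording")
    return TrialSet(
        trials=np.stack(trials),
        eye=np.asarray(eyes),
        onsets_s=np.asarray(onsets),
        rate_hz=recording.rate_hz,
        n_dropped_out_of_range=dropped,
    )


def reject_variance_outliers(
    trials: TrialSet, contamination: float = 0.05, seed: int = 0
) -> TrialSet:
    """Flag trials whose variance is anomalous (movement artifacts).

    An isolation forest is fit on log per-trial variance (pooled over
    channels); roughly a ``contamination`` fraction is flagged.  With fewer
    than 10 kept trials the screen is skipped (flags untouched).
    ``contamination=0`` flags nothing.  Trial order does not affect which
    trials are flagged.
    """
    n = trials.n_trials
    if n < 10:
        import warnings

        warnings.warn(f"variance screen skipped: only {n} trials (< 10)")
        return trials
    if contamination <= 0:
        return trials
    v = trials.trials.var(axis=(1, 2))
    feat = np.log(v + 1e-12)[:, None]
    order = np.argsort(feat[:, 0], kind="stable")  # order-invariant fit
    clf = IsolationForest(contamination=contamination, random_state=seed)
    pred_sorted = clf.fit_predict(feat[order])
    pred = np.empty(n, dtype=int)
    pred[order] = pred_sorted
    trials.variance_outlier = pred == -1
    return trials


def reject_alpha_trials(
    trials: TrialSet,
    alpha_band: tuple = (9.0, 12.0),
    low_band: tuple = (1.0, 9.0),
    ratio_threshold: float = 1.0,
) -> TrialSet:
    """Flag trials whose power spectrum peaks predominantly in the alpha band.

    Per trial (channels pooled by mean spectrum), the FFT power peak inside
    ``alpha_band`` is compared with the peak in the DC-exclusive ``low_band``;
    the trial is flagged when alpha peak > ratio_threshold x low peak.  An
    all-zero trial has no predominant band and is kept.
    """
    x = trials.trials
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / trials.rate_hz)
    P = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    P = P.mean(axis=1)  # pool channels
    in_alpha = (freqs >= alpha_band[0]) & (freqs <= alpha_band[1])
    in_low = (freqs >= low_band[0]) & (freqs < low_band[1])
    pk_alpha = P[:, in_alpha].max(axis=1)
    pk_low = P[:, in_low].max(axis=1)
    flag = pk_alpha > ratio_threshold * pk_low
    flag &= pk_alpha > 0  # null convention: silent trials are kept
    trials.alpha_reject = flag & ~trials.variance_outlier
    return trials


def preprocess_recording(
    recording: Recording,
    low_hz: float = 3.0,
    high_hz: float = 13.0,
    baseline_cutoff_hz: float = 0.5,
) -> Recording:
    """Baseline removal followed by band limiting on every channel; returns a
    new Recording with the same schedule/metadata."""
    y = swt_baseline_remove(recording.samples, baseline_cutoff_hz, recording.rate_hz)
    y = band_limit(y, low_hz, high_hz, recording.rate_hz)
    return Recording(
        samples=y,
        rate_hz=recording.rate_hz,
        channel_labels=recording.channel_labels,
        schedule=recording.schedule,
        meta=dict(recording.meta, filtered=f"{low_hz}-{high_hz}Hz"),
    )
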