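"""Multifocal VEP decoding: derived bipolar channels, m-sequence kernel
extraction, per-sector SNR, and SNR-weighted polarity-matched combination.

Four derived channels are formed as pairwise differences of the eight
monopolar electrodes (pairs closer to each other than to the left-ear
reference), canceling shared far-field activity.  Each sector's 500 ms
response kernel is recovered by correlating its ±1 stimulation sequence with
the continuous derived-channel EEG:

    response(tau) = (1/N) * sum_k s_k * x(t_k + tau),   tau in [0, 500) ms

over the sector's kept steps k.  Per-sector SNR is the ratio of waveform
standard deviations in a signal window (45–150 ms) and a late noise window
(325–430 ms), computed per individual sector rather than against a
cohort-averaged noise floor.  The per-sector optimized response polarity-
matches D1/D3/D4 to D2 and averages the four with SNR weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Recording
from .stimulus import DelayModel, SectorGeometry, StimulusSchedule, sector_delays_s

__all__ = [
    "DEFAULT_PAIRING",
    "DerivedChannelSet",
    "SectorResponse",
    "OptimizedResponse",
    "derive_channels",
    "extract_sector_responses",
    "sector_snr",
    "combine_derived",
]

# Dk = E_i - E_j, 1-based electrode indices.
DEFAULT_PAIRING = ((1, 3), (4, 5), (6, 8), (2, 7))

SIGNAL_WINDOW_MS = (45, 150)
NOISE_WINDOW_MS = (325, 430)
EPOCH_SAMPLES = 500


@dataclass
class DerivedChannelSet:
    signals: np.ndarray  # (4, n_samples)
    pairing: tuple
    rate_hz: float
    schedule: StimulusSchedule | None = None


@dataclass
class SectorResponse:
    sector_id: int
    eye: str
    derived_channel: int  # 1-based Dk index
    waveform: np.ndarray  # 500 samples
    snr: float
    snr_flag: str = ""  # "inf_noise" when the noise window had zero std


@dataclass
class OptimizedResponse:
    sector_id: int
    eye: str
    waveform: np.ndarray
    combined_snr: float
    polarity_flips: dict = field(default_factory=dict)  # Dk -> -1/0/+1 (0 = ambiguous)


def derive_channels(
    recording: Recording, pairing: tuple = DEFAULT_PAIRING
) -> DerivedChannelSet:
    """Dk(t) = Ei(t) - Ej(t) for each (i, j) pair (1-based indices)."""
    if len(pairing) != 4:
        raise ValueError("pairing must list exactly 4 channel pairs")
    n_ch = recording.n_channels
    sigs = []
    for i, j in pairing:
        if not (1 <= i <= n_ch and 1 <= j <= n_ch):
            raise ValueError(f"invalid channel index in pair ({i}, {j}); channels are 1..{n_ch}")
        sigs.append(recording.samples[i - 1] - recording.samples[j - 1])
    return DerivedChannelSet(
        signals=np.vstack(sigs),
        pairing=tuple(pairing),
        rate_hz=recording.rate_hz,
        schedule=recording.schedule,
    )


def extract_sector_responses(
    derived: DerivedChannelSet,
    schedule: StimulusSchedule | None = None,
    kept_mask: np.ndarray | None = None,
    geometry: list[SectorGeometry] | None = None,
    delay_model: DelayModel | None = None,
) -> list[SectorResponse]:
    """Decode every sector on every derived channel by the m-sequence
    technique, per eye.

    ``kept_mask`` (n_steps bool) excludes steps flagged by the rejection
    screens; steps whose 500 ms window leaves the recording are excluded.
    When ``geometry`` is given, each sector's step times are shifted by its
    display-sweep delay before sampling.
    """
    sched = schedule if schedule is not None else derived.schedule
    if sched is None or sched.paradigm != "mfvep":
        raise ValueError("an mfVEP schedule is required")
    if sched.states is None:
        raise ValueError("mfVEP schedule lacks compact state arrays")
    rate = derived.rate_hz
    n_samples = derived.signals.shape[1]
    n_sectors = sched.states.shape[0]
    keep = np.ones(len(sched.step_times_s), dtype=bool) if kept_mask is None else kept_mask.copy()
    step_idx = np.round(sched.step_times_s * rate).astype(int)
    keep &= step_idx >= 0
    responses: list[SectorResponse] = []
    for eye in ("L", "R"):
        eye_sel = (sched.step_eyes == eye) & keep
        if not eye_sel.any():
            continue
        delays = (
            np.round(sector_delays_s(geometry, eye, delay_model) * rate).astype(int)
            if geometry is not None
            else np.zeros(n_sectors, dtype=int)
        )
        base_idx = step_idx[eye_sel]
        states = sched.states[:, eye_sel].astype(float)
        # group sectors sharing a rounded delay: one window gather + matmul per group
        win = np.lib.stride_tricks.sliding_window_view(derived.signals, EPOCH_SAMPLES, axis=1)
        for d in np.unique(delays):
            secs = np.nonzero(delays == d)[0]
            idx = base_idx + d
            ok = (idx >= 0) & (idx + EPOCH_SAMPLES <= n_samples)
            if not ok.any():
                for s in secs:
                    responses.append(
                        SectorResponse(int(s + 1), eye, 0, np.zeros(EPOCH_SAMPLES), 0.0, "empty")
                    )
                continue
            idx = idx[ok]
            n = len(idx)
            st = states[secs][:, ok]
            for k in range(derived.signals.shape[0]):
                wav = st @ win[k][idx] / n  # (n_secs, 500)
                for row, s in enumerate(secs):
                    snr, flag = sector_snr(wav[row], rate_hz=rate, return_flag=True)
                    responses.append(
                        SectorResponse(int(s + 1), eye, k + 1, wav[row], snr, flag)
                    )
    return responses


def sector_snr(
    waveform: np.ndarray,
    signal_window_ms: tuple = SIGNAL_WINDOW_MS,
    noise_window_ms: tuple = NOISE_WINDOW_MS,
    rate_hz: float = 1000.0,
    return_flag: bool = False,
):
    """std(signal window) / std(noise window) of one decoded waveform.

    A zero-variance noise window yields +inf with an "inf_noise" flag."""
    w = np.asarray(waveform, dtype=float)
    s0, s1 = (int(round(t / 1000.0 * rate_hz)) for t in signal_window_ms)
    n0, n1 = (int(round(t / 1000.0 * rate_hz)) for t in noise_window_ms)
    if n1 > len(w) or s1 > len(w):
        raise ValueError("waveform does not cover the SNR windows")
    sig_sd = w[s0:s1].std()
    noi_sd = w[n0:n1].std()
    if noi_sd == 0:
        out, flag = np.inf, "inf_noise"
    else:
        out, flag = float(sig_sd / noi_sd), ""
    return (out, flag) if return_flag else out


def combine_derived(
    responses: list[SectorResponse],
    polarity_corr_window_ms: tuple = (0, 300),
    ambiguous_corr: float = 0.1,
    rate_hz: float = 1000.0,
) -> OptimizedResponse:
    """SNR-weighted average of one sector's D1..D4 responses, polarity-matched
    to D2.

    For k != 2 the waveform's sign is flipped when its Pearson correlation
    with D2 over 0–300 ms is negative; |corr| < ``ambiguous_corr`` applies no
    flip and records 0 in ``polarity_flips``.  The combined SNR is recomputed
    on the output waveform.
    """
    if not responses:
        raise ValueError("no responses to combine")
    sector = responses[0].sector_id
    eye = responses[0].eye
    if any(r.sector_id != sector or r.eye != eye for r in responses):
        raise ValueError("combine_derived expects responses of one sector and eye")
    by_ch = {r.derived_channel: r for r in responses}
    flags = {}
    ref = by_ch.get(2)
    c0, c1 = (int(round(t / 1000.0 * rate_hz)) for t in polarity_corr_window_ms)
    num = np.zeros(EPOCH_SAMPLES)
    den = 0.0
    for k in sorted(by_ch):
        r = by_ch[k]
        wav = r.waveform
        sign = 1
        if ref is not None and k != 2:
            a, b = wav[c0:c1], ref.waveform[c0:c1]
            sa, sb = a.std(), b.std()
            corr = float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb)) if sa > 0 and sb > 0 else 0.0
            if abs(corr) < ambiguous_corr:
                sign = 1
                flags[k] = 0
            else:
                sign = 1 if corr >= 0 else -1
                flags[k] = sign
        snr = r.snr if np.isfinite(r.snr) else 0.0
        num = num + snr * sign * wav
        den += snr
    out = num / den if den > 0 else np.mean([by_ch[k].waveform for k in sorted(by_ch)], axis=0)
    return OptimizedResponse(
        sector_id=sector,
        eye=eye,
        waveform=out,
        combined_snr=sector_snr(out, rate_hz=rate_hz),
        polarity_flips=flags,
    )
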