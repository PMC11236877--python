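"""Synthetic EEG generator for the VEP pipeline.

Emulates dichoptic pattern-reversal recordings with the statistical structure
the downstream stages assume: P100-like evoked kernels riding on 1/f Gaussian
background noise, intermittent alpha-band (8–13 Hz) bursts, sparse
high-amplitude movement artifacts, per-sector kernels driven by ±1
stimulation sequences for the multifocal paradigm, and masked-sector
("artificial defect") conditions in which a sector contributes nothing but
background.

All randomness flows from one seeded generator per operation; seeds are
recorded in the output metadata, so identical config + seed gives a
bit-identical Recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .preprocess import RATE_HZ, Recording
from .stimulus import (
    DelayModel,
    SectorGeometry,
    StimulusSchedule,
    build_dartboard_geometry,
    sector_delays_s,
)

__all__ = [
    "SimulationConfig",
    "LabeledResponseSet",
    "make_vep_template",
    "simulate_ffvep_recording",
    "simulate_mfvep_recording",
    "make_artificial_defect_dataset",
    "ring_mask_plan",
]

# Per-channel gain of the evoked response.  The topography varies across the
# occipital electrodes (cortical folding), which is what makes the pairwise
# derived channels (E1-E3, E4-E5, E6-E8, E2-E7) retain evoked signal; E7's
# gain exceeds E2's so the default D4 has inverted polarity, exercising the
# polarity-matching step.
DEFAULT_CHANNEL_GAINS = (1.0, 0.9, 0.35, 1.05, 0.4, 0.95, 1.2, 0.45)


@dataclass
class SimulationConfig:
    """Stated world of the simulator.

    Amplitudes in microvolts, times in ms.  ``sector_gains`` scales each
    sector's mfVEP kernel in [0, 1]; 0 means the sector is masked (defect) and
    contributes only background.  Noise defaults are chosen so the rejection
    screens operate at plausible (1–10%) rejection rates.
    """

    p100_peak_ms: dict = field(default_factory=lambda: {"L": 100.0, "R": 100.0})
    p100_amp_uv: dict = field(default_factory=lambda: {"L": 5.0, "R": 5.0})
    template_width_ms: float = 25.0
    mf_kernel_amp_uv: float = 1.0
    sector_gains: np.ndarray | dict | None = None  # (36,) or {"L": ..., "R": ...}
    noise_rms_uv: float = 2.0
    one_over_f_exponent: float = 1.0
    alpha_rate_hz: float = 0.05
    alpha_amp_uv: float = 8.0
    alpha_band: tuple = (8.0, 13.0)
    artifact_rate_hz: float = 0.01
    artifact_amp_uv: float = 40.0
    channel_gains: tuple = DEFAULT_CHANNEL_GAINS
    seed: int = 0

    def __post_init__(self):
        for eye in ("L", "R"):
            if not 0 < self.p100_peak_ms[eye] < 500:
                raise ValueError("P100 peak time must lie in (0, 500) ms")
            if self.p100_amp_uv[eye] < 0:
                raise ValueError("amplitudes must be >= 0")
        if any(g < 0 for g in self.channel_gains):
            raise ValueError("channel gains must be >= 0")

    def gains_for_eye(self, eye: str, n_sectors: int) -> np.ndarray:
        if self.sector_gains is None:
            return np.ones(n_sectors)
        if isinstance(self.sector_gains, dict):
            return np.asarray(self.sector_gains[eye], dtype=float)
        return np.asarray(self.sector_gains, dtype=float)


@dataclass
class LabeledResponseSet:
    """Decoded 500 ms waveforms with binary ground-truth labels.

    ``labels`` holds "normal"/"abnormal"; provenance records (test_id, eye,
    sector_id) per response.  ``snr`` carries each response's combined SNR.
    """

    responses: np.ndarray  # (n, 500)
    labels: np.ndarray  # (n,) str
    test_id: np.ndarray
    eye: np.ndarray
    sector_id: np.ndarray
    snr: np.ndarray | None = None

    def __len__(self) -> int:
        return self.responses.shape[0]


def make_vep_template(
    peak_time_ms: float = 100.0,
    amplitude: float = 5.0,
    width_ms: float = 25.0,
    rate_hz: float = RATE_HZ,
    duration_ms: float = 500.0,
) -> np.ndarray:
    """Biphasic evoked kernel: a negative lobe ~25 ms before the positive peak
    (N75-like for a 100 ms P100) and a positive peak whose maximum equals
    ``amplitude`` exactly at ``peak_time_ms``."""
    if not 0 < peak_time_ms < duration_ms:
        raise ValueError("peak_time_ms must lie in (0, duration)")
    if width_ms <= 0:
        raise ValueError("width_ms must be positive")
    if amplitude == 0:
        return np.zeros(int(round(duration_ms / 1000.0 * rate_hz)))
    n = int(round(duration_ms / 1000.0 * rate_hz))
    t = np.arange(n) / rate_hz * 1000.0
    w = width_ms
    shape = np.exp(-0.5 * ((t - peak_time_ms) / w) ** 2) - 0.55 * np.exp(
        -0.5 * ((t - (peak_time_ms - 25.0)) / (0.75 * w)) ** 2
    )
    m = int(np.argmax(shape))
    target = int(round(peak_time_ms / 1000.0 * rate_hz))
    shape = np.roll(shape, target - m)  # pin the discrete argmax to peak_time
    if target - m > 0:
        shape[: target - m] = 0.0
    elif target - m < 0:
        shape[target - m :] = 0.0
    return amplitude * shape / shape[target]


def _one_over_f_noise(rng: np.random.Generator, shape, exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ 1/f**exponent, scaled to
    the requested RMS.  ``shape = (..., n_samples)``."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if exponent == 0 or rms == 0:
        out = white
    else:
        f = np.fft.rfftfreq(n)
        scale = np.ones_like(f)
        nz = f > 0
        scale[nz] = f[nz] ** (-exponent / 2.0)
        scale[0] = 0.0
        out = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return rms * out / sd


def _add_alpha_bursts(rng, x: np.ndarray, cfg: SimulationConfig, rate_hz: float) -> None:
    """Poisson-timed Hann-enveloped alpha-band bursts, common to all channels
    (occipital alpha is a global rhythm)."""
    n = x.shape[-1]
    dur_s = n / rate_hz
    n_bursts = rng.poisson(cfg.alpha_rate_hz * dur_s)
    for _ in range(n_bursts):
        f = rng.uniform(*cfg.alpha_band)
        length = int(rng.uniform(0.8, 1.5) * rate_hz)
        start = rng.integers(0, max(1, n - length))
        tt = np.arange(length) / rate_hz
        burst = cfg.alpha_amp_uv * np.hanning(length) * np.sin(
            2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi)
        )
        x[:, start : start + length] += burst


def _add_artifacts(rng, x: np.ndarray, cfg: SimulationConfig, rate_hz: float) -> None:
    """Sparse high-amplitude movement artifacts: smoothed boxcar steps."""
    n = x.shape[-1]
    dur_s = n / rate_hz
    n_art = rng.poisson(cfg.artifact_rate_hz * dur_s)
    for _ in range(n_art):
        length = int(rng.uniform(0.2, 0.4) * rate_hz)
        start = rng.integers(0, max(1, n - length))
        amp = cfg.artifact_amp_uv * rng.choice([-1.0, 1.0])
        env = np.hanning(length)
        x[:, start : start + length] += amp * env


def _background(rng, cfg: SimulationConfig, n_ch: int, n_samp: int, rate_hz: float) -> np.ndarray:
    noise = _one_over_f_noise(rng, (n_ch, n_samp), cfg.one_over_f_exponent, cfg.noise_rms_uv)
    if cfg.alpha_amp_uv > 0 and cfg.alpha_rate_hz > 0:
        _add_alpha_bursts(rng, noise, cfg, rate_hz)
    if cfg.artifact_amp_uv > 0 and cfg.artifact_rate_hz > 0:
        _add_artifacts(rng, noise, cfg, rate_hz)
    return noise


def simulate_ffvep_recording(
    schedule: StimulusSchedule,
    config: SimulationConfig | None = None,
    rate_hz: float = RATE_HZ,
) -> Recording:
    """8-channel continuous EEG for a full-field schedule: each reversal event
    adds the eye's biphasic template (scaled by the per-channel gains) on top
    of background noise, alpha bursts, and artifacts."""
    cfg = config if config is not None else SimulationConfig()
    if schedule.paradigm != "ffvep":
        raise ValueError("schedule.paradigm must be 'ffvep'")
    rng = np.random.default_rng(cfg.seed)
    n_samp = int(round(schedule.total_duration_s * rate_hz))
    gains = np.asarray(cfg.channel_gains, dtype=float)
    n_ch = len(gains)
    evoked = np.zeros(n_samp)
    templates = {
        eye: make_vep_template(
            cfg.p100_peak_ms[eye], cfg.p100_amp_uv[eye], cfg.template_width_ms, rate_hz
        )
        for eye in ("L", "R")
    }
    tlen = len(templates["L"])
    for ev in schedule.events:
        i = int(round(ev.time_s * rate_hz))
        if 0 <= i and i + tlen <= n_samp:
            evoked[i : i + tlen] += templates[ev.eye]
    x = gains[:, None] * evoked[None, :]
    x += _background(rng, cfg, n_ch, n_samp, rate_hz)
    return Recording(
        samples=x,
        rate_hz=rate_hz,
        schedule=schedule,
        meta={"paradigm": "ffvep", "seed": cfg.seed},
    )


def simulate_mfvep_recording(
    schedule: StimulusSchedule,
    config: SimulationConfig | None = None,
    geometry: list[SectorGeometry] | None = None,
    delay_model: DelayModel | None = None,
    rate_hz: float = RATE_HZ,
) -> Recording:
    """Continuous EEG for a multifocal schedule.

    EEG = sum over sectors of gain_s x (±1 state stream ⊛ kernel), scaled by
    the per-channel gains, plus background.  Each sector's impulse train is
    placed at its display-delay-corrected step times; masked sectors (gain 0)
    contribute nothing.  Alpha bursts are injected independently of
    stimulation.
    """
    cfg = config if config is not None else SimulationConfig()
    if schedule.paradigm != "mfvep":
        raise ValueError("schedule.paradigm must be 'mfvep'")
    if schedule.states is None:
        raise ValueError("mfVEP schedule lacks compact state arrays")
    n_sectors = schedule.states.shape[0]
    for eye in ("L", "R"):
        if len(cfg.gains_for_eye(eye, n_sectors)) != n_sectors:
            raise ValueError(
                f"sector_gains length mismatch: schedule has {n_sectors} sectors"
            )
    geo = geometry if geometry is not None else build_dartboard_geometry()
    rng = np.random.default_rng(cfg.seed)
    n_samp = int(round(schedule.total_duration_s * rate_hz))
    gains = np.asarray(cfg.channel_gains, dtype=float)
    evoked = np.zeros(n_samp)
    step_idx = np.round(schedule.step_times_s * rate_hz).astype(int)
    for eye in ("L", "R"):
        eye_mask = schedule.step_eyes == eye
        if not eye_mask.any():
            continue
        kern = make_vep_template(
            cfg.p100_peak_ms[eye], cfg.mf_kernel_amp_uv, cfg.template_width_ms, rate_hz
        )
        delays = np.round(sector_delays_s(geo, eye, delay_model) * rate_hz).astype(int)
        sec_gain = cfg.gains_for_eye(eye, n_sectors)
        train = np.zeros(n_samp)
        cols = np.nonzero(eye_mask)[0]
        for s in range(n_sectors):
            if sec_gain[s] == 0:
                continue
            idx = step_idx[cols] + delays[s]
            vals = sec_gain[s] * schedule.states[s, cols]
            np.add.at(train, idx.clip(0, n_samp - 1), vals)
        evoked += fftconvolve(train, kern)[:n_samp]
    x = gains[:, None] * evoked[None, :]
    x += _background(rng, cfg, len(gains), n_samp, rate_hz)
    return Recording(
        samples=x,
        rate_hz=rate_hz,
        schedule=schedule,
        meta={"paradigm": "mfvep", "seed": cfg.seed},
    )


def ring_mask_plan(n_tests: int, geometry: list[SectorGeometry] | None = None) -> list[np.ndarray]:
    """Artificial-defect plan: in each test only the sectors of one (merged)
    ring are unmasked (stimulating); rings cycle across tests.  Returns, per
    test, the array of masked sector ids."""
    geo = geometry if geometry is not None else build_dartboard_geometry()
    rings = sorted({g.ring_index for g in geo})
    plan = []
    for t in range(n_tests):
        keep_ring = rings[t % len(rings)]
        masked = np.array([g.sector_id for g in geo if g.ring_index != keep_ring])
        plan.append(masked)
    return plan


def make_artificial_defect_dataset(
    n_tests: int = 16,
    mask_plan: list | None = None,
    config: SimulationConfig | None = None,
    seed: int = 0,
    eye: str = "L",
    segments: int = 8,
    mseqs=None,
) -> LabeledResponseSet:
    """Simulate ``n_tests`` monocular mfVEP runs with per-test masked sectors,
    run the full decode pipeline on each, and label masked sectors "abnormal"
    and unmasked "normal" (16 tests x 36 sectors = 576 samples by default)."""
    from .pipeline import decode_mfvep_recording  # deferred: avoids import cycle
    from .stimulus import build_mfvep_schedule, generate_msequences

    base_cfg = config if config is not None else SimulationConfig()
    if mask_plan is None:
        mask_plan = ring_mask_plan(n_tests)
    if len(mask_plan) != n_tests:
        raise ValueError("mask_plan must assign masks to every test")
    if mseqs is None:
        mseqs = generate_msequences(seed=1)
    schedule = build_mfvep_schedule(mseqs, segments=segments, eyes=eye)
    n_sectors = mseqs.n
    geo = build_dartboard_geometry()
    resp, labels, tid, eyes_, sids, snrs = [], [], [], [], [], []
    for t in range(n_tests):
        masked = np.asarray(mask_plan[t], dtype=int)
        gains = np.ones(n_sectors)
        if masked.size:
            gains[masked - 1] = 0.0
        cfg = replace(base_cfg, sector_gains=gains, seed=int(seed * 10_000 + t))
        rec = simulate_mfvep_recording(schedule, cfg, geometry=geo)
        optimized = decode_mfvep_recording(rec, geometry=geo)[eye]
        for o in optimized:
            resp.append(o.waveform)
            labels.append("abnormal" if o.sector_id in masked else "normal")
            tid.append(t)
            eyes_.append(eye)
            sids.append(o.sector_id)
            snrs.append(o.combined_snr)
    return LabeledResponseSet(
        responses=np.vstack(resp),
        labels=np.asarray(labels),
        test_id=np.asarray(tid),
        eye=np.asarray(eyes_),
        sector_id=np.asarray(sids),
        snr=np.asarray(snrs),
    )
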