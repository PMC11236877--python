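"""End-to-end analysis chains binding the stages together.

``run_ffvep_analysis``: filter -> epoch -> rejection screens -> array
averaging -> P100 metrics -> normative classification.

``decode_mfvep_recording``: filter -> derived channels -> step screening ->
m-sequence decode on D1..D4 -> per-sector SNR -> polarity-matched SNR-weighted
optimized responses, per eye.

``score_recording``: decode + feature extraction + model scoring, the full
multifocal report path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import IsolationForest

from .classify import Model, score_sectors
from .features import extract_feature_matrix
from .ffvep import (
    FfvepReport,
    NormativeStats,
    average_and_aggregate,
    classify_ffvep,
    compute_ffvep_metrics,
    default_normative_stats,
    detect_p100,
)
from .mfvep import (
    DEFAULT_PAIRING,
    OptimizedResponse,
    combine_derived,
    derive_channels,
    extract_sector_responses,
)
from .preprocess import (
    Recording,
    TrialSet,
    epoch,
    preprocess_recording,
    reject_alpha_trials,
    reject_variance_outliers,
)
from .stimulus import SectorGeometry, build_dartboard_geometry

__all__ = [
    "FfvepResult",
    "run_ffvep_analysis",
    "decode_mfvep_recording",
    "score_recording",
    "mfvep_step_screen",
]


@dataclass
class FfvepResult:
    report: FfvepReport
    metrics: object
    measures: dict
    trial_counts: dict
    responses: list = field(default_factory=list)


def run_ffvep_analysis(
    recording: Recording,
    norms: NormativeStats | None = None,
    search_window_ms: tuple = (70, 160),
    contamination: float = 0.05,
    seed: int = 0,
) -> FfvepResult:
    """Full-field chain on a continuous recording; returns the classified
    report plus per-stage trial counts (kept / rejected per screen)."""
    if norms is None:
        norms = default_normative_stats()
    rec = preprocess_recording(recording)
    trials = epoch(rec)
    trials = reject_variance_outliers(trials, contamination=contamination, seed=seed)
    trials = reject_alpha_trials(trials)
    responses = average_and_aggregate(trials)
    measures = {
        (r.array, r.eye): detect_p100(r, search_window_ms) for r in responses
    }
    metrics = compute_ffvep_metrics(measures)
    report = classify_ffvep(metrics, norms)
    return FfvepResult(
        report=report,
        metrics=metrics,
        measures=measures,
        trial_counts=trials.counts(),
        responses=responses,
    )


def mfvep_step_screen(
    derived_signals: np.ndarray,
    step_idx: np.ndarray,
    contamination: float = 0.05,
    seed: int = 0,
    epoch_samples: int = 500,
) -> np.ndarray:
    """Variance screen over the overlapping mfVEP step windows.

    Per step, the variance of the 500 ms window (pooled over derived
    channels) feeds the same isolation-forest outlier detector used for
    full-field trials; returns the kept mask.
    """
    n_samples = derived_signals.shape[1]
    ok = (step_idx >= 0) & (step_idx + epoch_samples <= n_samples)
    csum = np.cumsum(np.concatenate([[0.0], (derived_signals**2).sum(axis=0)]))
    csum1 = np.cumsum(np.concatenate([[0.0], derived_signals.sum(axis=0)]))
    keep = ok.copy()
    idx = step_idx[ok]
    power = (csum[idx + epoch_samples] - csum[idx]) / epoch_samples
    mean = (csum1[idx + epoch_samples] - csum1[idx]) / epoch_samples / derived_signals.shape[0]
    v = np.log(np.maximum(power - mean**2, 1e-12))[:, None]
    if len(v) >= 10 and contamination > 0:
        order = np.argsort(v[:, 0], kind="stable")
        clf = IsolationForest(contamination=contamination, random_state=seed)
        pred = np.empty(len(v), dtype=int)
        pred[order] = clf.fit_predict(v[order])
        keep[np.nonzero(ok)[0][pred == -1]] = False
    return keep


def decode_mfvep_recording(
    recording: Recording,
    geometry: list[SectorGeometry] | None = None,
    pairing=DEFAULT_PAIRING,
    contamination: float = 0.05,
    seed: int = 0,
    band=(3.0, 13.0),
) -> dict[str, list[OptimizedResponse]]:
    """Multifocal chain: returns per-eye lists of optimized sector responses
    (sector order), each carrying its combined SNR."""
    sched = recording.schedule
    if sched is None or sched.paradigm != "mfvep":
        raise ValueError("recording lacks an mfVEP schedule")
    geo = geometry if geometry is not None else build_dartboard_geometry()
    rec = preprocess_recording(recording, low_hz=band[0], high_hz=band[1])
    derived = derive_channels(rec, pairing)
    step_idx = np.round(sched.step_times_s * rec.rate_hz).astype(int)
    kept = mfvep_step_screen(derived.signals, step_idx, contamination, seed)
    responses = extract_sector_responses(derived, sched, kept_mask=kept, geometry=geo)
    out: dict[str, list[OptimizedResponse]] = {}
    for eye in ("L", "R"):
        per_sector: dict[int, list] = {}
        for r in responses:
            if r.eye == eye:
                per_sector.setdefault(r.sector_id, []).append(r)
        if per_sector:
            out[eye] = [combine_derived(per_sector[s]) for s in sorted(per_sector)]
    return out


def score_recording(
    recording: Recording,
    model: Model,
    geometry: list[SectorGeometry] | None = None,
) -> dict[str, list]:
    """Decode an mfVEP recording and score every sector 0–100 with the
    trained model; returns per-eye SectorScore lists."""
    decoded = decode_mfvep_recording(recording, geometry=geometry)
    out = {}
    for eye, optimized in decoded.items():
        W = np.vstack([o.waveform for o in optimized])
        F = extract_feature_matrix(W, model.reference)
        out[eye] = score_sectors(
            model,
            F,
            sector_ids=[o.sector_id for o in optimized],
            eyes=[eye] * len(optimized),
        )
    return out
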