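"""Recording container I/O and result rendering.

The container is HDF5: ``/eeg`` (float32, channel x time), ``/events`` (table
of time_s / eye / sector_id / state), ``/segments``, ``/steps`` + ``/states``
for compact mfVEP schedules, and ``/meta`` (one JSON string holding paradigm,
seeds and free-form metadata).  float32 samples round-trip bit-exactly.

``render_sector_map`` draws the per-sector visual-field score map: each
dartboard sector filled with gray level score/100 (white = certainly normal,
black = certainly abnormal/blocked, mid-gray = ambiguous), plus a CSV of the
scores.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .preprocess import Recording
from .stimulus import ScheduleEvent, SectorGeometry, Segment, StimulusSchedule

__all__ = [
    "write_recording",
    "read_recording",
    "render_sector_map",
    "scores_to_csv",
    "AnalysisBundle",
    "sector_responses_to_csv",
    "feature_matrix_to_csv",
]

_EYE_CODE = {"L": 0, "R": 1}
_EYE_NAME = {0: "L", 1: "R"}


def write_recording(recording: Recording, path) -> None:
    import h5py

    sched = recording.schedule
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=recording.samples.astype(np.float32))
        meta = {
            "rate_hz": recording.rate_hz,
            "channel_labels": list(recording.channel_labels),
            "meta": recording.meta,
        }
        if sched is not None:
            meta["paradigm"] = sched.paradigm
            meta["total_duration_s"] = sched.total_duration_s
            meta["step_s"] = sched.step_s
            meta["schedule_meta"] = {k: _jsonable(v) for k, v in sched.meta.items()}
            if sched.events:
                ev = np.array(
                    [(e.time_s, _EYE_CODE[e.eye], e.sector_id, e.state) for e in sched.events]
                )
                f.create_dataset("events", data=ev)
            if sched.states is not None:
                f.create_dataset("steps/times_s", data=sched.step_times_s)
                f.create_dataset(
                    "steps/eyes", data=np.array([_EYE_CODE[e] for e in sched.step_eyes], dtype=np.int8)
                )
                f.create_dataset("states", data=sched.states.astype(np.int8))
            seg = np.array(
                [(s.start_s, s.end_s, _EYE_CODE[s.eye], s.onset_discard_s) for s in sched.segments]
            )
            f.create_dataset("segments", data=seg)
        f.create_dataset("meta_json", data=json.dumps(meta))


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v


def read_recording(path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        if "eeg" not in f:
            raise ValueError("malformed container: 'eeg' missing")
        if "meta_json" not in f:
            raise ValueError("malformed container: 'meta_json' missing")
        samples = f["eeg"][...]
        meta = json.loads(f["meta_json"][()])
        sched = None
        if "paradigm" in meta:
            if "events" not in f and "states" not in f:
                raise ValueError("malformed container: 'events' missing")
            events = []
            if "events" in f:
                for t, eye, sid, st in f["events"][...]:
                    events.append(ScheduleEvent(float(t), _EYE_NAME[int(eye)], int(sid), int(st)))
            segments = [
                Segment(float(a), float(b), _EYE_NAME[int(e)], float(d))
                for a, b, e, d in f["segments"][...]
            ]
            step_times = f["steps/times_s"][...] if "steps" in f else None
            step_eyes = (
                np.array([_EYE_NAME[int(e)] for e in f["steps/eyes"][...]]) if "steps" in f else None
            )
            states = f["states"][...] if "states" in f else None
            sched = StimulusSchedule(
                paradigm=meta["paradigm"],
                events=events,
                segments=segments,
                total_duration_s=meta["total_duration_s"],
                step_s=meta.get("step_s"),
                step_times_s=step_times,
                step_eyes=step_eyes,
                states=states,
                meta=meta.get("schedule_meta", {}),
            )
    return Recording(
        samples=samples,
        rate_hz=meta["rate_hz"],
        channel_labels=tuple(meta["channel_labels"]),
        schedule=sched,
        meta=meta.get("meta", {}),
    )


@dataclass
class AnalysisBundle:
    """One session's results with full provenance: a reference to the source
    recording, the full-field report, the per-sector multifocal scores, and
    the parameters/seeds that produced every stage."""

    recording_path: str
    ffvep_report: dict | None = None
    sector_scores: dict = field(default_factory=dict)  # eye -> list of score dicts
    parameters: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "recording_path": self.recording_path,
                    "ffvep_report": self.ffvep_report,
                    "sector_scores": self.sector_scores,
                    "parameters": self.parameters,
                    "seeds": self.seeds,
                    "version": self.version,
                },
                fh,
                indent=2,
            )

    @staticmethod
    def from_json(path) -> "AnalysisBundle":
        with open(path) as fh:
            d = json.load(fh)
        return AnalysisBundle(**d)


def sector_responses_to_csv(responses, path) -> None:
    """Wide CSV of decoded sector responses: sector, eye, channel, snr, then
    the 500 waveform samples (w0..w499).  Accepts SectorResponse or
    OptimizedResponse objects."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sector_id", "eye", "channel", "snr"] + [f"w{i}" for i in range(500)])
        for r in responses:
            ch = getattr(r, "derived_channel", "optimized")
            snr = getattr(r, "snr", None)
            if snr is None:
                snr = getattr(r, "combined_snr", float("nan"))
            w.writerow([r.sector_id, r.eye, ch, f"{snr:.6g}"] + [f"{v:.6g}" for v in r.waveform])


def feature_matrix_to_csv(features, path, sector_ids=None) -> None:
    """Feature matrix CSV with the 19 canonical feature names as header."""
    from .features import FEATURE_NAMES

    F = np.asarray(features, dtype=float)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = (["sector_id"] if sector_ids is not None else []) + list(FEATURE_NAMES)
        w.writerow(header)
        for i, row in enumerate(F):
            lead = [sector_ids[i]] if sector_ids is not None else []
            w.writerow(lead + [f"{v:.9g}" for v in row])


def scores_to_csv(scores, path) -> None:
    """CSV of (sector_id, eye, score, call, ambiguous), one row per sector."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sector_id", "eye", "score", "call", "ambiguous"])
        for s in scores:
            w.writerow([s.sector_id, s.eye, f"{s.score:.2f}", s.call, int(s.ambiguous)])


def render_sector_map(scores, geometry: list[SectorGeometry], path=None, csv_path=None):
    """Grayscale visual-field map: each sector polygon filled with
    score/100.  Sectors missing from ``scores`` are hatched and flagged.
    Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Wedge

    by_sector = {s.sector_id: s for s in scores}
    fig, ax = plt.subplots(figsize=(5, 5))
    missing = []
    for g in geometry:
        sc = by_sector.get(g.sector_id)
        kwargs = dict(
            center=(0, 0),
            r=g.ecc_outer,
            width=g.ecc_outer - g.ecc_inner,
            theta1=g.theta_lo,
            theta2=g.theta_hi,
            edgecolor="0.5",
            linewidth=0.5,
        )
        if sc is None:
            missing.append(g.sector_id)
            ax.add_patch(Wedge(facecolor="white", hatch="///", **kwargs))
        else:
            ax.add_patch(Wedge(facecolor=str(sc.gray_level), **kwargs))
    lim = max(g.ecc_outer for g in geometry) * 1.05
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.set_xlabel("eccentricity (deg)")
    ax.set_title("sector scores (white=normal, black=abnormal)")
    if csv_path is not None:
        scores_to_csv(scores, csv_path)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig, missing
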