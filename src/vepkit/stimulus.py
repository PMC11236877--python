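"""Stimulus paradigm construction: dartboard geometry, stimulation sequences,
paradigm schedules, and display-delay correction.

The visual field from 0 to 22.25 degrees eccentricity is tiled by a dartboard
whose ring boundaries follow cortical magnification, so each ring drives a
roughly equal area of primary visual cortex.  The pre-merge layout has 60
sectors in 6 rings; uniting rings 3+4 and 5+6 radially yields the 36-sector
layout used for testing.

Two paradigms are produced:

* ffVEP — the whole dartboard pattern-reverses together; 90 trials per eye in
  6 alternating-eye segments of 30, inter-trial interval 0.5 s plus uniform
  0–0.1 s jitter.
* mfVEP — each sector reverses (or not) each step according to its own ±1
  pseudorandom sequence; 16 alternating-eye segments of 1024 steps give
  16,384 overlapping trials.

Event times are corrected for the OLED display's left-to-right refresh sweep,
which delays a sector's actual reversal linearly in its horizontal pixel
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SectorGeometry",
    "MSequenceSet",
    "ScheduleEvent",
    "Segment",
    "StimulusSchedule",
    "DelayModel",
    "build_dartboard_geometry",
    "generate_msequences",
    "build_ffvep_schedule",
    "build_mfvep_schedule",
    "correct_event_times",
    "paradigm_total_duration_s",
    "schedule_to_tsv",
    "schedule_from_tsv",
]

FULLFIELD = 0  # sector_id sentinel for whole-pattern reversal events

ECC_MAX_DEG = 22.25
N_RINGS_PRE = 6
SECTORS_PER_RING_PRE = (4, 8, 12, 12, 12, 12)  # totals 60
DEFAULT_MERGE_PLAN = ((3, 4), (5, 6))
FRAME_WIDTH_PX = 2048

# Display-sweep calibration: measured mean delay at the centre of each half of
# the 2048-px frame (left eye sees the left half, right eye the right half).
LEFT_CENTER_DELAY_MS = -3.3
RIGHT_CENTER_DELAY_MS = 4.36
_LEFT_CENTER_X = 512.0
_RIGHT_CENTER_X = 1536.0

# ffVEP block: 6 segments on a fixed 25 s pitch -> exactly 150 s (2.5 min).
FFVEP_SEGMENT_PITCH_S = 25.0
# mfVEP block: 16 segments of (2 s onset + 1024 steps) totalling 750 s
# (12.5 min) => step duration (750/16 - 2)/1024 s, i.e. ~2.63 frames at 60 fps.
MFVEP_TOTAL_S = 750.0
DEFAULT_FRAME_RATE_HZ = 60.0
DEFAULT_FRAMES_PER_STEP = (MFVEP_TOTAL_S / 16.0 - 2.0) * DEFAULT_FRAME_RATE_HZ / 1024.0
BREAK_BETWEEN_TESTS_S = 30.0


@dataclass(frozen=True)
class SectorGeometry:
    """One dartboard sector after ring merging.

    ``ring_index`` counts merged rings from fixation outward (1-based).
    ``theta_lo/theta_hi`` bound the angular span in degrees, measured
    counter-clockwise from the positive x axis.  ``centroid_x_pixel`` is the
    sector centroid's horizontal coordinate in the eye's half of a 2048-px
    frame (used for display-delay correction).
    """

    sector_id: int
    ring_index: int
    ecc_inner: float
    ecc_outer: float
    theta_lo: float
    theta_hi: float
    centroid_x_pixel: float

    @property
    def angular_span(self) -> float:
        return self.theta_hi - self.theta_lo


def integrated_magnification(ecc_deg, e2_deg: float = 2.5):
    """Integral of the inverse-linear cortical magnification M(E) ∝ 1/(E+E2)
    from 0 to ``ecc_deg`` (arbitrary units).  Ring boundaries are chosen so
    each pre-merge ring spans an equal increment of this integral."""
    return np.log1p(np.asarray(ecc_deg, dtype=float) / e2_deg)


def _ring_boundaries(ecc_max: float, n_rings: int, e2_deg: float) -> np.ndarray:
    total = integrated_magnification(ecc_max, e2_deg)
    levels = np.linspace(0.0, total, n_rings + 1)
    # invert log1p(E/e2) = level
    return e2_deg * np.expm1(levels)


def build_dartboard_geometry(
    ecc_max: float = ECC_MAX_DEG,
    n_rings_pre: int = N_RINGS_PRE,
    merge_plan=DEFAULT_MERGE_PLAN,
    sectors_per_ring=SECTORS_PER_RING_PRE,
    e2_deg: float = 2.5,
    eye: str = "L",
) -> list[SectorGeometry]:
    """Build the merged dartboard sector set.

    ``merge_plan`` is a list of (ring_a, ring_b) pairs of adjacent pre-merge
    rings (1-based) to unite radially; rings must not repeat across pairs and
    paired rings must carry equal sector counts.  An empty plan returns the
    pre-merge layout (60 sectors by default).
    """
    if ecc_max <= 0:
        raise ValueError("ecc_max must be positive")
    if len(sectors_per_ring) != n_rings_pre:
        raise ValueError("sectors_per_ring must list one count per pre-merge ring")
    used: set[int] = set()
    for pair in merge_plan:
        a, b = pair
        if not (1 <= a <= n_rings_pre and 1 <= b <= n_rings_pre):
            raise ValueError(f"merge_plan references ring outside 1..{n_rings_pre}: {pair}")
        if b != a + 1:
            raise ValueError(f"merge_plan pairs must be adjacent rings: {pair}")
        if used & {a, b}:
            raise ValueError(f"merge_plan rings overlap: {pair}")
        if sectors_per_ring[a - 1] != sectors_per_ring[b - 1]:
            raise ValueError(f"merged rings must have equal sector counts: {pair}")
        used |= {a, b}

    bounds = _ring_boundaries(ecc_max, n_rings_pre, e2_deg)
    # map pre-merge ring -> merged ring index and merged ecc bounds
    merged_rings: list[tuple[float, float, int]] = []  # (ecc_in, ecc_out, n_sectors)
    r = 1
    while r <= n_rings_pre:
        if any(a == r for a, _ in merge_plan):
            merged_rings.append((bounds[r - 1], bounds[r + 1], sectors_per_ring[r - 1]))
            r += 2
        else:
            merged_rings.append((bounds[r - 1], bounds[r], sectors_per_ring[r - 1]))
            r += 1

    px_per_deg = (FRAME_WIDTH_PX / 2.0) / 2.0 / ecc_max  # eye's half-frame, radius = quarter frame
    x_center = _LEFT_CENTER_X if eye == "L" else _RIGHT_CENTER_X
    sectors: list[SectorGeometry] = []
    sid = 1
    for ring_idx, (ecc_in, ecc_out, n_sec) in enumerate(merged_rings, start=1):
        span = 360.0 / n_sec
        for k in range(n_sec):
            th_lo = k * span
            th_hi = th_lo + span
            th_mid = np.deg2rad(0.5 * (th_lo + th_hi))
            ecc_mid = 0.5 * (ecc_in + ecc_out)
            cx = x_center + ecc_mid * px_per_deg * np.cos(th_mid)
            sectors.append(
                SectorGeometry(
                    sector_id=sid,
                    ring_index=ring_idx,
                    ecc_inner=float(ecc_in),
                    ecc_outer=float(ecc_out),
                    theta_lo=th_lo,
                    theta_hi=th_hi,
                    centroid_x_pixel=float(cx),
                )
            )
            sid += 1
    return sectors


@dataclass(frozen=True)
class MSequenceSet:
    """A set of mutually low-correlation balanced ±1 stimulation sequences."""

    sequences: np.ndarray  # (n, L) int8, values ±1
    frame_rate: float
    seed: int
    max_xcorr: float

    @property
    def n(self) -> int:
        return self.sequences.shape[0]

    @property
    def length(self) -> int:
        return self.sequences.shape[1]


def _balanced_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    half = length // 2
    seq = np.concatenate([np.ones(length - half), -np.ones(half)]).astype(np.int8)
    rng.shuffle(seq)
    return seq


def max_pairwise_xcorr(seqs: np.ndarray, max_lag: int) -> float:
    """Largest |normalized cross-correlation| over all ordered pairs and lags
    0..max_lag (direct scan; sequences assumed ±1 so the normalizer is L)."""
    n, L = seqs.shape
    worst = 0.0
    f = np.fft.rfft(seqs, 2 * L, axis=1)
    for i in range(n):
        cc = np.fft.irfft(f[i].conj()[None, :] * f, 2 * L, axis=1)[:, : max_lag + 1] / L
        cc[i, :] = 0.0  # ignore self at all lags (autocorr lag0 == 1 trivially)
        worst = max(worst, float(np.abs(cc).max()))
    return worst


def generate_msequences(
    n: int = 36,
    length: int = 2**14,
    seed: int = 0,
    max_xcorr: float = 0.05,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
    max_lag: int = 16,
    max_retries: int = 200,
) -> MSequenceSet:
    """Draw ``n`` balanced ±1 sequences with all pairwise normalized
    cross-correlations at lags 0..``max_lag`` below ``max_xcorr``.

    Sequences are seeded-random balanced draws with rejection: any sequence
    whose correlation against the accepted set exceeds the bound is redrawn.
    Deterministic for a fixed seed.
    """
    if length < 256:
        raise ValueError("length must be >= 256")
    if not 0 < max_xcorr < 1:
        raise ValueError("max_xcorr must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    fset: list[np.ndarray] = []  # cached rffts of accepted sequences
    nfft = 2 * length
    achieved = 0.0
    for _ in range(n):
        ok = False
        for _try in range(max_retries):
            cand = _balanced_sequence(rng, length)
            fc = np.fft.rfft(cand, nfft)
            if fset:
                F = np.vstack(fset)
                cc = np.fft.irfft(F.conj() * fc[None, :], nfft, axis=1)[:, : max_lag + 1] / length
                cc2 = np.fft.irfft(fc.conj()[None, :] * F, nfft, axis=1)[:, : max_lag + 1] / length
                worst = max(float(np.abs(cc).max()), float(np.abs(cc2).max()))
            else:
                worst = 0.0
            achieved = worst
            if worst <= max_xcorr:
                accepted.append(cand)
                fset.append(fc)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not satisfy max_xcorr={max_xcorr} after {max_retries} retries "
                f"(best achieved {achieved:.4f}); increase length or relax the bound"
            )
    return MSequenceSet(
        sequences=np.vstack(accepted),
        frame_rate=frame_rate,
        seed=seed,
        max_xcorr=max_xcorr,
    )


@dataclass(frozen=True)
class ScheduleEvent:
    time_s: float
    eye: str  # "L" | "R"
    sector_id: int  # FULLFIELD (0) for whole-pattern reversals
    state: int  # ±1


@dataclass(frozen=True)
class Segment:
    start_s: float
    end_s: float
    eye: str
    onset_discard_s: float

    def usable(self, t: float) -> bool:
        return (self.start_s + self.onset_discard_s) <= t <= (self.end_s - self.onset_discard_s)


@dataclass
class StimulusSchedule:
    """Timed stimulation plan.

    ffVEP schedules carry their reversal events in ``events``.  mfVEP
    schedules are large (36 sectors x 16,384 steps) and instead carry compact
    arrays: ``step_times_s`` (n_steps,), ``step_eyes`` (n_steps, "L"/"R") and
    ``states`` (n_sectors, n_steps) in ±1; ``events`` materializes them on
    demand.
    """

    paradigm: str  # "ffvep" | "mfvep"
    events: list[ScheduleEvent]
    segments: list[Segment]
    total_duration_s: float
    step_s: float | None = None  # mfVEP only: duration of one sequence step
    step_times_s: np.ndarray | None = None
    step_eyes: np.ndarray | None = None
    states: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def materialize_events(self) -> list[ScheduleEvent]:
        """Expand mfVEP step arrays into per-sector ScheduleEvents (large)."""
        if self.events or self.states is None:
            return self.events
        out = []
        n_sectors = self.states.shape[0]
        for k, (t, eye) in enumerate(zip(self.step_times_s, self.step_eyes)):
            for sec in range(n_sectors):
                out.append(ScheduleEvent(float(t), str(eye), sec + 1, int(self.states[sec, k])))
        return out

    def events_for_eye(self, eye: str) -> list[ScheduleEvent]:
        return [e for e in self.events if e.eye == eye]

    def usable_events(self) -> list[ScheduleEvent]:
        """Events outside every segment's onset/offset discard windows."""
        out = []
        for ev in self.events:
            seg = self.segment_at(ev.time_s)
            if seg is not None and seg.usable(ev.time_s):
                out.append(ev)
        return out

    def segment_at(self, t: float):
        for seg in self.segments:
            if seg.start_s <= t < seg.end_s:
                return seg
        return None


def build_ffvep_schedule(
    trials_per_eye: int = 90,
    segments: int = 6,
    base_interval_s: float = 0.5,
    jitter_s: float = 0.1,
    onset_discard_s: float = 2.0,
    seed: int = 0,
    segment_pitch_s: float = FFVEP_SEGMENT_PITCH_S,
) -> StimulusSchedule:
    """Full-field paradigm: alternating-eye segments of pattern reversals.

    ``segments`` counts total segments over both eyes; each eye receives
    ``trials_per_eye`` reversals split evenly across its segments.  Segments
    sit on a fixed ``segment_pitch_s`` grid so the default block lasts exactly
    6 x 25 s = 150 s.
    """
    if segments % 2 != 0:
        raise ValueError("segments must be even (eyes alternate)")
    per_seg, rem = divmod(trials_per_eye, segments // 2)
    if rem:
        raise ValueError(
            f"trials_per_eye={trials_per_eye} not divisible by per-eye segments={segments // 2}"
        )
    rng = np.random.default_rng(seed)
    events: list[ScheduleEvent] = []
    seg_list: list[Segment] = []
    state = 1
    for s in range(segments):
        eye = "L" if s % 2 == 0 else "R"
        start = s * segment_pitch_s
        t = start + onset_discard_s
        gaps = base_interval_s + rng.uniform(0.0, jitter_s, size=per_seg)
        for g in gaps:
            t += float(g)
            events.append(ScheduleEvent(time_s=t, eye=eye, sector_id=FULLFIELD, state=state))
            state = -state
        end = start + segment_pitch_s
        if t > end - onset_discard_s:
            raise ValueError("segment_pitch_s too short for the requested trial count")
        seg_list.append(Segment(start_s=start, end_s=end, eye=eye, onset_discard_s=onset_discard_s))
    return StimulusSchedule(
        paradigm="ffvep",
        events=events,
        segments=seg_list,
        total_duration_s=segments * segment_pitch_s,
        meta={"seed": seed, "trials_per_eye": trials_per_eye},
    )


def build_mfvep_schedule(
    mseqs: MSequenceSet,
    segments: int = 16,
    trials_per_segment: int = 1024,
    frames_per_step: float = DEFAULT_FRAMES_PER_STEP,
    onset_discard_s: float = 2.0,
    eyes: str = "alternate",
) -> StimulusSchedule:
    """Multifocal paradigm: per-sector ±1 state stream, alternating eyes
    (``eyes="alternate"``) or a monocular run (``eyes="L"``/``"R"``).

    One "trial" is one sequence step; each segment consumes the next
    ``trials_per_segment`` elements of every sector's sequence (cyclic if the
    sequence is shorter than the whole schedule).  Default geometry: 16
    segments x 1024 steps at ~43.8 ms/step + 2 s onsets = 750 s.
    """
    if mseqs.length < trials_per_segment:
        raise ValueError(
            f"sequence length {mseqs.length} shorter than trials_per_segment={trials_per_segment}"
        )
    step_s = frames_per_step / mseqs.frame_rate
    seg_list: list[Segment] = []
    seg_dur = onset_discard_s + trials_per_segment * step_s
    if eyes not in ("alternate", "L", "R"):
        raise ValueError("eyes must be 'alternate', 'L', or 'R'")
    times = np.empty(segments * trials_per_segment)
    eye_arr = np.empty(segments * trials_per_segment, dtype="<U1")
    cols = np.empty(segments * trials_per_segment, dtype=np.intp)
    for s in range(segments):
        eye = ("L" if s % 2 == 0 else "R") if eyes == "alternate" else eyes
        start = s * seg_dur
        seg_list.append(Segment(start_s=start, end_s=start + seg_dur, eye=eye, onset_discard_s=0.0))
        sl = slice(s * trials_per_segment, (s + 1) * trials_per_segment)
        times[sl] = start + onset_discard_s + np.arange(trials_per_segment) * step_s
        eye_arr[sl] = eye
        cols[sl] = (s * trials_per_segment + np.arange(trials_per_segment)) % mseqs.length
    states = mseqs.sequences[:, cols]
    return StimulusSchedule(
        paradigm="mfvep",
        events=[],
        segments=seg_list,
        total_duration_s=segments * seg_dur,
        step_s=step_s,
        step_times_s=times,
        step_eyes=eye_arr,
        states=states,
        meta={
            "seed": mseqs.seed,
            "segments": segments,
            "trials_per_segment": trials_per_segment,
            "frames_per_step": frames_per_step,
        },
    )


def paradigm_total_duration_s(
    ffvep: StimulusSchedule, mfvep: StimulusSchedule, break_s: float = BREAK_BETWEEN_TESTS_S
) -> float:
    """Duration of the combined testing session: ffVEP block, rest break,
    mfVEP block (default paradigms: 150 + 30 + 750 s = 15.5 min)."""
    return ffvep.total_duration_s + break_s + mfvep.total_duration_s


@dataclass(frozen=True)
class DelayModel:
    """Linear display-sweep delay per screen side: delay_ms = slope·x + intercept.

    Defaults pass through the measured side-centre calibration constants with a
    common slope joining them (the OLED refresh sweeps left to right, so delay
    grows linearly with horizontal pixel coordinate).
    """

    left_slope_ms_per_px: float = (RIGHT_CENTER_DELAY_MS - LEFT_CENTER_DELAY_MS) / (
        _RIGHT_CENTER_X - _LEFT_CENTER_X
    )
    left_intercept_ms: float = LEFT_CENTER_DELAY_MS - _LEFT_CENTER_X * (
        (RIGHT_CENTER_DELAY_MS - LEFT_CENTER_DELAY_MS) / (_RIGHT_CENTER_X - _LEFT_CENTER_X)
    )
    right_slope_ms_per_px: float = (RIGHT_CENTER_DELAY_MS - LEFT_CENTER_DELAY_MS) / (
        _RIGHT_CENTER_X - _LEFT_CENTER_X
    )
    right_intercept_ms: float = LEFT_CENTER_DELAY_MS - _LEFT_CENTER_X * (
        (RIGHT_CENTER_DELAY_MS - LEFT_CENTER_DELAY_MS) / (_RIGHT_CENTER_X - _LEFT_CENTER_X)
    )

    def delay_ms(self, x_pixel: float, side: str) -> float:
        if not 0 <= x_pixel < FRAME_WIDTH_PX:
            raise ValueError(f"pixel coordinate {x_pixel} outside [0, {FRAME_WIDTH_PX})")
        if side == "L":
            return self.left_slope_ms_per_px * x_pixel + self.left_intercept_ms
        return self.right_slope_ms_per_px * x_pixel + self.right_intercept_ms

    @staticmethod
    def identity() -> "DelayModel":
        return DelayModel(0.0, 0.0, 0.0, 0.0)


def correct_event_times(
    events: list[ScheduleEvent],
    sector_geometry: list[SectorGeometry] | None = None,
    delay_model: DelayModel | None = None,
) -> list[ScheduleEvent]:
    """Shift each event by the display-sweep delay of its sector's centroid.

    The eye determines the screen side (left eye sees the left half).
    Full-field events are corrected by their side's centre delay.  Returns new
    events; input order preserved.
    """
    dm = delay_model if delay_model is not None else DelayModel()
    cent = {}
    if sector_geometry is not None:
        cent = {g.sector_id: g.centroid_x_pixel for g in sector_geometry}
    out = []
    for ev in events:
        side = ev.eye
        if ev.sector_id == FULLFIELD:
            x = _LEFT_CENTER_X if side == "L" else _RIGHT_CENTER_X
        else:
            if ev.sector_id not in cent:
                raise ValueError(f"no geometry for sector {ev.sector_id}")
            x = cent[ev.sector_id]
            if side == "R":
                # geometry built for the left half; mirror into the right half
                x = x + (_RIGHT_CENTER_X - _LEFT_CENTER_X)
        d = dm.delay_ms(x, side) / 1000.0
        out.append(replace(ev, time_s=ev.time_s + d))
    return out


def sector_delays_s(
    sector_geometry: list[SectorGeometry],
    eye: str,
    delay_model: DelayModel | None = None,
) -> np.ndarray:
    """Per-sector display-sweep delay (seconds) for one eye, indexed by
    sector_id - 1.  Array counterpart of :func:`correct_event_times` for the
    compact mfVEP schedule representation."""
    dm = delay_model if delay_model is not None else DelayModel()
    out = np.zeros(len(sector_geometry))
    for g in sector_geometry:
        x = g.centroid_x_pixel
        if eye == "R":
            x = x + (_RIGHT_CENTER_X - _LEFT_CENTER_X)
        out[g.sector_id - 1] = dm.delay_ms(x, eye) / 1000.0
    return out


def schedule_to_tsv(schedule: StimulusSchedule, path) -> None:
    """Write events as TSV (time_s, eye, sector_id, state)."""
    with open(path, "w") as fh:
        fh.write("time_s\teye\tsector_id\tstate\n")
        for ev in schedule.events or schedule.materialize_events():
            fh.write(f"{ev.time_s:.6f}\t{ev.eye}\t{ev.sector_id}\t{ev.state}\n")


def schedule_from_tsv(path, paradigm: str = "ffvep") -> StimulusSchedule:
    """Read a bare event table back.  Segment structure is not stored in the
    TSV; a single all-covering segment with no discard window is synthesized."""
    events = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("time_s"):
            raise ValueError("not a schedule TSV (missing header)")
        for line in fh:
            t, eye, sid, st = line.rstrip("\n").split("\t")
            events.append(ScheduleEvent(float(t), eye, int(sid), int(st)))
    dur = (max(ev.time_s for ev in events) + 1.0) if events else 0.0
    segs = [Segment(0.0, dur, eye, 0.0) for eye in ("L", "R")] if events else []
    return StimulusSchedule(paradigm=paradigm, events=events, segments=segs, total_duration_s=dur)
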