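"""Dartboard geometry, stimulation sequences, paradigm schedules, and
display-delay correction."""

import numpy as np
import pytest
from scipy.integrate import quad

from vepkit import stimulus as st


class TestGeometry:
    def test_default_has_36_sectors_and_premerge_60(self):
        assert len(st.build_dartboard_geometry()) == 36
        assert len(st.build_dartboard_geometry(merge_plan=())) == 60

    def test_outermost_ring_reaches_ecc_max(self, geometry):
        assert geometry[-1].ecc_outer == pytest.approx(22.25)

    def test_rings_tile_without_gaps_and_equal_spans(self, geometry):
        by_ring = {}
        for g in geometry:
            by_ring.setdefault(g.ring_index, []).append(g)
        prev_outer = 0.0
        for r in sorted(by_ring):
            ring = by_ring[r]
            assert ring[0].ecc_inner == pytest.approx(prev_outer, abs=1e-12)
            prev_outer = ring[0].ecc_outer
            spans = {g.angular_span for g in ring}
            assert len(spans) == 1  # equal to machine precision
            assert sum(g.angular_span for g in ring) == pytest.approx(360.0)

    def test_ring_boundaries_match_quadrature_of_magnification(self):
        """Pre-merge ring edges split the integrated cortical magnification
        M(E) = 1/(E + 2.5) into six equal increments (dense-quadrature oracle)."""
        geo = st.build_dartboard_geometry(merge_plan=())
        edges = sorted({g.ecc_outer for g in geo})
        total, _ = quad(lambda e: 1.0 / (e + 2.5), 0, 22.25)
        for k, edge in enumerate(edges, start=1):
            seg, _ = quad(lambda e: 1.0 / (e + 2.5), 0, edge)
            assert seg == pytest.approx(k * total / 6.0, rel=1e-8)

    @pytest.mark.parametrize(
        "plan", [((3, 3),), ((0, 1),), ((5, 7),), ((3, 4), (4, 5))], ids=str
    )
    def test_invalid_merge_plans_rejected(self, plan):
        with pytest.raises(ValueError):
            st.build_dartboard_geometry(merge_plan=plan)


class TestMSequences:
    def test_same_seed_identical_and_type_contract(self):
        a = st.generate_msequences(n=4, length=2048, seed=7, max_xcorr=0.3)
        b = st.generate_msequences(n=4, length=2048, seed=7, max_xcorr=0.3)
        assert np.array_equal(a.sequences, b.sequences)
        assert set(np.unique(a.sequences)) == {-1, 1}
        assert a.sequences.shape == (4, 2048)

    def test_balanced_within_one(self, mseqs):
        sums = mseqs.sequences.sum(axis=1)
        assert np.all(np.abs(sums) <= 1)

    def test_xcorr_bound_against_direct_scan(self):
        """Every pairwise normalized cross-correlation at lags 0..16 stays
        below the bound (independent O(n^2 L) loop oracle)."""
        ms = st.generate_msequences(n=4, length=2048, seed=3, max_xcorr=0.3, max_lag=8)
        L = ms.length
        worst = 0.0
        for i in range(ms.n):
            for j in range(ms.n):
                if i == j:
                    continue
                for lag in range(9):
                    c = float(np.dot(ms.sequences[i, : L - lag], ms.sequences[j, lag:])) / L
                    worst = max(worst, abs(c))
        assert worst <= 0.3

    def test_unsatisfiable_bound_raises_with_achieved_value(self):
        with pytest.raises(RuntimeError, match="achieved"):
            st.generate_msequences(n=8, length=256, seed=0, max_xcorr=0.01, max_retries=5)

    def test_length_precondition(self):
        with pytest.raises(ValueError):
            st.generate_msequences(length=64)


class TestFfvepSchedule:
    def test_default_90_trials_per_eye(self):
        sched = st.build_ffvep_schedule()
        for eye in "LR":
            assert len(sched.events_for_eye(eye)) == 90

    def test_zero_jitter_gives_exact_half_second_gaps(self):
        sched = st.build_ffvep_schedule(jitter_s=0.0)
        for seg in sched.segments:
            t = [e.time_s for e in sched.events if seg.start_s <= e.time_s < seg.end_s]
            assert np.allclose(np.diff(t), 0.5)

    def test_gaps_within_jitter_bounds(self):
        sched = st.build_ffvep_schedule(seed=9)
        for seg in sched.segments:
            t = np.array([e.time_s for e in sched.events if seg.start_s <= e.time_s < seg.end_s])
            gaps = np.diff(t)
            assert np.all(gaps >= 0.5) and np.all(gaps <= 0.6)

    def test_eyes_alternate_and_no_event_in_discard_window(self):
        sched = st.build_ffvep_schedule()
        assert [s.eye for s in sched.segments] == ["L", "R"] * 3
        assert len(sched.usable_events()) == len(sched.events)
        for ev in sched.events:
            seg = sched.segment_at(ev.time_s)
            assert seg.usable(ev.time_s)

    def test_indivisible_trials_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            st.build_ffvep_schedule(trials_per_eye=91)


class TestMfvepSchedule:
    def test_default_16384_trials(self, mseqs):
        sched = st.build_mfvep_schedule(mseqs)
        assert len(sched.step_times_s) == 16 * 1024 == 16384

    def test_each_eye_receives_its_segments(self, mseqs):
        sched = st.build_mfvep_schedule(mseqs, segments=2, trials_per_segment=4)
        assert (sched.step_eyes == "L").sum() == 4
        assert (sched.step_eyes == "R").sum() == 4

    def test_states_equal_source_sequence_slices(self, mseqs):
        sched = st.build_mfvep_schedule(mseqs, segments=4, trials_per_segment=256)
        for seg in range(4):
            sl = slice(seg * 256, (seg + 1) * 256)
            assert np.array_equal(sched.states[:, sl], mseqs.sequences[:, sl])

    def test_sequence_shorter_than_segment_rejected(self):
        ms = st.generate_msequences(n=2, length=512, seed=1, max_xcorr=0.5)
        with pytest.raises(ValueError, match="shorter"):
            st.build_mfvep_schedule(ms, trials_per_segment=1024)

    def test_total_paradigm_duration_is_15_5_minutes(self, mseqs):
        ff = st.build_ffvep_schedule()
        mf = st.build_mfvep_schedule(mseqs)
        assert mf.total_duration_s == pytest.approx(750.0)
        assert st.paradigm_total_duration_s(ff, mf) == pytest.approx(930.0)  # 15.5 min

    def test_schedules_strictly_time_ordered(self, mseqs):
        ff = st.build_ffvep_schedule(seed=4)
        assert np.all(np.diff([e.time_s for e in ff.events]) > 0)
        mf = st.build_mfvep_schedule(mseqs)
        assert np.all(np.diff(mf.step_times_s) > 0)


class TestDelayCorrection:
    def test_left_fullfield_shifts_minus_3_3_ms(self):
        ev = [st.ScheduleEvent(10.0, "L", st.FULLFIELD, 1)]
        out = st.correct_event_times(ev)
        assert (out[0].time_s - 10.0) * 1000.0 == pytest.approx(-3.3)

    def test_right_fullfield_shifts_plus_4_36_ms(self):
        ev = [st.ScheduleEvent(10.0, "R", st.FULLFIELD, 1)]
        out = st.correct_event_times(ev)
        assert (out[0].time_s - 10.0) * 1000.0 == pytest.approx(4.36)

    def test_identity_model_leaves_events_unchanged(self, geometry):
        ev = [st.ScheduleEvent(3.0, "L", 12, -1)]
        out = st.correct_event_times(ev, geometry, st.DelayModel.identity())
        assert out[0].time_s == 3.0

    def test_linearity_midpoint(self):
        """Correction at the midpoint of two pixel coordinates equals the
        mean of the endpoint corrections."""
        dm = st.DelayModel()
        x1, x2 = 300.0, 900.0
        mid = dm.delay_ms(0.5 * (x1 + x2), "L")
        assert mid == pytest.approx(0.5 * (dm.delay_ms(x1, "L") + dm.delay_ms(x2, "L")))

    def test_centroid_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            st.DelayModel().delay_ms(2048.0, "L")


def test_schedule_tsv_round_trip(tmp_path):
    sched = st.build_ffvep_schedule(seed=6)
    p = tmp_path / "sched.tsv"
    st.schedule_to_tsv(sched, p)
    back = st.schedule_from_tsv(p)
    assert len(back.events) == len(sched.events)
    for a, b in zip(back.events, sched.events):
        assert a.time_s == pytest.approx(b.time_s, abs=1e-6)
        assert (a.eye, a.sector_id, a.state) == (b.eye, b.sector_id, b.state)
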