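"""Build the testing paradigm: dartboard geometry, stimulation sequences,
and the combined ffVEP + mfVEP schedule.

Prints the design constants of the stated paradigm: 36 merged sectors (60
pre-merge), 90 full-field trials per eye, 16,384 multifocal steps, and a
15.5-minute combined session.
"""

from vepkit import stimulus as st

geometry = st.build_dartboard_geometry()
premerge = st.build_dartboard_geometry(merge_plan=())
print(f"dartboard: {len(geometry)} sectors after merging ({len(premerge)} pre-merge)")
for ring in range(1, 5):
    ring_secs = [g for g in geometry if g.ring_index == ring]
    print(
        f"  ring {ring}: {len(ring_secs):2d} sectors, "
        f"{ring_secs[0].ecc_inner:5.2f}-{ring_secs[0].ecc_outer:5.2f} deg eccentricity"
    )

mseqs = st.generate_msequences(seed=1)
print(
    f"\nstimulation sequences: {mseqs.n} x {mseqs.length} balanced ±1, "
    f"max pairwise cross-correlation {st.max_pairwise_xcorr(mseqs.sequences, 16):.4f}"
)

ffvep = st.build_ffvep_schedule(seed=0)
mfvep = st.build_mfvep_schedule(mseqs)
total = st.paradigm_total_duration_s(ffvep, mfvep)
print(f"\nffVEP: {len(ffvep.events_for_eye('L'))} trials/eye, {ffvep.total_duration_s:.0f} s")
print(f"mfVEP: {len(mfvep.step_times_s)} steps, {mfvep.total_duration_s:.0f} s")
print(f"combined session: {total / 60:.1f} min (incl. 30 s break)")

# display-delay correction: the OLED sweep delays each sector by its
# horizontal position; full-field events use the side-centre constants
ev = st.correct_event_times(ffvep.events[:1], geometry)
print(f"\nleft-eye full-field event delay: {(ev[0].time_s - ffvep.events[0].time_s) * 1e3:+.2f} ms")
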