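# Methods

`vepkit` implements the analysis chain of a combined full-field (ffVEP) and
multifocal (mfVEP) visual evoked potential test: 8 occipital EEG channels at
1000 samples/s, a dartboard stimulus spanning 0–22.25° eccentricity, and a
machine-learning classifier that scores each of 36 visual-field sectors.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Stimulus model

**Dartboard geometry.** The pre-merge layout has 60 sectors in 6 rings; rings
3+4 and 5+6 are united radially to give the 36 test sectors. Ring boundaries
follow an inverse-linear cortical magnification M(E) ∝ 1/(E + E₂) with
E₂ = 2.5° by default: each pre-merge ring spans an equal increment of
∫M dE, so rings drive roughly equal areas of V1. Angular sector counts per
pre-merge ring are (4, 8, 12, 12, 12, 12); merging pairs of 12-sector rings
radially leaves 4 + 8 + 12 + 12 = 36. Both the magnification function and the
ring counts are configurable; the defaults are one consistent choice among
several plausible dartboard layouts.

**Stimulation sequences.** Each sector reverses (state +1) or holds (−1)
per step according to its own balanced ±1 pseudorandom sequence
(length 2¹⁴ by default). Sequences are drawn with rejection until every
pairwise normalized cross-correlation at lags 0–16 is below 0.05; at the
default length the typical worst pair sits near 0.03. Classical
shift-register m-sequences are not used because 36 mutually low-correlation
sequences are needed and the decode runs on per-eye subsets of the step
stream, where shift-register orthogonality does not survive partial-period
summation anyway.

**Schedules.** ffVEP: 90 reversals per eye in 6 alternating-eye segments of
30, inter-trial interval 0.5 s + U(0, 0.1) s, 2 s onset/offset discard.
Segments sit on a fixed 25 s pitch so the block lasts exactly 150 s; the
residual slack is the eye-switch pause (the published trial arithmetic
under-fills the stated 2.5 min, so the pitch is the package's own choice).
mfVEP: 16 alternating-eye segments of 1024 steps. The step duration defaults
to (750/16 − 2)/1024 s ≈ 43.8 ms (≈2.63 frames at 60 fps) so that 16
segments with 2 s onsets total exactly 12.5 min; the step count, frame rate
and section duration are mutually under-determined, so frames_per_step is a
float configuration parameter. With the 30 s inter-test break the session is
930 s = 15.5 min.

**Display-delay correction.** The OLED display refreshes left to right, so a
sector's physical reversal lags the trigger linearly in its horizontal pixel
coordinate. The model ships measured side-centre constants (−3.3 ms left,
+4.36 ms right of the 2048-px frame) joined by a common slope; every decoder
consumes delay-corrected event times, and full-field events use their eye's
centre constant.

## Synthetic data

The simulator generates the stated world the pipeline assumes, not
biophysics. Evoked kernels are biphasic (negative lobe ~25 ms before the
positive peak, i.e. an N75–P100 pair for a 100 ms peak), Gaussian-lobed, with
the discrete argmax pinned to the configured peak time and the maximum equal
to the configured amplitude (defaults 100 ms, 5 µV full-field, 1 µV per
mfVEP sector, width 25 ms). The mfVEP forward model is the convolution of
each sector's ±1 state stream with its kernel, scaled by a per-sector gain in
[0, 1]; gain 0 (masked/defect) contributes nothing but background, matching
the hypothesis that masking emulates complete loss of vision.

Background is 1/f Gaussian noise (exponent 1, 2 µV RMS per channel),
plus Poisson-timed alpha bursts (8–13 Hz sinusoids under a Hann envelope,
0.05 bursts/s, 8 µV) and sparse Hann-shaped movement artifacts (0.01/s,
40 µV). No quantitative noise levels are published for the hardware; these
defaults were chosen once so the two rejection screens operate at realistic
1–10 % rejection rates and are config-exposed. Channel gains
(1.0, 0.9, 0.35, 1.05, 0.4, 0.95, 1.2, 0.45) give the evoked response a
non-uniform scalp topography so pairwise derived channels retain signal;
E7 > E2 makes the default D4 polarity-inverted, exercising the polarity
matcher. All randomness flows from one seeded generator per operation, so a
config + seed pair reproduces a recording bit-exactly.

What the simulator does **not** model: volume conduction, cortical folding,
inter-subject topography variability, eye movements/fixation loss, electrode
impedance drift. A green end-to-end test therefore establishes that the
pipeline recovers what the forward model encodes at realistic noise — not
clinical performance.

## Signal conditioning

Every channel passes a stationary-wavelet (symlet-4) baseline removal with a
0.5 Hz effective cutoff, then band limiting to 3–13 Hz via a 4th-order Bessel
high-pass (corner = −3 dB point, applied forward-backward for zero phase)
and an SWT low-pass. The SWT approximation at depth d is realized as the
zero-phase frequency-domain projection Π_j |H_j(ω)|²/2 over dilated
scaling-filter responses — exactly the undecimated analysis/conjugate-
synthesis cascade with details dropped, shift-invariant by construction,
with reflect padding against wrap-around. Depth is
floor(log₂(rate/cutoff)) − 1. Measured contracts: ≥ 20 dB at 0.1 Hz with
≤ 1 dB at 10 Hz for the baseline stage; ≤ 3 dB at 8 Hz and ≥ 12 dB at 1 and
30 Hz for the band limiter. PyWavelets is not available in the runtime
environment, so the transform is implemented in-package (`_wavelets.py`).

Epochs are [t, t + 0.5 s) at 1 kHz — exactly 500 samples. Two screens flag
(never mutate) trials: an isolation forest on log per-trial variance
(contamination 0.05; fit on value-sorted input so flags are independent of
trial order; contamination 0 disables the screen, since the estimator itself
rejects 0), and an alpha screen that flags a trial when its FFT power peak in
9–12 Hz exceeds the peak in the DC-exclusive 1–9 Hz band (peak comparison
rather than integrated band power — the choice is exposed in config). An
all-zero trial has no predominant band and is kept.

## Full-field analysis

Kept trials are averaged per electrode, then pooled: LA = mean(E1, E2) (O1),
CA = mean(E3..E6) (Oz), RA = mean(E7, E8) (O2), per eye. The P100 is the
maximum positive deflection in a 70–160 ms window (window bracketing the
normative means with margin; ties break earlier; no positive value = absent).
Amplitude is baseline-to-peak on the baseline-removed waveform — the simplest
convention consistent with normative ln(1+amp) statistics near 1.4–1.6; a
trough-to-peak alternative is configurable. Band limiting to 3–13 Hz biases
the measured peak ~2 ms late relative to the generative peak; this is
exactly why device-specific normative statistics are required, and the
parameter-recovery criterion tests the regression slope, not the offset.

Comparison metrics: interocular peak-time difference and amplitude ratio per
array, interhemispheric (LA vs RA, same eye) difference and ratio. Ratios
are larger/smaller (≥ 1); any comparison involving an absent P100 is NA.
Classification against a normative table (the package ships a 13-subject /
26-eye table; amplitudes on the ln(1+amp) scale):

* latencies/differences — normal < m+2s, borderline in [m+2s, m+3s] (closed,
  "between 2 and 3 std"), abnormal above;
* amplitudes — absent or negative P100 is abnormal outright; otherwise
  abnormal < m−3s, borderline [m−3s, m−2s), normal ≥ m−2s;
* ratios — normal < 2, borderline [2, 2.5], abnormal > 2.5.

Interhemispheric peak-time differences have no entry in the shipped
normative table and classify "unclassified" unless a user-fitted table
provides one. Interhemispheric comparisons are taken LA-vs-RA at matched eye.

## Multifocal analysis

Derived channels (default D1 = E1−E3, D2 = E4−E5, D3 = E6−E8, D4 = E2−E7,
fully configurable — the published pairing diagram is not machine-readable,
so the default is an informed stand-in consistent with the "closer together
than to the reference" rule) cancel shared far-field activity. Each sector's
kernel is decoded by the m-sequence correlation

    r(τ) = (1/N) Σ_k s_k · x(t_k + τ),  τ ∈ [0, 500) ms,

over the sector's kept steps of one eye, at delay-corrected step times
(sectors sharing a rounded delay are decoded in one matrix product). Steps
flagged by the variance screen (run on the overlapping 500 ms step windows)
are excluded.

Sector SNR = std(45–150 ms) / std(325–430 ms) of the decoded waveform,
computed per individual sector rather than against a cohort-averaged noise
window — per-sector noise preserves the statistic's discriminative power.
The functional form (std ratio; RMS ratio available) is a design choice; the
windows are fixed. The optimized response polarity-matches D1/D3/D4 to D2
(Pearson correlation over 0–300 ms; |r| < 0.1 records an ambiguous 0 and
applies no flip) and averages with SNR weights; its SNR is recomputed.

Decode fidelity in the stated world: with one active sector and no noise the
recovered kernel's normalized RMS error is ~0.04 and worst-case cross-talk
~3 % (bounds 0.1 and 10 %). With all 36 sectors active simultaneously,
partial-sequence correlation noise from ~23 overlapping kernel lags per
sector sets a decode floor of roughly 0.3 × kernel RMS even without sensor
noise; this floor is inherent to plain correlation decoding with random
sequences on finite data, is shared by both classes, and is well below the
masked/stimulated SNR separation the classifier consumes.

## Features

Nineteen statistics per optimized response, in a fixed order (12 custom + 7
canonical time-series statistics). Filter codes: BP = 3–50 Hz band-pass,
LP/HP at the stated corner; all per-feature filters are 4th-order Bessel
forward-backward with magnitude-normalized corners (the published table does
not fix the family; one family is used everywhere for comparability).
Notable conventions: peak ratios rank local extrema of either sign with a
10 ms minimum separation (suppresses sample-jitter peaks) and fall back,
flagged, to the lowest available peak when fewer than 3/4 exist; the
alpha-power ratio compares spectral peak power in 8–13 Hz against 0–8 Hz;
wavelet features are stds of the first half of level-1/2 DWT approximation
coefficients (symlet-4); zero-crossings are counted on the band-passed
signal. Non-finite values (zero-variance windows) map to 0 so the classifier
always receives finite vectors.

The seven canonical statistics (CO_f1ecac, CO_FirstMin_ac,
MD_hrv_classic_pnn40, DN_OutlierInclude_{p,n}_001_mdrmd,
SB_BinaryStats_diff_longstretch0, SB_MotifThree_quantile_hh) are implemented
in-package on the z-scored series (no reference package is installed in the
runtime environment); a naive loop-based transcription in the test suite
provides the independent oracle at 1e-6. SB_MotifThree uses the 50–200 ms
slice, the others the full 0–500 ms band-passed signal. Constant inputs
return a 0 sentinel.

The reference template for `response_cor` is the mean of the training set's
normal-labeled responses over 0–200 ms, stored with the model — the source
of the published template is unstated, and a data-driven template keeps the
model file self-contained.

## Classification

Training operates on raw 500 ms waveforms (augment first, then extract
features — matching the described signal-space augmentation; a feature-space
option exists for speed). Augmentation to a target count (production default
2¹⁶ = 65,536): draw a source uniformly, find its nearest same-class
neighbor (exact KD-tree; class-restricted to avoid manufactured label
noise — the published procedure is silent on this), mix with
α ~ N(0.5, 0.25²) clipped to [0, 1]. Class proportions follow the source
distribution within sampling error.

The classifier is an RBF-kernel SVM (C = 1, γ = 'scale') on z-scored
features with cross-validated sigmoid probability calibration
(CalibratedClassifierCV, cv = 5, ensemble=False); the calibrated probability
is the score source (which probability the published score uses is unstated).
Sector score = 100 · P(normal); call abnormal iff score < 50 (exactly 50 is
normal, the strict "below 50" reading); scores in [40, 60] carry an
"ambiguous" flag rendered mid-gray. Evaluation reports accuracy, sensitivity
(recall on abnormal), specificity (recall on normal) and ROC AUC; a
single-class evaluation set flags AUC undefined.

The end-to-end benchmark trains on 7 simulated ring-mask tests and evaluates
on a disjoint 16-test / 576-sector set (distinct simulation seeds). For CPU
budgets the benchmark augments to 8192 rather than 65,536 — the constant
65,536 is still exercised by the augmentation-count check — and reaches
accuracy ≥ 0.85 with balanced sensitivity/specificity in the stated world.
Ablations (no augmentation; without the 7 canonical features) are run to
confirm neither addition hurts held-out accuracy.

## Numerical choices and degenerate inputs

* Epochs are half-open [t, t+500) sample windows; event times round to the
  nearest sample.
* SNR with a zero-variance noise window reports +inf with a flag; combining
  treats non-finite SNR weights as 0, and an all-zero weight set falls back
  to the unweighted mean.
* The variance screen is skipped (with a warning) below 10 trials.
* z-scoring guards exact constants via peak-to-peak, not only std, because
  the float std of a constant array can be a rounding residue.
* Seeds derived from a user seed stay below 2³¹.

## Known limitations

* The decode floor with all sectors active (above) caps waveform fidelity in
  fully stimulated fields; sequence co-design (e.g. low partial-correlation
  families) would lower it but is out of scope.
* The shipped normative table covers the published metrics only; metrics
  without entries are reported but not classified.
* The simulator's alpha bursts are stimulus-independent, whereas real alpha
  is amplified when stimuli are unseen; the classifier's alpha features are
  therefore exercised, but their clinical effect size is not reproduced.
* Catch-22 conventions follow the published algorithm descriptions; without
  the reference binary in the environment, exact agreement with the upstream
  C implementation is asserted only against the in-repo transcription.
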