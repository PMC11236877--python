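# vepkit

Simulation, decoding, and classification of full-field and multifocal visual
evoked potentials (VEPs).

Pattern-reversal VEPs are scalp EEG responses to a reversing visual stimulus.
The P100 component's peak time is a standard biomarker of optic-nerve
demyelination (multiple sclerosis, optic neuritis), but full-field testing
gives no spatial information. Multifocal VEP (mfVEP) testing drives 36
dartboard sectors of the visual field concurrently with uncorrelated ±1
pseudorandom sequences and recovers each sector's response kernel by
correlating its sequence with the continuous EEG:

    r_s(τ) = (1/N) Σ_k s_k · x(t_k + τ),   τ ∈ [0, 500) ms

`vepkit` implements the complete analysis chain for a combined 15.5-minute
ffVEP + mfVEP session recorded from 8 occipital electrodes at 1 kHz:

* **stimulus** — cortical-magnification dartboard geometry (36 sectors, 60
  pre-merge), balanced low-cross-correlation ±1 sequences, ffVEP/mfVEP
  schedules, linear display-sweep delay correction;
* **synth** — a seeded generative model (biphasic evoked kernels, 1/f noise,
  alpha bursts, movement artifacts, masked-sector "artificial defects") so
  every stage is testable without hardware;
* **preprocess** — stationary-wavelet baseline removal (0.5 Hz), 3–13 Hz band
  limiting (Bessel high-pass + SWT low-pass), 500 ms epoching, isolation-
  forest variance screening and alpha-band (9–12 Hz) trial rejection;
* **ffvep** — O1/Oz/O2 array averaging, P100 peak time and amplitude,
  interocular/interhemispheric metrics, and normal/borderline/abnormal
  classification against normative statistics (mean+2σ / mean+3σ rules,
  amplitudes on the ln(1+amp) scale, ratio thresholds 2 / 2.5);
* **mfvep** — four bipolar derived channels, m-sequence kernel extraction,
  per-sector SNR (std 45–150 ms / std 325–430 ms), SNR-weighted
  polarity-matched optimized responses;
* **features** — a 19-element feature vector per sector response (12 custom
  waveform/spectral statistics + 7 canonical time-series statistics);
* **classify** — nearest-neighbor mixing augmentation (to 2¹⁶ samples),
  RBF-kernel SVM with probability calibration, 0–100 sector scores
  (score < 50 ⇒ abnormal; 40–60 flagged ambiguous), held-out evaluation;
* **io_report** — HDF5 recording container and grayscale visual-field maps.

The package is a library: the importable API plus the narrative scripts in
`examples/` (one per capability) are the interface. See `docs/methods.md`
for the models, parameter defaults, and design decisions.

## Worked example

`python examples/03_mfvep_decode.py` simulates a monocular mfVEP run with an
artificial scotoma (sectors 3, 7, 15, 22, 28, 33 masked to black), decodes
all 36 sectors, and ranks them by combined SNR:

```
recording: 8 channels x 375 s; masked sectors [3, 7, 15, 22, 28, 33]

six lowest-SNR sectors (expected: the masked ones):
  sector 28: combined SNR  0.69  [masked]
  sector 22: combined SNR  0.72  [masked]
  sector 15: combined SNR  0.93  [masked]
  sector  3: combined SNR  1.15  [masked]
  sector  7: combined SNR  1.36  [masked]
  sector 33: combined SNR  2.21  [masked]

median SNR, stimulated sectors: 13.42
median SNR, masked sectors:     1.04
```

A masked sector's decode contains only background, so its early "signal"
window matches its late "noise" window (SNR ≈ 1); stimulated sectors carry
the evoked kernel in the early window and score an order of magnitude
higher. `examples/05_train_and_score.py` continues to the classifier: it
trains on artificial-defect simulations and scores a fresh recording's
sectors 0–100, recovering the programmed scotoma (masked sectors score ~0,
stimulated sectors 92–100).

The other examples: `01_paradigm_and_geometry.py` (design constants:
36/60 sectors, 90 ffVEP trials/eye, 16,384 mfVEP steps, 15.5 min session),
`02_ffvep_report.py` (a delayed left-eye P100 classified borderline with an
abnormal interocular difference), `04_features.py` (feature vectors of an
evoked vs an alpha-dominated response).

## Acceptance script

`scripts/acceptance.py` re-runs the main computation from scratch on freshly
generated synthetic inputs: paradigm construction, a noiseless decoder-
fidelity measurement (kernel NRMSE and cross-talk), the full-field
P100-recovery regression, and a scaled-down train/evaluate round of the
sector classifier, printing each measured value. Run it from the repository
root:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
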