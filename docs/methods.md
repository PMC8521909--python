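# Methods

This note documents the models, defaults and numerical choices behind the
`jae` package, and what the synthetic cohort does and does not establish.

## Synthetic cohort model

The generator emulates the qualitative acoustics of pediatric knee
recordings rather than their physics:

- **Motion.** The knee angle follows a raised cosine per flexion/extension
  cycle (minimum = full extension at each cycle start), sampled at 50 Hz.
  Per-cycle period jitter (2% SD) and range-of-motion jitter (5% SD) emulate
  imperfect pacing; jittered periods are rescaled so the session length is
  exact, which keeps array shapes a function of the layout only, never of
  the seed. Measurement noise is 0.3° RMS on a 90° range of motion.
- **Healthy audio.** Gaussian white noise with RMS 1 (acceleration a.u.) —
  the noise-like emission of a smoothly articulating joint.
- **JIA audio.** The same noise plus clicks: per cycle a Poisson(6) number
  of transients at uniform phases, each an exponentially decaying sinusoid
  (3 ms time constant, carrier uniform in 2–8 kHz, peak 8× the noise RMS).
  Click morphology is a modeling choice; only "spike-like, high-frequency,
  high-energy" is constrained by the phenomenon.
- **Follow-up.** The JIA profile with click rate and amplitude divided by 5,
  emulating successful treatment. Follow-up sessions carry an *unknown*
  label and are excluded from all training.
- **Seeding.** Per-subject streams are derived by hashing
  (seed, subject_id, stream), so cohorts are bit-reproducible and enlarging
  a cohort never changes existing subjects' signals.

Default layout: 25 JIA + 18 healthy baselines, 10 follow-ups, 4 channels per
subject, 10 cycles of 4 s. The default audio rate is 25 kHz rather than the
clinical acquisition rate of 100 kHz: the analysis band ends at 10 kHz, so
nothing the pipeline measures is lost, while a full cohort stays in memory.
`fs_audio` is a config knob; the band-pass upper edge auto-clamps to
0.45·fs (with a warning) when a configured band does not fit under Nyquist,
or rejects the config when `auto_clamp_band` is off.

**What passing tests show — and don't.** The generator produces stationary
Gaussian backgrounds and idealized clicks. Real recordings add sensor
placement variability, motion artifacts, ambient noise, subject-specific
baselines and non-stationary click statistics. Tests on this cohort
establish that the pipeline recovers a known planted effect, stays at chance
when there is none, and never leaks held-out information — not that the
clinical effect size or the published accuracy figures transfer. The
synthetic class separation is in fact much cleaner than clinical data
(near-perfect LOSO accuracy at the default click amplitude), so absolute
accuracies reported by the scripts are properties of the simulation, not of
the disease.

## Preprocessing

- **Band-pass.** Windowed-sinc (Hamming) linear-phase FIR, order
  4·fs/f_low rounded to even (401 taps at 25 kHz), applied by centered
  convolution so the group delay is exactly compensated and output length
  equals input length. Any design meeting the stop-band (≥40 dB at 50 Hz)
  and pass-band (±1 dB at 1 kHz) checks would be conforming.
- **Cycle segmentation.** Boundaries are local minima of the 5 Hz low-passed
  knee-angle trace (minimum separation half the expected period, 10%
  prominence, period re-estimated once from the first detection pass). The
  recording edges are accepted as boundaries when the nearest interior
  minimum lies about a full period away. A 5 Hz low-passed, block-averaged
  envelope of the audio is correlated with the angle trace and reported as a
  QC number; the IMU remains the sole boundary source. Indexing is 0-based,
  half-open [start, end).
- **Framing.** round(0.4 s · fs) samples per frame, non-overlapping,
  contiguous from the cycle start; a trailing remainder shorter than one
  frame is discarded (a nominal 4 s cycle yields 10 frames).

## Features

Ten base features per frame; spectral quantities use the Hann-windowed
one-sided magnitude spectrum, time-domain quantities the raw frame:
ZCR (sign changes/s), energy (Σx²), RMS, signal entropy (Shannon entropy,
bits, of the energy distribution over 32 subframes), spectral centroid and
spread (power-weighted mean/SD of frequency), spectral roll-off (85th power
percentile — a convention; nothing in the phenomenon fixes it), spectral
entropy (bits, of the normalized power spectrum), spectral flux (squared
difference of successive sum-normalized magnitude spectra; defined 0 for a
cycle's first frame), and spectral density (mean periodogram PSD over the
analysis band).

Per cycle each base feature is summarized across frames by mean, population
SD (n denominator), and CoV = SD/(|mean| + 1e-12). The resulting 30 columns
are a registry, not a constant: the clinical study used 49 features whose
full list is not public, and every downstream stage is dimension-agnostic,
so extending the registry changes nothing structurally.

Degenerate inputs: an all-zero frame yields all-zero features by convention
(never NaN); zero-variance columns are standardized with an ε = 1e-12 SD
guard and a warning, which maps constant columns to exactly zero.

## Classification and evaluation

The logistic model is fitted by minimizing the (optionally ridge-penalized)
Bernoulli negative log-likelihood with L-BFGS — a quasi-Newton MLE.
Convergence: gradient ∞-norm < 1e-6 or 500 iterations (warning + best
iterate otherwise). The default ridge of 1e-4 on the coefficients (never
the intercept) exists because the synthetic classes are often linearly
separable, where the unpenalized MLE diverges; ridge = 0 recovers the pure
MLE. The fit is cross-checked in the tests against an independent
implementation (scikit-learn at C = 1/ridge).

LOSO protocol per fold: remove all rows of one subject, standardize the
remainder on itself, fit, transform the held-out rows with the *training*
statistics, predict. Probabilities above 0.5 label a cycle JIA; the subject
score is the arithmetic mean of their cycle probabilities, with score > 0.5
labeling the subject JIA and a tie counting as healthy. Both the
mean-probability rule and the majority-of-cycle-labels rule are reported
(ties → healthy in both). ROC curves and trapezoid AUC are computed over
cycle probabilities.

A note on the null behavior: with zero planted effect, LOSO accuracy on a
class-balanced cohort sits systematically *below* 50% — removing a whole
subject tilts every training fold against the held-out subject's class (the
well-known LOSO anti-learning bias). On the study's own imbalanced 25/18
layout the tilt partially cancels and cycle accuracy stays within a few
points of chance; the chance-level tests therefore run on that layout.

## Importance and the accuracy grid

Ranking requires an already standardized matrix (checked, since coefficient
magnitudes are only comparable on standardized columns) and uses a single
fit on all labeled baseline rows; ties keep column order. The grid evaluates
top-k columns (k = 1..20 by default) against m = 1..max test cycles: one
LOSO pass per k, and per held-out subject up to `perm_cap` unique m-subsets
of its pooled rows (all four channels; exhaustive when C(n, m) ≤ cap,
rejection-sampled with a per-(subject, k, m) sub-seed otherwise), each
subset classified by the mean-probability rule. Subjects with fewer than m
rows contribute their full row set.

## Longitudinal scoring

Each paired subject's two visits are scored by a model trained on baseline
rows excluding that subject's own baseline (no identity leakage); an
`exclude="cohort"` option instead trains one model on all never-followed-up
subjects, matching the clinical protocol's description. The drop
delta = baseline − follow-up is tested with t = mean/(sd/√n) using the
sample (n−1) SD and the upper-tail Student-t probability at n−1 dof.
Zero-variance deltas with nonzero mean are flagged and reported as t = ±∞,
p ∈ {0, 1}.

## Problem sizes in tests and scripts

The test suite and the analysis scripts run cohorts at reduced audio rates
(2–4 kHz, click band scaled into the reduced Nyquist range) and the
acceptance script runs the full default cohort at 25 kHz; these sizes were
chosen so a complete run takes minutes on a single core while exercising
every code path at the study's subject/cycle/channel layout. The pipeline
itself is rate-agnostic.

## Known limitations

- No physical joint-acoustics model: click morphology, rates and amplitudes
  are phenomenological knobs.
- Heterogeneous sampling rates within a cohort, artifact rejection beyond
  the band-pass, streaming operation, and probability calibration are out
  of scope.
- The 49-feature clinical registry cannot be reproduced exactly; the
  30-column default registry is an explicit stand-in.
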