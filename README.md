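# jae — joint acoustic emission analysis for knee health scoring

Knees emit faint vibrations ("joint acoustic emissions", JAEs) when they
articulate. In juvenile idiopathic arthritis (JIA), synovial inflammation and
cartilage change add periodic, high-energy clicks to these emissions, while
healthy knees sound like broadband noise. This package implements a complete,
tested analysis pipeline that turns raw knee-vibration and knee-angle
recordings into a per-subject **joint health score**, for researchers working
on acoustic digital biomarkers of joint disease.

Because no patient recordings are publicly deposited, the package ships a
first-class synthetic cohort generator that reproduces the study design
(25 JIA / 18 healthy subjects, 10 attenuated follow-ups, four contact
accelerometers per subject, 10 flexion/extension cycles of ~4 s, a 50 Hz IMU
angle trace) so every stage is reproducible end to end from a seed.

## The method

1. **Preprocessing.** Each accelerometer channel is band-pass filtered with a
   linear-phase FIR (250 Hz–10 kHz analysis band; the upper edge adapts to
   the sampling rate), segmented into flexion/extension cycles at the local
   minima of the low-passed knee-angle trace, and divided into non-overlapping
   400 ms frames.
2. **Features.** Per frame: zero-crossing rate, energy, RMS, signal entropy,
   and the spectral centroid, spread, flux, roll-off, entropy and mean band
   PSD of the Hann-windowed spectrum. Per cycle, each base feature's
   mean/SD/CoV across frames forms one row of the matrix **X** — one row per
   (subject, channel, cycle).
3. **Scoring.** Logistic regression P(JIA | x) = σ(b₀ + βᵀx) is fitted by
   quasi-Newton maximum likelihood under leave-one-subject-out
   cross-validation, with the standardization statistics and the model
   refitted per fold on **X′** (all rows minus the held-out subject's
   **X**_subject). The subject's joint health score is the mean of their
   per-cycle probabilities; score > 0.5 classifies the subject as JIA (a tie
   is healthy). A majority-of-cycles rule is reported alongside.
4. **Importance & data efficiency.** Features are ranked by |βᵢ| from one fit
   on all standardized baseline rows; an accuracy grid then maps subject-level
   LOSO accuracy against the number of top-ranked features and the number of
   cycles available at test time (up to `perm_cap` unique cycle subsets per
   cell).
5. **Longitudinal tracking.** Follow-up sessions (never used for training)
   are scored against baseline-trained models; the per-subject score drop is
   tested with a one-tailed paired t-test at n − 1 degrees of freedom.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py      # cohort + per-class signal stats
python analysis/02_segment_and_extract.py  # feature matrix X
python analysis/03_loso_evaluation.py      # LOSO joint health scores
python analysis/04_feature_importance.py   # ranking + accuracy grid
python analysis/05_longitudinal_tracking.py
```

With the default seed this prints (abridged):

```
X: 2120 rows x 30 features
rows per session: 40.0 +/- 0.0
cycle accuracy    99.5%   (sens 99.6%, spec 99.4%, AUC 0.999)
subject accuracy 100.0%  (mean-probability rule)
top 5 features by |coefficient|:
  spectral_entropy_mean        53.295
  spectral_spread_mean         49.840
  ...
mean drop 0.985 +/- 0.016; t = 199.7, dof = 9, one-tailed p = 5.05e-18
```

Read: every cycle row is 30 features summarizing one movement cycle from one
accelerometer; LOSO classification separates the synthetic classes almost
perfectly (the synthetic click effect is cleaner than clinical data — see
`docs/methods.md`); spectral dispersion features dominate the ranking; and
after the simulated treatment attenuates the clicks five-fold, every
subject's score drops by ~1.0, a highly significant paired effect.

The same stages are available as a CLI (`jae simulate|segment|extract|
evaluate|importance|heatmap|longitudinal|run-all`) driven by a YAML config
whose committed defaults hold all protocol constants.

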