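# Methods

## Problem and model

The package detects heartbeats in carotid laser-Doppler-vibrometry (LDV)
signals. The LDV channel measures the vessel-wall vibrational velocity
(mm/s; hardware reporting volts is converted at 5 mm/s/V); a synchronous
ECG channel (500 Hz, as both channels) supplies the gold-standard beat
anchors. Classification operates on raw fixed-length LDV windows — there
is deliberately no feature extraction, so the models must cope with the
waveform variability directly.

## Window labeling

For each cardiac cycle, windows of `window_len` = 75 samples (150 ms)
start at the detected R peak and advance by `step` = 15 samples until the
window end exceeds the next R peak by more than `overrun` = 60 samples.
The 150 ms window is sized to capture the carotid pulse, which peaks
102 ± 15 ms after R with a 142 ± 19 ms full width at half maximum
(FWHM): the beat window therefore contains the systolic upstroke.

Decisions where the design was genuinely open:

- The grid **restarts at each R peak**, so the beat window is always
  grid-aligned; no nearest-grid snapping is needed.
- The stopping rule is *emit while window end ≤ next R + overrun*
  (windows may straddle the next R). The prose form of the rule admits an
  off-by-one, so the strict variant is exposed as
  `WindowingConfig(strict_stop=True)`; an independent brute-force
  enumerator in the tests pins the chosen inequality.
- With default geometry and resting RR intervals (~0.85 s) each cycle
  yields `floor((RR + overrun − window_len)/step) + 1` ≈ 30 windows, i.e.
  a no-beat:beat ratio near 30:1.
- **Undersampling is per subject**: each subject contributes equally many
  no-beat windows as it has beat windows, drawn uniformly without
  replacement, so balancing cannot shift the subject mix.

## QRS detection

R peaks come from a Pan–Tompkins detector: zero-phase Butterworth
band-pass 5–15 Hz, five-point derivative, squaring, centered 150 ms
moving-window integration, then adaptive signal/noise peak tracking with
dual thresholds, a 200 ms refractory period and a search-back pass
triggered at 1.66× the running RR average. Fiducials are refined to the
local raw-ECG maximum within ±50 ms. All thresholds are relative, so
detection is invariant to amplitude scaling. Constants are exposed as
keyword arguments; defaults follow the classic description.

## Classifiers

Four classifiers are trained on z-scored windows: RBF-kernel soft-margin
SVM, decision tree, random forest (class probabilities averaged over
trees) and KNN (Euclidean). Hyperparameters are grid-searched — SVM
γ ∈ {0.001, 0.01, 0.1} × C ∈ {1, 10, 100}; RF depth {3,4,5} ×
trees {50…500 step 50, 600}; DT depth {5,10,15,20}; KNN K ∈ {3,5,7,9} —
by stratified 5-fold inner cross-validation maximizing beat-class f1,
then refit on the whole training fold. Evaluation is leave-one-subject-out
throughout, so no subject leaks between training and test.

Choices worth noting:

- **Standardization.** Absolute LDV amplitudes depend on the optics and
  electronics, so windows are z-scored with training-fold statistics
  (disable with `scale=False` / `--no-scale`). This makes predictions
  invariant to affine rescaling of the raw signal and is the main place
  where the procedure is under-determined by its description.
- **Kernel parameterization.** The RBF kernel is exp(−γ‖·‖²) with a
  single tuned width γ (any separate scale constant is absorbed into γ).
- **Probabilities.** SVM decision values are mapped to probabilities by a
  Platt sigmoid fitted on inner folds
  (`CalibratedClassifierCV(..., ensemble=False)`); tree/forest/KNN emit
  their native class fractions. Hard labels are `probability > 0.5`; the
  strict inequality breaks ties toward no-beat (conservative detection;
  with the odd K grid, KNN cannot tie anyway).
- **Model selection degeneracy.** On nearly separable training sets many
  grid points tie at inner-CV f1 = 1.0 and the search falls back to the
  first-listed (smoothest) settings. This is inherent to selecting by a
  saturated metric; it is visible on very clean synthetic data and is one
  reason the synthetic defaults include noise.

## Evaluation

Per-class recall TP/(TP+FN), precision TP/(TP+FP) and their harmonic mean
f1 are computed for both classes; macro averages are unweighted two-class
means, appropriate for the ~30:1 imbalance of full-length signals.
Undefined precision (no predicted positives) is reported as 0 and
flagged; a class absent from the truth is excluded from the macro average
with a warning. ROC curves sweep the unique probabilities; AUC is the
trapezoidal area, equal to the Mann–Whitney pair-ordering statistic with
ties counted ½. Classifier comparisons across LOSO folds use a one-way
repeated-measures ANOVA (subjects as blocks, F = MS_treat/MS_err on
(k−1, (n−1)(k−1)) df, no sphericity correction — k is small); a constant
matrix returns the degenerate F = 0, p = 1.

## Full-length deployment and heart rate

The sweep classifies windows starting at 0, 15, 30, … samples using the
LDV channel only. A sweep window is gold-labeled *beat* iff its start
lies in [R, R + step) — the unique grid window "starting at" that beat;
this one-grid-cell tolerance is this package's definition, chosen to be
the strictest consistent with training. Beat picking keeps windows with
probability strictly above 0.9, chains candidates closer than a 250 ms
refractory interval and keeps each chain's most probable member
(earliest on ties). Instantaneous HR is 60/IBI stamped at the closing
detection; intervals outside 0.3–2.0 s are discarded as implausible; the
per-subject error is |mean HR(LDV) − mean HR(ECG)|, which is invariant to
the constant detection latency, so no latency correction is applied.

## Synthetic data

The generator emulates the features that drive window classification:

- **Rhythm.** RR intervals ~ truncated normal; mean 60/`hr_mean_bpm`, SD
  converted from `hr_sd_bpm` by the delta method, floored at 300 ms.
  Defaults 70 ± 3 bpm (resting supine young adults).
- **ECG.** Per beat: narrow biphasic QRS (R Gaussian σ 12 ms with small
  Q/S lobes) plus a low T hump peaking 280 ms after R (QT ≈ 400 ms at
  70 bpm). Morphology only needs to be detectable by Pan–Tompkins.
- **Carotid pulse.** One unimodal pulse per beat; peak lag ~
  N(102, 15²) ms, FWHM ~ N(142, 19²) ms (draws floored at 20 ms), peak
  amplitude `pulse_amp` = 1 mm/s (absolute scale is arbitrary — real
  amplitudes are hardware-dependent, which is why classifiers
  standardize). The default shape is gamma-like,
  (t/t_m)^a · exp(a(1 − t/t_m)) with a = 3, giving the steep systolic
  upstroke and slower decay of arterial pulses; a symmetric Gaussian
  is available (`pulse_shape="gaussian"`). A symmetric bump was tried
  first but makes ±30 ms-shifted windows nearly indistinguishable,
  which real pulses are not.
- **Jugular contribution.** A secondary pulse at the T-wave position with
  amplitude `jugular_amp_frac` = 0.20 of the primary. The fraction is
  calibrated so that the Fig-4-style mean-waveform measurement on default
  cohorts reproduces the published pulse statistics (~103 ms delay,
  ~157 ms width vs 142 ± 19 configured — the residual widening comes
  from delay jitter and the jugular shoulder); at 0.35 the jugular
  shoulder straddles the half-maximum level and corrupts the width
  measurement, which real recordings evidently do not.
- **Noise and drift.** White noise (SD 0.1, i.e. 10% of the pulse
  amplitude, on both channels in their own units) and sinusoidal
  respiratory drift (0.25 Hz, 0.1 mm/s).
- **Cohorts.** Per-subject multiplicative factors (1 + jitter·z, clipped
  to [0.5, 1.5], default jitter 0.1) on amplitude, delay, width and heart
  rate, drawn once per subject.

What the generator does **not** emulate — hence what passing tests do not
show about real data: motion/swallowing artifacts, beat-to-beat pulse
morphology changes, dicrotic notches, arrhythmias, low-SNR mispointing,
or 1/f sensor noise. Synthetic performance is an upper bound for
machinery correctness, not a claim about clinical accuracy.

## Problem sizes

Tests and the acceptance script use desk-scale experiments chosen to
exercise every pipeline stage: a 6-subject × 60 s cohort for LOSO and
full-length runs, 20 × 60 s for pulse statistics, and a single ~7 min
recording (>500 beats) for QRS recovery.

## Known limitations

- The full-length **macro-f1** under the one-grid-cell gold tolerance
  saturates near 0.70 on synthetic cohorts at any noise level: the
  classifier assigns probability > 0.5 to 2–3 windows adjacent to each
  beat (a 142 ms-wide pulse cannot be localized to one 30 ms cell from
  raw windows), so beat-class precision is bounded near ⅓ while recall,
  AUC (~0.96) and heart-rate error (<1 bpm typical) remain excellent.
  Relaxing the gold tolerance or sharpening the probability profile
  (e.g. selecting hyperparameters by localization rather than balanced
  f1) would raise it, at the cost of changing the measured quantity.
- The RR model is stationary (no respiratory sinus arrhythmia
  autocorrelation); heart-rate variability metrics should not be derived
  from it.
- Undersampling discards most no-beat windows; rare waveform variants
  may be underrepresented in training.
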