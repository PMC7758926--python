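# Methods

This note documents the detection pipeline, the synthetic data model, the
numerical conventions, and the design decisions that were genuinely open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem and pipeline

Postictal generalized EEG suppression (PGES) is defined by all scalp
channels staying below 10 µV after a seizure, once noise and artifacts are
discounted. Its *end* — the return of activity — lacks a crisp criterion
and is the quantity of interest here. The package frames end-of-PGES
detection as snippet classification:

1. **Montage and rate.** Recordings (13 electrodes of the 10-20 system,
   200–250 Hz) are reduced to the 10-channel longitudinal bipolar montage
   and Fourier-resampled to 200 Hz. Fourier (frequency-domain) resampling
   was chosen over polyphase filtering; both preserve in-band amplitude,
   and frequency resampling is the more literal match to how such archives
   are typically converted. The canonical channel order
   [FP1, F7, T7, P7, FP2, F8, T8, P8, Fz, Cz] (each bipolar channel named
   by its first electrode) fixes every downstream feature index.
2. **Snippets.** 10-s windows (2000 samples) cut at uniformly random
   sample-grid starts; a window is positive iff the annotated transition
   time lies in the *open* interval (start, start + 10 s). The open
   interval is a deterministic tie-break: a transition exactly on the
   boundary contributes no usable post-transition (or pre-transition)
   signal. Negative windows may fall anywhere else, including entirely
   inside the suppression or entirely after it. Equal per-class, per-patient
   counts are requested at dataset assembly; shortfalls warn rather than
   silently truncate. Windows may overlap; start times are recorded so
   callers can enforce non-overlap.
3. **Filtering.** Two 5th-order Butterworth bandpasses (prototype order 5,
   i.e. a 10-pole bandpass), applied forward–backward with odd-extension
   edge padding of 3× the filter length: 1–47 Hz for denoising and 3–8 Hz
   to isolate slow-wave activity, which often carries the transition out of
   suppression. Frequencies below 3 Hz are avoided in the slow-wave band
   because drift and movement artifacts concentrate there. Note that
   forward–backward filtering is zero-phase (a symmetric pulse keeps its
   center) but its edge transients are *not* time-symmetric under finite
   padding; with the 1 Hz band edge these transients decay over roughly
   2–3 s. Tests of steady-state response therefore measure away from the
   edges, and the time-reversal symmetry property is asserted on the window
   interior.
4. **Features.** 127 = C(10,2) + 7·10 + 12 features per snippet (general
   formula C(k,2) + 7k + 12 for k ≥ 2 channels); families and counts as in
   the README table. Conventions:
   * "Normalized" always means divided by the population variance (÷N) of
     the same filtered per-channel series the feature was computed from —
     in particular the low-frequency summaries use the 3–8 Hz variance, not
     the broadband one.
   * The least-variance channel (minimal full-snippet variance, ties to the
     lowest canonical index) serves as a proxy for the channel least
     contaminated by artifacts.
   * **Denominator guard:** any ratio or normalization whose denominator
     has magnitude below ε = 1e-12 (µV or µV²) is defined as 0, and a
     Pearson correlation involving a zero-variance channel is 0. Filtered
     EEG is zero-mean, so first-half means can be arbitrarily small; the
     classifier contract requires finite, deterministic input. This is the
     single largest interpretive convention in the package. Mean ratios use
     signed means (no absolute value); the guard absorbs the instability.
   * Temporal-ratio halves split at N/2: first half [0, N/2), last half
     [N/2, N). Sliding-difference windows (50 samples, step 10) are fully
     contained — starts 0, 10, …, N−50 — so the two half-window sums always
     have 25 samples each.
   * Channel-subset feature vectors are *recomputed* for the subset, never
     sliced from the 127-vector: correlation pairs, the least-variance
     channel and every "sum across channels" summary are subset-dependent
     by definition.
5. **Classifier.** Random forest, 501 trees (an ensemble size selected by
   cross-validation in the original development of this method; exposed as
   `n_trees` but the selection is not re-run), bootstrap sampling,
   sqrt(n_features) candidate features per split, all other tree
   hyperparameters at library defaults. The snippet score is the fraction
   of trees voting positive; the default operating threshold for
   precision/recall/F1 is 0.5. Prediction refuses feature tables whose
   column names or order differ from those seen at fit time.
6. **Evaluation.** ROC built by sweeping all distinct score thresholds;
   the trapezoidal area equals the Mann–Whitney statistic with half-weight
   ties (verified against an all-pairs oracle). Evaluation is always
   patient-independent: no patient contributes to both sides of a split.
   Experiment conditions refit the model with a per-condition seed derived
   as CRC32(condition label) XOR master seed, so conditions are independent
   yet individually reproducible.

## Synthetic data model

The generator (`pgeskit.synthdata`) emulates the *data model* of annotated
peri-ictal recordings, not seizure physiology:

* **Durations** drawn from a normal with mean 46.90 s, SD 33.04 s,
  truncated at ≥ 20 s; the annotated transition time is uniform in
  [0.25, 0.75] of the duration.
* **Suppression segment:** independent per-channel 1–47 Hz noise scaled by
  `suppression_amp_uv`/3 (≈3σ excursions reach the nominal amplitude;
  default 5 µV).
* **Activity segment:** begins ramping at (transition − ramp) and reaches
  full amplitude (`activity_amp_uv`, default 40 µV) at the annotated time,
  default ramp 0.5 s. Its waveform is slow-wave (a 4–6 Hz oscillation plus
  3–8 Hz noise), broadband 1–47 Hz noise, or a mix (default), split into a
  shared component and per-channel components with weights √c and √(1−c)
  for coherence c (default 0.6) — c = 1 with zero noise gives identical
  channels, hence pairwise correlation exactly 1.
* **Noise and artifacts:** additive white Gaussian sensor noise
  (`noise_sd_uv`, default 2 µV) everywhere, plus Poisson-timed (default
  0.1/s) single-channel artifact bursts of 0.1–0.4 s: Gaussian-windowed
  35–95 Hz band noise, mimicking scalp EMG/movement transients, whose power
  lies mostly above the 1–47 Hz analysis band (scalp EMG concentrates above
  ~30 Hz).
* **Suppression guarantee:** the composite pre-transition segment is
  hard-capped at 9.5 µV per channel. Noise and artifact draws are
  unbounded, so without the cap no sample-level bound could hold; clipping
  is how the generator *enforces* the clinical < 10 µV definition rather
  than merely approximating it. Consequences worth knowing: with large
  `noise_sd_uv` the cap itself creates a pre/post variance contrast that
  makes detection easy regardless of filtering, so "hard" study conditions
  should be built from weak activity contrast and artifact bursts, not from
  extreme white noise.
* **Raw-electrode mode** emits 13 referential electrode series constructed
  by back-substitution along the three bipolar chains (O1, O2, Pz set to
  zero), so applying the default montage reproduces the montaged recording
  exactly — this exercises the montage path end to end.

What passing tests on this generator do **not** show: performance on real
postictal EEG. The generator has stationary segments, a single clean
transition, Gaussian noise, and artifacts of one stereotyped kind; real
recordings have nonstationary rhythms, gradual or fragmented recoveries,
multiple near-suppressions, and richer artifact families. Results on the
synthetic data validate the machinery and directional behavior
(more channels help; filtering helps under out-of-band contamination;
no signal ⇒ chance AUC), not clinical accuracy.

## Study configurations used by the tests and the acceptance script

* **Easy configuration** (detection sanity): 20 patients, suppression 5 µV,
  activity 40 µV, noise 2 µV, default artifacts, 15 snippets per class per
  patient, 70/30 patient split — sized so the whole run takes tens of
  seconds on one CPU.
* **Artifact-contaminated configuration** (ablations): 30 patients,
  activity 12 µV, noise 1 µV, bursts at 2/s with 50 µV amplitude, 50/50
  split. Chosen off the AUC ceiling so that filter and channel-count
  effects are measurable; with 40 µV activity both arms of every ablation
  saturate near AUC 1 and differences vanish.
* **Null configuration** (chance-level check): activity amplitude equal to
  suppression amplitude, coherence 0, *broadband* activity band and no
  artifacts — the two sides of the transition are then statistically
  identical, which is what makes it a genuine null; any band change at the
  annotation would itself be signal.

## Known limitations

* The ε-guard convention for degenerate denominators is this package's
  choice; other implementations may return NaN or drop features, which
  changes classifier input on near-flat channels.
* The EDF writer produces a minimal single-data-record, 16-bit file
  (round-trip error bounded by the physical-range quantization step). It
  writes no clinical metadata and is intended for data exchange of
  synthetic/test recordings, not archival EEG.
* Only the longitudinal bipolar montage is supported; onset detection,
  artifact-specific denoising (ICA, EOG/EMG regression) and time-distance
  evaluation metrics are out of scope.
* AUC comparisons between nearby conditions on modest synthetic cohorts
  carry sampling noise of roughly ±0.01–0.02; single-seed differences
  smaller than that should not be over-read.
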