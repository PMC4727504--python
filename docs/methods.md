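# Methods

## Signal path

Input EEG is referential, from the nine-electrode neonatal 10:20 montage
(F4, F3, T4, T3, C4, C3, CZ, O2, O1), sampled at 250 or 256 Hz. Features
are computed per recorded channel; no bipolar re-derivation is applied.
The recording-bandwidth 0.5 Hz high-pass is treated as a property of the
acquisition, not reapplied in software: sub-delta drift ends up in the
0–2 Hz band power and the detector learns its (ir)relevance from data.

Preprocessing applies a zero-phase (forward–backward) order-8 Butterworth
low-pass at 12.8 Hz and decimates to 32 Hz — by stride 8 from 256 Hz, or by
16/125 polyphase rational resampling from 250 Hz. The squared magnitude
response keeps the < 10 Hz pass-band within 2 % and attenuates ≥ 15 Hz by
more than 20 dB. Zero-phase filtering preserves inter-channel timing.
Epochs are 8 s (256 samples) with a 4 s hop; epoch *k* starts at 4*k*
seconds and the last epoch must fit inside the record.

## Features

All 55 features are computed per channel-epoch; the fixed order is
`neoseiz.features.FEATURE_NAMES`. Choices the feature names alone do not
pin down:

* **Spectra** are one-sided periodograms of the Hamming-windowed,
  mean-removed epoch (frequency resolution 0.125 Hz). Total power
  integrates the 0–12 Hz band; SEF*p* is the lowest frequency at which the
  cumulative 0–12 Hz power reaches *p* %. Sub-bands are the eleven
  overlapping 2 Hz bands 0–2, 1–3, …, 10–12 Hz, half-open in frequency.
* **Wavelet energy** uses the Daubechies-4 DWT. At 32 Hz a level-7
  decomposition yields eight coefficient arrays [cA7, cD7, …, cD1], whose
  5th entry, cD4, spans 1–2 Hz — the band a rhythmic neonatal discharge
  occupies. The feature is the energy (sum of squares) of cD4, computed
  from a level-4 decomposition, which yields the identical array.
* **AR modelling error** (orders 1–9) is the Yule–Walker prediction-error
  variance from biased autocovariances of the demeaned epoch, via a
  Levinson–Durbin recursion batched across epochs. The recursion makes the
  error non-increasing in order, a property the test suite asserts on every
  epoch.
* **Shannon entropy** uses 10 equal-width amplitude bins spanning the
  epoch's range (bin index ⌊(x−min)/width⌋, top edge closed), making it
  scale-invariant. **SVD entropy** and **Fisher information** are computed
  on the singular values of the (m = 10, lag 1) delay-embedding matrix,
  normalised to unit sum. **Spectral entropy** is the Shannon entropy of
  the 0–12 Hz periodogram normalised to unit sum, divided by log of the bin
  count, hence in [0, 1].
* **Degenerate epochs** (constant within a channel): ratio-based features
  (mobility, complexity, skewness, kurtosis, entropies, normalised band
  powers) are set to 0 and the channel-epoch is flagged, never fatal.

## Classifier

One model serves every channel: epochs are pooled across channels and
records, standardised (per-feature mean/scale from training data), and fed
to an RBF-kernel SVM with balanced class weights. C is chosen from {1, 10}
(γ = "scale") by 3-fold cross-validated AUC; a balanced subsample caps the
SVM problem at 5 000 rows to keep the quadratic program tractable. The
margin is mapped to probability by sigmoid (Platt) calibration fitted with
the same folds — a monotone map, so ranking by margin is preserved. An
epoch is labelled seizure-positive for training when ≥ 50 % of its 8 s
overlaps a reference event. A feature-name checksum stored in the model
guards against feature-layout drift at prediction time.

Per-epoch probabilities become a 1 Hz trace by averaging over the (up to
two) epochs covering each second; trailing seconds covered by no epoch take
the nearest epoch's value. Channels are fused by the per-second maximum:
the electrographic definition requires only one channel, so any channel
alone must be able to trigger. The fused trace is smoothed by a 15 s
centred moving average (configurable, default on) before thresholding.
Detection events are maximal runs ≥ θ, after bridging dips shorter than 2 s
and discarding runs shorter than 10 s (mirroring the electrographic
minimum); both limits are configurable.

A structural consequence worth knowing: detections at a higher threshold
are always nested inside detections at a lower threshold, so detected
seconds and SDR are non-increasing in threshold — but FD/h need not be,
because lowering the threshold can merge a false detection into an event
that also touches a reference seizure. The test suite asserts the true
invariants and leaves the FD/h curve descriptive.

## Agreement metrics

Intervals are half-open `[onset, offset)` seconds from record start, which
makes the 1 Hz binarisation exact: second *t* is seizure iff `[t, t+1)`
intersects an event. Undefined quantities (sensitivity on a seizure-free
record, SDR with no reference events, κ when chance agreement is 1) are
reported as `None`, never as a placeholder number. Prevalence and bias
indices follow the Byrt–Bishop–Carlin convention (|TP−TN|/N, |FP−FN|/N).
Any-overlap requires at least one shared second on the analysis grid. The
AUC is the rank statistic over per-second probabilities; the nine-threshold
(sensitivity, specificity) curve, anchored at (0, 100) and (100, 0), is
reported alongside with its trapezoidal area. Seizure period is defined as
first onset to last offset; onset is postnatal age at the first event. The
ICC is two-way, absolute-agreement, average-measures — ICC(A,k), computed
via pingouin — because the two raters (expert, SDA) are fixed and the
question is agreement, not consistency; pairs where either rater is
undefined (no detections) are dropped and at least three pairs are
required. The AED concurrency window is the closed interval [t − 90 min,
t]; boundary-touching seizures count as concurrent (the conservative
reading of an arbitrary cut-off). Cohort summaries use median and IQR.

## Synthetic cohort

The simulator produces records carrying the statistical signatures the
detector relies on; it does not claim physiological realism.

* **Background**: spatially correlated (ρ = 0.5) 1/f^1.5 noise at ~30 µV
  RMS per channel. The 0.5–3 Hz delta band, augmented by a narrowband
  rhythmic component (0.3× the intrinsic delta RMS), is amplitude-modulated
  with the sleep-cycle period (default 3 000 s, depth 0.8) with unit-mean
  modulation, so the time-averaged spectrum keeps its power law while delta
  power waxes and wanes as in intermediate/quiet sleep.
* **Seizures**: a harmonic spike-wave carrier (relative harmonic
  amplitudes 1 : 0.4 : 0.2, two zero crossings per cycle) whose
  instantaneous frequency falls linearly from f_start (uniform 1.5–3.5 Hz)
  to f_end (0.4–0.7 × f_start), under a ramp–plateau–ramp envelope (15 %
  ramps, zero at both ends), applied focally with exponentially decaying
  channel weights at 2–4 × background RMS. Durations are log-normal with
  median 115 s and σ = 0.7 — matching the reported medians and quartile
  spread of seizure duration in monitored term-neonate cohorts — truncated
  at the 10 s electrographic minimum. Counts are Poisson (mean 4 per
  record, minimum 1); placement is non-overlapping with ≥ 30 s gaps.
* **Artefacts** (each logged as ground truth, placed clear of seizures so
  training labels stay unambiguous): respiration — a rhythmic wave
  phase-locked to the simulated ~0.65 Hz respiration trace on three
  channels; pulse — Gaussian spikes aligned to simulated ECG R-peaks
  (~2.3 Hz with 4 % RR jitter) on one channel; sweat — high-amplitude
  (250 µV) semi-rhythmic waves low-passed below 0.5 Hz on four channels.

What passing tests on this cohort do **not** show: robustness to real
electrode artefact diversity, inter-subject background variability,
HIE-grade-specific backgrounds, dysrhythmic or low-amplitude seizure
morphologies, or montage/reference effects. The synthetic seizures are
deliberately learnable (rhythmic, high-amplitude); real-world detection
rates will be lower, particularly for short or subtle seizures.

## Problem sizes and numerical choices

The end-to-end study trains on six 1 h synthetic seizure records and
evaluates on four held-out 1 h records (seed-derived record streams via
`numpy.random.SeedSequence`), a size at which the SVM fit and the full
detection pass complete in about a minute; unit tests use shorter records
(60–900 s) for the same pipelines. All randomness flows from a single
seed; reruns are byte-identical. EDF writing quantises to 16-bit with
per-channel scaling (relative error ~4 × 10⁻⁵); EDF reading goes through
mne, with a direct header check that all EEG channels share one sampling
rate (mixed-rate files are rejected rather than silently resampled).
Overlapping annotation intervals are merged on load — the binary agreement
model is insensitive to sub-event structure. Zero crossings count strict
sign changes with zeros attached to the preceding sign. Filters are
applied with `sosfiltfilt` (zero phase); repeated preprocessing of an
already-32 Hz record changes RMS by < 0.1 %.
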