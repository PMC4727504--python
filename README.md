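# neoseiz

Automated seizure detection for term-neonate EEG, with the full validation
framework used to judge such detectors, and a seeded synthetic EEG cohort
simulator so the whole pipeline can be trained and tested end-to-end without
clinical data.

Electrographic seizures in newborns — sudden, evolving, repetitive
stereotyped discharges lasting ≥ 10 s on at least one EEG channel — are
mostly missed at the cotside without continuous EEG review, and few
clinicians can read neonatal EEG. A seizure detection algorithm (SDA) scores
the multi-channel EEG continuously and raises a per-second *probability of
seizure*, which a clinician-adjustable threshold turns into detections.
This package is for signal-processing and clinical-neurophysiology
researchers who want a transparent, fully tested reference implementation of
that pipeline and of the agreement metrics used to validate one.

## The detector

EEG from the nine-electrode neonatal 10:20 montage (F4, F3, T4, T3, C4, C3,
CZ, O2, O1; 250 or 256 Hz) is down-sampled to 32 Hz behind a zero-phase
12.8 Hz anti-aliasing filter and cut into 8 s epochs with 50 % overlap.
Each channel-epoch is summarised by **55 features**: 28 frequency-domain
(total power 0–12 Hz, peak frequency, spectral edge frequencies SEF80/90/95,
eleven overlapping 2 Hz sub-band powers raw and normalised, Daubechies-4
wavelet energy in the 1–2 Hz detail band), 23 time-domain (curve length,
extrema count, RMS, Hjorth activity/mobility/complexity, zero crossings of
the epoch and its first two differences, Yule–Walker AR model error for
orders 1–9, skewness, kurtosis, Teager nonlinear energy, variances of Δ and
ΔΔ) and 4 information-theoretic (Shannon, SVD and spectral entropy, Fisher
information).

An RBF-kernel support vector machine, trained on pooled labelled epochs and
calibrated with a monotone logistic (Platt) map, converts each epoch into a
seizure probability. Per-channel probabilities are laid on a 1 Hz grid
(mean over the epochs covering each second), fused by the per-second
maximum across channels, smoothed (15 s moving average), and thresholded at
one of nine sensitivities θ ∈ {0.1, …, 0.9}: runs ≥ θ lasting ≥ 10 s (after
bridging < 2 s dips) become detected seizure events.

## The validation framework

Expert and SDA annotations of the same record are compared on a 1 Hz binary
grid:

* **time-based ("overlap integral")** — per-second TP/TN/FP/FN;
  sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); Cohen's
  κ = (p_o − p_e)/(1 − p_e) with prevalence index |TP−TN|/N and bias index
  |FP−FN|/N; AUC of the probability trace;
* **event-based ("any overlap")** — seizure detection rate (SDR, % of
  expert events touched by ≥ 1 detection) and false detections per hour
  (FD/h), plus the detection rate by seizure duration;
* **clinical summaries** — per-baby seizure burden, number, mean/median
  duration, onset and period, compared between raters by the two-way
  absolute-agreement average-measures ICC; baby-level seizure/non-seizure
  identification; and whether detections would have supported antiepileptic
  drug (AED) decisions in the 90 min before each dose.

## Worked example

The agreement metrics on a reconstructed hour-long annotation pair
(expert events 0–200 s, 1000–1100 s, 2000–2100 s; SDA events 0–600 s,
1000–1300 s, 3000–3200 s):

```python
from neoseiz import (SeizureEvent, SeizureEventList, binarize,
                     temporal_agreement, event_agreement, kappa_indices)

expert = SeizureEventList([SeizureEvent(0, 200), SeizureEvent(1000, 1100),
                           SeizureEvent(2000, 2100)], record_duration=3600)
sda = SeizureEventList([SeizureEvent(0, 600), SeizureEvent(1000, 1300),
                        SeizureEvent(3000, 3200)], record_duration=3600)

counts, tm = temporal_agreement(binarize(expert), binarize(sda))
kap = kappa_indices(counts)
em = event_agreement(expert, sda)
print(f"TP={counts.tp} TN={counts.tn} FP={counts.fp} FN={counts.fn}")
print(f"sensitivity={tm.sensitivity:.1f}%  specificity={tm.specificity:.1f}%")
print(f"kappa={kap.kappa:.3f}  prevalence={kap.prevalence_index:.3f}  "
      f"bias={kap.bias_index:.3f}")
print(f"SDR={em.sdr:.1f}%  FD/h={em.fd_per_h:.1f}")
```

prints

```
TP=300 TN=2400 FP=800 FN=100
sensitivity=75.0%  specificity=75.0%
kappa=0.283  prevalence=0.583  bias=0.194
SDR=66.7%  FD/h=1.0
```

Of the 400 expert seizure-seconds the SDA recovered 300 (sensitivity 75 %),
and of the 3200 seizure-free seconds it left 2400 unmarked (specificity
75 %). Two of the three expert events were touched by a detection (SDR
66.7 %) and one detection touched no expert event (1 false detection in the
one-hour record). The high prevalence index reflects the rarity of seizure
seconds, which is why κ is reported alongside raw agreement.

## The command-line pipeline

```bash
neoseiz simulate --out cohort --n-seizure 6 --n-nonseizure 4 --seed 7
neoseiz train    --data cohort --model sda.pkl --records sz00,...,sz05 --seed 1
neoseiz detect   --model sda.pkl --data cohort --out detections --threshold 0.5
neoseiz evaluate --data cohort --detections detections --out report
```

`simulate` writes EDF recordings, expert-style annotation text files
(`onset<TAB>offset` seconds) and YAML sidecars (postnatal age, AED times);
`evaluate` writes a JSON/CSV/text report with the per-threshold agreement
grid, AUC, duration profile, ICC table, baby classification and AED
support. Every output embeds the seed and a configuration hash; pinned
configurations reproduce byte-identical outputs.

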