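# Methods

## The measurement model

A subject's elbow flexion–extension movement is observed through three
channels sampled at 2000 Hz: biceps brachii sEMG, triceps brachii sEMG and
the elbow angle (degrees; the package fixes 0° = full extension, ≈140° =
full flexion, so repetition boundaries are angle *maxima*). The acquisition
protocol per subject is a 10 s rest recording, three 5 s maximum voluntary
contraction (MVC) trials per muscle, and one movement trial of 15
repetitions at a comfortable pace (default 2.0 s per cycle, jittered ±20 %).

## Synthetic-data generator

Real recordings of this protocol are not publicly available, so the
generator is a first-class component. sEMG is modeled as
amplitude-modulated band-limited noise: a unit-RMS Gaussian carrier filtered
to 20–450 Hz is multiplied by an *activation envelope* a(t) ∈ [0, 1] (the
fraction of MVC drive) and a per-subject gain, then contaminated with a
60 Hz sinusoid (−10 dB relative to the full-activation carrier RMS), a
low-pass-filtered baseline drift (<2 Hz, 10 % relative amplitude) and white
noise (−20 dB). MVC trials use a(t) ≡ 1 with short raised-cosine ramps;
rest uses a(t) ≡ 0.02.

The four tone classes differ only in how a(t) depends on the cycle phase p
(flexion → extension → flexion) and angular speed |ω|:

| class     | envelope |
|-----------|----------|
| normal    | reciprocal: agonist half-sine lobe (peak 0.55) + 0.05 baseline |
| spastic   | normal + burst in the *lengthening* muscle, gain ∝ min(|ω|/150° s⁻¹, 2)·0.45 |
| rigid     | constant co-contraction (biceps 0.50, triceps 0.45), independent of ω |
| hypotonic | normal × 0.35 (the factor is constrained < 0.5) |

These amplitudes are free parameters of the generator, not estimates of any
clinical cohort; they were chosen once so that each class differs in
quantities the pipeline actually measures (amplitude → MAV/RMS, burstiness
→ WL/STD, co-contraction → cross-channel pattern). Per-subject variation:
a lognormal gain (σ = 0.3) on all signals — removed by MVC normalization,
which is the reason that step exists — and lognormal jitter (σ = 0.1) on the
envelope amplitudes. Consequences for interpretation: passing tests show
the *pipeline* recovers class structure that is present by construction;
they say nothing about discriminability in human data, where class overlap,
electrode placement variability, fatigue and co-morbidities are all absent
from this model. Motor-unit-level physiology (firing statistics, conduction
velocity) is deliberately not modeled.

## Preprocessing

Order: band-pass/notch → EMD → MVC normalization.

* **Filtering.** 4th-order Butterworth 20–500 Hz plus an IIR notch at 60 Hz
  (quality 30), both applied forward–backward (zero phase; the pipeline is
  offline so causality is not needed). At 2000 Hz sampling the 500 Hz edge
  is feasible; the implementation nudges an edge at/above Nyquist down to
  0.999·Nyquist rather than failing.
* **EMD.** Classical sifting: cubic-spline envelopes through local extrema
  (end effects handled by mirroring the two outermost extrema), mean-envelope
  subtraction, Cauchy-type stopping criterion (normalized squared change
  < 0.2, at most 12 siftings per mode, at most 10 modes). The denoised
  signal is the sum of IMFs whose power-weighted mean frequency lies inside
  the analysis band; the residual trend is always discarded. Because
  sifting yields modes of roughly halving frequency, extraction stops early
  once a mode falls below the band's lower edge — later modes would be
  discarded anyway. Constant input yields no IMFs and returns zeros with a
  warning. Which modes to drop is a design choice; the in-band-mean-frequency
  rule is one concrete, configurable reading of "interference removal".
* **MVC normalization.** The denominator is the maximum over MVC trials of
  the peak 100 ms moving-window RMS, computed per muscle on trials filtered
  with the same spec (no EMD on MVC trials — the reference is a smooth
  amplitude statistic, not a waveform). The statistic (peak vs mean, window
  length) is configurable; peak-of-100-ms-RMS is standard practice.
  Normalized signals are unitless fractions of MVC, making the amplitude
  features gain-invariant (verified to <1 % end to end).

## Segmentation

The angle trace is smoothed with a zero-phase 2 Hz low-pass; local maxima
with prominence ≥ 50 % of the trace range — including the end points, which
is why a 15-cycle trace yields 16 marks — delimit repetitions. Windows are
half-open sample-index intervals `[m_k, m_{k+1})` (0-based; the boundary
sample belongs to the later window), so windows of one muscle partition the
signal between the first and last mark. Windows shorter than 64 samples are
rejected with a logged warning: the N−2-term features degenerate on tiny
windows. Whether any repetitions should be discarded on quality grounds is
left to the caller; by default all detected repetitions are kept.

## Features

Eleven descriptors per muscle and window, computed exactly as defined in
the package (`tonus.features`), with these fixed conventions:

* STD uses the population (1/N) divisor.
* ZC counts strict sign changes with sgn(0) = +1 and no amplitude threshold.
* SSC carries a 1/N prefactor (so it is a *rate*, not a count).
* LD = log((1/N)Σx² + 1), natural log. Note this differs from the
  conventional log-detector exp(mean log |x|); the simpler form is kept
  deliberately as the package's definition.
* MMAV averages the MAVs of M = 4 equal contiguous sub-windows
  (configurable; M = 1 recovers MAV).
* The periodogram is one-sided in mean-square (power) units — an on-grid
  amplitude-A tone carries total power A²/2 — and the three spectral
  features are computed on the 20–500 Hz restriction: PSD is the total
  in-band power, MNF the power-weighted mean frequency, MDF the half-power
  frequency with linear interpolation between bins.

All time-domain features are verified against naive loop implementations at
1e−12 relative tolerance.

## Classification protocol

* **Split.** Stratified 80:20 at the *sample* (window) level by default:
  per class, round(0.8·n) rows to train. This treats the 585 windows as
  i.i.d., which leaks subject identity across the split — windows of one
  subject are correlated. The faithful-to-protocol sample split is kept as
  the default; `grouping="subject"` assigns whole subjects per class to one
  side and is the defensible choice when generalization to unseen subjects
  is the question. The two options give very different numbers on data with
  strong subject effects; neither is silently substituted for the other.
* **Tuning.** Grid search per model family maximizing mean 10-fold
  stratified CV accuracy *within the training portion* (nested-within-train
  reading of "split + 10-fold CV"); ties resolve to the first grid entry.
  Default grids: KNN k ∈ {1,3,…,15} × {uniform, distance}; SVM (RBF)
  C ∈ {0.1,1,10,100} × γ ∈ {scale, 0.01, 0.1, 1}; RF 200/500 trees ×
  depth {∞,10} × features {√p, p/2}; GBM rate {0.05,0.1} × depth {2,3} ×
  100 trees. KNN and SVM see z-scored features (scaler fit on train only);
  tree ensembles consume raw features.
* **Metrics.** Macro-averaged accuracy/precision/recall/F1 over the four
  classes (classes are near-balanced so macro vs weighted is minor, but
  macro is fixed); F1 is the per-class harmonic mean before averaging.
  Confusion matrices are row percentages (rows = true class, sum to 100).
* **Importance.** Permutation importance on the held-out set (the method is
  model-agnostic and measures what the *fitted* model uses), mean accuracy
  drop over 20 shuffles, floored at 0 and normalized to 100 %. Aggregations:
  per feature (biceps + triceps columns summed) and per muscle. A model
  whose accuracy no single column can change gets a uniform attribution
  with a warning.

## Determinism and problem sizes

Every random draw descends from a single seed via spawned `SeedSequence`s:
the same configuration reproduces byte-identical cohorts, splits and
reports. The test suite runs the full default study (39 subjects ×
15 repetitions → 585 × 23) once end-to-end — about 1.5 minutes on one CPU,
EMD being the dominant cost — and uses a tiny fixture (2 subjects per
class × 3 repetitions, 24 rows, < 30 s) everywhere else. The multi-seed
class-recovery check trains the full four-model protocol on the first seed
and the cheapest strong family (KNN) on the remaining seeds as a lower
bound on the best model's accuracy.

## Known limitations

* The generator's class envelopes are stylized; accuracy on synthetic
  cohorts is a property of the generator/pipeline pair, not a clinical claim.
* EMD sifting uses a fixed stopping rule; no ensemble (EEMD) variant.
* The elbow-angle convention (maxima = full flexion) must hold for the
  segmentation to be meaningful on external data; traces using the opposite
  convention must be inverted by the caller.
* Spectral features assume the 2000 Hz sampling keeps the 20–500 Hz band
  well inside Nyquist; other rates are supported but unvalidated.
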