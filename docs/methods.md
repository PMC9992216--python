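# Methods

## The question the package addresses

Myoelectric pattern-recognition (EMG-PR) prosthesis control trains a
classifier on windows of surface EMG recorded while a user holds each
gesture for some signal-recording duration (SRD). The SRD is a protocol
choice with competing pressures: short recordings give little training data;
long sustained holds induce fatigue, which changes the amplitude and
spectrum of the signal, so windows recorded late in a long hold are drawn
from a different distribution than the early windows a deployed system
mostly sees. This package implements a complete, reproducible pipeline for
quantifying that trade-off: synthetic multichannel EMG in, per-SRD decoding
scores (classification accuracy, macro Matthews correlation, Friedman
comparisons) out, under Within-SRD and Between-SRD train/test scenarios.

Absolute accuracies on real recordings depend on hardware, subjects and
unstated classifier settings and are not a target; the object of interest is
the qualitative dependence of generalization on SRD.

## Synthetic EMG model

Each recording is an 8-channel, 20 s block sampled at 4000 Hz (1000 Hz in
the quick profile), built as:

```
x_c(t) = g_c * s_c * r_c * carrier_c(t) * env(t) * force(t) * drift(t)
         + cocontraction_c(t) + noise_c(t)
```

* **Carrier** — white Gaussian noise band-passed to 20–450 Hz (4th-order
  Butterworth, zero-phase) and normalized to unit RMS per channel: the
  standard interference-pattern surrogate for the superposition of many
  motor-unit action potentials.
* **Spatial gains `g_c`** — each single finger (T, I, M, R, L) projects a
  Gaussian activation bump across the 8-electrode ring; a combined gesture
  sums the bumps of its component fingers (scaled by `1/sqrt(#fingers)`),
  with a small per-class jitter. Gestures sharing fingers are therefore
  close in feature space, which is what makes the 15-class problem hard in
  a structured, plausible way.
* **Subject and trial perturbations `s_c`, `r_c`** — log-normal per-channel
  gain factors (sigma 0.10 and 0.05): electrode placement and day-to-day
  variability.
* **Force fluctuation `force(t)`** — exp(0.35 · z(t)) with z white noise
  low-passed at 0.8 Hz and unit-normalized: voluntary contraction force is
  not constant over a 20 s hold, and this slow wandering is the dominant
  source of within-recording feature spread.
* **Fatigue drift** (`drift_strength` d, default 2, switchable off) with
  time fraction u = t/T:
  - amplitude growth `1 + 0.5·d·u²` (doubling by the end of the hold),
  - spectral compression: a blockwise first-order low-pass whose cutoff
    falls as `450/(1 + d·u²)` Hz (state carried across blocks),
  - co-contraction: a class-independent broad activation component with
    amplitude `0.5·d·u²` relative to the mean channel gain, blurring the
    class-discriminative spatial pattern late in the hold.
  The quadratic time course concentrates the drift in the final quarter of
  the hold, reflecting progressive fatigue onset during sustained
  contraction. All three components scale with one knob and vanish at d=0.
* **Noise** — Gaussian noise passed through the same 20–450 Hz band-pass
  (the acquisition chain band-limits everything it records), scaled to an
  in-band SNR of −3 dB against the recording-mean clean RMS. Channels with
  near-zero gesture gain carry the same noise floor, so "inactive channel"
  patterns are informative, as in real montages.

Defaults were calibrated once so the pipeline operates in a mid-accuracy
regime (Between-SRD CA roughly 45–60 % for 15 classes) where SRD effects
are visible; at high SNR without force fluctuation the synthetic problem is
nearly perfectly separable and every protocol comparison saturates.

Every recording's random stream derives from
`SeedSequence([tag, master_seed, subject, class, trial])`, so any single
recording is reproducible in isolation and datasets are bit-identical
across runs.

**What the generator does not emulate:** motor-unit discharge structure,
electrode shift, limb-position and contraction-force *level* confounds,
rest periods, inter-channel crosstalk correlation, and any amplitude
calibration to real hardware. Passing tests therefore demonstrate that the
pipeline recovers the qualitative SRD trade-off under a controlled fatigue
mechanism — not that real recordings would yield the same numbers.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass (20–450 Hz) plus a 2nd-order IIR
notch (default 50 Hz, Q = 30; configurable to 60 Hz). Zero-phase
application avoids phase-shifting window boundaries. A 4th-order band-pass
is the field's standard choice; its roll-off is gentle (a 500 Hz tone
retains ~7 % power), which the tests encode as measured.

SRD truncation takes the *prefix* (first L seconds) of the filtered
recording — shorter SRD groups are nested leading portions of the hold — 
with an optional offset for random crops. Windowing happens after
truncation (a window never spans the truncation boundary): 150 ms windows,
100 ms increments, trailing samples dropped, giving
`floor((N − W)/S) + 1` windows per channel (9/49/99/149/199 for
1/5/10/15/20 s at 4000 Hz).

## Features

Three per-window, per-channel feature sets, concatenated channel-major into
a windows × (8·d) matrix:

* **TD4** (d=4): MAV, WL, ZC, SSC. ZC counts sign changes with
  `|x_n − x_{n+1}| ≥ 0.01`; SSC counts interior samples with
  `(x_n − x_{n−1})(x_n − x_{n+1}) ≥ 0.01`.
* **NTDF** (d=6): SIS (Σx²), normRSD1/normRSD2 (RMS of first/second
  differences normalized by window length k), normLogDet (geometric mean of
  |x| divided by k — a constant monotone transform at fixed window length),
  mMSR (mean √|x|), mASM (mean of |x|^e(n) with e = 0.50 for
  0.25k ≤ n ≤ 0.75k, else 0.75, 1-based n).
* **RMS** (d=1).

Fractional powers act on |x| so negative samples are defined. All
operators are verified against independent explicit-loop oracles at 1e−9
relative tolerance.

## Decoding and evaluation

Classifiers: LDA (SVD solver, automatic shrinkage fallback on singular
scatter), KNN (k = 5, Euclidean), random forest (100 trees, seeded; 50 in
the quick profile). KNN and LDA receive z-scored features — the scaler is
fit on training rows only — because the feature sets mix magnitudes (SIS is
quadratic in amplitude, mMSR sub-linear); forests are scale-invariant and
take raw features. Hyperparameters are deliberately plain defaults, all
overridable: the comparison across SRDs, not peak accuracy, is the point.

Scenarios (always per subject):

* **Within-SRD**: train trials 1+2, test trial 3, same SRD group.
* **Between-SRD (faithful)**: train on all trials of one SRD group, test
  against all trials of every SRD group. Because shorter groups are
  prefixes, training windows reappear in overlapping test groups; the
  diagonal cell is then trivially perfect for a 1-NN. This is the stated
  protocol and is kept as the default; a *strict* mode (train trials 1+2,
  test trial 3) removes the overlap for users who want a leakage-free
  variant.

Metrics: CA = 100·trace/total of the confusion matrix; per-class MCC by
one-vs-rest binarization with the 0-when-undefined convention; macro MCC as
their unweighted mean; per-gesture recall as the row-normalized diagonal.
Subject aggregation is the unweighted mean of per-subject scores; pooled
confusion matrices are available as the window-weighted alternative. The
Friedman test ranks SRD groups within each subject block (average ranks on
ties, standard tie correction, chi-square reference distribution with
k−1 df); fully tied tables return statistic 0, p = 1.

## Problem sizes and profiles

The quick profile (`test_profile_config`) runs 2 subjects at 1000 Hz with
50-tree forests — the full grid (2 scenarios × 3 features × 3 classifiers ×
5 SRDs) completes in a couple of minutes and is what the test suite and the
acceptance script use, at 3 subjects for the trend computation. The
paper-scale profile (`paper_profile_config`, 8 subjects at 4000 Hz) is the
documented full-size configuration. Sampling rate mainly scales the number
of samples per window (150 vs 600); window counts, and hence training-set
sizes, are unchanged, so the quick profile preserves the structure of the
comparison.

## The Between-SRD trend

With drift enabled, the pipeline reproduces the qualitative ordering that
motivates the analysis: 1 s training is worst (too few windows, no coverage
of the drift range), accuracy rises through 5 and 10 s, and 20 s training
falls below 15 s — the final, most-drifted quarter of the hold pulls the
learned class models away from the early-window distribution that dominates
the test pool. The margins are assessed against the across-seed standard
error of the paired (per-seed) differences, since generator seeds shift the
overall difficulty of all SRD groups together.

## Known limitations

* The fatigue mechanism is a modeling choice; the real phenomenon's
  magnitude and time course are not calibrated to data.
* Faithful Between-SRD mode shares windows between train and test by
  construction; use strict mode for leakage-free estimates.
* LDA/KNN/RF hyperparameters are defaults, not tuned; absolute accuracies
  should not be compared across studies.
* `normLogDet`'s length normalization is one of several defensible
  readings; it differs from alternatives by a constant factor at fixed
  window length and cannot affect any classifier used here.
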