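# Methods

## Overview

`eegaffect` classifies binary emotional condition (negative = 0,
positive = 1) from multichannel EEG. The pipeline is:

1. **Cleaning** — per channel, DC-offset removal followed by an order-4
   Butterworth band-pass, both zero-phase, applied to the full
   recording before windowing so edge transients never contaminate
   interior windows.
2. **Epoching** — non-overlapping fixed windows (default 1 s at
   128 Hz); each window is one classification record.
3. **Feature extraction** — 148 features per window: 140 spectral
   statistics (14 channels x 5 bands x {mean, std} of the periodogram
   PSD of the band-decomposed signal) plus 8 frontal-brain-asymmetry
   (FBA) valence/arousal metrics from the alpha/beta band powers at
   F7/F8.
4. **Normalization and selection** — 5% winsorizing cap, min-max to
   [0, 1], one-way ANOVA-F ranking, percentile selection.
5. **Global optimization (GOM)** — for each of eight classifier
   families, sweep the selection percentile (5..100 step 5) and the
   family's hyperparameter grid, scoring every configuration with
   leave-one-subject-out (LOGO) cross-validation, and report each
   family's best cell.

## Signal processing

**Band-pass.** Defaults 0.16–43 Hz, order 4, zero-phase
(forward-backward). Zero-phase filtering doubles the effective
attenuation and removes phase distortion, which is preferable when the
downstream features are band powers. The 0.16 Hz edge implies pole time
constants near one second, far longer than scipy's default
forward-backward padding (capped at the signal length) can absorb.
Filtering therefore mirrors the signal repeatedly until three time
constants of context exist at each edge and trims afterwards. Mirror
(even) extension preserves the local mean, so no spurious DC steps are
injected; it also makes the operation symmetric under time reversal to
better than 1e-9, which is asserted as a property test. Odd extension
was rejected — iterated reflections accumulate DC offsets that a
0.16 Hz high-pass cannot reject within a finite segment.

**DC removal.** Default is a first-order zero-phase Butterworth
high-pass at 0.16 Hz followed by subtraction of the residual
finite-segment mean, so the output mean is zero to machine precision on
any input; plain per-signal mean subtraction is available by flag
(`method="mean"`). DC removal precedes band-passing; with these cutoffs
the two orders are near-equivalent.

**Edge attenuation in the band filter bank.** An order-4 response
cannot provide 20 dB of rejection for content sitting 2 Hz outside a
band edge (e.g. a 10 Hz tone leaks into theta at |H|^2 ≈ 0.14). Tests of
band separation therefore use band-centered probes; this is a property
of the chosen filter order, not an implementation artifact.

**Bands.** delta 0.5–4, theta 4–8, alpha 8–14, beta 14–30, gamma
30–40 Hz, non-overlapping, upper edges strictly below Nyquist. The
8–14/14–30 alpha/beta edges are used everywhere, including inside the
FBA metrics.

**PSD.** One-sided rectangular-taper (boxcar) periodogram of the full
window, no detrending, no Welch averaging. It satisfies the discrete
Parseval identity (integral of density = mean square of the signal)
to 1e-6 relative, asserted as a property test. The per-feature
statistics are the arithmetic mean and the *population* (divide-by-N)
standard deviation of the density vector — fixed for reproducibility.

**Band power** is the integral of the one-sided periodogram over
`low <= f < high` (density x bin width), floored at `1e-12` before any
ratio or logarithm so degenerate windows yield finite features rather
than mid-pipeline errors.

## Frontal-asymmetry metrics

With `aL, aR` the alpha and `bL, bR` the beta band powers at F7 (left)
and F8 (right):

    v1 = aR/bR - aL/bL           a1 = (aL + aR) / (bL + bR)
    v2 = ln aL - ln aR           a2 = -(ln aL + ln aR)
    v3 = bL/aL - bR/aR           a3 = log2((bL + bR) / (aL + aR))
    v4 = aR - aL                 a4 = (bL + bR) / (aL + aR)

Valence metrics are antisymmetric under exchange of F7 and F8 and
vanish for symmetric inputs; v2 and a3 are invariant to a common
rescaling of the signal, while v4 scales with the square of the
amplitude. All three facts are property-tested.

## Normalization and selection

**Cap rule (winsorization).** Per feature, the top `ceil(0.05 * n)`
training values are replaced by the maximum of the remaining 95%. With
fewer than 20 rows the cap degenerates to the column maximum (no-op).
Capping happens *before* min-max scaling so outputs land exactly in
[0, 1] and the combined transform is idempotent under refitting.

**Min-max.** `x' = (min(x, cap) - min) / (max - min)` using the
training minimum/maximum of the capped values. A constant feature maps
to 0 for every row; held-out values are clipped into [0, 1].

**ANOVA-F.** One-way F statistic per feature
(`(SSB/(k-1)) / (SSW/(N-k))`), computed via scikit-learn's `f_classif`;
degenerate (constant) features score 0 and rank last. Tests check
agreement with an independent sums-of-squares oracle and with the
squared two-sample t statistic to 1e-9 relative.

**Percentile selection** keeps the `max(1, ceil(p/100 * n))`
highest-scoring features — a fixed, tested rounding rule — with ties
broken toward the lower column index. Selected sets are nested across
percentiles.

**Leakage policy.** In the default `strict` mode the cap, min-max
ranges and F-scores are refit inside every training fold, so the
held-out subject influences nothing. `paper` mode fits them once on
the full matrix before splitting, which leaks the held-out subject's
marginal distribution into the transform; both modes are available
because fold-internal fitting is the defensible default but not the
only plausible protocol for this design.

## Global optimization

**Roster and grids.** svm_linear / svm_poly / svm_rbf / svm_sigmoid
(C x gamma x tol x shrinking variants), decision_tree, random_forest,
knn — exhaustive grids — and a multilayer perceptron tuned by budgeted
random search (default 20 draws) over depth {1,2,4,5}, width 32..1024
step 8, dropout rate 0..0.9 step 0.1, optimizer and output-activation
choices. The sigmoid-kernel machine uses the kernel-machine grid
{C, gamma, tol, shrinking}: a sigmoid SVC cannot accept linear-model
parameters (penalty/loss/max_iter). For the perceptron, scikit-learn's
`MLPClassifier` provides no dropout layer or adamax solver: the sampled
dropout rate is realized as a weight-decay penalty of equivalent
strength via the monotone map `alpha = 10**(-4 + 3*d)`, both optimizer
choices run the adam-family solver, and the output activation is
determined by the label encoding. The tree grid's historical
`max_features='auto'` is executed as `'sqrt'`.

**Search.** Every candidate is scored by its mean held-out accuracy
over the LOGO folds; a candidate whose fit fails on any fold (e.g. the
out-of-bag/no-bootstrap combination in the forest grid) scores 0 and is
logged, never fatal. Ties keep the earlier candidate in deterministic
enumeration order. Single-level LOGO is used: the grid search's
internal CV is the same LOGO loop (an honest nested protocol would
re-tune inside each outer fold; the single-level variant is what the
percentile-sweep bookkeeping — models x percentiles x subjects —
presumes).

**Evaluation.** The winning configuration of each (model, percentile)
cell is refit across the LOGO folds; that final pass is the counted
"cross-validation evaluation" (8 models x 20 percentiles x 10 subjects
= 1,600 at full scale) and supplies the pooled held-out predictions.
Reported metrics: accuracy, macro-averaged precision/recall/F-score
(macro is symmetric for this balanced two-class design; undefined
per-class precision counts as 0), and mean wall-clock seconds of a
single-row predict call. Pooling over folds is the default; per-fold
averaging of accuracy is available from the stored fold accuracies.

**Determinism.** All stochastic components (forest bootstrap, tree and
perceptron initialization, random-search draws) take seeds fanned out
deterministically from the single run seed. Ranking and tie-breaking
use only (accuracy, F-score) plus deterministic enumeration order —
prediction time is reported but never used to order results, since a
timing-dependent tie-break would make reruns non-reproducible.

## Synthetic data generator

Real recordings for this task are not publicly deposited, so the
generator emulates the study shape: 10 subjects x 2,048 balanced
one-second records (20,480 total) at 128 Hz on the 14-channel montage.
Each channel is

    x = sqrt(subject_gain) * (pink noise + alpha oscillator + beta oscillator)

* **Background**: 1/f^gamma Gaussian noise (default exponent 1), unit
  power.
* **Oscillators**: narrowband-filtered Gaussian noise in 8–14 Hz and
  14–30 Hz (not pure tones), so band powers fluctuate window to window
  with realistic chi-squared-like variance. Total oscillator power
  equals `snr` times the noise power, split equally between the two
  bands.
* **Class signal**: for label 1 the F8 alpha-oscillator power is
  multiplied by `asymmetry_effect` and the F7 alpha power divided by
  it; label 0 swaps the channels. The planted F8:F7 alpha-power ratio
  is therefore `asymmetry_effect**2` (default effect 2.0 → ratio 4),
  `asymmetry_effect = 1` is an exact null, and beta stays symmetric
  unless `plant_beta_asymmetry` is set. The squared-ratio convention is
  deliberate: with one-second windows an alpha band power is the sum of
  roughly six independent periodogram bins, so the ratio of two
  channels' powers fluctuates like an F(12,12) variate and a planted
  ratio of only 2 would cap per-window separability near 88% — too weak
  for the planted signal to be recoverable well above the noise floor,
  which is the generator's purpose.
* **Subject effect**: a log-normal gain (`subject_sd`, default 0.2)
  common to all channels of a subject, shifting raw powers across
  subjects while cancelling exactly in asymmetry ratios — the FBA
  features are the subject-invariant pathway, by design.
* Non-frontal channels carry identical background statistics and no
  class signal, so univariate selection should (and does, in the
  score-table check) prefer F7/F8-derived columns.

**What it does not emulate**: volume conduction and channel
correlation, eye-blink/EMG artifacts, non-stationarity within a
session, individual alpha-peak frequencies, and any temporal dependence
between windows beyond filter continuity. Passing tests on this
generator therefore demonstrate that the pipeline recovers a planted
frontal-asymmetry signal under realistic spectral noise — not that the
reported real-data accuracies are reproducible.

## Problem sizes used by the test suite

Chosen as the smallest sizes at which each claim is meaningful: the
study-shape check runs the full default generator (10 x 2,048 records,
counting only); the bookkeeping check runs the full 8 x 20 x 10 sweep
with single-point grids (1,600 evaluations); signal-recovery and
determinism checks use 3 subjects x 256 and 3 x 64 records. The
acceptance script recomputes the study-shape record count from scratch
at the full default size.

## Known limitations

* Single-level LOGO tuning means reported accuracies are model-selection
  optimistic; use the nested protocol for honest generalization
  estimates if it matters.
* Prediction time is wall-clock and environment-dependent; it is
  reported for cost comparison only and excluded from all assertions
  and orderings.
* The window length behind the per-subject record count of the original
  design is not recoverable; 1 s non-overlapping windows are the
  package default and the generator matches them.
* No artifact rejection (ICA, re-referencing, blink removal) is
  included; inputs are assumed to be continuous EEG already free of
  gross artifacts.
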