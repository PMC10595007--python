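# eegaffect

Classify binary emotional state (negative vs. positive condition) from
multichannel EEG using frontal-brain-asymmetry (FBA) features and a
globally optimized classifier sweep.

The package is aimed at affective-computing and BCI researchers who
want a reproducible, leakage-aware reference pipeline from raw
channel x time EEG matrices (14-channel consumer montage, 128 Hz) to a
ranked classifier report — plus a synthetic-EEG generator with a
planted, class-dependent frontal alpha asymmetry, so every stage is
testable without human recordings.

## The method

Each 1 s window of cleaned EEG (0.16–43 Hz zero-phase Butterworth,
DC removed) becomes a 148-dimensional feature vector:

* **140 spectral statistics** — for every channel `c` of the montage and
  band `b` in {delta 0.5–4, theta 4–8, alpha 8–14, beta 14–30, gamma
  30–40 Hz}, the mean and population standard deviation of the
  periodogram PSD of the band-decomposed signal.
* **8 FBA metrics** — with α<sub>F7</sub>, α<sub>F8</sub>,
  β<sub>F7</sub>, β<sub>F8</sub> the alpha/beta band powers at the
  left/right frontal electrodes:

  | valence | arousal |
  |---|---|
  | v1 = α_F8/β_F8 − α_F7/β_F7 | a1 = (α_F7+α_F8)/(β_F7+β_F8) |
  | v2 = ln α_F7 − ln α_F8 | a2 = −(ln α_F7 + ln α_F8) |
  | v3 = β_F7/α_F7 − β_F8/α_F8 | a3 = log₂((β_F7+β_F8)/(α_F7+α_F8)) |
  | v4 = α_F8 − α_F7 | a4 = (β_F7+β_F8)/(α_F7+α_F8) |

Features are winsorized (top 5% of each feature capped at the 95% max),
min-max scaled to [0, 1], and ranked by one-way ANOVA F against the
class labels. The **global optimization model** then sweeps eight
classifier families (four SVM kernels, decision tree, random forest,
k-NN, MLP) x selection percentiles {5, 10, …, 100} x each family's
hyperparameter grid, scoring everything with leave-one-subject-out
cross-validation — 8 x 20 x 10 = 1,600 cross-validation evaluations at
full scale — and reports each family's best cell with pooled held-out
accuracy, macro precision/recall/F-score and prediction time.
Normalization and selection are refit inside each training fold by
default, so the held-out subject leaks into nothing.

See `docs/methods.md` for assumptions, numerical choices and
limitations.

## Worked example

`python examples/run_gom_small.py` simulates 3 subjects x 64 balanced
records with the default planted asymmetry, extracts features, and
runs a reduced sweep (two families, three percentiles):

```
feature matrix: 192 records x 148 features

18 cross-validation evaluations, 2124 model fits

classifier  percentile  accuracy  precision   recall  f_score  pred_time_s
svm_linear           5  0.958333   0.958532 0.958333 0.958329     0.000154
       knn          50  0.947917   0.947917 0.947917 0.947917     0.000461
```

Each row is one classifier family at its best selection percentile:
the linear SVM peaks with only 5% of the features (8 of 148) because
the planted class signal lives in the frontal alpha columns, which the
ANOVA-F ranking finds immediately. Accuracy is the fraction of pooled
held-out windows (subjects never seen in training) classified
correctly; chance is 0.5.

The other examples print the FBA metrics for a worked band-power quad
(`examples/frontal_asymmetry_metrics.py`) and walk one recording
through cleaning, epoching and feature extraction
(`examples/extract_features.py`).

The same pipeline is scriptable from the shell:

```sh
eegaffect run --out-dir out/            # simulate -> extract -> optimize
eegaffect simulate --out-dir data/
eegaffect extract --recordings data/ --out features.csv
eegaffect optimize --features features.csv --out report.csv
```

All stage parameters live in a single YAML config (`--config`); every
output carries the config hash so mismatched artifacts are detected.

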