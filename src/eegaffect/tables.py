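"""Feature-matrix normalization and univariate feature selection.

Normalization is a two-step, fit-on-train transform: (1) a 5% cap rule
(winsorization) that replaces each feature's top ``ceil(0.05 * n)``
values by the maximum of the remaining 95%, then (2) min-max scaling of
the capped values into [0, 1]. Held-out data is transformed with the
training caps and ranges and clipped into [0, 1].

Selection ranks features by the one-way ANOVA F statistic of the
feature against the two condition classes and keeps the top
``max(1, ceil(percentile/100 * n_features))``, with ties broken toward
the lower column index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif

from .errors import ConfigurationError, StatisticalError

#: The percentile grid swept by the optimizer: 5, 10, ..., 100.
PERCENTILE_GRID: tuple[int, ...] = tuple(range(5, 101, 5))

#: Below this many rows the cap rule degenerates to a no-op (cap = max).
MIN_ROWS_FOR_CAP = 20


@dataclass
class NormalizationModel:
    """Fitted per-feature cap values and min/max ranges."""

    columns: list[str]
    cap: np.ndarray
    min_: np.ndarray
    max_: np.ndarray


@dataclass
class SelectionModel:
    """Fitted univariate selection: scores, kept indices, percentile."""

    scores: np.ndarray
    selected_indices: np.ndarray
    percentile: int

    @property
    def n_selected(self) -> int:
        return len(self.selected_indices)


def _as_array(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), [str(c) for c in matrix.columns]
    x = np.asarray(matrix, dtype=float)
    return x, [str(i) for i in range(x.shape[1])]


def fit_cap(matrix) -> np.ndarray:
    """Per-feature cap: maximum of the lowest 95% of values.

    The top ``ceil(0.05 * n)`` values of each column are the "highest
    measurements" to be replaced. With fewer than ``MIN_ROWS_FOR_CAP``
    rows the cap is the column maximum (no-op).
    """
    x, _ = _as_array(matrix)
    n = x.shape[0]
    if n == 0:
        raise StatisticalError("cannot fit caps on an empty matrix")
    if n < MIN_ROWS_FOR_CAP:
        return x.max(axis=0)
    m = math.ceil(0.05 * n)
    srt = np.sort(x, axis=0)
    return srt[n - m - 1, :]


def fit_normalization(matrix) -> NormalizationModel:
    """Fit cap values then min/max of the capped training data."""
    x, cols = _as_array(matrix)
    cap = fit_cap(x)
    capped = np.minimum(x, cap)
    return NormalizationModel(
        columns=cols, cap=cap, min_=capped.min(axis=0), max_=capped.max(axis=0)
    )


def apply_cap_and_minmax(matrix, model: NormalizationModel):
    """Cap then min-max scale into [0, 1] with the fitted model.

    Constant training features (max == min) map to 0 for every row;
    held-out values beyond the training range are clipped.
    """
    x, cols = _as_array(matrix)
    if x.shape[1] != len(model.columns):
        raise ConfigurationError(
            f"matrix has {x.shape[1]} columns, model was fit on {len(model.columns)}"
        )
    span = model.max_ - model.min_
    safe = np.where(span > 0, span, 1.0)
    scaled = (np.minimum(x, model.cap) - model.min_) / safe
    scaled = np.where(span > 0, scaled, 0.0)
    scaled = np.clip(scaled, 0.0, 1.0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(scaled, columns=cols, index=matrix.index)
    return scaled


def anova_f_scores(matrix, labels) -> np.ndarray:
    """One-way ANOVA F statistic of each feature against the class labels.

    ``F = (SS_between / (k-1)) / (SS_within / (N-k))``. Degenerate
    features with zero between- and within-class variance score 0.
    """
    x, _ = _as_array(matrix)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StatisticalError("ANOVA needs at least two classes")
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            raise StatisticalError(f"class {cls!r} has fewer than 2 rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features emit runtime warnings
        scores, _ = f_classif(x, y)
    scores = np.asarray(scores, dtype=float)
    scores[~np.isfinite(scores)] = 0.0
    return scores


def select_percentile(scores, percentile: int) -> SelectionModel:
    """Keep the top ``max(1, ceil(p/100 * n))`` features by score.

    ``percentile`` must be on the 5..100-step-5 grid. Ties are broken
    toward the lower column index; returned indices are ascending.
    """
    if percentile not in PERCENTILE_GRID:
        raise ConfigurationError(
            f"percentile must be one of {PERCENTILE_GRID}, got {percentile}"
        )
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n == 0:
        raise ConfigurationError("no features to select from")
    k = max(1, math.ceil(percentile / 100.0 * n))
    order = np.argsort(-scores, kind="stable")  # stable => lower index wins ties
    selected = np.sort(order[:k])
    return SelectionModel(scores=scores, selected_indices=selected, percentile=percentile)


@dataclass
class FoldTransform:
    """Normalization + selection fitted on one training fold.

    Bundles the leak-free transform applied identically to the training
    and held-out sides of a cross-validation split.
    """

    normalization: NormalizationModel
    selection: SelectionModel

    @classmethod
    def fit(cls, train_features: pd.DataFrame, train_labels, percentile: int) -> "FoldTransform":
        norm = fit_normalization(train_features)
        scaled = apply_cap_and_minmax(train_features, norm)
        scores = anova_f_scores(scaled, train_labels)
        sel = select_percentile(scores, percentile)
        return cls(normalization=norm, selection=sel)

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        scaled = apply_cap_and_minmax(features, self.normalization)
        arr = scaled.to_numpy(dtype=float) if isinstance(scaled, pd.DataFrame) else scaled
        return arr[:, self.selection.selected_indices]
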