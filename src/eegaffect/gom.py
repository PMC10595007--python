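"""Global optimization of emotion classifiers.

The Global Optimization Model (GOM) jointly sweeps a roster of eight
classifier families, their hyperparameter grids, and the univariate
feature-selection percentile grid (5..100 step 5), scoring every cell
with leave-one-subject-out (LOGO) cross-validation. The report keeps,
for each family, the best percentile with its tuned hyperparameters and
pooled held-out metrics — accuracy, macro precision/recall/F-score and
mean single-input prediction time.

With the full roster, full percentile grid and 10 subjects, the sweep
performs 8 x 20 x 10 = 1,600 cross-validation evaluations (one per
model, percentile and held-out subject), over and above the inner
grid-search fits.

In ``strict`` mode, normalization and selection are refit inside every
training fold so the held-out subject leaks into nothing; ``paper``
mode fits them once on the full dataset before splitting.
"""

from __future__ import annotations

import itertools
import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datamodel import GROUP_COLUMN, LABEL_COLUMN, feature_columns, validate_feature_matrix
from .errors import ConfigurationError, StatisticalError
from .tables import (
    PERCENTILE_GRID,
    anova_f_scores,
    apply_cap_and_minmax,
    fit_normalization,
    select_percentile,
)

logger = logging.getLogger(__name__)

#: Hyperparameter grids for the exhaustive-search families, transcribed
#: from the published roster. The sigmoid-kernel machine uses the
#: kernel-machine parameterization (the published sigmoid grid lists
#: linear-model parameters that a kernel SVC cannot accept).
MODEL_GRIDS: dict[str, dict[str, list]] = {
    "svm_linear": {
        "kernel": ["linear"],
        "C": [0.1, 1, 10],
        "tol": [1e-4, 1e-3, 1e-2],
        "shrinking": [True, False],
    },
    "svm_poly": {
        "kernel": ["poly"],
        "C": [0.1, 1, 10],
        "degree": [2, 3, 4],
        "gamma": ["scale", "auto"],
        "tol": [1e-4, 1e-3, 1e-2],
        "shrinking": [True, False],
    },
    "svm_rbf": {
        "kernel": ["rbf"],
        "C": [0.1, 1, 10],
        "gamma": ["scale", "auto"],
        "tol": [1e-4, 1e-3, 1e-2],
        "shrinking": [True, False],
    },
    "svm_sigmoid": {
        "kernel": ["sigmoid"],
        "C": [0.1, 1, 10],
        "gamma": ["scale", "auto"],
        "tol": [1e-4, 1e-3, 1e-2],
        "shrinking": [True, False],
    },
    "decision_tree": {
        "criterion": ["entropy"],
        "splitter": ["best", "random"],
        "max_depth": [3, 6, 9, 12, 15, None],
        "min_samples_split": [2, 3, 4, 5],
        "min_samples_leaf": [1, 2, 3, 4],
        "max_features": ["auto", "sqrt", "log2", None],
        "ccp_alpha": [0.0, 0.010, 0.020, 0.030],
    },
    "random_forest": {
        "criterion": ["entropy"],
        "max_depth": [3, None],
        "min_samples_split": [2],
        "min_samples_leaf": [1],
        "n_estimators": [50, 100, 200],
        "bootstrap": [True, False],
        "oob_score": [True, False],
        "warm_start": [True, False],
        "ccp_alpha": [0.0],
    },
    "knn": {
        "n_neighbors": [5, 10, 20],
        "weights": ["uniform", "distance"],
        "algorithm": ["auto", "ball_tree", "kd_tree", "brute"],
        "leaf_size": [30, 60, 120],
        "p": [1, 2, 3],
    },
    # sampled, not enumerated: see ModelSpec.search == "budgeted_random"
    "mlp": {
        "n_layers": [1, 2, 4, 5],
        "width": list(range(32, 1025, 8)),
        "dropout": [round(0.1 * k, 1) for k in range(10)],
        "optimizer": ["adam", "adamax"],
        "output_activation": ["softmax", "sigmoid"],
    },
}

MODEL_FAMILIES: tuple[str, ...] = tuple(MODEL_GRIDS)


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family with its hyperparameter search space."""

    family: str
    grid: dict[str, list] = None  # type: ignore[assignment]
    search: str = "exhaustive"
    budget: int = 20
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_GRIDS:
            raise ConfigurationError(
                f"unknown model family {self.family!r}; known: {MODEL_FAMILIES}"
            )
        if self.grid is None:
            object.__setattr__(self, "grid", MODEL_GRIDS[self.family])
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ConfigurationError(f"{self.family}: grid must be non-empty")
        if self.search not in ("exhaustive", "budgeted_random"):
            raise ConfigurationError(f"unknown search strategy {self.search!r}")


def default_roster(mlp_budget: int = 20, mlp_max_iter: int = 200) -> list[ModelSpec]:
    """The eight-family roster with the published grids."""
    roster = [
        ModelSpec(family=f)
        for f in MODEL_FAMILIES
        if f != "mlp"
    ]
    roster.append(
        ModelSpec(
            family="mlp",
            search="budgeted_random",
            budget=mlp_budget,
            fixed={"max_iter": mlp_max_iter},
        )
    )
    return roster


def build_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate the sklearn estimator for one grid point.

    Tree ``max_features='auto'`` is translated to ``'sqrt'`` (its
    historical meaning for classifiers). The perceptron's sampled
    dropout rate is realized as an L2 penalty of equivalent strength
    (``alpha = 10**(-4 + 3*dropout)``) since the plain MLP used here
    regularizes by weight decay; both sampled optimizer variants use the
    adam-family solver, and the output activation is chosen by the
    library from the target encoding.
    """
    p = dict(params)
    if family.startswith("svm_"):
        return SVC(**p)
    if family == "decision_tree":
        if p.get("max_features") == "auto":
            p["max_features"] = "sqrt"
        return DecisionTreeClassifier(random_state=seed, **p)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **p)
    if family == "knn":
        return KNeighborsClassifier(**p)
    if family == "mlp":
        hidden = (int(p.pop("width")),) * int(p.pop("n_layers"))
        alpha = 10.0 ** (-4.0 + 3.0 * float(p.pop("dropout")))
        p.pop("optimizer", None)
        p.pop("output_activation", None)
        return MLPClassifier(
            hidden_layer_sizes=hidden,
            alpha=alpha,
            solver="adam",
            random_state=seed,
            **p,
        )
    raise ConfigurationError(f"unknown model family {family!r}")


def enumerate_candidates(spec: ModelSpec, seed: int = 0) -> list[dict]:
    """Deterministic candidate list for a spec.

    Exhaustive search enumerates the cartesian product of the grid in
    key order; budgeted random search draws ``budget`` configurations
    with a generator seeded from ``seed``.
    """
    keys = list(spec.grid)
    if spec.search == "exhaustive":
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(spec.grid[k] for k in keys))
        ]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(spec.budget):
        out.append({k: spec.grid[k][int(rng.integers(len(spec.grid[k])))] for k in keys})
    return out


def logo_splits(groups) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-group-out splits, one per distinct group (sorted order)."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise StatisticalError(
            "leave-one-subject-out needs at least 2 distinct groups; "
            f"got {list(uniq)}"
        )
    idx = np.arange(len(groups))
    return [(idx[groups != g], idx[groups == g]) for g in uniq]


def classification_metrics(y_true, y_pred) -> tuple[float, float, float, float]:
    """Accuracy plus macro-averaged precision, recall and F-score.

    Undefined per-class precision (a class never predicted) counts as 0
    for that class before averaging.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ConfigurationError("y_true and y_pred must have equal length")
    if len(y_true) < 1:
        raise ConfigurationError("need at least one prediction")
    acc = accuracy_score(y_true, y_pred)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], average="macro", zero_division=0
    )
    return float(acc), float(prec), float(rec), float(f1)


@dataclass
class CVEvaluation:
    """Pooled LOGO results for one (model, percentile) cell."""

    model_family: str
    percentile: int
    best_hyperparameters: dict
    y_true: np.ndarray
    y_pred: np.ndarray
    fold_accuracies: list[float]
    accuracy: float
    precision: float
    recall: float
    f_score: float
    prediction_time_s: float

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class GOMReport:
    """Ranked summary of the sweep plus all per-cell evaluations."""

    rows: list[CVEvaluation]
    cells: list[CVEvaluation]
    n_cv_evaluations: int
    n_fits: int
    failures: list[tuple[str, int, str]]
    mode: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Summary table: one ranked row per model family."""
        return pd.DataFrame(
            [
                {
                    "classifier": r.model_family,
                    "percentile": r.percentile,
                    "accuracy": r.accuracy,
                    "precision": r.precision,
                    "recall": r.recall,
                    "f_score": r.f_score,
                    "pred_time_s": r.prediction_time_s,
                }
                for r in self.rows
            ]
        )

    def cells_frame(self) -> pd.DataFrame:
        """Long-format table with every (model, percentile) cell."""
        return pd.DataFrame(
            [
                {
                    "classifier": c.model_family,
                    "percentile": c.percentile,
                    "accuracy": c.accuracy,
                    "precision": c.precision,
                    "recall": c.recall,
                    "f_score": c.f_score,
                    "pred_time_s": c.prediction_time_s,
                    "best_hyperparameters": repr(c.best_hyperparameters),
                }
                for c in self.cells
            ]
        )


def _fit_predict_folds(family, params, folds, seed):
    """Fit one candidate on every fold; returns per-fold (y_true, y_pred)."""
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        for x_tr, y_tr, x_te, y_te in folds:
            est = build_estimator(family, params, seed=seed)
            est.fit(x_tr, y_tr)
            results.append((est, y_te, est.predict(x_te)))
    return results


def _time_single_predictions(family, params, folds, seed, fold_fits, max_rows=10) -> float:
    times = []
    for (x_tr, y_tr, x_te, y_te), (est, _, _) in zip(folds, fold_fits):
        rows = x_te[: max_rows]
        for row in rows:
            t0 = time.perf_counter()
            est.predict(row.reshape(1, -1))
            times.append(time.perf_counter() - t0)
    return float(np.mean(times)) if times else 0.0


def grid_search(
    spec: ModelSpec,
    features,
    labels,
    groups,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Tune one model on raw features with LOGO cross-validation.

    Every candidate is scored by its mean held-out accuracy across the
    LOGO folds; ties keep the earlier candidate in deterministic
    enumeration order. A candidate whose fit fails on any fold scores 0
    (logged, not fatal).

    Returns ``(best_hyperparameters, info)`` where ``info`` carries the
    best candidate's per-fold accuracies, pooled metrics and the number
    of model fits executed.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    splits = logo_splits(groups)
    folds = [(x[tr], y[tr], x[te], y[te]) for tr, te in splits]
    best, n_fits = _search_candidates(spec, folds, seed)
    if best is None:
        raise StatisticalError(f"{spec.family}: every grid point failed to fit")
    params, mean_acc, fold_fits, fold_accs = best
    y_true = np.concatenate([t for _, t, _ in fold_fits])
    y_pred = np.concatenate([p for _, _, p in fold_fits])
    acc, prec, rec, f1 = classification_metrics(y_true, y_pred)
    info = {
        "mean_fold_accuracy": mean_acc,
        "fold_accuracies": fold_accs,
        "accuracy": acc,
        "precision": prec,
        "recall": rec,
        "f_score": f1,
        "n_fits": n_fits,
    }
    return params, info


def _search_candidates(spec: ModelSpec, folds, seed: int):
    """Evaluate all candidates; return the best and the fit count."""
    best = None
    n_fits = 0
    for params in enumerate_candidates(spec, seed=seed):
        try:
            fold_fits = _fit_predict_folds(spec.family, params, folds, seed)
            n_fits += len(folds)
        except Exception as exc:  # failing grid point scores 0, run continues
            logger.warning("%s: grid point %r failed: %s", spec.family, params, exc)
            continue
        fold_accs = [accuracy_score(t, p) for _, t, p in fold_fits]
        mean_acc = float(np.mean(fold_accs))
        if best is None or mean_acc > best[1]:
            best = (params, mean_acc, fold_fits, fold_accs)
    return best, n_fits


def _prepare_fold_data(x_frame: pd.DataFrame, y, splits, percentiles, mode: str):
    """Normalization/selection per fold (strict) or global (paper).

    Returns ``fold_data[fold][percentile] -> (x_tr, y_tr, x_te, y_te)``
    realized lazily as a closure over cached transforms.
    """
    y = np.asarray(y)
    if mode == "paper":
        norm = fit_normalization(x_frame)
        scaled = np.asarray(apply_cap_and_minmax(x_frame, norm), dtype=float)
        scores = anova_f_scores(scaled, y)
        sel = {p: select_percentile(scores, p).selected_indices for p in percentiles}

        def folds_for(percentile: int):
            cols = sel[percentile]
            return [
                (scaled[np.ix_(tr, cols)], y[tr], scaled[np.ix_(te, cols)], y[te])
                for tr, te in splits
            ]

        return folds_for

    if mode != "strict":
        raise ConfigurationError(f"unknown leakage mode {mode!r} (use 'strict' or 'paper')")

    cache = []
    for tr, te in splits:
        norm = fit_normalization(x_frame.iloc[tr])
        s_tr = np.asarray(apply_cap_and_minmax(x_frame.iloc[tr], norm), dtype=float)
        s_te = np.asarray(apply_cap_and_minmax(x_frame.iloc[te], norm), dtype=float)
        scores = anova_f_scores(s_tr, y[tr])
        cache.append((s_tr, y[tr], s_te, y[te], scores))

    def folds_for(percentile: int):
        out = []
        for s_tr, y_tr, s_te, y_te, scores in cache:
            cols = select_percentile(scores, percentile).selected_indices
            out.append((s_tr[:, cols], y_tr, s_te[:, cols], y_te))
        return out

    return folds_for


def _family_seed(run_seed: int, family_index: int) -> int:
    ss = np.random.SeedSequence(entropy=run_seed, spawn_key=(family_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_gom(
    dataset: pd.DataFrame,
    roster: list[ModelSpec] | None = None,
    percentiles: tuple[int, ...] = PERCENTILE_GRID,
    mode: str = "strict",
    seed: int = 0,
) -> GOMReport:
    """Run the full sweep and return the ranked report.

    For every (model, percentile) cell: select features at that
    percentile, tune hyperparameters by LOGO grid search, then evaluate
    the winning configuration once more across the LOGO folds — that
    final evaluation is what the cross-validation counter counts, so a
    full-scale run (8 models, 20 percentiles, 10 subjects) performs
    1,600 of them. Per family, the report keeps the best percentile
    (highest accuracy, ties to higher F-score, then lower percentile).
    """
    validate_feature_matrix(dataset)
    roster = default_roster() if roster is None else roster
    for p in percentiles:
        if p not in PERCENTILE_GRID:
            raise ConfigurationError(f"percentile {p} not on the 5..100 step-5 grid")
    x_frame = dataset[feature_columns(dataset)]
    y = dataset[LABEL_COLUMN].to_numpy()
    groups = dataset[GROUP_COLUMN].to_numpy()
    splits = logo_splits(groups)
    folds_for = _prepare_fold_data(x_frame, y, splits, percentiles, mode)

    cells: list[CVEvaluation] = []
    failures: list[tuple[str, int, str]] = []
    rows: list[CVEvaluation] = []
    n_cv = 0
    n_fits = 0

    for fam_idx, spec in enumerate(roster):
        fam_seed = _family_seed(seed, fam_idx)
        family_cells: list[CVEvaluation] = []
        for percentile in percentiles:
            folds = folds_for(percentile)
            try:
                best, fits = _search_candidates(spec, folds, fam_seed)
                n_fits += fits
                if best is None:
                    raise StatisticalError("every grid point failed")
                params = best[0]
                # final evaluation of the winning configuration: the
                # counted cross-validation pass for this cell
                fold_fits = _fit_predict_folds(spec.family, params, folds, fam_seed)
                n_fits += len(folds)
                n_cv += len(folds)
            except Exception as exc:
                logger.warning(
                    "GOM cell (%s, percentile=%d) failed: %s",
                    spec.family, percentile, exc,
                )
                failures.append((spec.family, percentile, str(exc)))
                continue
            y_true = np.concatenate([t for _, t, _ in fold_fits])
            y_pred = np.concatenate([p for _, _, p in fold_fits])
            acc, prec, rec, f1 = classification_metrics(y_true, y_pred)
            pred_time = _time_single_predictions(spec.family, params, folds, fam_seed, fold_fits)
            family_cells.append(
                CVEvaluation(
                    model_family=spec.family,
                    percentile=percentile,
                    best_hyperparameters=params,
                    y_true=y_true,
                    y_pred=y_pred,
                    fold_accuracies=[accuracy_score(t, p) for _, t, p in fold_fits],
                    accuracy=acc,
                    precision=prec,
                    recall=rec,
                    f_score=f1,
                    prediction_time_s=pred_time,
                )
            )
        cells.extend(family_cells)
        if family_cells:
            best_cell = family_cells[0]
            for cell in family_cells[1:]:
                if (cell.accuracy, cell.f_score) > (best_cell.accuracy, best_cell.f_score):
                    best_cell = cell
            rows.append(best_cell)
        else:
            failures.append((spec.family, -1, "no percentile cell succeeded"))

    # stable sort: ties keep roster order so reruns are byte-identical
    # (prediction time is reported but never used to order results)
    rows.sort(key=lambda r: (-r.accuracy, -r.f_score))
    return GOMReport(
        rows=rows,
        cells=cells,
        n_cv_evaluations=n_cv,
        n_fits=n_fits,
        failures=failures,
        mode=mode,
        seed=seed,
    )
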