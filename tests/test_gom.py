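"""LOGO splitting, grid search, metrics and the GOM sweep."""

import numpy as np
import pandas as pd
import pytest

import eegaffect as ea
from eegaffect.errors import ConfigurationError, StatisticalError
from eegaffect.gom import _prepare_fold_data, enumerate_candidates


class TestLogoSplits:
    def test_three_groups(self):
        splits = ea.logo_splits(["A", "A", "B", "B", "C"])
        assert len(splits) == 3
        train, test = splits[2]  # groups iterate in sorted order
        np.testing.assert_array_equal(test, [4])
        np.testing.assert_array_equal(train, [0, 1, 2, 3])

    def test_ten_groups_ten_splits(self):
        groups = [f"S{i}" for i in range(10) for _ in range(3)]
        splits = ea.logo_splits(groups)
        assert len(splits) == 10
        for train, test in splits:
            assert len(train) + len(test) == 30
            assert set(train) & set(test) == set()

    def test_singleton_groups(self):
        splits = ea.logo_splits(["a", "b", "c"])
        assert all(len(tr) == 2 and len(te) == 1 for tr, te in splits)

    def test_single_group_rejected(self):
        with pytest.raises(StatisticalError):
            ea.logo_splits(["A", "A", "A"])


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        assert ea.classification_metrics([0, 1, 0, 1], [0, 1, 0, 1]) == (1, 1, 1, 1)

    def test_macro_averaged_worked_example(self):
        acc, prec, rec, f1 = ea.classification_metrics([0, 0, 1, 1], [0, 1, 1, 1])
        assert acc == pytest.approx(0.75)
        assert prec == pytest.approx((1 + 2 / 3) / 2)
        assert rec == pytest.approx((0.5 + 1) / 2)

    def test_all_one_predictions_on_balanced_truth(self):
        acc, prec, _, _ = ea.classification_metrics([0, 0, 1, 1], [1, 1, 1, 1])
        assert acc == 0.5
        assert prec == pytest.approx(0.25)  # missing-class precision counts as 0

    def test_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            ea.classification_metrics([0, 1], [0])


def _separable_data(n_per_group=8, n_groups=4, n_features=5, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels, groups = [], [], []
    for g in range(n_groups):
        for k in range(n_per_group):
            y = k % 2
            x = rng.normal(size=n_features)
            x[0] += 4.0 * (1 if y else -1)
            rows.append(x)
            labels.append(y)
            groups.append(f"G{g}")
    return np.array(rows), np.array(labels), np.array(groups)


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self):
        x, y, g = _separable_data()
        spec = ea.ModelSpec("knn", grid={"n_neighbors": [5]})
        params, info = ea.grid_search(spec, x, y, g)
        assert params == {"n_neighbors": 5}
        assert info["n_fits"] == 4
        assert 0 <= info["accuracy"] <= 1

    def test_dominant_point_wins(self):
        x, y, g = _separable_data()
        # k = n_train degenerates to the majority vote (chance on balanced
        # data), so k=1 strictly dominates on every fold
        spec = ea.ModelSpec("knn", grid={"n_neighbors": [24, 1]})
        params, _ = ea.grid_search(spec, x, y, g)
        assert params["n_neighbors"] == 1

    def test_svm_linear_grid_executes_18_fits_per_group(self):
        x, y, g = _separable_data(n_groups=3)
        spec = ea.ModelSpec("svm_linear")
        assert len(enumerate_candidates(spec)) == 18
        _, info = ea.grid_search(spec, x, y, g, seed=0)
        assert info["n_fits"] == 18 * 3

    def test_failing_grid_point_scores_zero_not_fatal(self):
        x, y, g = _separable_data()
        spec = ea.ModelSpec(
            "random_forest",
            grid={
                "n_estimators": [5],
                "bootstrap": [False, True],
                "oob_score": [True],  # invalid with bootstrap=False
            },
        )
        params, _ = ea.grid_search(spec, x, y, g, seed=0)
        assert params["bootstrap"] is True

    def test_budgeted_random_draws_are_deterministic(self):
        spec = ea.ModelSpec("mlp", search="budgeted_random", budget=5)
        a = enumerate_candidates(spec, seed=11)
        b = enumerate_candidates(spec, seed=11)
        c = enumerate_candidates(spec, seed=12)
        assert a == b
        assert len(a) == 5
        assert a != c


def _tiny_matrix(n_groups=2, n_per=6, seed=0):
    rng = np.random.default_rng(seed)
    n = n_groups * n_per
    frame = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"f{i}" for i in range(6)])
    labels = np.tile([0, 1], n // 2)
    frame["f0"] += 3.0 * (2 * labels - 1)
    frame["label"] = labels
    frame["group"] = [f"G{i // n_per}" for i in range(n)]
    return frame


class TestRunGom:
    def test_minimal_sweep_shape(self):
        frame = _tiny_matrix()
        rep = ea.run_gom(
            frame,
            roster=[ea.ModelSpec("knn", grid={"n_neighbors": [5]})],
            percentiles=(50,),
            seed=0,
        )
        assert rep.n_cv_evaluations == 2  # 2 groups x 1 model x 1 percentile
        assert len(rep.rows) == 1
        assert len(rep.cells) == 1
        assert rep.rows[0].percentile == 50

    def test_cell_and_row_accounting(self):
        frame = _tiny_matrix(n_groups=3)
        roster = [
            ea.ModelSpec("knn", grid={"n_neighbors": [5]}),
            ea.ModelSpec("svm_linear", grid={"kernel": ["linear"], "C": [1]}),
        ]
        rep = ea.run_gom(frame, roster=roster, percentiles=(5, 50, 100), seed=0)
        assert len(rep.cells) == 6
        assert len(rep.rows) == 2
        assert rep.n_cv_evaluations == 2 * 3 * 3
        assert {r.model_family for r in rep.rows} == {"knn", "svm_linear"}
        assert all(c.percentile in ea.PERCENTILE_GRID for c in rep.cells)

    def test_report_is_deterministic_for_fixed_seed(self):
        frame = _tiny_matrix(n_groups=3, seed=4)
        roster = [ea.ModelSpec("svm_linear", grid={"kernel": ["linear"], "C": [0.1, 1]})]
        a = ea.run_gom(frame, roster=roster, percentiles=(5, 100), seed=9)
        b = ea.run_gom(frame, roster=roster, percentiles=(5, 100), seed=9)
        fa, fb = a.to_frame(), b.to_frame()
        pd.testing.assert_frame_equal(
            fa.drop(columns="pred_time_s"), fb.drop(columns="pred_time_s")
        )

    def test_strict_mode_fold_transforms_ignore_heldout_rows(self):
        frame = _tiny_matrix(n_groups=3, seed=2)
        cols = [c for c in frame.columns if c.startswith("f")]
        y = frame["label"].to_numpy()
        splits = ea.logo_splits(frame["group"].to_numpy())

        corrupted = frame.copy()
        mask = corrupted["group"] == "G0"
        corrupted.loc[mask, cols] = corrupted.loc[mask, cols] * 1e6

        folds_a = _prepare_fold_data(frame[cols], y, splits, (50,), "strict")(50)
        folds_b = _prepare_fold_data(corrupted[cols], y, splits, (50,), "strict")(50)
        # fold 0 holds out G0: its training side must be identical
        np.testing.assert_array_equal(folds_a[0][0], folds_b[0][0])

        # paper mode leaks: the same training block differs once G0 is corrupted
        paper_a = _prepare_fold_data(frame[cols], y, splits, (50,), "paper")(50)
        paper_b = _prepare_fold_data(corrupted[cols], y, splits, (50,), "paper")(50)
        assert not np.array_equal(paper_a[0][0], paper_b[0][0])

    def test_label_permutation_gives_chance_accuracy(self, planted_features):
        rng = np.random.default_rng(0)
        shuffled = planted_features.copy()
        for g in shuffled["group"].unique():
            idx = shuffled.index[shuffled["group"] == g]
            shuffled.loc[idx, "label"] = rng.permutation(shuffled.loc[idx, "label"].to_numpy())
        rep = ea.run_gom(
            shuffled,
            roster=[ea.ModelSpec("svm_linear", grid={"kernel": ["linear"], "C": [1]})],
            percentiles=(5,),
            seed=0,
        )
        assert 0.35 <= rep.rows[0].accuracy <= 0.65

    def test_ranking_is_total_order_by_accuracy(self):
        frame = _tiny_matrix(n_groups=3, seed=6)
        roster = [
            ea.ModelSpec("knn", grid={"n_neighbors": [5]}),
            ea.ModelSpec("svm_linear", grid={"kernel": ["linear"], "C": [1]}),
            ea.ModelSpec("decision_tree", grid={"criterion": ["entropy"], "max_depth": [3]}),
        ]
        rep = ea.run_gom(frame, roster=roster, percentiles=(50,), seed=0)
        accs = [r.accuracy for r in rep.rows]
        assert accs == sorted(accs, reverse=True)


def test_published_grid_sizes():
    sizes = {f: len(enumerate_candidates(ea.ModelSpec(f))) for f in ea.MODEL_FAMILIES if f != "mlp"}
    assert sizes["svm_linear"] == 3 * 3 * 2
    assert sizes["svm_poly"] == 3 * 3 * 2 * 3 * 2
    assert sizes["svm_rbf"] == 3 * 2 * 3 * 2
    assert sizes["svm_sigmoid"] == 3 * 2 * 3 * 2
    assert sizes["decision_tree"] == 2 * 6 * 4 * 4 * 4 * 4
    assert sizes["random_forest"] == 2 * 3 * 2 * 2 * 2
    assert sizes["knn"] == 3 * 2 * 4 * 3 * 3
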