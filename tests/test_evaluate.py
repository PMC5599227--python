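import numpy as np
import pytest

from nirsbci.evaluate import (
    GridSpec,
    SVMPipeline,
    cross_validate,
    fold_indices,
    grid_search,
    learning_curve,
    stratified_kfold,
)
from nirsbci.exceptions import ParameterError
from nirsbci.models import SVMSpec


def _labels_100_50_50():
    return np.array(["rest"] * 100 + ["right"] * 50 + ["left"] * 50)


class TestStratifiedKFold:
    def test_design_counts_k10(self):
        y = _labels_100_50_50()
        fold_of = stratified_kfold(y, k=10, seed=0)
        for fold in range(10):
            test = y[fold_of == fold]
            assert (test == "rest").sum() == 10
            assert (test == "right").sum() == 5
            assert (test == "left").sum() == 5

    def test_leave_one_out(self):
        y = np.array(["rest", "rest", "right", "left"])
        fold_of = stratified_kfold(y, k=4, seed=0)
        assert sorted(np.bincount(fold_of, minlength=4).tolist()) == [1, 1, 1, 1]

    def test_partition_property(self):
        y = _labels_100_50_50()
        fold_of = stratified_kfold(y, k=7, seed=1)
        all_test = np.concatenate([np.flatnonzero(fold_of == f) for f in range(7)])
        assert sorted(all_test.tolist()) == list(range(200))
        for f in range(7):
            train, test = fold_indices(fold_of, f)
            assert set(train) & set(test) == set()
            assert len(train) + len(test) == 200

    def test_per_class_counts_differ_at_most_one(self):
        y = _labels_100_50_50()
        fold_of = stratified_kfold(y, k=3, seed=2)
        for cls in ("rest", "right", "left"):
            counts = [np.sum((fold_of == f) & (y == cls)) for f in range(3)]
            assert max(counts) - min(counts) <= 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ParameterError, match="exceeds"):
            stratified_kfold(["rest", "left"], k=3)

    def test_same_seed_same_assignment(self):
        y = _labels_100_50_50()
        np.testing.assert_array_equal(
            stratified_kfold(y, 10, seed=5), stratified_kfold(y, 10, seed=5))


class _Memorizer:
    """Nearest-row lookup: perfect on any data without duplicate rows."""

    def fit(self, x, y):
        self.x, self.y = x.copy(), np.asarray(y).copy()
        return self

    def predict(self, x):
        idx = [int(np.argmin(np.sum((self.x - row) ** 2, axis=1))) for row in x]
        return self.y[idx]


class _MajorityDummy:
    def fit(self, x, y):
        vals, counts = np.unique(np.asarray(y), return_counts=True)
        self.majority = vals[np.argmax(counts)]
        return self

    def predict(self, x):
        return np.full(len(x), self.majority)


class _Failer:
    def fit(self, x, y):
        raise RuntimeError("broken fold")

    def predict(self, x):  # pragma: no cover
        raise RuntimeError


class TestCrossValidate:
    def _data(self, seed=0):
        rng = np.random.default_rng(seed)
        y = _labels_100_50_50()
        x = rng.standard_normal((200, 6)) + (y == "right")[:, None]
        return x, y

    def test_memorizer_scores_one_on_separable_data(self):
        rng = np.random.default_rng(1)
        y = _labels_100_50_50()
        x = rng.standard_normal((200, 4))
        x[:, 0] += np.select([y == "rest", y == "right", y == "left"],
                             [0.0, 100.0, -100.0])
        report = cross_validate(_Memorizer, x, y, k=10, seed=0)
        assert report.mean_accuracy == pytest.approx(1.0)

    def test_majority_dummy_scores_class_prior(self):
        x, y = self._data()
        report = cross_validate(_MajorityDummy, x, y, k=10, seed=0)
        assert report.mean_accuracy == pytest.approx(0.5)

    def test_mean_equals_fold_mean(self):
        x, y = self._data()
        report = cross_validate(_MajorityDummy, x, y, k=8, seed=3)
        assert report.mean_accuracy == pytest.approx(
            float(np.mean(report.fold_accuracies)))
        assert report.k == 8 == len(report.fold_accuracies)

    def test_failed_fold_marked(self):
        x, y = self._data()
        report = cross_validate(_Failer, x, y, k=5, seed=0)
        assert report.failed_folds == (0, 1, 2, 3, 4)
        assert np.isnan(report.mean_accuracy)

    def test_same_seed_identical_report(self):
        x, y = self._data()
        r1 = cross_validate(_MajorityDummy, x, y, k=10, seed=4)
        r2 = cross_validate(_MajorityDummy, x, y, k=10, seed=4)
        assert r1.fold_accuracies == r2.fold_accuracies


class TestLeakage:
    def test_poisoning_held_out_rows_never_changes_fitted_statistics(self):
        """Corrupting test-fold rows must not affect training-fold fits."""
        rng = np.random.default_rng(7)
        y = _labels_100_50_50()
        x = rng.standard_normal((200, 12))
        fold_of = stratified_kfold(y, k=5, seed=0)
        train_idx, test_idx = fold_indices(fold_of, 0)

        pipe_clean = SVMPipeline(SVMSpec(n_components=4), seed=0)
        pipe_clean.fit(x[train_idx], y[train_idx])

        poisoned = x.copy()
        poisoned[test_idx] = 1e6
        pipe_poisoned = SVMPipeline(SVMSpec(n_components=4), seed=0)
        pipe_poisoned.fit(poisoned[train_idx], y[train_idx])

        np.testing.assert_array_equal(pipe_clean.minmax_.col_min,
                                      pipe_poisoned.minmax_.col_min)
        np.testing.assert_array_equal(pipe_clean.minmax_.col_max,
                                      pipe_poisoned.minmax_.col_max)
        np.testing.assert_array_equal(pipe_clean.pca_.components_,
                                      pipe_poisoned.pca_.components_)

    def test_label_permutation_null(self):
        """Accuracy with permuted labels stays within the 95% binomial band
        of the majority-class rate (0.5 for the 2:1:1 design)."""
        rng = np.random.default_rng(8)
        y = _labels_100_50_50()
        x = rng.standard_normal((200, 10)) + (y == "right")[:, None] * 3
        y_perm = rng.permutation(y)
        report = cross_validate(
            lambda: SVMPipeline(SVMSpec(n_components=5), seed=0),
            x, y_perm, k=10, seed=0)
        half_width = 1.96 * np.sqrt(0.25 / 200)
        assert abs(report.mean_accuracy - 0.5) <= half_width


class TestGridSearch:
    def _data(self):
        rng = np.random.default_rng(2)
        y = np.array(["rest", "right", "left"] * 20)
        x = rng.standard_normal((60, 6))
        x[:, 0] += np.select([y == "rest", y == "right", y == "left"],
                             [0.0, 4.0, -4.0])
        return x, y

    def test_singleton_grid_returns_that_point(self):
        x, y = self._data()
        grid = GridSpec(svm_c_grid=(1.0,), pca_components_grid=(3,))
        result = grid_search(SVMSpec(), grid, x, y, k=5, seed=0)
        assert result.best_hyperparameters == {
            "n_components": 3, "c_regularization": 1.0}

    def test_one_report_per_grid_point(self):
        x, y = self._data()
        grid = GridSpec(svm_c_grid=(0.1, 1.0), pca_components_grid=(2, 3, 4))
        result = grid_search(SVMSpec(), grid, x, y, k=5, seed=0)
        assert len(result.reports) == 6

    def test_known_best_point_selected(self):
        """Exhaustive oracle: recompute every grid point's CV accuracy and
        verify the returned argmax matches."""
        x, y = self._data()
        grid = GridSpec(svm_c_grid=(0.01, 1.0), pca_components_grid=(1, 4))
        result = grid_search(SVMSpec(), grid, x, y, k=5, seed=0)
        best_by_oracle = max(
            result.reports,
            key=lambda r: (r.mean_accuracy,),
        )
        assert result.best_report.mean_accuracy == best_by_oracle.mean_accuracy

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError, match="non-empty"):
            GridSpec(svm_c_grid=())


class TestLearningCurve:
    def _data(self):
        rng = np.random.default_rng(3)
        y = _labels_100_50_50()
        x = rng.standard_normal((200, 6)) + np.select(
            [y == "rest", y == "right", y == "left"], [0.0, 2.0, -2.0])[:, None]
        return x, y

    def test_full_size_equals_cross_validate(self):
        x, y = self._data()
        factory = lambda: SVMPipeline(SVMSpec(n_components=3), seed=0)
        curve = learning_curve(factory, x, y, sizes=[200], k=5, seed=9, repeats=1)
        direct = cross_validate(factory, x, y, k=5, seed=9)
        assert curve[200] == pytest.approx(direct.mean_accuracy)

    def test_zero_repeats_rejected(self):
        x, y = self._data()
        with pytest.raises(ParameterError, match="repeats"):
            learning_curve(lambda: _MajorityDummy(), x, y, sizes=[100],
                           k=5, seed=0, repeats=0)

    def test_too_small_size_skipped_with_warning(self):
        x, y = self._data()
        with pytest.warns(UserWarning, match="skipped"):
            curve = learning_curve(lambda: _MajorityDummy(), x, y,
                                   sizes=[3, 100], k=5, seed=0, repeats=1)
        assert 3 not in curve and 100 in curve

    def test_subsample_preserves_class_ratio(self):
        x, y = self._data()
        curve = learning_curve(lambda: _MajorityDummy(), x, y,
                               sizes=[40, 80], k=5, seed=0, repeats=2)
        # majority dummy accuracy equals the rest-class share when the
        # 2:1:1 ratio is preserved in every subsample
        for size, acc in curve.items():
            assert acc == pytest.approx(0.5, abs=0.01)
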