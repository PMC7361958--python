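"""Classifier bank, fold construction, and accuracy aggregation."""

import numpy as np
import pytest

from eegdx import (
    ClassifierSpec,
    ContractError,
    FoldError,
    LabeledFeatures,
    ParameterError,
    TrainingError,
    kfold_cross_validate,
    make_folds,
    predict,
    run_grid,
    train,
)

ALL_KINDS = ("lda", "svm_linear_ova", "knn", "ann")


def _blobs(rng, n_per=50, sep=10.0, n_classes=2, dim=2):
    """Well-separated Gaussian blobs (class means sep sigmas apart)."""
    xs, ys = [], []
    for c in range(n_classes):
        centre = np.zeros(dim)
        centre[c % dim] = c * sep
        xs.append(rng.standard_normal((n_per, dim)) + centre)
        ys.extend([["neurotypical", "epilepsy", "autism"][c]] * n_per)
    return LabeledFeatures(matrix=np.vstack(xs), labels=np.array(ys))


class TestTrainPredict:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_separated_blobs_resubstitution_perfect(self, kind, rng):
        data = _blobs(rng)
        model = train(ClassifierSpec(kind=kind, seed=0), data)
        pred = predict(model, data)
        assert np.mean(pred == data.labels) == 1.0

    def test_knn_k1_memorizes_training_set(self, rng):
        data = _blobs(rng, sep=1.0)  # even overlapping classes
        model = train(ClassifierSpec(kind="knn", k_neighbors=1), data)
        assert np.array_equal(predict(model, data), data.labels)

    def test_single_class_rejected(self, rng):
        data = LabeledFeatures(
            matrix=rng.standard_normal((10, 2)),
            labels=np.array(["epilepsy"] * 10),
        )
        with pytest.raises(TrainingError):
            train(ClassifierSpec(kind="lda"), data)

    def test_nonfinite_features_rejected(self):
        data = LabeledFeatures(
            matrix=np.array([[1.0, np.nan], [0.0, 1.0]]),
            labels=np.array(["a", "b"]),
        )
        with pytest.raises(TrainingError):
            train(ClassifierSpec(kind="svm_linear_ova"), data)

    def test_knn_midpoint_tie_breaks_to_first_class(self):
        # two training points, one per class, probe at the exact midpoint:
        # votes and distances tie, so the fixed (sorted) class order decides
        data = LabeledFeatures(
            matrix=np.array([[0.0], [2.0]]),
            labels=np.array(["epilepsy", "neurotypical"]),
        )
        model = train(
            ClassifierSpec(kind="knn", k_neighbors=2, standardize=False), data
        )
        assert predict(model, np.array([[1.0]]))[0] == "epilepsy"

    def test_dimension_mismatch_rejected(self, rng):
        data = _blobs(rng)
        model = train(ClassifierSpec(kind="lda"), data)
        with pytest.raises(ContractError):
            predict(model, rng.standard_normal((3, 5)))

    def test_predictions_limited_to_training_classes(self, rng):
        data = _blobs(rng, n_classes=3, dim=3)
        for kind in ALL_KINDS:
            model = train(ClassifierSpec(kind=kind, seed=1), data)
            pred = predict(model, rng.standard_normal((20, 3)) * 30)
            assert set(pred) <= set(model.classes)

    def test_training_is_deterministic_per_seed(self, rng):
        data = _blobs(rng, n_classes=3, dim=3, sep=2.0)
        probe = rng.standard_normal((50, 3))
        for kind in ALL_KINDS:
            a = predict(train(ClassifierSpec(kind=kind, seed=42), data), probe)
            b = predict(train(ClassifierSpec(kind=kind, seed=42), data), probe)
            assert np.array_equal(a, b)


class TestFolds:
    def test_partition_disjoint_and_exhaustive(self, rng):
        labels = np.array(["a"] * 55 + ["b"] * 45)
        folds = make_folds(labels, k=10, seed=3)
        seen = np.concatenate([te for _, te in folds])
        assert len(seen) == 100
        assert len(np.unique(seen)) == 100
        for tr, te in folds:
            assert set(tr) | set(te) == set(range(100))
            assert not set(tr) & set(te)

    def test_stratified_fold_proportions(self, rng):
        labels = np.array(["a"] * 60 + ["b"] * 40)
        folds = make_folds(labels, k=10, seed=0, stratified=True)
        for _, te in folds:
            n_a = int(np.sum(labels[te] == "a"))
            assert abs(n_a - 6) <= 1
            assert abs((len(te) - n_a) - 4) <= 1

    def test_small_class_under_stratification_rejected(self):
        labels = np.array(["a"] * 50 + ["b"] * 5)
        with pytest.raises(FoldError, match="members per class"):
            make_folds(labels, k=10, seed=0, stratified=True)

    def test_group_folds_never_split_a_subject(self, rng):
        labels = np.array(["a", "b"] * 50)
        groups = np.repeat([f"s{i}" for i in range(20)], 5)
        folds = make_folds(labels, k=5, seed=1, groups=groups)
        for tr, te in folds:
            assert not set(groups[tr]) & set(groups[te])

    def test_leave_one_out_fold_count(self):
        labels = np.array(["a", "b"] * 10)
        folds = make_folds(labels, k=20, seed=0, stratified=False)
        assert len(folds) == 20
        assert all(len(te) == 1 for _, te in folds)


class TestCrossValidation:
    def test_one_hot_features_give_perfect_accuracy(self):
        labels = np.array(["neurotypical", "epilepsy", "autism"] * 20)
        classes = sorted(set(labels))
        onehot = np.array([[1.0 if l == c else 0.0 for c in classes] for l in labels])
        data = LabeledFeatures(matrix=onehot, labels=labels)
        for kind in ("lda", "svm_linear_ova", "knn"):
            res = kfold_cross_validate(data, ClassifierSpec(kind=kind, seed=0),
                                       k=10, seed=0)
            assert res.mean_accuracy == 100.0

    def test_permuted_labels_give_chance_accuracy(self, rng):
        x = rng.standard_normal((200, 4))
        labels = np.array(["a", "b"] * 100)
        rng.shuffle(labels)
        data = LabeledFeatures(matrix=x, labels=labels)
        res = kfold_cross_validate(data, ClassifierSpec(kind="knn", seed=0),
                                   k=10, seed=0)
        assert 40.0 <= res.mean_accuracy <= 60.0

    def test_mean_is_exact_arithmetic_mean_of_folds(self, rng):
        data = _blobs(rng, n_per=30, sep=1.5)
        res = kfold_cross_validate(data, ClassifierSpec(kind="knn", seed=0),
                                   k=6, seed=4)
        assert res.mean_accuracy == sum(res.fold_accuracies) / res.k
        assert res.k == len(res.fold_accuracies) == 6

    def test_confusion_trace_equals_total_correct(self, rng):
        data = _blobs(rng, n_per=30, sep=1.0, n_classes=3, dim=3)
        res = kfold_cross_validate(data, ClassifierSpec(kind="lda"), k=5, seed=2)
        expected_correct = round(
            sum(a / 100.0 * 18 for a in res.fold_accuracies)
        )
        assert res.total_correct == int(np.trace(res.confusion))
        assert res.total_correct == expected_correct
        assert res.total_count == 90
        # confusion row sums = per-class held-out counts
        assert np.array_equal(res.confusion.sum(axis=1), [30, 30, 30])

    def test_standardization_fit_on_training_fold_only(self, rng):
        # the stored scaler must equal the training matrix's own moments
        data = _blobs(rng)
        model = train(ClassifierSpec(kind="knn", standardize=True), data)
        assert np.allclose(model._scaler_mean, data.matrix.mean(axis=0))
        assert np.allclose(model._scaler_scale, data.matrix.std(axis=0))


class TestRunGrid:
    def _feature_data(self, rng, n=60):
        """Tiny feature table with ordering metadata over two statistics."""
        labels = np.array(["neurotypical", "epilepsy"] * (n // 2))
        shift = (labels == "epilepsy").astype(float)[:, None] * 5
        matrix = rng.standard_normal((n, 4)) + np.hstack([shift] * 4)
        ordering = (
            ("ch0", "D1", "lbp"), ("ch0", "A4", "lbp"),
            ("ch0", "D1", "entropy"), ("ch0", "A4", "entropy"),
        )
        return LabeledFeatures(matrix=matrix, labels=labels, ordering=ordering)

    def test_grid_has_one_cell_per_combination(self, rng):
        data = self._feature_data(rng)
        table, results = run_grid(
            data, ["lbp", "entropy"], ["lda", "knn"], k=5, seed=1
        )
        assert len(table) == 4
        assert set(results) == {
            ("lbp", "lda"), ("lbp", "knn"), ("entropy", "lda"), ("entropy", "knn"),
        }

    def test_grid_deterministic_for_same_seed(self, rng):
        data = self._feature_data(rng)
        t1, _ = run_grid(data, ["lbp"], ["lda", "knn", "svm_linear_ova"],
                         k=5, seed=9)
        t2, _ = run_grid(data, ["lbp"], ["lda", "knn", "svm_linear_ova"],
                         k=5, seed=9)
        assert t1.equals(t2)

    def test_separable_grid_all_perfect(self, rng):
        data = self._feature_data(rng)
        table, _ = run_grid(data, ["lbp", "entropy"], ["lda", "knn"], k=5, seed=0)
        assert (table["mean_accuracy"] == 100.0).all()

    def test_unknown_component_rejected(self, rng):
        data = self._feature_data(rng)
        with pytest.raises(ParameterError):
            run_grid(data, ["power"], ["lda"], k=5, seed=0)
        with pytest.raises(ParameterError):
            run_grid(data, ["lbp"], ["forest"], k=5, seed=0)

    def test_select_statistic_slices_columns(self, rng):
        data = self._feature_data(rng)
        sub = data.select_statistic("entropy")
        assert sub.matrix.shape == (60, 2)
        assert all(s == "entropy" for _, _, s in sub.ordering)
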