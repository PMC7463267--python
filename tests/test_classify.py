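import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from pssmfold import LabeledDataset, evaluate, grid_search_train, predict
from pssmfold.classify import (
    SelectionConfig,
    apply_scaler,
    cross_validated_report,
    fit_scaler,
    load_model,
    save_model,
)


def _toy_dataset(rng, n_classes=3, n_per_class=20, n_features=8, sep=4.0):
    """Well-separated Gaussian blobs as a stand-in feature matrix."""
    rows, labels = [], []
    for c in range(n_classes):
        center = np.zeros(n_features)
        center[c % n_features] = sep * (c + 1)
        rows.append(rng.normal(0, 1.0, (n_per_class, n_features)) + center)
        labels += [f"fold{c + 1}"] * n_per_class
    return LabeledDataset(
        matrix=np.vstack(rows),
        protein_ids=[f"p{i}" for i in range(n_classes * n_per_class)],
        labels=labels,
        feature_ids=[f"f{j}" for j in range(n_features)],
    )


class TestScaler:
    def test_midpoint_maps_to_zero(self):
        params = fit_scaler(np.array([[2.0], [6.0]]))
        assert apply_scaler(params, np.array([[4.0]]))[0, 0] == pytest.approx(0.0)

    def test_constant_feature_maps_to_zero(self):
        params = fit_scaler(np.array([[3.0], [3.0]]))
        out = apply_scaler(params, np.array([[3.0], [99.0]]))
        np.testing.assert_array_equal(out, 0.0)

    def test_training_data_bounded(self, rng):
        m = rng.normal(size=(30, 5)) * 10
        out = apply_scaler(fit_scaler(m), m)
        assert out.min() >= -1.0 - 1e-12 and out.max() <= 1.0 + 1e-12

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            fit_scaler(np.empty((0, 3)))


class TestEvaluate:
    def test_perfect_predictions(self):
        labels = ["a", "b", "c"] * 4
        report = evaluate(labels, labels, ["a", "b", "c"])
        np.testing.assert_array_equal(np.diagonal(report.confusion_matrix), 4)
        assert report.accuracy == 1.0
        np.testing.assert_allclose(report.sensitivity, 1.0)
        np.testing.assert_allclose(report.precision, 1.0)
        np.testing.assert_allclose(report.f1, 1.0)

    def test_hand_computed_counts(self):
        # class A: TP=9, FN=1, FP=2
        truth = ["A"] * 10 + ["B"] * 3
        pred = ["A"] * 9 + ["B"] + ["A", "A", "B"]
        report = evaluate(truth, pred, ["A", "B"])
        assert report.sensitivity[0] == pytest.approx(0.9)
        assert report.precision[0] == pytest.approx(9 / 11, abs=1e-4)
        assert report.f1[0] == pytest.approx(18 / 21, abs=1e-4)

    def test_degenerate_single_class_predictor(self):
        truth = ["x"] * 5 + ["y"] * 5
        pred = ["x"] * 10
        report = evaluate(truth, pred, ["x", "y"])
        assert report.accuracy == pytest.approx(0.5)
        assert report.precision[0] == pytest.approx(0.5)
        assert report.f1[1] == 0.0

    def test_absent_class_flagged(self):
        report = evaluate(["a", "a"], ["a", "b"], ["a", "b"])
        assert report.undefined_sensitivity[1]
        assert report.sensitivity[1] == 0.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="not in class_labels"):
            evaluate(["a"], ["z"], ["a", "b"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            evaluate(["a", "b"], ["a"], ["a", "b"])

    def test_row_sums_and_total(self, rng):
        classes = ["a", "b", "c"]
        truth = rng.choice(classes, 60)
        pred = rng.choice(classes, 60)
        report = evaluate(truth, pred, classes)
        for i, lab in enumerate(classes):
            assert report.confusion_matrix[i].sum() == (truth == lab).sum()
        assert report.confusion_matrix.sum() == 60
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion_matrix) / 60
        )

    def test_macro_f1_permutation_invariant(self, rng):
        classes = ["a", "b", "c"]
        truth = rng.choice(classes, 50).tolist()
        pred = rng.choice(classes, 50).tolist()
        base = evaluate(truth, pred, classes).macro_f1
        swap = {"a": "c", "b": "a", "c": "b"}
        permuted = evaluate(
            [swap[t] for t in truth], [swap[p] for p in pred], classes
        ).macro_f1
        assert base == pytest.approx(permuted, abs=1e-12)

    def test_matches_sklearn_oracle(self, rng):
        classes = ["a", "b", "c", "d"]
        truth = rng.choice(classes, 80)
        pred = rng.choice(classes, 80)
        report = evaluate(truth, pred, classes)
        prec, rec, f1, _ = precision_recall_fscore_support(
            truth, pred, labels=classes, zero_division=0
        )
        np.testing.assert_allclose(report.precision, prec, atol=1e-12)
        np.testing.assert_allclose(report.sensitivity, rec, atol=1e-12)
        np.testing.assert_allclose(report.f1, f1, atol=1e-12)


class TestGridSearchTrain:
    def test_single_point_grid(self, rng):
        data = _toy_dataset(rng)
        model, table = grid_search_train(
            data, c_exponents=[3], gamma_exponents=[-2], folds=4, selection=None
        )
        assert model.c == 2.0 ** 3
        assert model.gamma == 2.0 ** -2
        assert len(table) == 1

    def test_tie_breaks_to_smaller_c_then_gamma(self, rng):
        # cleanly separable data: every grid point reaches identical accuracy
        data = _toy_dataset(rng, sep=50.0)
        model, table = grid_search_train(
            data, c_exponents=[0, 4], gamma_exponents=[-4, -2],
            folds=3, selection=None,
        )
        top = table["mean_cv_accuracy"].max()
        winners = table[table["mean_cv_accuracy"] == top]
        assert model.c == winners["C"].min()
        sub = winners[winners["C"] == model.c]
        assert model.gamma == sub["gamma"].min()

    def test_single_class_is_error(self, rng):
        data = _toy_dataset(rng, n_classes=1)
        data = LabeledDataset(
            matrix=data.matrix,
            protein_ids=data.protein_ids,
            labels=["same"] * data.n_samples,
            feature_ids=data.feature_ids,
        )
        with pytest.raises(ValueError, match="2 classes"):
            grid_search_train(data, [0], [0])

    def test_empty_grid_is_error(self, rng):
        with pytest.raises(ValueError, match="grid"):
            grid_search_train(_toy_dataset(rng), [], [0])

    def test_folds_reduced_for_small_classes(self, rng, caplog):
        data = _toy_dataset(rng, n_per_class=4)
        model, _ = grid_search_train(
            data, [0], [-3], folds=10, selection=None
        )
        assert model.metadata["folds"] == 4

    def test_tuned_beats_untuned_corner(self, rng):
        data = _toy_dataset(rng, sep=2.0)
        model, table = grid_search_train(
            data, c_exponents=range(-6, 5, 2), gamma_exponents=range(-8, 1, 2),
            folds=4, selection=None,
        )
        corner = table[
            (table["c_exponent"] == -6) & (table["gamma_exponent"] == -8)
        ]["mean_cv_accuracy"].iloc[0]
        assert model.metadata["best_mean_cv_accuracy"] >= corner

    def test_determinism(self, rng):
        data = _toy_dataset(rng)
        m1, t1 = grid_search_train(data, [-2, 2], [-4, 0], folds=4, seed=9)
        m2, t2 = grid_search_train(data, [-2, 2], [-4, 0], folds=4, seed=9)
        assert (m1.c, m1.gamma) == (m2.c, m2.gamma)
        assert t1.equals(t2)

    def test_selection_inside_cv_runs(self, rng):
        data = _toy_dataset(rng, n_features=12)
        model, _ = grid_search_train(
            data, [0], [-3], folds=3,
            selection=SelectionConfig(n_bins=5, band_fraction=0.5),
        )
        assert 0 < len(model.feature_ids) <= 12
        assert set(model.feature_ids) <= set(data.feature_ids)


class TestPredict:
    def test_training_labels_reproduced_on_separable_data(self, rng):
        data = _toy_dataset(rng, n_classes=2, sep=10.0)
        model, _ = grid_search_train(data, [4], [-2], folds=3, selection=None)
        assert predict(model, data) == data.labels

    def test_k2_reduces_to_binary_machine(self, rng):
        data = _toy_dataset(rng, n_classes=2, sep=10.0)
        model, _ = grid_search_train(data, [2], [-2], folds=3, selection=None)
        assert len(model.svm.classes_) == 2
        preds = predict(model, data)
        assert set(preds) <= set(data.labels)

    def test_ovo_vote_matches_sklearn_on_clean_data(self, rng):
        data = _toy_dataset(rng, n_classes=4, sep=8.0)
        model, _ = grid_search_train(data, [2], [-3], folds=3, selection=None)
        x = apply_scaler(model.scaler, data.matrix)
        np.testing.assert_array_equal(
            predict(model, data), model.svm.predict(x)
        )

    def test_column_permutation_invariance(self, rng):
        data = _toy_dataset(rng)
        model, _ = grid_search_train(data, [2], [-3], folds=3, selection=None)
        perm = rng.permutation(data.n_features)
        shuffled = LabeledDataset(
            matrix=data.matrix[:, perm],
            protein_ids=data.protein_ids,
            labels=data.labels,
            feature_ids=[data.feature_ids[j] for j in perm],
        )
        assert predict(model, data) == predict(model, shuffled)

    def test_missing_features_listed(self, rng):
        data = _toy_dataset(rng)
        model, _ = grid_search_train(data, [2], [-3], folds=3, selection=None)
        partial = data.subset_features(data.feature_ids[:3])
        with pytest.raises(ValueError, match="missing"):
            predict(model, partial)


class TestCrossValidatedReport:
    def test_report_totals(self, rng):
        data = _toy_dataset(rng)
        report = cross_validated_report(
            data, c=4.0, gamma=0.125, folds=4, selection=None
        )
        assert report.confusion_matrix.sum() == data.n_samples
        assert report.accuracy > 0.9  # separable blobs


class TestPersistence:
    def test_round_trip(self, rng, tmp_path):
        data = _toy_dataset(rng)
        model, _ = grid_search_train(data, [2], [-3], folds=3, selection=None)
        save_model(model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        assert loaded.c == model.c and loaded.gamma == model.gamma
        assert loaded.feature_ids == model.feature_ids
        assert loaded.class_labels == model.class_labels
        assert predict(loaded, data) == predict(model, data)

    def test_tampered_archive_rejected(self, rng, tmp_path):
        data = _toy_dataset(rng)
        model, _ = grid_search_train(data, [2], [-3], folds=3, selection=None)
        save_model(model, tmp_path / "model")
        blob = tmp_path / "model" / "machinery.joblib"
        blob.write_bytes(blob.read_bytes() + b"x")
        with pytest.raises(ValueError, match="hash mismatch"):
            load_model(tmp_path / "model")
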