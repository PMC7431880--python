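"""Classifier panel, cross-validation, metrics, and paired comparison."""

import numpy as np
import pytest
from scipy import stats

from phasetrack.classify import (
    CLASSIFIER_NAMES,
    build_classifier,
    compare_approaches,
    confusion_metrics,
    cross_validate,
    make_splits,
    run_benchmark,
)


def blobs(n=50, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0.0, 1.0, (n, 2)), rng.normal(sep, 1.0, (n, 2))]
    )
    y = np.array(["epithelial"] * n + ["mesenchymal"] * n)
    return X, y


class TestBuildClassifier:
    def test_all_nineteen_constructible(self):
        assert len(CLASSIFIER_NAMES) == 19
        for name in CLASSIFIER_NAMES:
            model = build_classifier(name, seed=0, n_features=10)
            assert hasattr(model, "fit")

    def test_cubic_svm_uses_degree_three(self):
        assert build_classifier("svm-cubic").degree == 3

    def test_weighted_knn_configuration(self):
        model = build_classifier("knn-weighted")
        assert model.n_neighbors == 10 and callable(model.weights)

    def test_neural_net_shape(self):
        model = build_classifier("neural-net")
        assert model.hidden_layer_sizes == (10,)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_classifier("svm-quartic")


class TestSplits:
    def test_partition_properties(self):
        _, y = blobs(n=50)
        splits = make_splits(y, folds=5, seed=0)
        test_sets = [set(te) for _, te in splits]
        assert all(len(te) == 20 for te in test_sets)
        assert set().union(*test_sets) == set(range(100))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not test_sets[i] & test_sets[j]

    def test_small_class_rejected(self):
        y = np.array(["a"] * 3 + ["b"] * 20)
        with pytest.raises(ValueError):
            make_splits(y, folds=5)


class TestCrossValidate:
    def test_separable_blobs_perfect_linear_svm(self):
        X, y = blobs(sep=8.0)
        report = cross_validate(X, y, ["svm-linear"], seed=0)
        assert report.metrics.loc[("feature_based", "svm-linear"), "accuracy"] == 1.0

    def test_label_shuffle_near_chance(self):
        rng = np.random.default_rng(0)
        X, y = blobs(sep=8.0)
        y = rng.permutation(y)
        report = cross_validate(X, y, CLASSIFIER_NAMES, seed=0)
        acc = report.metrics["accuracy"].to_numpy()
        assert np.all(np.abs(acc - 0.5) <= 0.12)

    def test_pooled_equals_fold_mean_for_equal_folds(self):
        X, y = blobs(n=50, sep=3.0, seed=2)
        report = cross_validate(X, y, ["lda"], seed=0)
        pooled = report.confusions[("feature_based", "lda")]
        pooled_acc = np.trace(pooled) / pooled.sum()
        fold_acc = report.metrics.loc[("feature_based", "lda"), "accuracy"]
        assert pooled_acc == pytest.approx(fold_acc, abs=1e-12)


class TestConfusionMetrics:
    def test_perfect_matrix(self):
        assert confusion_metrics(np.array([[50, 0], [0, 50]])) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_case(self):
        # rows true, cols predicted; positive class = index 1 (TP = 45)
        cm = np.array([[40, 10], [5, 45]])
        acc, prec, rec, f1 = confusion_metrics(cm, positive_index=1)
        assert acc == pytest.approx(0.85)
        assert prec == pytest.approx(45 / 55)
        assert rec == pytest.approx(0.9)
        assert f1 == pytest.approx(2 * (45 / 55) * 0.9 / (45 / 55 + 0.9))

    def test_swapping_positive_class(self):
        cm = np.array([[40, 10], [5, 45]])
        acc1, prec1, rec1, _ = confusion_metrics(cm, 1)
        acc0, prec0, rec0, _ = confusion_metrics(cm, 0)
        assert acc0 == acc1
        assert prec0 == pytest.approx(40 / 45) and rec0 == pytest.approx(0.8)

    def test_empty_denominator_convention(self):
        acc, prec, rec, f1 = confusion_metrics(np.array([[10, 0], [0, 0]]), 1)
        assert (prec, rec, f1) == (0.0, 0.0, 0.0) and acc == 1.0

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.zeros((2, 2)))


class TestCompareApproaches:
    def test_identical_vectors_p_one(self):
        v = np.linspace(0.8, 0.99, 19)
        table = compare_approaches({"a": v, "b": v.copy()})
        assert table.loc[0, "p_value"] == 1.0
        assert "zero" in table.loc[0, "note"]

    def test_uniform_shift_highly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.8, 0.95, 19)
        table = compare_approaches({"a": a, "b": a + 0.05})
        assert table.loc[0, "p_value"] < 1e-3
        # exact two-sided sign-flip bound: 2 * 2^-19 with all signs equal
        assert table.loc[0, "p_value"] >= 2 * 2.0 ** -19 - 1e-12

    def test_pair_order_does_not_change_p(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.7, 0.9, 19)
        b = a + rng.normal(0.02, 0.01, 19)
        p_ab = compare_approaches({"a": a, "b": b}).loc[0, "p_value"]
        p_ba = compare_approaches({"b": b, "a": a}).loc[0, "p_value"]
        assert p_ab == pytest.approx(p_ba)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_approaches({"a": np.ones(19), "b": np.ones(18)})

    def test_wilcoxon_matches_scipy_reference(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.7, 0.95, 19)
        b = a + rng.normal(0.0, 0.03, 19)
        ours = compare_approaches({"a": a, "b": b}).loc[0, "p_value"]
        ref = stats.wilcoxon(a, b, zero_method="wilcox").pvalue
        assert ours == pytest.approx(ref)


class TestRunBenchmark:
    def test_report_shape_and_shared_partition(self):
        rng = np.random.default_rng(0)
        n = 40
        base = np.vstack([rng.normal(0, 1, (n, 20)), rng.normal(1.2, 1, (n, 20))])
        y = np.array(["epithelial"] * n + ["mesenchymal"] * n)
        matrices = {
            "static": base[:, :8],
            "value_based": base,
            "feature_based": base + rng.normal(0, 0.1, base.shape),
        }
        report = run_benchmark(
            matrices, y, top_k={"static": 5, "value_based": 5, "feature_based": 5},
            seed=0, classifier_names=("lda", "knn-fine", "tree-medium"),
        )
        assert report.metrics.shape == (3 * 3, 4)
        assert set(report.metrics.columns) == {"accuracy", "precision", "recall", "f_score"}
        assert len(report.comparisons) == 3

    def test_mismatched_cells_rejected(self):
        y = np.array(["a"] * 10 + ["b"] * 10)
        with pytest.raises(ValueError):
            run_benchmark({"static": np.zeros((19, 3))}, y)
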