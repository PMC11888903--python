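"""Harness: splits, scaling, tuning, metric arithmetic and trial orchestration."""

import numpy as np
import pandas as pd
import pytest

from phca import (
    BlobSpec,
    ExperimentConfig,
    LabelledDataset,
    aggregate_trials,
    apply_scaler,
    default_search_space,
    evaluate,
    fit_scaler,
    make_gaussian_classes,
    misclassification_report,
    random_search_cv,
    run_trials,
    stratified_split,
)
from phca.evaluation import SearchSpace, _scale_arrays, trials_table


def dataset_from_counts(counts, n_features=2, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.concatenate([[c] * n for c, n in counts.items()])
    return LabelledDataset.from_arrays(
        rng.normal(size=(len(labels), n_features)), labels, tuple(counts))


class TestStratifiedSplit:
    def test_exact_divisibility(self):
        data = dataset_from_counts({c: 100 for c in range(24)})
        train, test = stratified_split(data, 0.1, seed=1)
        assert all(n == 10 for n in test.class_counts().values())
        assert all(n == 90 for n in train.class_counts().values())

    def test_imbalanced_rounding_within_one_row(self):
        counts = {"a": 313, "b": 290, "c": 450}
        data = dataset_from_counts(counts)
        _, test = stratified_split(data, 0.1, seed=3)
        for c, n in counts.items():
            assert abs(test.class_counts()[c] - 0.1 * n) <= 1
        assert sum(test.class_counts().values()) == round(0.1 * sum(counts.values()))

    def test_same_seed_same_partition(self):
        data = dataset_from_counts({"a": 31, "b": 17})
        a = stratified_split(data, 0.2, seed=9)
        b = stratified_split(data, 0.2, seed=9)
        assert np.array_equal(a[1].features, b[1].features)

    def test_partition_invariant_to_row_order(self):
        data = dataset_from_counts({"a": 20, "b": 12})
        rng = np.random.default_rng(0)
        perm = rng.permutation(data.n_rows)
        shuffled = LabelledDataset(data.features[perm], data.labels[perm],
                                   data.class_catalogue)
        test_a = stratified_split(data, 0.25, seed=4)[1]
        test_b = stratified_split(shuffled, 0.25, seed=4)[1]
        rows = lambda d: sorted(map(tuple, d.features))
        assert rows(test_a) == rows(test_b)

    def test_disjoint_and_exhaustive(self):
        data = dataset_from_counts({"a": 9, "b": 14})
        train, test = stratified_split(data, 0.3, seed=0)
        assert train.n_rows + test.n_rows == data.n_rows
        all_rows = sorted(map(tuple, np.vstack([train.features, test.features])))
        assert all_rows == sorted(map(tuple, data.features))

    def test_singleton_class_rejected(self):
        data = dataset_from_counts({"a": 5, "b": 1})
        with pytest.raises(ValueError):
            stratified_split(data, 0.2, seed=0)


class TestScaler:
    def test_two_point_feature(self):
        data = LabelledDataset.from_arrays([[0.0], [2.0]], ["a", "b"])
        scaled = apply_scaler(fit_scaler(data), data)
        assert scaled.features.ravel() == pytest.approx([-1.0, 1.0])

    def test_constant_feature_centered_not_divided(self):
        data = LabelledDataset.from_arrays([[5.0, 1.0], [5.0, 3.0]], ["a", "b"])
        scaled = apply_scaler(fit_scaler(data), data)
        assert scaled.features[:, 0] == pytest.approx([0.0, 0.0])

    def test_train_mean_maps_to_zero(self):
        rng = np.random.default_rng(1)
        train = LabelledDataset.from_arrays(rng.normal(size=(20, 3)),
                                            ["a"] * 10 + ["b"] * 10)
        params = fit_scaler(train)
        probe = LabelledDataset.from_arrays(params.mean[None, :], ["a"], ("a", "b"))
        assert apply_scaler(params, probe).features == pytest.approx(0.0, abs=1e-9)

    def test_transformed_training_moments(self):
        rng = np.random.default_rng(2)
        train = LabelledDataset.from_arrays(rng.normal(5, 3, size=(50, 4)), ["a"] * 50, ("a",))
        scaled = apply_scaler(fit_scaler(train), train)
        assert np.abs(scaled.features.mean(axis=0)).max() < 1e-9
        assert scaled.features.std(axis=0) == pytest.approx(np.ones(4))

    def test_fold_scaling_ignores_validation_rows(self):
        """Scaler statistics inside a fold depend only on its training part."""
        rng = np.random.default_rng(3)
        train_X = rng.normal(size=(30, 3))
        val_a = rng.normal(size=(10, 3))
        val_b = val_a * 100 + 7  # corrupted validation rows
        scaled_train_a, _ = _scale_arrays(train_X, val_a)
        scaled_train_b, sb = _scale_arrays(train_X, val_b)
        assert np.array_equal(scaled_train_a, scaled_train_b)
        # and the validation transform uses the training statistics
        assert sb == pytest.approx((val_b - train_X.mean(0)) / train_X.std(0))


class TestRandomSearch:
    def test_single_combination_space(self, separable_blobs):
        space = SearchSpace({"KNN": lambda rng: {"n_neighbors": 3}})
        params, score = random_search_cv("KNN", space, separable_blobs, n_iter=5, seed=0)
        assert params == {"n_neighbors": 3}
        assert 0.0 <= score <= 1.0

    def test_dominant_combination_wins(self, separable_blobs):
        # k=1 separates the blobs; k = n_train forces the majority class
        toggle = iter([{"n_neighbors": 135}, {"n_neighbors": 1}] * 10)
        space = SearchSpace({"KNN": lambda rng: next(toggle)})
        params, score = random_search_cv("KNN", space, separable_blobs, n_iter=4, seed=0)
        assert params == {"n_neighbors": 1}
        assert score == pytest.approx(1.0)

    def test_phca_selects_h0_when_strictly_best(self):
        # at separation 6 the three choices score 0.973 / 0.053 / 0.933 in CV
        # (computed by enumerating each choice directly), so H0 must win
        data = make_gaussian_classes(BlobSpec(n_classes=3, sizes=25,
                                              separation=6.0, seed=5))
        params, score = random_search_cv("PHCA", default_search_space(), data,
                                         n_iter=20, seed=5)
        assert params == {"homology_dimension": "H0_ONLY"}
        assert score == pytest.approx(0.9733, abs=1e-3)

    def test_reproducible_per_seed(self, separable_blobs):
        space = default_search_space()
        a = random_search_cv("CART", space, separable_blobs, n_iter=5, seed=11)
        b = random_search_cv("CART", space, separable_blobs, n_iter=5, seed=11)
        assert a == b

    def test_class_smaller_than_folds_rejected(self):
        data = dataset_from_counts({"a": 3, "b": 10})
        with pytest.raises(ValueError):
            random_search_cv("KNN", default_search_space(), data, folds=5, seed=0)


class TestEvaluate:
    def test_perfect_predictions(self):
        report = evaluate(list("ABAB"), list("ABAB"), ("A", "B"))
        assert report.as_dict() == {m: 1.0 for m in report.as_dict()}

    def test_hand_worked_two_class_example(self):
        report = evaluate(list("AAAABBBB"), list("AAABBBBB"), ("A", "B"))
        assert report.accuracy == pytest.approx(0.875)
        assert report.precision == pytest.approx(0.9)
        assert report.recall == pytest.approx(0.875)
        assert report.f1 == pytest.approx(0.87302, abs=5e-6)
        assert report.specificity == pytest.approx(0.875)

    def test_all_wrong_two_class(self):
        report = evaluate(list("AABB"), list("BBAA"), ("A", "B"))
        assert report.accuracy == 0.0
        assert report.specificity == 0.0

    def test_counts_partition_test_set(self):
        report = evaluate(list("AAABBC"), list("ABABBC"), ("A", "B", "C"))
        assert report.confusion.sum() == 6
        per_class = report.per_class[["TP", "FP", "FN", "TN"]].sum(axis=1)
        assert (per_class == 6).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(["A"], ["A", "B"], ("A", "B"))


class TestMisclassificationReport:
    def test_diagonal_matrix_is_clean(self):
        report = evaluate(list("AABB"), list("AABB"), ("A", "B"))
        assert misclassification_report(report) == []

    def test_single_cell(self):
        conf = np.array([[10, 6], [0, 10]])
        assert misclassification_report(conf, ("M", "F")) == [("M", "F", 6)]

    def test_cumulative_sum_linearity(self):
        a = evaluate(list("AAB"), list("ABB"), ("A", "B"))
        b = evaluate(list("ABB"), list("BBB"), ("A", "B"))
        summed = a.confusion + b.confusion
        assert misclassification_report(summed, ("A", "B")) == [("A", "B", 2)]

    def test_ranking_and_tie_order(self):
        conf = np.array([[0, 2, 3], [2, 0, 0], [0, 0, 0]])
        assert misclassification_report(conf, ("x", "y", "z")) == [
            ("x", "z", 3), ("x", "y", 2), ("y", "x", 2)]


@pytest.fixture(scope="module")
def phca_trials():
    def factory(seed):
        return make_gaussian_classes(BlobSpec(n_classes=3, sizes=30, seed=seed))
    config = ExperimentConfig(dataset=factory, roster=("PHCA",), n_trials=2,
                              n_iter=4, base_seed=3)
    return run_trials(config)


class TestRunTrials:
    def test_separable_blobs_classified_perfectly(self, phca_trials):
        assert phca_trials[0].metrics["PHCA"].accuracy == pytest.approx(1.0)

    def test_distinct_trials_use_distinct_splits(self, phca_trials):
        assert phca_trials[0].seed != phca_trials[1].seed

    def test_aggregate_mean_matches_per_trial_values(self, phca_trials):
        agg = aggregate_trials(phca_trials)
        table = trials_table(phca_trials)
        acc = agg[(agg.classifier == "PHCA") & (agg.metric == "accuracy")]
        expected = table[(table.classifier == "PHCA") & (table.metric == "accuracy")]["value"].mean()
        assert acc["mean"].iloc[0] == pytest.approx(expected)
        assert set(agg.columns) == {"classifier", "metric", "mean", "min", "max", "iqr"}
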