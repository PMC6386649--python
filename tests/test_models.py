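"""Split plans, collinearity filtering, metrics and the nested-CV protocol."""

import numpy as np
import pandas as pd
import pytest

from accelval.errors import UndefinedStatisticError
from accelval.models import (
    balanced_accuracy,
    confusion_matrix,
    evaluate_regression,
    feature_importance,
    gini_impurity,
    nested_split,
    remove_collinear,
    train_and_evaluate,
    train_and_evaluate_regression,
)


class TestNestedSplit:
    def test_fold_sizes_and_coverage(self):
        plan = nested_split(100, outer_folds=5, seed=0)
        tests = [f.test for f in plan.folds]
        assert all(len(t) == 20 for t in tests)
        union = np.sort(np.concatenate(tests))
        np.testing.assert_array_equal(union, np.arange(100))

    def test_each_fold_partitions_items(self):
        plan = nested_split(100, outer_folds=5, seed=3)
        for f in plan.folds:
            parts = np.sort(np.concatenate([f.train, f.validation, f.test]))
            np.testing.assert_array_equal(parts, np.arange(100))
            # validation is 20% of the 80-item development set
            assert len(f.validation) == 16

    def test_deterministic(self):
        a = nested_split(60, seed=9)
        b = nested_split(60, seed=9)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa.test, fb.test)
            np.testing.assert_array_equal(fa.train, fb.train)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            nested_split(20, outer_folds=5)

    def test_stratified_training_folds_keep_all_classes(self):
        labels = np.array(["a"] * 60 + ["b"] * 30 + ["c"] * 10)
        plan = nested_split(100, seed=4, labels=labels)
        for f in plan.folds:
            assert set(labels[f.train]) == {"a", "b", "c"}


class TestRemoveCollinear:
    def test_duplicated_feature_leaves_one(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=200)})
        kept = remove_collinear(df, 0.9)
        assert "c" in kept
        assert len([k for k in kept if k in ("a", "b")]) == 1

    def test_orthogonal_features_all_retained(self, rng):
        df = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        assert remove_collinear(df, 0.9) == list("abcd")

    def test_hub_feature_dropped_first(self, rng):
        # f1 = (f2 + f3)/sqrt(2) correlates ~0.71 with each satellite while
        # f2 and f3 stay orthogonal: the greedy rule (highest mean absolute
        # correlation first) drops the hub and keeps both satellites
        n = 20000
        u, w = rng.normal(size=n), rng.normal(size=n)
        df = pd.DataFrame({"f1": (u + w) / np.sqrt(2), "f2": u, "f3": w})
        c = df.corr().abs()
        threshold = 0.65
        assert c.loc["f1", "f2"] > threshold and c.loc["f1", "f3"] > threshold
        assert c.loc["f2", "f3"] < threshold
        assert remove_collinear(df, threshold) == ["f2", "f3"]


class TestConfusionMatrix:
    def test_perfect_predictions_give_identity(self):
        y = ["a", "b", "c", "a"]
        m = confusion_matrix(y, y)
        np.testing.assert_allclose(m.to_numpy(), np.eye(3))

    def test_columns_sum_to_one(self, rng):
        y_true = rng.choice(list("abc"), 200)
        y_pred = rng.choice(list("abc"), 200)
        m = confusion_matrix(y_true, y_pred)
        np.testing.assert_allclose(m.sum(axis=0), 1.0, atol=1e-9)

    def test_hand_counted_example(self):
        m = confusion_matrix(["A", "A", "B", "B"], ["A", "B", "B", "B"])
        np.testing.assert_allclose(m["A"], [0.5, 0.5])
        np.testing.assert_allclose(m["B"], [0.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["a"], ["a", "b"])

    def test_rows_are_predictions(self):
        m = confusion_matrix(["a", "a", "a"], ["b", "b", "b"], labels=["a", "b"])
        assert m.loc["b", "a"] == pytest.approx(1.0)  # predicted b, actually a


class TestBalancedAccuracy:
    def test_perfect_classifier(self):
        counts = confusion_matrix(["a", "b"] * 10, ["a", "b"] * 10, normalize=False)
        assert balanced_accuracy(counts, "a") == 1.0

    def test_worked_arithmetic(self):
        # TP=40 FN=10 TN=30 FP=20 -> (0.8 + 0.6) / 2
        y_true = ["pos"] * 50 + ["neg"] * 50
        y_pred = ["pos"] * 40 + ["neg"] * 10 + ["pos"] * 20 + ["neg"] * 30
        counts = confusion_matrix(y_true, y_pred, normalize=False)
        assert balanced_accuracy(counts, "pos") == pytest.approx(0.7)

    def test_majority_guessing_scores_half(self):
        y_true = ["a"] * 50 + ["b"] * 50
        counts = confusion_matrix(y_true, ["a"] * 100, normalize=False)
        assert balanced_accuracy(counts, "a") == pytest.approx(0.5)

    def test_absent_class_is_undefined(self):
        counts = confusion_matrix(["a", "a", "b"], ["a", "a", "b"], normalize=False)
        with pytest.raises(UndefinedStatisticError):
            balanced_accuracy(counts, "z")


class TestGini:
    @pytest.mark.parametrize(
        "p,expected", [((1, 0), 0.0), ((0.5, 0.5), 0.5), ((0.2, 0.8), 0.32)]
    )
    def test_known_values(self, p, expected):
        assert gini_impurity(p) == pytest.approx(expected)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity([0.7, 0.7])
        with pytest.raises(ValueError):
            gini_impurity([-0.2, 1.2])


class TestEvaluateRegression:
    def test_perfect_predictions(self):
        r = evaluate_regression([1, 2, 3], [1, 2, 3])
        assert r.rmse == 0.0 and r.r_squared == 1.0

    def test_mean_prediction_scores_zero(self):
        truths = np.array([1.0, 2.0, 3.0])
        r = evaluate_regression(np.full(3, truths.mean()), truths)
        assert r.r_squared == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        r = evaluate_regression([1, 2, 5], [1, 2, 3])
        assert r.rmse == pytest.approx(np.sqrt(4 / 3))
        assert r.r_squared == pytest.approx(-1.0)

    def test_constant_truths_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            evaluate_regression([1, 2], [3, 3])


def separable_dataset(rng, n=150):
    y = np.array(["a", "b"] * (n // 2))
    X = pd.DataFrame(
        {
            "signal": np.where(y == "a", 0.0, 10.0) + rng.normal(0, 0.1, n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        }
    )
    return X, y


class TestTrainAndEvaluate:
    def test_separable_classes_are_perfectly_classified(self, rng):
        X, y = separable_dataset(rng)
        plan = nested_split(len(X), seed=0, labels=y)
        r = train_and_evaluate(X, y, "random_forest", plan, seed=0)
        assert r.overall_accuracy == 1.0

    def test_permuted_labels_score_near_chance(self, rng):
        n = 300
        y = rng.permutation(np.array(["a", "b", "c"] * (n // 3)))
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("wxyz"))
        plan = nested_split(n, seed=1, labels=y)
        r = train_and_evaluate(X, y, "random_forest", plan, seed=1)
        assert 0.23 <= r.overall_accuracy <= 0.43  # 95% band around 1/3

    def test_deterministic_given_seed(self, rng):
        X, y = separable_dataset(rng)
        plan = nested_split(len(X), seed=2, labels=y)
        a = train_and_evaluate(X, y, "decision_tree", plan, seed=5)
        b = train_and_evaluate(X, y, "decision_tree", plan, seed=5)
        assert a.overall_accuracy == b.overall_accuracy
        assert a.fold_accuracies == b.fold_accuracies
        pd.testing.assert_frame_equal(a.confusion, b.confusion)

    def test_test_rows_never_touch_selection_stages(self, rng):
        """Nested-CV hygiene: fingerprints of every pre-test stage equal the
        development-rows digest, and never the test-rows digest."""
        import hashlib

        X, y = separable_dataset(rng)
        plan = nested_split(len(X), seed=3, labels=y)
        r = train_and_evaluate(X, y, "decision_tree", plan, seed=3)

        def digest(idx):
            h = hashlib.sha256()
            h.update(np.ascontiguousarray(X.to_numpy()[np.sort(idx)]).tobytes())
            return h.hexdigest()

        for fold, fp in zip(plan.folds, r.stage_fingerprints):
            assert fp["collinearity_rows"] == digest(fold.development)
            assert fp["tuning_fit_rows"] == digest(fold.train)
            assert fp["tuning_score_rows"] == digest(fold.validation)
            assert fp["test_rows"] == digest(fold.test)
            assert fp["test_rows"] != fp["collinearity_rows"]
            assert not set(fold.test) & set(fold.development)

    def test_accuracy_consistent_with_normalized_confusion(self, rng):
        """Micro accuracy = class-frequency-weighted diagonal of the
        column-normalized matrix."""
        X, y = separable_dataset(rng)
        plan = nested_split(len(X), seed=4, labels=y)
        r = train_and_evaluate(X, y, "svm", plan, seed=4)
        freq = pd.Series(r.pooled_true).value_counts()
        recon = sum(
            r.confusion.loc[c, c] * freq[c] for c in r.labels
        ) / freq.sum()
        assert recon == pytest.approx(r.overall_accuracy, abs=1e-9)


class TestFeatureImportance:
    def test_informative_feature_ranked_first(self, rng):
        n = 300
        y = np.array(["a", "b"] * (n // 2))
        X = pd.DataFrame(
            {
                "mvm": np.where(y == "a", 0.0, 1.0) + rng.normal(0, 0.2, n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        plan = nested_split(n, seed=0, labels=y)
        r = train_and_evaluate(X, y, "random_forest", plan, seed=0)
        assert r.importance[0][0] == "mvm"
        assert len(r.importance) == 3

    def test_pure_noise_importances_are_flat(self, rng):
        from sklearn.ensemble import RandomForestClassifier

        n = 500
        y = rng.choice(["a", "b"], n)
        X = pd.DataFrame(rng.normal(size=(n, 8)), columns=[f"f{i}" for i in range(8)])
        forest = RandomForestClassifier(200, random_state=0).fit(X, y)
        ranking = feature_importance(forest, list(X.columns))
        values = [v for _, v in ranking]
        assert max(values) <= 3 * np.median(values)

    def test_non_forest_model_rejected(self):
        from sklearn.tree import DecisionTreeClassifier

        with pytest.raises(TypeError):
            feature_importance(DecisionTreeClassifier(), ["a"])


class TestRegressionProtocol:
    def test_forest_recovers_linear_signal(self, rng):
        n = 200
        X = pd.DataFrame({"a": rng.uniform(0, 1, n), "b": rng.normal(size=n)})
        y = 3.0 * X["a"] + rng.normal(0, 0.05, n)
        plan = nested_split(n, seed=0)
        r = train_and_evaluate_regression(X, y, "random_forest", plan, seed=0)
        assert r.r_squared > 0.9
        assert r.rmse < 0.3
        assert r.importance[0][0] == "a"
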