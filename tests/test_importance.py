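"""Balanced accuracy, PFI, impurity importances, exact Shapley, CV and the
label-permutation significance test."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

import helpers
from epiforest.errors import InvalidArgumentError, UndefinedScoreError
from epiforest.importance import (
    balanced_accuracy,
    builtin_gini_importance,
    cv_balanced_accuracy,
    default_forest,
    label_permutation_test,
    permutation_feature_importance,
    shap_mean_importance,
)
from epiforest.shapley import expected_value, tree_shap_values


def stump_factory(random_state=None, **kw):
    return DecisionTreeClassifier(max_depth=1, random_state=random_state)


def small_forest(random_state=None, **kw):
    return RandomForestClassifier(
        n_estimators=30, random_state=random_state, **kw
    )


class _MajorityModel:
    """Predicts the training majority class regardless of features."""

    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self._c = vals[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self._c)


class TestBalancedAccuracy:
    def test_unweighted_class_mean(self):
        assert balanced_accuracy([0, 0, 1, 1], [0, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_prediction(self):
        assert balanced_accuracy([0, 1, 1], [0, 1, 1]) == 1.0

    def test_inverted_prediction(self):
        assert balanced_accuracy([0, 0, 1], [1, 1, 0]) == 0.0

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedScoreError):
            balanced_accuracy([1, 1, 1], [1, 1, 1])


class TestPermutationFeatureImportance:
    def test_perfectly_informative_feature_takes_all_mass(self, rng):
        X = rng.integers(0, 3, size=(400, 5)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        prof = permutation_feature_importance(
            X, y, model_factory=small_forest, n_repeats=5, rng=0
        )
        assert prof.scores[0] > 0.95
        assert prof.metric == "PFI"

    def test_unread_features_have_exactly_zero_raw_score(self, rng):
        # a depth-1 stump reads a single column; permuting any other
        # column cannot change predictions, so those decreases are 0 exactly
        X = rng.integers(0, 3, size=(200, 5)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        prof = permutation_feature_importance(
            X, y, model_factory=stump_factory, n_repeats=6, rng=1
        )
        assert (prof.raw_scores[1:] == 0.0).all()
        assert prof.scores[0] == 1.0

    def test_constant_model_yields_flagged_all_zero_profile(self, rng):
        X = rng.integers(0, 3, size=(100, 4)).astype(float)
        y = rng.integers(0, 2, 100)
        prof = permutation_feature_importance(
            X, y, model_factory=lambda random_state=None: _MajorityModel(),
            n_repeats=3, rng=2,
        )
        assert prof.all_zero
        assert (prof.scores == 0).all()

    def test_multi_feature_units_enumerate_all_tuples(self, rng):
        X = rng.integers(0, 3, size=(120, 5)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        prof2 = permutation_feature_importance(
            X, y, tuple_size=2, model_factory=small_forest, n_repeats=2, rng=3
        )
        assert len(prof2.units) == 10
        assert prof2.metric == "PFI2"
        prof3 = permutation_feature_importance(
            X, y, tuple_size=3, model_factory=small_forest, n_repeats=2, rng=3
        )
        assert len(prof3.units) == 10
        assert prof3.metric == "PFI3"

    def test_default_repeats_is_features_minus_one(self, rng):
        X = rng.integers(0, 3, size=(80, 4)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        prof = permutation_feature_importance(
            X, y, model_factory=stump_factory, rng=4
        )
        assert prof.metadata["n_repeats"] == 3

    def test_repeat_averaging_reduces_variance(self, rng):
        X = rng.integers(0, 3, size=(200, 5)).astype(float)
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        var = {}
        for n_rep in (1, 8):
            tops = [
                permutation_feature_importance(
                    X, y, model_factory=small_forest, n_repeats=n_rep, rng=s
                ).scores[0]
                for s in range(6)
            ]
            var[n_rep] = np.var(tops)
        assert var[8] <= var[1] + 1e-9


class TestBuiltinGini:
    def test_forced_single_split_concentrates_importance(self, rng):
        X = rng.integers(0, 3, size=(300, 5)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        rf = RandomForestClassifier(
            n_estimators=20, max_depth=1, max_features=None, random_state=0
        ).fit(X, y)
        prof = builtin_gini_importance(rf)
        np.testing.assert_allclose(prof.scores, [1, 0, 0, 0, 0])

    def test_normalization_and_determinism(self, rng):
        X = rng.integers(0, 3, size=(200, 5)).astype(float)
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        rf = RandomForestClassifier(n_estimators=30, random_state=5).fit(X, y)
        p1 = builtin_gini_importance(rf)
        rf2 = RandomForestClassifier(n_estimators=30, random_state=5).fit(X, y)
        p2 = builtin_gini_importance(rf2)
        assert p1.scores.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p1.scores, p2.scores)

    def test_unfitted_model_rejected(self):
        with pytest.raises(InvalidArgumentError):
            builtin_gini_importance(RandomForestClassifier())


class TestExactTreeShapley:
    def test_local_additivity(self, rng):
        X = rng.integers(0, 3, size=(300, 5)).astype(float)
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        rf = RandomForestClassifier(n_estimators=15, random_state=0).fit(X, y)
        sub = X[:40]
        phi = tree_shap_values(rf, sub)
        recon = phi.sum(axis=1) + expected_value(rf, sub)
        np.testing.assert_allclose(recon, rf.predict_proba(sub)[:, 1], atol=1e-10)

    def test_single_feature_model_concentrates_attribution(self, rng):
        X = rng.integers(0, 3, size=(300, 5)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        rf = RandomForestClassifier(
            n_estimators=10, max_depth=1, max_features=None, random_state=0
        ).fit(X, y)
        prof = shap_mean_importance(rf, X)
        np.testing.assert_allclose(prof.scores, [1, 0, 0, 0, 0], atol=1e-12)

    def test_duplicated_feature_symmetry(self, rng):
        X = rng.integers(0, 3, size=(400, 4)).astype(float)
        X[:, 1] = X[:, 0]  # exact copy
        y = (X[:, 0] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=200, random_state=0).fit(X, y)
        prof = shap_mean_importance(rf, X[:100])
        a, b = prof.scores[0], prof.scores[1]
        assert abs(a - b) / max(a, b) < 0.2
        assert a + b > 0.9

    def test_non_tree_model_rejected(self, rng):
        from sklearn.linear_model import LogisticRegression

        X = rng.integers(0, 3, size=(50, 3)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        lr = LogisticRegression().fit(X, y)
        with pytest.raises(InvalidArgumentError):
            tree_shap_values(lr, X)


class TestCrossValidation:
    def test_separable_data_scores_one(self, rng):
        X = rng.integers(0, 3, size=(200, 4)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        fit = cv_balanced_accuracy(X, y, folds=5, model_factory=small_forest, rng=0)
        assert fit.cv_balanced_accuracy == pytest.approx(1.0)
        assert len(fit.fold_scores) == 5

    def test_null_data_scores_near_half(self, rng):
        X = rng.integers(0, 3, size=(400, 4)).astype(float)
        y = rng.integers(0, 2, 400)
        fit = cv_balanced_accuracy(X, y, folds=5, model_factory=small_forest, rng=1)
        assert abs(fit.cv_balanced_accuracy - 0.5) < 0.08

    def test_too_many_folds_rejected(self, rng):
        X = rng.integers(0, 3, size=(10, 3)).astype(float)
        y = np.array([0, 1] * 5)
        with pytest.raises(InvalidArgumentError):
            cv_balanced_accuracy(X, y, folds=20)

    def test_grid_search_tunes_hyperparameters(self, rng):
        X = rng.integers(0, 3, size=(120, 3)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        fit = cv_balanced_accuracy(
            X, y, folds=3, model_factory=small_forest, rng=2,
            grid={"max_depth": [1, 3]},
        )
        assert fit.hyperparameters["max_depth"] in (1, 3)


class TestLabelPermutationTest:
    def test_separable_data_minimal_p(self, rng):
        X = rng.integers(0, 3, size=(60, 3)).astype(float)
        y = (X[:, 0] > 0).astype(int)

        def tiny(random_state=None, **kw):
            return RandomForestClassifier(n_estimators=5, random_state=random_state)

        obs, nulls, p = label_permutation_test(
            X, y, B=19, folds=3, model_factory=tiny, rng=0
        )
        assert obs == pytest.approx(1.0, abs=0.05)
        assert p == pytest.approx(1 / 20)
        assert abs(np.mean(nulls) - 0.5) < 0.15

    def test_small_b_rejected(self, rng):
        X = rng.integers(0, 3, size=(30, 3)).astype(float)
        y = rng.integers(0, 2, 30)
        with pytest.raises(InvalidArgumentError):
            label_permutation_test(X, y, B=0)


def test_default_forest_is_gini_with_sqrt_features():
    rf = default_forest(random_state=0)
    assert rf.criterion == "gini"
    assert rf.max_features == "sqrt"
    assert rf.n_estimators == 100
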