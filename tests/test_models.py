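"""Classifier harness: tuning, selection and the two importance schemes."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline

from copdtriage.models import (
    DegenerateLabelsError,
    ImportanceRanking,
    ModelError,
    ModelRecord,
    importance_gb,
    importance_lr,
    select_top_models,
    train_and_tune,
)


def toy_features(n=300, p=6, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)]
    )
    return X


class TestTrainAndTune:
    def test_separable_labels_reach_high_cv_accuracy(self):
        X = toy_features()
        y = (X["f0"] > 0).astype(int) + 1  # deterministic threshold on one feature
        rec = train_and_tune(X, y, "LR", seed=0)
        assert rec.cv_accuracy >= 99.0

    def test_grid_of_size_one_is_selected(self):
        X = toy_features()
        y = (X["f0"] > 0).astype(int)
        rec = train_and_tune(X, y, "LR", grid={"clf__estimator__C": [0.42]}, seed=0)
        assert rec.best_params == {"clf__estimator__C": 0.42}

    def test_deterministic_under_seed(self):
        X = toy_features()
        y = ((X["f0"] + 0.5 * X["f1"] + np.sin(X["f2"])) > 0).astype(int)
        a = train_and_tune(X, y, "GB", seed=5)
        b = train_and_tune(X, y, "GB", seed=5)
        assert a.cv_fold_accuracies == b.cv_fold_accuracies
        assert a.best_params == b.best_params

    def test_single_class_labels_rejected(self):
        X = toy_features(n=50)
        with pytest.raises(DegenerateLabelsError):
            train_and_tune(X, np.ones(50, dtype=int), "LR", seed=0)


class TestSelectTopModels:
    def test_single_record_is_top(self):
        X = toy_features()
        y = (X["f0"] > 0).astype(int)
        rec = train_and_tune(X, y, "LR", seed=0)
        sel = select_top_models([rec], X, y)
        assert sel.top_two == [rec]

    def test_higher_validation_accuracy_wins(self):
        X = toy_features(seed=3)
        y = (X["f0"] > 0).astype(int)
        good = train_and_tune(X, y, "LR", seed=0)
        # NB on pure noise features relative to a rotated target does worse
        y_hard = ((X["f1"] * X["f2"]) > 0).astype(int)
        bad = train_and_tune(X, y_hard, "NB", seed=0)
        sel = select_top_models([good, bad], X, y)
        assert sel.top_two[0] is good

    def test_empty_records_rejected(self):
        with pytest.raises(ModelError, match="nothing to select"):
            select_top_models([], toy_features(), np.array([]))


def fitted_record(estimator, feature_names, family, task="triage"):
    return ModelRecord(
        family=family, task=task, estimator=estimator, best_params={},
        cv_fold_accuracies=[], cv_accuracy=0.0, feature_names=feature_names,
        seed=0,
    )


class TestImportanceGB:
    def test_stumps_on_one_feature_concentrate_importance(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(400, 3)), columns=["a", "b", "c"])
        y = (X["a"] > 0).astype(int)
        gb = Pipeline([("clf", GradientBoostingClassifier(
            max_depth=1, n_estimators=25, random_state=0))]).fit(X.to_numpy(), y)
        imp = importance_gb(fitted_record(gb, ["a", "b", "c"], "GB"))
        scores = dict(imp.ranking)
        assert scores["a"] == pytest.approx(1.0)
        assert scores["b"] == 0.0 and scores["c"] == 0.0

    def test_fractions_sum_to_one_and_nonnegative(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(300, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = ((X["f0"] + X["f3"]) > 0).astype(int)
        gb = Pipeline([("clf", GradientBoostingClassifier(
            n_estimators=30, random_state=0))]).fit(X.to_numpy(), y)
        imp = importance_gb(fitted_record(gb, list(X.columns), "GB"))
        vals = np.array([v for _, v in imp.ranking])
        assert vals.sum() == pytest.approx(1.0, abs=1e-9)
        assert (vals >= 0).all()
        # and sorted non-increasing
        assert (np.diff(vals) <= 1e-12).all()

    def test_informative_feature_outranks_noise(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"signal": rng.normal(size=500),
                          "noise": rng.normal(size=500)})
        y = (X["signal"] > 0).astype(int)
        gb = Pipeline([("clf", GradientBoostingClassifier(
            n_estimators=30, random_state=0))]).fit(X.to_numpy(), y)
        imp = importance_gb(fitted_record(gb, list(X.columns), "GB"))
        assert imp.ranking[0][0] == "signal"

    def test_unfitted_model_rejected(self):
        gb = Pipeline([("clf", GradientBoostingClassifier())])
        with pytest.raises(ModelError, match="not fitted"):
            importance_gb(fitted_record(gb, ["a"], "GB"))


class TestImportanceLR:
    def test_single_binary_model_orders_by_coefficient_magnitude(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(500, 3)), columns=["a", "b", "c"])
        logit = 2.0 * X["a"] - 0.5 * X["b"] + 0.0 * X["c"]
        y = (logit + 0.1 * rng.normal(size=500) > 0).astype(int)
        lr = Pipeline([("clf", LogisticRegression(max_iter=2000))]).fit(X.to_numpy(), y)
        imp = importance_lr(fitted_record(lr, ["a", "b", "c"], "LR"))
        assert [name for name, _ in imp.ranking] == ["a", "b", "c"]

    def test_hand_set_coefficients_average_ranks(self):
        # four binary models with known coefficients -> known average ranks
        coefs = np.array([
            [3.0, 2.0, 1.0],   # ranks 1, 2, 3
            [1.0, 3.0, 2.0],   # ranks 3, 1, 2
            [3.0, 1.0, 2.0],   # ranks 1, 3, 2
            [2.0, 3.0, 1.0],   # ranks 2, 1, 3
        ])
        expected = coefs.copy()
        for i in range(4):
            expected[i] = rankdata(-np.abs(coefs[i]))
        expected_avg = expected.mean(axis=0)  # [1.75, 1.75, 2.5]

        class FakeBinary:
            def __init__(self, c):
                self.coef_ = c.reshape(1, -1)

        class FakeOVR(OneVsRestClassifier):
            def __init__(self, coefs):
                super().__init__(LogisticRegression())
                self.estimators_ = [FakeBinary(c) for c in coefs]

        est = Pipeline([("clf", FakeOVR(coefs))])
        imp = importance_lr(fitted_record(est, ["a", "b", "c"], "LR"))
        scores = dict(imp.ranking)
        assert scores["a"] == pytest.approx(expected_avg[0])
        assert scores["b"] == pytest.approx(expected_avg[1])
        assert scores["c"] == pytest.approx(expected_avg[2])
        # tie between a and b broken by name; c (zero-ish effect) last
        assert [n for n, _ in imp.ranking] == ["a", "b", "c"]

    def test_zero_coefficient_everywhere_is_worst(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(600, 3)), columns=["a", "b", "dead"])
        X["dead"] = 0.0  # constant feature: coefficient shrinks to zero
        y = pd.cut(2 * X["a"] + X["b"], bins=[-np.inf, -1, 0, 1, np.inf],
                   labels=[1, 2, 3, 4]).astype(int)
        ovr = Pipeline([
            ("clf", OneVsRestClassifier(LogisticRegression(max_iter=2000)))
        ]).fit(X.to_numpy(), y)
        imp = importance_lr(fitted_record(ovr, list(X.columns), "LR"))
        assert imp.ranking[-1][0] == "dead"

    def test_plain_multiclass_fit_rejected(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 2))
        y = rng.integers(1, 4, size=200)
        lr = Pipeline([("clf", LogisticRegression(max_iter=500))]).fit(X, y)
        with pytest.raises(ModelError, match="one-vs-rest"):
            importance_lr(fitted_record(lr, ["a", "b"], "LR"))
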