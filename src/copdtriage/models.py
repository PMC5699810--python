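"""Classifier training, tuning, selection and feature importance.

Nine classifier families (gradient-boosted trees, one-vs-rest logistic
regression, three SVM kernels, random forest, extra trees, naive Bayes,
k-nearest neighbours) are tuned by exhaustive grid search with stratified
5-fold cross-validation, then compared by their accuracy against the
consensus labels of the held-out validation cases; the per-family winners
and the overall top two are reported.

Two importance schemes match the two top families:

* gradient boosting — for every tree, each internal split credits its
  feature with the fraction of the tree's samples passing through that node;
  per-tree fractions are averaged over the whole ensemble and normalised to
  sum to one;
* logistic regression — within each one-vs-rest binary model the features
  are ranked by absolute coefficient (features are standardised first so
  coefficients are scale-comparable), and the final score is the average
  rank across the binary models; lower means more important.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


class ModelError(ValueError):
    pass


class DegenerateLabelsError(ModelError):
    pass


FAMILIES = ("GB", "LR", "SVML", "SVMP", "SVMG", "RF", "NB", "KNN", "ET")

#: Default hyperparameter grids (package configuration; kept deliberately
#: small so a full family sweep stays tractable on one CPU).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "GB": {"clf__n_estimators": [100], "clf__max_depth": [2, 3], "clf__learning_rate": [0.1]},
    "LR": {"clf__estimator__C": [0.1, 1.0, 10.0]},
    "SVML": {"clf__C": [0.1, 1.0]},
    "SVMP": {"clf__C": [1.0], "clf__degree": [2, 3]},
    "SVMG": {"clf__C": [1.0, 10.0], "clf__gamma": ["scale"]},
    "RF": {"clf__n_estimators": [200], "clf__max_depth": [None, 8]},
    "NB": {"clf__var_smoothing": [1e-9]},
    "KNN": {"clf__n_neighbors": [5, 15]},
    "ET": {"clf__n_estimators": [200]},
}

_SCALED = {"LR", "SVML", "SVMP", "SVMG", "KNN"}


def make_estimator(family: str, seed: int = 0) -> Pipeline:
    """Fresh pipeline for one family; scaled families get a StandardScaler."""
    if family == "GB":
        clf = GradientBoostingClassifier(random_state=seed)
    elif family == "LR":
        clf = OneVsRestClassifier(LogisticRegression(max_iter=5000))
    elif family == "SVML":
        clf = SVC(kernel="linear", random_state=seed)
    elif family == "SVMP":
        clf = SVC(kernel="poly", random_state=seed)
    elif family == "SVMG":
        clf = SVC(kernel="rbf", random_state=seed)
    elif family == "RF":
        clf = RandomForestClassifier(random_state=seed)
    elif family == "NB":
        clf = GaussianNB()
    elif family == "KNN":
        clf = KNeighborsClassifier()
    elif family == "ET":
        clf = ExtraTreesClassifier(random_state=seed)
    else:
        raise ModelError(f"unknown family {family!r}")
    steps = [("scale", StandardScaler())] if family in _SCALED else []
    steps.append(("clf", clf))
    return Pipeline(steps)


@dataclass
class ModelRecord:
    family: str
    task: str  # "triage" | "exacerbation"
    estimator: Pipeline
    best_params: dict
    cv_fold_accuracies: list[float]
    cv_accuracy: float  # mean CV accuracy of the best configuration, %
    feature_names: list[str]
    seed: int
    validation_accuracy: float | None = None


def train_and_tune(
    features: pd.DataFrame,
    labels,
    family: str,
    task: str = "triage",
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
) -> ModelRecord:
    """Exhaustive grid search with stratified k-fold CV accuracy; refits best.

    Deterministic given ``seed`` (fold shuffling and any stochastic fitting
    share it).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("degenerate labels: fewer than two classes present")
    grid = grid if grid is not None else DEFAULT_GRIDS[family]
    if not grid:
        raise ModelError("grid must be non-empty")
    est = make_estimator(family, seed=seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(est, grid, scoring="accuracy", cv=cv, n_jobs=1, refit=True)
    search.fit(features.to_numpy(float), y)
    best = search.best_index_
    fold_accs = [
        100.0 * float(search.cv_results_[f"split{i}_test_score"][best]) for i in range(folds)
    ]
    return ModelRecord(
        family=family,
        task=task,
        estimator=search.best_estimator_,
        best_params=dict(search.best_params_),
        cv_fold_accuracies=fold_accs,
        cv_accuracy=100.0 * float(search.best_score_),
        feature_names=list(features.columns),
        seed=seed,
    )


@dataclass
class SelectionResult:
    per_family: dict[str, ModelRecord]
    top_two: list[ModelRecord]
    table: pd.DataFrame  # family comparison (validation accuracy, %)


def select_top_models(
    records: list[ModelRecord],
    validation_features: pd.DataFrame,
    validation_consensus,
) -> SelectionResult:
    """Score records on the validation consensus; pick per-family best + top 2."""
    if not records:
        raise ModelError("nothing to select")
    tasks = {r.task for r in records}
    if len(tasks) != 1:
        raise ModelError("records must share a task")
    y = np.asarray(validation_consensus)
    X = validation_features.to_numpy(float)
    for r in records:
        pred = r.estimator.predict(X)
        r.validation_accuracy = 100.0 * float(np.mean(pred == y))
    per_family: dict[str, ModelRecord] = {}
    for r in records:
        cur = per_family.get(r.family)
        if cur is None or (r.validation_accuracy, -len(str(r.best_params))) > (
            cur.validation_accuracy,
            -len(str(cur.best_params)),
        ):
            per_family[r.family] = r
    ranked = sorted(
        per_family.values(), key=lambda r: (-r.validation_accuracy, r.family)
    )
    table = pd.DataFrame(
        [
            dict(
                family=r.family,
                validation_accuracy=r.validation_accuracy,
                cv_accuracy=r.cv_accuracy,
                best_params=str(r.best_params),
            )
            for r in ranked
        ]
    ).set_index("family")
    return SelectionResult(per_family=per_family, top_two=ranked[:2], table=table)


# ---------------------------------------------------------------------------
# Feature importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceRanking:
    task: str
    method: str  # "gb_sample_fraction" | "lr_average_rank"
    ranking: list[tuple[str, float]]  # best first

    def top(self, k: int) -> list[str]:
        return [name for name, _ in self.ranking[:k]]


def _tree_sample_fractions(tree, n_features: int) -> np.ndarray:
    """Fraction of a tree's samples passing through splits on each feature."""
    t = tree.tree_
    out = np.zeros(n_features)
    total = t.weighted_n_node_samples[0]
    for node in range(t.node_count):
        if t.children_left[node] != -1:  # internal node
            out[t.feature[node]] += t.weighted_n_node_samples[node] / total
    return out


def importance_gb(record: ModelRecord) -> ImportanceRanking:
    """Sample-fraction importance averaged over all trees in the GB ensemble."""
    clf = record.estimator.named_steps.get("clf")
    if not isinstance(clf, GradientBoostingClassifier):
        raise ModelError("importance_gb requires a gradient-boosting record")
    if not hasattr(clf, "estimators_"):
        raise ModelError("not fitted")
    p = len(record.feature_names)
    trees = [t for stage in clf.estimators_ for t in np.ravel(stage)]
    fractions = np.mean([_tree_sample_fractions(t, p) for t in trees], axis=0)
    total = fractions.sum()
    if total > 0:
        fractions = fractions / total
    order = np.lexsort((record.feature_names, -fractions))
    ranking = [(record.feature_names[i], float(fractions[i])) for i in order]
    return ImportanceRanking(task=record.task, method="gb_sample_fraction", ranking=ranking)


def importance_lr(record: ModelRecord) -> ImportanceRanking:
    """Average absolute-coefficient rank across the one-vs-rest binary models."""
    clf = record.estimator.named_steps.get("clf")
    if isinstance(clf, OneVsRestClassifier):
        if not hasattr(clf, "estimators_"):
            raise ModelError("not fitted")
        coefs = [np.ravel(est.coef_) for est in clf.estimators_]
    elif isinstance(clf, LogisticRegression):
        if not hasattr(clf, "coef_"):
            raise ModelError("not fitted")
        if clf.coef_.shape[0] != 1:
            raise ModelError("requires one-vs-rest for multiclass")
        coefs = [np.ravel(clf.coef_)]
    else:
        raise ModelError("importance_lr requires a logistic-regression record")
    # rank 1 = largest |coefficient| within each binary model; ties average
    ranks = np.mean([rankdata(-np.abs(c), method="average") for c in coefs], axis=0)
    order = np.lexsort((record.feature_names, ranks))
    ranking = [(record.feature_names[i], float(ranks[i])) for i in order]
    return ImportanceRanking(task=record.task, method="lr_average_rank", ranking=ranking)
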