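"""Multi-class regulatory-status model harness.

Eight algorithm families (RF, XGBoost, complement naive Bayes, gradient
boosting, k-nearest neighbours, logistic regression, a single-hidden-layer
perceptron, and an SVM) are trained on the descriptor feature space to
predict a regulatory label set, evaluated with a confusion matrix and
support-weighted accuracy/precision/recall/F1, externally validated, and
applied to unlabelled molecules with per-class tallying.

Conventions:

* the y1 class order is fixed to (banned, restricted, unrestricted);
* metric averaging is support-weighted, which makes the weighted recall of
  a complete evaluation equal the accuracy — an algebraic identity this
  harness asserts rather than hides;
* distance/margin-based learners (KNN, SVM, LR, ANN) get a z-score
  standardizer fitted on the training data only; complement naive Bayes
  gets a min-max scaler because it requires nonnegative features;
* the train/test split is stratified by label: with only eight restricted
  molecules an unstratified 24-molecule test set can miss a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.naive_bayes import ComplementNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "ALGORITHMS",
    "CLASS_ORDER_Y1",
    "CLASS_ORDER_Y2",
    "CLASS_ORDER_Y3",
    "ModelSpec",
    "FittedModel",
    "ConfusionMatrix",
    "MetricsReport",
    "split_dataset",
    "train_classifier",
    "tune_classifier",
    "evaluate",
    "external_validate",
    "apply_and_tally",
    "tally_labels",
]

ALGORITHMS = ("RF", "XGBoost", "CNB", "GBM", "KNN", "LR", "ANN", "SVM")

#: Class encoding orders.  y1 follows the confusion-matrix convention
#: P = banned, N = restricted, M = unrestricted.
CLASS_ORDER_Y1 = ("banned", "restricted", "unrestricted")
CLASS_ORDER_Y2 = ("yes", "no")
CLASS_ORDER_Y3 = ("yes", "no", "not_listed")

#: Algorithms whose features are z-scored (fit on training data only).
_SCALED = {"KNN", "SVM", "LR", "ANN"}

#: Small documented hyperparameter grids for training-set cross-validation.
SMALL_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"model__n_estimators": [100, 500]},
    "XGBoost": {"model__n_estimators": [100, 500]},
    "CNB": {"model__alpha": [0.5, 1.0]},
    "GBM": {"model__n_estimators": [100, 500]},
    "KNN": {"model__n_neighbors": [3, 5, 7]},
    "LR": {"model__C": [0.1, 1.0, 10.0]},
    "ANN": {"model__alpha": [1e-4, 1e-2]},
    "SVM": {"model__C": [0.1, 1.0, 10.0]},
}


@dataclass(frozen=True)
class ModelSpec:
    """An algorithm choice with hyperparameter overrides and a seed."""

    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )


@dataclass
class ConfusionMatrix:
    """K x K confusion counts; rows = predicted class, columns = true class."""

    class_labels: tuple[str, ...]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.class_labels, name="predicted"),
            columns=pd.Index(self.class_labels, name="true"),
        )


@dataclass
class MetricsReport:
    """Support-weighted classification metrics with per-class breakdown."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: pd.DataFrame
    averaging: str = "weighted"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "averaging": self.averaging,
            "per_class": self.per_class.to_dict(orient="index"),
        }


def split_dataset(
    labels: pd.Series,
    ratio: float = 0.7,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[list[str], list[str]]:
    """Split molecule names into train/test id lists.

    ``ratio`` is the train fraction; the train size is the floor of
    ``ratio * n`` (79 molecules at 0.7 give 55 train / 24 test).  With
    ``stratify`` the split preserves label proportions and requires every
    class to be populated.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("train ratio must lie strictly between 0 and 1")
    names = np.asarray(labels.index)
    y = labels.to_numpy()
    if stratify:
        counts = labels.value_counts()
        empty = [c for c in counts.index if counts[c] == 0]
        if empty:
            raise ValueError(f"cannot stratify: empty classes {empty}")
    train, test = train_test_split(
        names,
        train_size=ratio,
        random_state=seed,
        stratify=y if stratify else None,
        shuffle=True,
    )
    return list(train), list(test)


def _build_estimator(spec: ModelSpec):
    seed, hp = spec.seed, dict(spec.hyperparameters)
    algo = spec.algorithm
    if algo == "RF":
        model = RandomForestClassifier(random_state=seed, **hp)
    elif algo == "XGBoost":
        model = XGBClassifier(
            random_state=seed,
            eval_metric="mlogloss",
            **{"n_estimators": 100, **hp},
        )
    elif algo == "CNB":
        model = ComplementNB(**hp)
    elif algo == "GBM":
        model = GradientBoostingClassifier(random_state=seed, **hp)
    elif algo == "KNN":
        model = KNeighborsClassifier(**hp)
    elif algo == "LR":
        model = LogisticRegression(max_iter=5000, random_state=seed, **hp)
    elif algo == "ANN":
        model = MLPClassifier(
            hidden_layer_sizes=(64,),
            early_stopping=True,
            max_iter=1000,
            random_state=seed,
            **hp,
        )
    elif algo == "SVM":
        model = SVC(random_state=seed, **hp)
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(algo)

    steps = []
    if algo in _SCALED:
        steps.append(("scale", StandardScaler()))
    elif algo == "CNB":
        steps.append(("scale", MinMaxScaler()))
    steps.append(("model", model))
    return Pipeline(steps)


@dataclass
class FittedModel:
    """An opaque fitted handle: pipeline + label codec + feature manifest."""

    spec: ModelSpec
    pipeline: Pipeline
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]

    def _check_features(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        values = X.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("non-finite feature values")
        return values

    def predict(self, X: pd.DataFrame) -> pd.Series:
        values = self._check_features(X)
        codes = self.pipeline.predict(values)
        return pd.Series(
            [self.classes[int(c)] for c in codes], index=X.index, name="prediction"
        )


def train_classifier(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: pd.Series,
    class_order: Sequence[str] | None = None,
) -> FittedModel:
    """Fit one algorithm on a complete numeric feature frame.

    Labels are encoded against ``class_order`` (default: the sorted labels
    present); any standardization is fitted inside the pipeline, on the
    training data only.
    """
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite feature values")
    classes = tuple(class_order) if class_order else tuple(sorted(y.unique()))
    unknown = set(y.unique()) - set(classes)
    if unknown:
        raise ValueError(f"labels outside class order: {sorted(unknown)}")
    code = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([code[v] for v in y.loc[X.index]])
    pipeline = _build_estimator(spec)
    pipeline.fit(values, y_codes)
    return FittedModel(
        spec=spec,
        pipeline=pipeline,
        classes=classes,
        feature_names=tuple(X.columns),
    )


def tune_classifier(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: pd.Series,
    class_order: Sequence[str] | None = None,
    cv: int = 3,
) -> FittedModel:
    """Select hyperparameters from the documented small grid by CV.

    Cross-validation runs on the training set only; the refit model is
    returned as a :class:`FittedModel`.
    """
    classes = tuple(class_order) if class_order else tuple(sorted(y.unique()))
    code = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([code[v] for v in y.loc[X.index]])
    search = GridSearchCV(
        _build_estimator(spec), SMALL_GRIDS[spec.algorithm], cv=cv, n_jobs=1
    )
    search.fit(X.to_numpy(dtype=float), y_codes)
    chosen = {
        k.removeprefix("model__"): v for k, v in search.best_params_.items()
    }
    tuned = ModelSpec(
        spec.algorithm, {**dict(spec.hyperparameters), **chosen}, spec.seed
    )
    return train_classifier(tuned, X, y, class_order=classes)


def evaluate(
    pred: Sequence[str],
    truth: Sequence[str],
    class_order: Sequence[str],
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix plus support-weighted metric suite.

    The confusion matrix is oriented rows = predicted, columns = true.
    Accuracy is trace/total; precision, recall and F1 are per-class
    one-vs-rest values combined by class-support weights, with
    zero-division classes contributing 0.
    """
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth) or len(pred) == 0:
        raise ValueError("pred and truth must have equal nonzero length")
    classes = tuple(class_order)
    index = {c: i for i, c in enumerate(classes)}
    outside = [v for v in set(pred) | set(truth) if v not in index]
    if outside:
        raise ValueError(f"labels outside class order: {sorted(outside)}")
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    for p, t in zip(pred, truth):
        counts[index[p], index[t]] += 1

    total = counts.sum()
    accuracy = counts.trace() / total
    support = counts.sum(axis=0)  # column sums = true counts
    predicted = counts.sum(axis=1)
    rows = {}
    weighted = np.zeros(3)
    for i, c in enumerate(classes):
        tp = counts[i, i]
        prec = tp / predicted[i] if predicted[i] else 0.0
        rec = tp / support[i] if support[i] else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        rows[c] = {
            "precision": prec, "recall": rec, "f1": f1, "support": int(support[i]),
        }
        weighted += support[i] * np.array([prec, rec, f1])
    weighted /= total
    report = MetricsReport(
        accuracy=float(accuracy),
        precision=float(weighted[0]),
        recall=float(weighted[1]),
        f1=float(weighted[2]),
        per_class=pd.DataFrame.from_dict(rows, orient="index"),
    )
    return ConfusionMatrix(classes, counts), report


def external_validate(
    model: FittedModel, X_ext: pd.DataFrame, y_ext: pd.Series
) -> MetricsReport:
    """Score a fitted model on an untouched external label set."""
    if len(X_ext) == 0:
        raise ValueError("external validation set is empty")
    pred = model.predict(X_ext)
    _, report = evaluate(pred, y_ext.loc[X_ext.index], model.classes)
    return report


def apply_and_tally(
    model: FittedModel, X_unlabeled: pd.DataFrame
) -> tuple[pd.Series, dict[str, int]]:
    """Predict unlabelled molecules and tally predictions per class."""
    if len(X_unlabeled) == 0:
        empty = pd.Series(dtype=object, name="prediction")
        return empty, {c: 0 for c in model.classes}
    pred = model.predict(X_unlabeled)
    return pred, tally_labels(pred, model.classes)


def tally_labels(
    labels: Sequence[str], class_order: Sequence[str]
) -> dict[str, int]:
    """Count labels per class; the counts sum to the input size."""
    counts = {c: 0 for c in class_order}
    for v in labels:
        if v not in counts:
            raise ValueError(f"label {v!r} outside class order")
        counts[v] += 1
    return counts
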