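"""The four configured classifiers, the evaluation metrics and CV schemes.

The pipeline compares an MLP, an RBF-kernel SVM, a random forest and a
Gaussian naive-Bayes classifier on bag-of-visual-words features.  The
configurations are fixed (they were selected once by grid search and are
hard-coded here rather than re-searched):

* MLP — seven hidden layers {50, 30, 20, 20, 20, 30, 50}, ReLU, SGD,
  L2 regularisation alpha = 1e-5, constant learning rate.
* SVM — RBF kernel k(x, x') = exp(-gamma ||x - x'||^2), gamma = 0.001.
* RF — 100 trees, Gini impurity split criterion.
* GNB — per-class per-feature Gaussian with MAP decision rule.

Metrics are reported in percent from the binary confusion counts:
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean,
accuracy = (TP+TN)/total; multi-class metrics are macro-averaged.
Evaluation uses stratified fivefold cross-validation (each fold 80%
train / 20% test) and, for transfer studies, ordered train-on-A /
test-on-B dataset pairs that share only the training set's codebook.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .bovw import BovwEncoder
from .simulator import HIT


@dataclass(frozen=True)
class MLPConfig:
    hidden_layers: tuple[int, ...] = (50, 30, 20, 20, 20, 30, 50)
    activation: str = "relu"
    solver: str = "sgd"
    alpha: float = 1e-5
    learning_rate: str = "constant"
    learning_rate_init: float = 0.01
    max_epochs: int = 1000
    # the 7-layer net sits on a flat ln(2) loss plateau for its first ~100
    # epochs; a loose tolerance would stop there before learning starts
    tol: float = 1e-6
    plateau_patience: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass(frozen=True)
class SVMConfig:
    gamma: float = 0.001
    C: float = 1.0
    kernel: str = "rbf"
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass(frozen=True)
class RFConfig:
    n_estimators: int = 100
    criterion: str = "gini"
    seed: int = 0

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass(frozen=True)
class GNBConfig:
    var_smoothing: float = 1e-9
    seed: int = 0  # unused (GNB is deterministic); kept for interface symmetry


MODEL_CONFIGS = {"mlp": MLPConfig, "svm": SVMConfig, "rf": RFConfig, "nb": GNBConfig}


def make_classifier(model_config) -> BaseEstimator:
    """Instantiate the sklearn estimator for a model config (or its name)."""
    if isinstance(model_config, str):
        model_config = MODEL_CONFIGS[model_config]()
    if isinstance(model_config, MLPConfig):
        return MLPClassifier(
            hidden_layer_sizes=model_config.hidden_layers,
            activation=model_config.activation,
            solver=model_config.solver,
            alpha=model_config.alpha,
            learning_rate=model_config.learning_rate,
            learning_rate_init=model_config.learning_rate_init,
            max_iter=model_config.max_epochs,
            tol=model_config.tol,
            n_iter_no_change=model_config.plateau_patience,
            random_state=model_config.seed,
        )
    if isinstance(model_config, SVMConfig):
        return SVC(
            kernel=model_config.kernel,
            gamma=model_config.gamma,
            C=model_config.C,
            random_state=model_config.seed,
        )
    if isinstance(model_config, RFConfig):
        return RandomForestClassifier(
            n_estimators=model_config.n_estimators,
            criterion=model_config.criterion,
            random_state=model_config.seed,
        )
    if isinstance(model_config, GNBConfig):
        return GaussianNB(var_smoothing=model_config.var_smoothing)
    raise TypeError(f"unknown model config {type(model_config).__name__}")


@dataclass
class EvaluationReport:
    """Confusion counts plus the four derived metrics, in percent.

    For binary problems TP counts true hits; for multi-class problems the
    full confusion matrix is stored and precision/recall/F1 are
    macro-averaged.  ``precision_undefined`` flags a degenerate TP+FP = 0
    (precision is then reported as 0).
    """

    confusion: np.ndarray
    classes: list
    precision: float
    recall: float
    f1: float
    accuracy: float
    precision_undefined: bool = False

    @property
    def tp(self) -> int:
        return int(self.confusion[0, 0])

    @property
    def fn(self) -> int:
        return int(self.confusion[0, 1:].sum())

    @property
    def fp(self) -> int:
        return int(self.confusion[1:, 0].sum())

    @property
    def tn(self) -> int:
        return int(self.confusion[1:, 1:].sum())

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "precision_undefined": self.precision_undefined,
        }


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Percent metrics from binary confusion counts (exact formulas)."""
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion counts")
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    accuracy = (tp + tn) / total
    return {
        "precision": 100.0 * precision,
        "recall": 100.0 * recall,
        "f1": 100.0 * f1,
        "accuracy": 100.0 * accuracy,
    }


def _ordered_classes(labels: np.ndarray) -> list:
    """Hit first (it is the positive class), then the rest sorted."""
    classes = sorted(set(np.asarray(labels).tolist()))
    if HIT in classes:
        classes.remove(HIT)
        classes.insert(0, HIT)
    return classes


def evaluate_predictions(y_true, y_pred, classes: list | None = None) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from true and predicted labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = _ordered_classes(np.concatenate([y_true, y_pred]))
    cm = _sk_confusion(y_true, y_pred, labels=classes)
    n_classes = len(classes)
    if n_classes == 2:
        tp, fn = int(cm[0, 0]), int(cm[0, 1])
        fp, tn = int(cm[1, 0]), int(cm[1, 1])
        m = metrics_from_counts(tp, fp, fn, tn)
        undefined = (tp + fp) == 0
    else:
        # macro average of one-vs-rest metrics
        per = []
        undefined = False
        for i in range(n_classes):
            tp = int(cm[i, i])
            fp = int(cm[:, i].sum() - tp)
            fn = int(cm[i, :].sum() - tp)
            tn = int(cm.sum() - tp - fp - fn)
            if tp + fp == 0:
                undefined = True
            per.append(metrics_from_counts(tp, fp, fn, tn))
        m = {
            k: float(np.mean([p[k] for p in per]))
            for k in ("precision", "recall", "f1")
        }
        m["accuracy"] = 100.0 * float(np.trace(cm)) / float(cm.sum())
    return EvaluationReport(
        confusion=cm,
        classes=list(classes),
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        accuracy=m["accuracy"],
        precision_undefined=undefined,
    )


def train(features: np.ndarray, labels, model_config) -> BaseEstimator:
    """Fit one configured classifier; errors on single-class training sets."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    clf = make_classifier(model_config)
    clf.fit(np.asarray(features), labels)
    return clf


def evaluate(model: BaseEstimator, features: np.ndarray, labels) -> EvaluationReport:
    """Evaluate a trained model on held-out features."""
    pred = model.predict(np.asarray(features))
    classes = _ordered_classes(np.asarray(labels))
    return evaluate_predictions(labels, pred, classes)


def confusion_matrix(model: BaseEstimator, features: np.ndarray, labels) -> tuple[np.ndarray, list]:
    """(class x class counts, class order): rows true, columns predicted."""
    report = evaluate(model, features, labels)
    return report.confusion, report.classes


def _resolve_config(model, random_state: int):
    """Turn a model name into its config dataclass with the given seed."""
    if not isinstance(model, str):
        return model
    cfg_cls = MODEL_CONFIGS[model]
    return cfg_cls() if cfg_cls is GNBConfig else cfg_cls(seed=random_state)


class HitMissPipeline(ClassifierMixin, BaseEstimator):
    """Codebook + classifier trained together on per-frame descriptors.

    ``fit(descriptor_lists, labels)`` learns the visual-word codebook on
    the training descriptors only, encodes the histograms and fits the
    configured classifier, so no test information can leak into the
    codebook during cross-validation.  ``n_classes`` for the codebook is
    inferred from the training labels (k = 5 * n_classes).
    """

    def __init__(self, model: str | object = "mlp", normalize: bool = True,
                 random_state: int = 0):
        self.model = model
        self.normalize = normalize
        self.random_state = random_state

    def _model_config(self):
        return _resolve_config(self.model, self.random_state)

    def fit(self, X: Sequence[np.ndarray], y) -> "HitMissPipeline":
        y = np.asarray(y)
        classes = sorted(set(y.tolist()))
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        self.encoder_ = BovwEncoder(
            n_classes=len(classes),
            normalize=self.normalize,
            random_state=self.random_state,
        ).fit(X)
        features = self.encoder_.transform(X)
        self.classifier_ = train(features, y, self._model_config())
        self.classes_ = np.array(_ordered_classes(y))
        return self

    def transform(self, X: Sequence[np.ndarray]) -> np.ndarray:
        return self.encoder_.transform(X)

    def predict(self, X: Sequence[np.ndarray]) -> np.ndarray:
        return self.classifier_.predict(self.encoder_.transform(X))

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())


def cross_validate(
    X: Sequence[np.ndarray] | np.ndarray,
    labels,
    model: str | object = "mlp",
    k_folds: int = 5,
    random_state: int = 0,
) -> dict:
    """Stratified k-fold cross-validation of the codebook + classifier.

    Each fold holds out 1/k of the frames (20% at the default fivefold)
    and refits the full pipeline — codebook included — on the remaining
    80%.  ``X`` is a sequence of per-frame descriptor arrays (the
    codebook is refit per fold) or a ready feature matrix (the classifier
    alone is refit).  Returns mean and standard deviation of each metric
    across folds plus the per-fold reports.
    """
    labels = np.asarray(labels)
    counts = {c: int((labels == c).sum()) for c in set(labels.tolist())}
    short = [c for c, n in counts.items() if n < k_folds]
    if short:
        raise ValueError(f"classes {short} have fewer than {k_folds} members")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=random_state)
    is_matrix = isinstance(X, np.ndarray) and X.ndim == 2
    reports: list[EvaluationReport] = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        if is_matrix:
            clf = train(X[tr], labels[tr], _resolve_config(model, random_state))
            reports.append(evaluate(clf, X[te], labels[te]))
        else:
            pipe = HitMissPipeline(model=model, random_state=random_state)
            pipe.fit([X[i] for i in tr], labels[tr])
            pred = pipe.predict([X[i] for i in te])
            reports.append(evaluate_predictions(labels[te], pred,
                                                _ordered_classes(labels)))
    summary = {}
    for key in ("accuracy", "precision", "recall", "f1"):
        vals = np.array([getattr(r, key) for r in reports])
        summary[f"{key}_mean"] = float(vals.mean())
        summary[f"{key}_std"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    summary["n_folds"] = k_folds
    summary["reports"] = reports
    return summary


def cross_dataset(
    train_descriptors: Sequence[np.ndarray],
    train_labels,
    test_descriptors: Sequence[np.ndarray],
    test_labels,
    model: str | object = "mlp",
    random_state: int = 0,
) -> float:
    """Train on one dataset, test on another; returns accuracy in percent.

    The codebook is fitted on the training dataset only and reused to
    encode the test dataset, mimicking deployment on a new experiment.
    """
    pipe = HitMissPipeline(model=model, random_state=random_state)
    pipe.fit(train_descriptors, train_labels)
    pred = pipe.predict(test_descriptors)
    return 100.0 * float((pred == np.asarray(test_labels)).mean())


def cross_dataset_matrix(
    datasets: dict[str, tuple[Sequence[np.ndarray], np.ndarray]],
    model: str | object = "mlp",
    random_state: int = 0,
):
    """Accuracy for every ordered (train, test) dataset pair, as a DataFrame."""
    import pandas as pd

    names = list(datasets)
    out = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        Xa, ya = datasets[a]
        pipe = HitMissPipeline(model=model, random_state=random_state).fit(Xa, ya)
        for b in names:
            Xb, yb = datasets[b]
            out.loc[a, b] = 100.0 * float((pipe.predict(Xb) == np.asarray(yb)).mean())
    return out
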