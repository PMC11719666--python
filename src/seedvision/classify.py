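"""Reverse-validation harness: four classifier families on feature tables.

The fused (fire, ice) representation is validated by classification:
if two scalars discriminate the three seed classes at least as well as
the 31 raw features, the fusion kept the discriminative signal. Four
model families are trained on a stratified 70/30 split:

* **BP** — a one-hidden-layer (16 unit) perceptron trained by
  backpropagation;
* **SVM** — an RBF-kernel support vector machine;
* **DBN** — a minimal deep belief network: two stacked Bernoulli RBMs
  (64 and 32 hidden units) pretrained on min-max scaled features by
  contrastive divergence, then fine-tuned end to end by backpropagation
  through a softmax output layer;
* **RF** — a 500-tree random forest.

Feature scaling statistics always come from the training split only.
All model hyperparameters are pinned defaults chosen for
reproducibility, not tuned per dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix
from sklearn.neural_network import BernoulliRBM, MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC

__all__ = ["MODEL_KINDS", "SplitSpec", "EvalReport", "DBNClassifier",
           "stratified_split", "build_model", "train_eval",
           "compare_matrices"]

MODEL_KINDS = ("BP", "SVM", "DBN", "RF")

_META_COLUMNS = ("sample_id", "label")


@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0


@dataclass
class EvalReport:
    model_kind: str
    train_accuracy: float        # percent
    test_accuracy: float         # percent
    confusion: np.ndarray        # k x k counts, rows = true class
    classes: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {"model": self.model_kind, "seed": self.seed,
                "train_acc": self.train_accuracy,
                "test_acc": self.test_accuracy,
                "classes": [str(c) for c in self.classes],
                "confusion": self.confusion.tolist()}


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    feats = [c for c in table.columns if c not in _META_COLUMNS]
    X = table[feats].to_numpy(dtype=np.float64)
    y = table["label"].to_numpy()
    return X, y


def stratified_split(table: pd.DataFrame, spec: SplitSpec | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic per-class 70/30 split of a labeled feature table.

    Train counts per class are round(train_fraction * n_class); train
    and test are disjoint and cover every sample.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    labels = table["label"].to_numpy()
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        if idx.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        n_train = int(round(spec.train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        if spec.stratified:
            idx = rng.permutation(idx)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return (table.iloc[sorted(train_idx)].reset_index(drop=True),
            table.iloc[sorted(test_idx)].reset_index(drop=True))


class DBNClassifier(BaseEstimator, ClassifierMixin):
    """Deep belief network: greedy RBM pretraining + backprop fine-tuning.

    Two stacked Bernoulli RBMs (``hidden`` units each) are pretrained
    unsupervised by contrastive divergence on features scaled to [0, 1];
    their weights then initialize a logistic-activation multilayer
    perceptron with a softmax output, which is fine-tuned end to end by
    backpropagation. Expects inputs already in [0, 1] (pair with a
    min-max scaler).
    """

    def __init__(self, hidden=(64, 32), rbm_learning_rate=0.05,
                 rbm_n_iter=30, max_iter=2000, random_state=0):
        self.hidden = hidden
        self.rbm_learning_rate = rbm_learning_rate
        self.rbm_n_iter = rbm_n_iter
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        rbms = []
        V = X
        for i, n_units in enumerate(self.hidden):
            rbm = BernoulliRBM(n_components=n_units,
                               learning_rate=self.rbm_learning_rate,
                               n_iter=self.rbm_n_iter,
                               random_state=self.random_state + i)
            V = rbm.fit_transform(V)
            rbms.append(rbm)
        mlp = MLPClassifier(hidden_layer_sizes=tuple(self.hidden),
                            activation="logistic", solver="lbfgs",
                            max_iter=self.max_iter,
                            random_state=self.random_state, warm_start=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            mlp.set_params(max_iter=1)
            mlp.fit(X, y)                    # allocate the weight structure
            mlp.set_params(max_iter=self.max_iter)
            for i, rbm in enumerate(rbms):
                mlp.coefs_[i] = rbm.components_.T.copy()
                mlp.intercepts_[i] = rbm.intercept_hidden_.copy()
            mlp.fit(X, y)                    # fine-tune the whole stack
        self.rbms_ = rbms
        self.mlp_ = mlp
        self.classes_ = mlp.classes_
        return self

    def predict(self, X):
        return self.mlp_.predict(np.asarray(X, dtype=np.float64))

    def predict_proba(self, X):
        return self.mlp_.predict_proba(np.asarray(X, dtype=np.float64))


def build_model(model_kind: str, seed: int = 0) -> Pipeline:
    """Pinned-default pipeline for one of the four model kinds."""
    if model_kind == "BP":
        return Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPClassifier(hidden_layer_sizes=(16,), max_iter=3000,
                                  random_state=seed)),
        ])
    if model_kind == "SVM":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", random_state=seed)),
        ])
    if model_kind == "RF":
        return Pipeline([
            ("scale", StandardScaler()),
            ("rf", RandomForestClassifier(n_estimators=500, random_state=seed)),
        ])
    if model_kind == "DBN":
        return Pipeline([
            ("minmax", MinMaxScaler()),
            ("dbn", DBNClassifier(hidden=(64, 32), random_state=seed)),
        ])
    raise ValueError(f"unknown model kind {model_kind!r}; "
                     f"valid kinds: {', '.join(MODEL_KINDS)}")


def train_eval(model_kind: str, train: pd.DataFrame, test: pd.DataFrame,
               seed: int = 0) -> EvalReport:
    """Fit one model kind and report accuracies plus the test confusion."""
    Xtr, ytr = _split_xy(train)
    Xte, yte = _split_xy(test)
    model = build_model(model_kind, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xtr, ytr)
    classes = np.unique(np.concatenate([ytr, yte]))
    train_acc = 100.0 * float(np.mean(model.predict(Xtr) == ytr))
    pred = model.predict(Xte)
    test_acc = 100.0 * float(np.mean(pred == yte))
    conf = confusion_matrix(yte, pred, labels=classes)
    return EvalReport(model_kind=model_kind, train_accuracy=train_acc,
                      test_accuracy=test_acc, confusion=conf,
                      classes=classes, seed=seed)


def compare_matrices(raw_reports: dict[str, EvalReport],
                     fireice_reports: dict[str, EvalReport]) -> pd.DataFrame:
    """Per-model test-accuracy deltas (fire-ice minus raw features).

    Both report sets must come from the same split (same seed and the
    same per-class test counts), otherwise the comparison is meaningless
    and an error is raised.
    """
    if set(raw_reports) != set(fireice_reports):
        raise ValueError("report sets cover different model kinds")
    rows = []
    for kind in sorted(raw_reports):
        r, f = raw_reports[kind], fireice_reports[kind]
        if r.seed != f.seed or not np.array_equal(
                r.confusion.sum(axis=1), f.confusion.sum(axis=1)):
            raise ValueError(f"{kind}: reports come from different splits")
        rows.append({"model": kind,
                     "raw_test_acc": r.test_accuracy,
                     "fireice_test_acc": f.test_accuracy,
                     "delta": f.test_accuracy - r.test_accuracy})
    return pd.DataFrame(rows)
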