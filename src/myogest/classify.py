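"""The three gesture classifiers and train/test splitting.

Hyperparameters follow the published configuration: a feed-forward network
with hidden layers (116, 48), tanh activation and the LBFGS optimizer; an
RBF-kernel SVM with C=80 and gamma=0.04 decomposed one-vs-one (K(K-1)/2
binary problems); and a Gini decision tree with min_samples_split=2 and
min_samples_leaf=2.  SVM and ANN inputs are rescaled using training-set
statistics only, since AR coefficients (order 1) and MAV/SD (tens of
counts) live on incompatible scales.  The default is min-max scaling to
[0, 1]: a fixed RBF width of gamma=0.04 presumes bounded features —
under per-feature unit variance the 80-dimensional squared distances
concentrate near 160 and the kernel degenerates to near-diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .synth import GestureLabel

__all__ = [
    "ClassifierSpec",
    "TrainedClassifier",
    "DataSplit",
    "CLASSIFIER_KINDS",
    "split_dataset",
    "train",
    "predict",
    "accuracy",
]

CLASSIFIER_KINDS = ("ann", "svm", "dt")


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one classifier.

    Only the parameters of the active ``kind`` are used; every default is
    overridable.  ``standardize`` controls the training-set z-scoring step
    (on by default for svm/ann, ignored by the scale-invariant tree).
    """

    kind: str = "svm"
    # ann
    hidden_layers: tuple[int, ...] = (116, 48)
    activation: str = "tanh"
    solver: str = "lbfgs"
    max_iter: int = 500
    # svm
    C: float = 80.0
    gamma: float = 0.04
    kernel: str = "rbf"
    multiclass: str = "one_vs_one"
    # dt
    criterion: str = "gini"
    min_samples_split: int = 2
    min_samples_leaf: int = 2
    # shared; scaling applies to svm/ann (the tree is scale-invariant)
    scaling: str = "minmax"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
        if self.multiclass not in ("one_vs_one", "one_vs_rest"):
            raise ValueError("multiclass must be 'one_vs_one' or 'one_vs_rest'")
        if self.scaling not in ("minmax", "zscore", "none"):
            raise ValueError("scaling must be 'minmax', 'zscore' or 'none'")


@dataclass
class TrainedClassifier:
    """A fitted classifier plus the spec and scaler state that produced it."""

    spec: ClassifierSpec
    pipeline: Pipeline
    classes: list[GestureLabel]

    @property
    def n_features(self) -> int:
        return int(self.pipeline.n_features_in_)


@dataclass(frozen=True)
class DataSplit:
    """Disjoint, exhaustive, stratified train/test index split."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    test_fraction: float


def split_dataset(
    labels: np.ndarray,
    test_fraction: float,
    seed: int = 0,
) -> DataSplit:
    """Stratified random split of sample indices, deterministic in ``seed``."""
    y = np.asarray(labels)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples to stratify")
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
    train_idx, test_idx = next(splitter.split(np.zeros((y.size, 1)), y))
    return DataSplit(train_idx=np.sort(train_idx), test_idx=np.sort(test_idx), test_fraction=test_fraction)


def _build_estimator(spec: ClassifierSpec):
    if spec.kind == "ann":
        return MLPClassifier(
            hidden_layer_sizes=spec.hidden_layers,
            activation=spec.activation,
            solver=spec.solver,
            max_iter=spec.max_iter,
            random_state=spec.seed,
        )
    if spec.kind == "svm":
        return SVC(
            C=spec.C,
            gamma=spec.gamma,
            kernel=spec.kernel,
            decision_function_shape="ovo" if spec.multiclass == "one_vs_one" else "ovr",
            random_state=spec.seed,
        )
    return DecisionTreeClassifier(
        criterion=spec.criterion,
        min_samples_split=spec.min_samples_split,
        min_samples_leaf=spec.min_samples_leaf,
        random_state=spec.seed,
    )


def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> TrainedClassifier:
    """Fit a classifier on labeled feature vectors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_samples, n_features) matching y")
    if np.unique(y).size < 2:
        raise ValueError("training needs at least 2 classes")
    steps = []
    if spec.scaling != "none" and spec.kind in ("svm", "ann"):
        scaler = MinMaxScaler() if spec.scaling == "minmax" else StandardScaler()
        steps.append(("scale", scaler))
    steps.append(("clf", _build_estimator(spec)))
    pipe = Pipeline(steps)
    pipe.fit(X, y)
    classes = [GestureLabel(int(c)) for c in pipe.classes_]
    return TrainedClassifier(spec=spec, pipeline=pipe, classes=classes)


def predict(model: TrainedClassifier, features: np.ndarray) -> GestureLabel | np.ndarray:
    """Predict gesture label(s); a 1-D input returns a single label."""
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {x.shape[1]}")
    pred = model.pipeline.predict(x)
    if single:
        return GestureLabel(int(pred[0]))
    return pred


def accuracy(model: TrainedClassifier, X: np.ndarray, y: np.ndarray) -> float:
    """Percentage of correct predictions, in [0, 100]."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("accuracy of an empty set is undefined")
    pred = model.pipeline.predict(np.asarray(X, dtype=float))
    return 100.0 * float(np.mean(pred == y))
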