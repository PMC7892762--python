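"""Linear max-margin readout on firing-rate features.

Only the readout of a liquid state machine is trained: a linear SVM
(C = 1, one-vs-rest) maps per-neuron mean firing rates to class labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.svm import LinearSVC

__all__ = ["ReadoutConfig", "EvalReport", "train_readout", "evaluate", "save_model", "load_model"]


@dataclass
class ReadoutConfig:
    """Readout hyper-parameters: linear kernel, C = 1, one-vs-rest."""

    c: float = 1.0
    standardize: bool = False
    max_iter: int = 20000

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("C must be positive")


@dataclass
class EvalReport:
    """Accuracy plus a row-normalised (percentage) confusion matrix.

    Rows are true labels, columns predicted; each row of
    ``confusion_pct`` sums to 100 (up to rounding) for classes present in
    the test set.
    """

    accuracy: float
    labels: np.ndarray
    confusion_counts: np.ndarray
    confusion_pct: np.ndarray
    n_samples: int

    def per_class_counts(self) -> np.ndarray:
        return self.confusion_counts.sum(axis=1)


class ReadoutModel:
    """Fitted linear readout; thin wrapper storing the training scaler."""

    def __init__(self, svc: LinearSVC, mean: np.ndarray | None, scale: np.ndarray | None):
        self.svc = svc
        self.mean = mean
        self.scale = scale

    def _transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.mean is not None:
            x = (x - self.mean) / self.scale
        return x

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.svc.predict(self._transform(x))

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._transform(x))

    @property
    def classes_(self) -> np.ndarray:
        return self.svc.classes_


def train_readout(
    features: np.ndarray,
    labels: np.ndarray,
    config: ReadoutConfig | None = None,
    seed: int | None = None,
) -> ReadoutModel:
    """Fit the linear SVM readout on (n_samples, n_neurons) rate features.

    Features are used raw by default (all are rates on a common scale);
    set ``standardize`` in the config to z-score them.  Deterministic for
    a fixed seed.  Requires at least two classes.
    """
    config = config or ReadoutConfig()
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to train a readout")
    mean = scale = None
    if config.standardize:
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        x = (x - mean) / scale
    svc = LinearSVC(
        C=config.c, random_state=seed, max_iter=config.max_iter, dual="auto"
    )
    svc.fit(x, y)
    return ReadoutModel(svc, mean, scale)


def evaluate(model, features: np.ndarray, labels: np.ndarray) -> EvalReport:
    """Evaluate a readout (anything with ``predict``) on held-out features.

    The confusion matrix is computed over the union of true and predicted
    labels; percentages are per true-label row, matching the convention of
    feeding a fixed number of samples per class and counting predictions.
    """
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("empty test set")
    pred = np.asarray(model.predict(np.asarray(features, dtype=np.float64)))
    classes = np.unique(np.concatenate([y, pred]))
    counts = confusion_matrix(y, pred, labels=classes)
    row = counts.sum(axis=1, keepdims=True)
    pct = np.divide(
        100.0 * counts, row, out=np.zeros_like(counts, dtype=np.float64), where=row > 0
    )
    return EvalReport(
        accuracy=float((pred == y).mean()),
        labels=classes,
        confusion_counts=counts,
        confusion_pct=pct,
        n_samples=int(y.size),
    )


def save_model(model: ReadoutModel, path: str | Path) -> None:
    """Persist readout coefficients and intercepts as JSON."""
    payload = {
        "coef": model.svc.coef_.tolist(),
        "intercept": model.svc.intercept_.tolist(),
        "classes": model.svc.classes_.tolist(),
        "mean": None if model.mean is None else model.mean.tolist(),
        "scale": None if model.scale is None else model.scale.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ReadoutModel:
    payload = json.loads(Path(path).read_text())
    svc = LinearSVC()
    svc.coef_ = np.asarray(payload["coef"], dtype=np.float64)
    svc.intercept_ = np.asarray(payload["intercept"], dtype=np.float64)
    svc.classes_ = np.asarray(payload["classes"])
    mean = payload["mean"]
    scale = payload["scale"]
    return ReadoutModel(
        svc,
        None if mean is None else np.asarray(mean),
        None if scale is None else np.asarray(scale),
    )
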