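"""Probabilistic-classifier plumbing for the elicitation loop.

Two models drive the acquisition scores:

* ``M_u`` — trained once on the *observed* (cheap) features of every
  example, fully and partially observed alike, and then frozen: the loop
  never refits it.
* ``M_o`` — trained on the concatenated observed + elicitable features of
  the fully observed pool only, and retrained each time that pool grows.

Both are exposed through one contract (:class:`ProbabilisticClassifier`):
``predict_proba`` returns one class-posterior row per example with
columns in a fixed label order. The label order is the order of first
appearance in the label column, shared by both models so divergences
always compare aligned classes.

Supported families: gradient boosting (its class probabilities are used
directly) and a linear-kernel SVM whose margins are mapped to
probabilities by Platt scaling, i.e. the logistic transform
``1 / (1 + exp(A*s + B))`` fitted by maximum likelihood on the model's
own training scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Any

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

if TYPE_CHECKING:  # pragma: no cover
    from .data import SplitDataset

__all__ = [
    "ClassifierSpec",
    "ProbabilisticClassifier",
    "PlattCalibrator",
    "platt_calibrate",
    "train_observed_model",
    "train_full_model",
    "mean_log_likelihood",
    "DegenerateLabelError",
]

CLASSIFIER_FAMILIES = ("gradient_boosting", "linear_svm")

_GB_DEFAULTS: dict[str, Any] = {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1}
_SVM_DEFAULTS: dict[str, Any] = {"C": 1.0}


class DegenerateLabelError(ValueError):
    """Training labels contain a single class."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier family to fit and how.

    ``linear_svm`` produces margins, not probabilities, so it requires
    ``calibration="platt"`` (the default for that family); gradient
    boosting is probabilistic already and uses ``calibration="none"``.
    One spec instance is shared across every strategy in an experiment so
    all methods see identical classifier settings.
    """

    family: str = "gradient_boosting"
    params: dict[str, Any] = field(default_factory=dict)
    calibration: str | None = None
    calibration_cv: int | None = None  # optional k-fold Platt fitting

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"unknown classifier family {self.family!r}; expected one of {CLASSIFIER_FAMILIES}"
            )
        if self.calibration is None:
            object.__setattr__(
                self, "calibration", "platt" if self.family == "linear_svm" else "none"
            )
        if self.family == "linear_svm" and self.calibration != "platt":
            raise ValueError("linear_svm emits margins; calibration must be 'platt'")
        if self.calibration not in ("none", "platt"):
            raise ValueError("calibration must be 'none' or 'platt'")

    def resolved_params(self) -> dict[str, Any]:
        base = dict(_GB_DEFAULTS if self.family == "gradient_boosting" else _SVM_DEFAULTS)
        base.update(self.params)
        return base


@dataclass(frozen=True)
class PlattCalibrator:
    """Logistic map s -> 1 / (1 + exp(A*s + B)) from margins to probabilities."""

    A: float
    B: float

    def __call__(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return 1.0 / (1.0 + np.exp(self.A * s + self.B))


def platt_calibrate(scores, labels) -> PlattCalibrator:
    """Fit Platt's (A, B) by minimising the logistic negative log-likelihood.

    ``labels`` are 0/1 with 1 the positive class; both classes must be
    present. Equivalent to an unpenalised univariate logistic regression
    of the label on the score: P(y=1|s) = sigmoid(w*s + b) with A = -w,
    B = -b.
    """
    s = np.asarray(scores, dtype=float).reshape(-1, 1)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise DegenerateLabelError("Platt scaling needs both classes in the labels")
    # C=inf: unpenalised fit, i.e. the plain Platt maximum-likelihood problem
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    lr.fit(s, y)
    return PlattCalibrator(A=-float(lr.coef_[0, 0]), B=-float(lr.intercept_[0]))


class ProbabilisticClassifier:
    """Fitted classifier returning class posteriors in a fixed label order.

    Wraps the underlying sklearn estimator, the first-appearance label
    encoding, and (for margin classifiers) the per-class Platt
    calibrators. ``class_labels`` gives the column order of
    ``predict_proba``.
    """

    def __init__(self, estimator, class_labels: np.ndarray, n_features: int,
                 calibrators: list[PlattCalibrator] | None = None):
        self._estimator = estimator
        self.class_labels = np.asarray(class_labels)
        self.n_features = n_features
        self._calibrators = calibrators

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got shape {X.shape}"
            )
        if self._calibrators is None:
            return self._estimator.predict_proba(X)
        scores = self._estimator.decision_function(X)
        if scores.ndim == 1:  # binary margin: calibrate P(class 1)
            p1 = self._calibrators[0](scores)
            probs = np.column_stack([1.0 - p1, p1])
        else:  # one-vs-rest margins: calibrate each, renormalise
            cols = [cal(scores[:, k]) for k, cal in enumerate(self._calibrators)]
            probs = np.column_stack(cols)
            probs = probs / probs.sum(axis=1, keepdims=True)
        return probs

    def predict(self, X) -> np.ndarray:
        idx = np.argmax(self.predict_proba(X), axis=1)
        return self.class_labels[idx]


def encode_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode labels in order of first appearance.

    Returns (codes, classes) where ``classes[codes] == labels``. The
    first-appearance order is shared by every model in a run so posterior
    columns always align.
    """
    labels = np.asarray(labels)
    classes = labels[np.sort(np.unique(labels, return_index=True)[1])]
    lookup = {c: k for k, c in enumerate(classes.tolist())}
    codes = np.array([lookup[v] for v in labels.tolist()], dtype=int)
    return codes, classes


def _fit(X: np.ndarray, labels: np.ndarray, spec: ClassifierSpec, seed: int) -> ProbabilisticClassifier:
    codes, classes = encode_labels(labels)
    if classes.size < 2:
        raise DegenerateLabelError("training labels contain a single class")
    params = spec.resolved_params()
    if spec.family == "gradient_boosting":
        est = GradientBoostingClassifier(random_state=seed, **params)
        est.fit(X, codes)
        return ProbabilisticClassifier(est, classes, X.shape[1])
    est = LinearSVC(random_state=seed, **params)
    est.fit(X, codes)
    scores = est.decision_function(X)
    if scores.ndim == 1:
        cals = [platt_calibrate(scores, codes == 1)]
    else:
        cals = [platt_calibrate(scores[:, k], codes == k) for k in range(classes.size)]
    return ProbabilisticClassifier(est, classes, X.shape[1], calibrators=cals)


def train_observed_model(dataset: "SplitDataset", spec: ClassifierSpec, seed: int = 0) -> ProbabilisticClassifier:
    """Fit M_u on the observed features of *all* examples (E_o and E_u).

    Labels are known for the whole cohort, so the cheap-feature model
    sees every row once, up front; the elicitation loop treats the
    returned model as frozen.
    """
    return _fit(dataset.observed, dataset.labels, spec, seed)


def train_full_model(dataset: "SplitDataset", spec: ClassifierSpec, seed: int = 0) -> ProbabilisticClassifier:
    """Fit M_o on observed + elicitable features of the current E_o only."""
    idx = dataset.e_o
    X = dataset.full_features(idx)
    if np.isnan(X).any():
        raise ValueError("missing elicitable values inside E_o")
    return _fit(X, dataset.labels[idx], spec, seed)


def mean_log_likelihood(
    model: ProbabilisticClassifier, X, labels, *, clamp_eps: float = 1e-10
) -> float:
    """Per-example mean log P(y_i | x_i) in nats; always <= 0 up to clamping.

    The mean (not the sum) makes the convergence tolerance independent of
    how large the training pool has grown.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("empty example set")
    probs = model.predict_proba(X)
    lookup = {c: k for k, c in enumerate(model.class_labels.tolist())}
    cols = np.array([lookup[v] for v in labels.tolist()], dtype=int)
    p_true = np.clip(probs[np.arange(len(labels)), cols], clamp_eps, None)
    return float(np.mean(np.log(p_true)))
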