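"""Base-model registry, exhaustive combination enumeration, and soft voting.

Five base classifiers (LR, SVM, KNN, RF, AdaBoost) are used with library
default hyperparameters and a fixed random state.  Every subset of size 3,
4 or 5 — sixteen in total — is evaluated as a soft-voting ensemble: member
class probabilities are averaged with uniform weights and the class with
the larger mean probability is predicted (a tie at exactly 0.5 goes to the
positive class, GBM).

The SVM is fitted with probability outputs enabled (internal Platt-style
calibration) because soft voting requires class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import SingleClassError

#: canonical base-model order; subset enumeration follows it
MODEL_IDS: tuple[str, ...] = ("LR", "SVM", "KNN", "RF", "AdaBoost")


@dataclass(frozen=True)
class ModelSpec:
    """A base-model identifier with its (default) hyperparameters and seed."""

    identifier: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def build(self):
        return build_model(self.identifier, seed=self.seed,
                           **self.hyperparameters)


def build_model(identifier: str, seed: int = 0, **overrides):
    """Instantiate a base classifier with its default hyperparameters.

    Defaults: KNN k=5 Minkowski; SVM RBF C=1 gamma='scale' with probability
    outputs; LR L2 C=1; RF 100 Gini trees; AdaBoost 50 rounds, learning
    rate 1.0.
    """
    if identifier == "LR":
        params = dict(C=1.0, tol=1e-4, fit_intercept=True,
                      max_iter=1000, random_state=seed)
    elif identifier == "SVM":
        params = dict(C=1.0, kernel="rbf", gamma="scale", random_state=seed)
    elif identifier == "KNN":
        params = dict(n_neighbors=5, metric="minkowski")
    elif identifier == "RF":
        params = dict(n_estimators=100, criterion="gini", random_state=seed)
    elif identifier == "AdaBoost":
        params = dict(n_estimators=50, learning_rate=1.0, random_state=seed)
    else:
        raise ValueError(f"unknown model identifier: {identifier}")
    params.update(overrides)
    if identifier == "SVM":
        # soft voting needs class probabilities; wrap the (default-
        # hyperparameter) SVC in cross-validated Platt calibration
        return CalibratedClassifierCV(SVC(**params), ensemble=False)
    cls = {"LR": LogisticRegression, "KNN": KNeighborsClassifier,
           "RF": RandomForestClassifier, "AdaBoost": AdaBoostClassifier}
    return cls[identifier](**params)


@dataclass(frozen=True)
class EnsembleSpec:
    """A numbered subset (size >= 3) of the five base-model identifiers."""

    set_index: int
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("ensemble members must be unique")

    @property
    def label(self) -> str:
        return " + ".join(self.members)


def enumerate_ensembles(models=MODEL_IDS, min_size: int = 3
                        ) -> list[EnsembleSpec]:
    """All subsets of size >= ``min_size``, ordered by size then by position
    in the given model order (C(5,3)+C(5,4)+C(5,5) = 16 for the canonical
    five)."""
    models = tuple(models)
    if not models:
        raise ValueError("model list must be non-empty")
    if len(set(models)) != len(models):
        raise ValueError("model identifiers must be unique")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    specs = []
    idx = 1
    for size in range(min_size, len(models) + 1):
        for combo in combinations(models, size):
            specs.append(EnsembleSpec(set_index=idx, members=combo))
            idx += 1
    return specs


def fit_members(spec: EnsembleSpec, X_train, y_train, seed: int = 0) -> dict:
    """Fit each member of the ensemble independently on the training fold."""
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise SingleClassError("training fold contains a single class")
    fitted = {}
    for member in spec.members:
        model = build_model(member, seed=seed)
        model.fit(np.asarray(X_train, dtype=float), y)
        fitted[member] = model
    return fitted


def predict_proba_matrix(model, X) -> np.ndarray:
    """Per-sample class probabilities ordered as (negative, positive)."""
    proba = model.predict_proba(np.asarray(X, dtype=float))
    order = np.argsort(model.classes_)
    return proba[:, order]


def soft_vote(prob_matrices: list[np.ndarray]
              ) -> tuple[np.ndarray, np.ndarray]:
    """Average member probability matrices and predict the larger class.

    Returns ``(ensemble_probabilities, predicted_labels)``; a positive-class
    mean probability of exactly 0.5 predicts the positive class (GBM).
    """
    if not prob_matrices:
        raise ValueError("soft_vote requires at least one member")
    stack = np.stack([np.asarray(p, dtype=float) for p in prob_matrices])
    if not all(m.shape == stack[0].shape for m in stack):
        raise ValueError("probability matrices must share dimensions")
    mean = stack.mean(axis=0)
    labels = (mean[:, 1] >= 0.5).astype(int)
    return mean, labels
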