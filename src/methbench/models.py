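"""Uniform train/score contract over the classifier suite.

Nine shallow learners from scikit-learn plus the three deep models from
:mod:`methbench.nn`, all behind one interface: ``train(spec, X, y)``
returns a fitted object whose ``score(X)`` yields a per-sample case
probability in [0, 1].  Shallow models run with their library defaults
unless the ModelSpec's hyperparameters override them; every family is
seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .nn import JointAE, JointVAE, SimpleDNN

__all__ = ["ModelSpec", "TrainedModel", "train", "MODEL_FAMILIES",
           "reconstruction_quality"]

MODEL_FAMILIES = (
    "logreg_none", "logreg_l1", "logreg_l2", "logreg_elasticnet",
    "decision_tree", "random_forest", "svm_linear", "svm_rbf", "adaboost",
    "simple_dnn", "joint_ae", "joint_vae",
)

DEEP_FAMILIES = ("simple_dnn", "joint_ae", "joint_vae")


@dataclass
class ModelSpec:
    """Which classifier to train, on which methylation scale, and how."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    scale: str = "M"  # the beta/M choice is itself a hyperparameter

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {MODEL_FAMILIES}")
        if self.scale not in ("beta", "M"):
            raise ValueError("scale must be 'beta' or 'M'")

    def manifest(self) -> str:
        return json.dumps({"family": self.family, "seed": self.seed,
                           "scale": self.scale,
                           "hyperparameters": self.hyperparameters},
                          sort_keys=True)


class TrainedModel:
    """A fitted classifier with a [0, 1] scoring interface."""

    def __init__(self, spec: ModelSpec, estimator, kind: str):
        self.spec = spec
        self.estimator = estimator
        self._kind = kind  # 'proba' | 'decision' | 'deep'

    def score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._kind == "proba":
            return self.estimator.predict_proba(X)[:, 1]
        if self._kind == "decision":
            return expit(self.estimator.decision_function(X))
        return self.estimator.score(X)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.score(X) >= threshold).astype(int)


def _build_shallow(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.family == "logreg_none":
        return LogisticRegression(C=np.inf, max_iter=hp.pop("max_iter", 1000),
                                  random_state=seed, **hp), "proba"
    if spec.family == "logreg_l2":
        return LogisticRegression(l1_ratio=0.0, max_iter=hp.pop("max_iter", 1000),
                                  random_state=seed, **hp), "proba"
    if spec.family == "logreg_l1":
        return LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                  max_iter=hp.pop("max_iter", 1000),
                                  random_state=seed, **hp), "proba"
    if spec.family == "logreg_elasticnet":
        return LogisticRegression(solver="saga",
                                  l1_ratio=hp.pop("l1_ratio", 0.5),
                                  max_iter=hp.pop("max_iter", 1000),
                                  random_state=seed, **hp), "proba"
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp), "proba"
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp), "proba"
    if spec.family == "svm_linear":
        return SVC(kernel="linear", random_state=seed, **hp), "decision"
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf", random_state=seed, **hp), "decision"
    if spec.family == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp), "proba"
    raise AssertionError(spec.family)


def _build_deep(spec: ModelSpec, n_features: int):
    hp = dict(spec.hyperparameters)
    epochs = hp.pop("epochs", None)
    batch_size = hp.pop("batch_size", 128)
    lr = hp.pop("lr", 1e-4)
    if spec.family == "simple_dnn":
        net = SimpleDNN(n_features, lr=lr, seed=spec.seed,
                        **{k: hp[k] for k in ("hidden", "l2", "dropout") if k in hp})
    elif spec.family == "joint_ae":
        net = JointAE(n_features, scale=spec.scale,
                      loss_weight=hp.pop("loss_weight", 0.5), lr=lr,
                      l2=hp.pop("l2", 0.0), seed=spec.seed)
    else:
        net = JointVAE(n_features, scale=spec.scale,
                       clf_scale=hp.pop("clf_scale", 1.0), lr=lr,
                       l2=hp.pop("l2", 0.0), seed=spec.seed)
    return net, epochs, batch_size


def train(spec: ModelSpec, features, labels) -> TrainedModel:
    """Fit one classifier family on a samples x k feature matrix."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(float).ravel()
    if np.isnan(X).any():
        raise ValueError("NaN in features")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in training labels")
    if spec.family in DEEP_FAMILIES:
        net, epochs, batch_size = _build_deep(spec, X.shape[1])
        net.fit(X, y, epochs=epochs, batch_size=batch_size)
        return TrainedModel(spec, net, "deep")
    est, kind = _build_shallow(spec)
    est.fit(X, y.astype(int))
    return TrainedModel(spec, est, kind)


def reconstruction_quality(model: TrainedModel, features) -> float:
    """Pearson r between input and its autoencoder reconstruction."""
    if not hasattr(model.estimator, "reconstruct"):
        raise ValueError(f"model family {model.spec.family!r} has no decoder")
    return model.estimator.reconstruction_quality(np.asarray(features, float))
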