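"""Ten classifiers behind one fit/predict contract, registry-discoverable by
their benchmark abbreviations.

=============  ==========================================================
GNB            Gaussian naive Bayes
KNN            K-nearest neighbours, K = 10
LDA            linear discriminant analysis (as a classifier)
LR             multinomial logistic regression, L2 penalty, C = 1
RF             random forest, 100 trees
SVM_LIN        linear SVM, C = 1
SVM_LIN_CV     linear SVM, C tuned by grid search in an inner CV
SVM_RBF        RBF SVM, C = 1, kernel scale by the median heuristic
SVM_RBF_CV     RBF SVM, C and kernel scale sigma tuned by grid search
NN             multi-layer perceptron, one hidden layer of 128 units
=============  ==========================================================

SVMs are one-vs-rest; ties break by decision-function margin and then by
(sorted) label order.  All stochastic methods consume the spec seed.  The
``*_CV`` variants only carry their candidate grid here — the actual nested
search lives in :mod:`ramantax.benchmark`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .dimred import median_pairwise_distance

CLASSIFIER_METHODS = (
    "GNB", "KNN", "LDA", "LR", "RF",
    "SVM_LIN", "SVM_LIN_CV", "SVM_RBF", "SVM_RBF_CV", "NN",
)
CV_TUNED = frozenset({"SVM_LIN_CV", "SVM_RBF_CV"})

_DEFAULT_GRIDS = {
    "SVM_LIN_CV": {"C": (0.01, 0.1, 1.0, 10.0, 100.0)},
    # sigma_scale multiplies the median-pairwise-distance heuristic
    "SVM_RBF_CV": {"C": (0.01, 0.1, 1.0, 10.0, 100.0),
                   "sigma_scale": (0.01, 0.1, 1.0, 10.0)},
}


class ClassifierConfigError(ValueError):
    """Invalid classifier specification."""


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier with its fixed parameters and (for CV variants) grid."""

    method: str
    fixed_params: dict = field(default_factory=dict)
    tunable_grid: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in CLASSIFIER_METHODS:
            raise ClassifierConfigError(
                f"unknown classifier {self.method!r}; known: {CLASSIFIER_METHODS}"
            )
        if self.tunable_grid is None:
            grid = dict(_DEFAULT_GRIDS.get(self.method, {}))
        else:
            grid = dict(self.tunable_grid)
        if self.method in CV_TUNED and not grid:
            raise ClassifierConfigError(
                f"{self.method} requires a nonempty hyperparameter grid"
            )
        if self.method not in CV_TUNED and grid:
            raise ClassifierConfigError(
                f"{self.method} is not CV-tuned; its grid must be empty"
            )
        object.__setattr__(self, "tunable_grid", grid)

    @property
    def k_neighbors(self) -> int:
        return int(self.fixed_params.get("n_neighbors", 10))

    @property
    def n_trees(self) -> int:
        return int(self.fixed_params.get("n_estimators", 100))


@dataclass
class FittedClassifier:
    spec: ClassifierSpec
    estimator: object
    classes: np.ndarray
    n_features: int
    hyperparams: dict = field(default_factory=dict)


def build_estimator(spec: ClassifierSpec, X: np.ndarray,
                    hyperparams: dict | None = None):
    """Instantiate the underlying estimator for given hyperparameters.

    ``X`` is needed by the RBF variants to resolve the median-distance
    kernel-scale heuristic at fit scale.
    """
    hp = dict(hyperparams or {})
    m = spec.method
    if m == "GNB":
        return GaussianNB()
    if m == "KNN":
        return KNeighborsClassifier(n_neighbors=spec.k_neighbors)
    if m == "LDA":
        return LinearDiscriminantAnalysis()
    if m == "LR":
        return LogisticRegression(C=spec.fixed_params.get("C", 1.0),
                                  max_iter=2000)
    if m == "RF":
        return RandomForestClassifier(n_estimators=spec.n_trees,
                                      random_state=spec.seed)
    if m in ("SVM_LIN", "SVM_LIN_CV"):
        C = hp.get("C", spec.fixed_params.get("C", 1.0))
        return OneVsRestClassifier(SVC(kernel="linear", C=C))
    if m in ("SVM_RBF", "SVM_RBF_CV"):
        C = hp.get("C", spec.fixed_params.get("C", 1.0))
        sigma = median_pairwise_distance(X, seed=spec.seed) * hp.get(
            "sigma_scale", spec.fixed_params.get("sigma_scale", 1.0)
        )
        gamma = 1.0 / (2.0 * max(sigma, 1e-12) ** 2)
        return OneVsRestClassifier(SVC(kernel="rbf", C=C, gamma=gamma))
    if m == "NN":
        return MLPClassifier(hidden_layer_sizes=(128,), max_iter=200,
                             early_stopping=True, random_state=spec.seed)
    raise AssertionError(m)  # unreachable


def fit_classifier(spec: ClassifierSpec, features: np.ndarray, labels,
                   hyperparams: dict | None = None) -> FittedClassifier:
    """Fit one classifier; deterministic given the spec seed."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    est = build_estimator(spec, X, hyperparams)
    est.fit(X, y)
    return FittedClassifier(spec=spec, estimator=est, classes=classes,
                            n_features=X.shape[1],
                            hyperparams=dict(hyperparams or {}))


def predict(fc: FittedClassifier, features: np.ndarray) -> np.ndarray:
    """Predict one training-set label per row; empty input -> empty output."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    if X.shape[1] != fc.n_features:
        raise ValueError(
            f"feature dimensionality {X.shape[1]} differs from the "
            f"{fc.n_features} the model was trained on"
        )
    if X.shape[0] == 0:
        return np.array([], dtype=fc.classes.dtype)
    return np.asarray(fc.estimator.predict(X))
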