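"""Window classifiers: RBF-SVM, decision tree, random forest and KNN.

Each classifier consumes raw LDV signal windows (no feature extraction) and
emits a beat probability.  Hyperparameters are selected by grid search with
stratified 5-fold cross-validation on the training set, maximizing the
beat-class f1; evaluation uses the leave-one-subject-out (LOSO) protocol so
no subject contributes to both training and test.

Because absolute LDV amplitudes depend on the optics and electronics, the
windows are z-score standardized with training-set statistics by default
(disable with ``scale=False``), making predictions invariant to affine
rescaling of the raw signal.

The soft-margin RBF-SVM dual solution (coefficients ``a_k* y_k`` bounded by
the box constraint C and summing to zero, decision value a kernel expansion
over the support vectors plus a bias) is exposed through :func:`svm_dual`
for direct verification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .windowing import BEAT, NO_BEAT, WindowDataset

KINDS = ("svm", "dt", "rf", "knn")


def gaussian_kernel(x, x2, gamma: float) -> float:
    """RBF kernel exp(-gamma * ||x - x2||^2).

    Symmetric in its arguments, in (0, 1], and equal to 1 iff x == x2.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise ValueError("inputs must have equal length")
    return float(np.exp(-gamma * np.sum((x - x2) ** 2)))


def grid_spaces(kind: str) -> dict[str, list]:
    """Hyperparameter search space for each classifier kind.

    svm: gamma in {0.001, 0.01, 0.1} x C in {1, 10, 100};
    rf: depth in {3, 4, 5} x trees in {50..500 step 50, 600};
    dt: depth in {5, 10, 15, 20}; knn: K in {3, 5, 7, 9}.
    """
    if kind == "svm":
        return {"gamma": [0.001, 0.01, 0.1], "C": [1, 10, 100]}
    if kind == "rf":
        return {
            "max_depth": [3, 4, 5],
            "n_estimators": [50, 100, 150, 200, 250, 300, 350, 400, 450, 500, 600],
        }
    if kind == "dt":
        return {"max_depth": [5, 10, 15, 20]}
    if kind == "knn":
        return {"n_neighbors": [3, 5, 7, 9]}
    raise ValueError(f"unknown classifier kind: {kind!r}")


@dataclass
class ClassifierSpec:
    """What to train: classifier kind, search grid, inner folds and seed."""

    kind: str
    grid: dict | None = None
    inner_folds: int = 5
    seed: int = 0
    scale: bool = True

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind: {self.kind!r}")
        if self.grid is None:
            self.grid = grid_spaces(self.kind)


@dataclass
class TrainedClassifier:
    """A fitted window classifier with its scaler and chosen hyperparameters."""

    kind: str
    chosen_hyperparams: dict
    model: object
    scaler: StandardScaler | None
    n_features: int

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"window length {X.shape[1]} does not match training "
                f"length {self.n_features}"
            )
        return self.scaler.transform(X) if self.scaler is not None else X


def _base_estimator(kind: str, seed: int):
    if kind == "svm":
        # Platt sigmoid calibration fitted on inner folds; ensemble=False
        # refits the single SVC on the whole training set
        return CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed),
            method="sigmoid",
            cv=StratifiedKFold(5, shuffle=True, random_state=seed),
            ensemble=False,
        )
    if kind == "rf":
        return RandomForestClassifier(random_state=seed)
    if kind == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if kind == "knn":
        return KNeighborsClassifier(metric="euclidean")
    raise ValueError(f"unknown classifier kind: {kind!r}")


def fit(spec: ClassifierSpec, train: WindowDataset) -> TrainedClassifier:
    """Grid-search, cross-validate and refit one classifier on ``train``.

    The inner stratified 5-fold CV scores each grid point by beat-class f1;
    the best point is refit on the full (standardized) training set.

    Raises
    ------
    ValueError
        If the training set contains a single class or fewer than
        ``inner_folds`` samples in either class.
    """
    y = train.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if counts.min() < spec.inner_folds:
        raise ValueError(
            f"need >= {spec.inner_folds} samples per class for inner CV"
        )
    scaler = None
    X = train.X
    if spec.scale:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    cv = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True, random_state=spec.seed)
    grid = spec.grid
    if spec.kind == "svm":
        grid = {f"estimator__{k}": v for k, v in grid.items()}
    search = GridSearchCV(
        _base_estimator(spec.kind, spec.seed),
        grid,
        scoring="f1",  # f1 of the positive (beat) class
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    return TrainedClassifier(
        kind=spec.kind,
        chosen_hyperparams={k.split("__")[-1]: v for k, v in search.best_params_.items()},
        model=search.best_estimator_,
        scaler=scaler,
        n_features=train.X.shape[1],
    )


def predict_proba(model: TrainedClassifier, X) -> np.ndarray:
    """Beat-class probability for each window, in [0, 1]."""
    Xt = model._transform(X)
    proba = model.model.predict_proba(Xt)
    beat_col = int(np.flatnonzero(model.model.classes_ == BEAT)[0])
    return proba[:, beat_col]


def predict(model: TrainedClassifier, X) -> np.ndarray:
    """Hard beat/no-beat labels: beat iff beat probability > 0.5.

    The strict inequality breaks probability ties toward no-beat
    (conservative detection).
    """
    return np.where(predict_proba(model, X) > 0.5, BEAT, NO_BEAT)


def svm_dual(model: TrainedClassifier) -> dict:
    """Expose the fitted SVM dual solution for independent verification.

    Returns gamma, C, the support vectors (in standardized feature space),
    the signed dual coefficients ``a_k* y_k``, and the bias b.  The decision
    value for a (standardized) input x is
    ``sum_k a_k* y_k exp(-gamma ||x - sv_k||^2) + b``.
    """
    if model.kind != "svm":
        raise ValueError("svm_dual requires an SVM model")
    svc: SVC = model.model.calibrated_classifiers_[0].estimator
    return {
        "gamma": float(svc.gamma),
        "C": float(svc.C),
        "support_vectors": np.asarray(svc.support_vectors_),
        "dual_coef": np.asarray(svc.dual_coef_[0]),
        "bias": float(svc.intercept_[0]),
    }


def loso_split(ds: WindowDataset) -> Iterator[tuple[str, WindowDataset, WindowDataset]]:
    """Leave-one-subject-out folds: (held-out subject, train set, test set).

    One fold per subject; the test folds partition the dataset exactly.
    Requires at least two subjects.
    """
    subjects = sorted(set(ds.subject_ids))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    for subj in subjects:
        test_mask = ds.subject_ids == subj
        yield subj, ds.subset(~test_mask), ds.subset(test_mask)
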