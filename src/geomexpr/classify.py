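"""Classifiers, SMOTE balancing and the repeated-CV evaluation protocol.

Four classifier families are supported, mirroring the reference
protocol: quadratic and cubic polynomial-kernel SVMs, K(x, y) =
(1 + x.y)^d with d in {2, 3}, built one-vs-one over the C(C-1)/2
class pairs and combined by majority vote; 1-nearest-neighbour; and a
random-subspace ensemble of 200 1-NN learners, each trained on
round(d/2) features drawn without replacement, combined by averaging
per-class scores.

Evaluation is n independent stratified 10-fold cross-validations with
different shuffles; summary statistics (std, median, mean, max, min)
are taken over the per-repetition mean accuracies, and the pooled
confusion matrix is row-normalized to percent in the fixed class
order SU, SA, HA, FE, DI, AN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .landmarks import DISPLAY_ORDER

__all__ = [
    "ClassifierSpec",
    "SVM3",
    "SVM2",
    "KNN1",
    "EKNN",
    "make_estimator",
    "smote_balance",
    "train_predict",
    "evaluate",
    "CVReport",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative description of one of the four classifier families.

    ``family`` is one of ``svm_poly``, ``knn``,
    ``subspace_knn_ensemble``.  For SVMs ``degree`` is the kernel
    exponent (2 or 3) and ``box_constraint`` the soft-margin C.  For
    the ensemble, ``n_learners`` weak 1-NN learners each see
    ``subspace_dims`` features (default round(d/2), resolved at fit
    time).  ``standardize`` rescales features using statistics learned
    on the training split only.
    """

    family: str = "svm_poly"
    degree: int = 3
    k: int = 1
    n_learners: int = 200
    subspace_dims: Optional[int] = None  # None -> round(d/2)
    box_constraint: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("svm_poly", "knn", "subspace_knn_ensemble"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.family == "svm_poly" and self.degree not in (2, 3):
            raise ValueError(f"svm degree must be 2 or 3, got {self.degree}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


SVM3 = ClassifierSpec(family="svm_poly", degree=3)
SVM2 = ClassifierSpec(family="svm_poly", degree=2)
KNN1 = ClassifierSpec(family="knn", k=1)
EKNN = ClassifierSpec(family="subspace_knn_ensemble", k=1)


def make_estimator(spec: ClassifierSpec, n_features: int, seed: Optional[int] = None):
    """Build the scikit-learn estimator for a spec.

    The polynomial kernel is parameterized as gamma=1, coef0=1 so that
    it evaluates exactly (1 + x.y)^d.  SVC performs one-vs-one voting
    internally; ties fall to the earliest class in the label encoding
    (see :func:`evaluate` for the fixed expression order).
    """
    if spec.family == "svm_poly":
        est: BaseEstimator = SVC(
            kernel="poly", degree=spec.degree, gamma=1.0, coef0=1.0, C=spec.box_constraint
        )
    elif spec.family == "knn":
        est = KNeighborsClassifier(n_neighbors=spec.k)
    else:
        m = spec.subspace_dims if spec.subspace_dims is not None else max(1, round(n_features / 2))
        if not 1 <= m <= n_features:
            raise ValueError(f"subspace_dims {m} outside [1, {n_features}]")
        est = BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=spec.k),
            n_estimators=spec.n_learners,
            max_features=m,
            max_samples=1.0,
            bootstrap=False,
            bootstrap_features=False,
            random_state=None if seed is None else int(seed) % (2**31),
        )
    if spec.standardize:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    target_per_class: int,
    k_neighbors: int = 5,
    rng: Union[int, np.random.Generator, None] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Oversample every class to exactly ``target_per_class`` rows.

    Synthetic rows follow the SMOTE construction: for a random
    original row x of the minority class, pick one of its k
    same-class nearest neighbours x_nn and emit x + u * (x_nn - x)
    with u ~ Uniform(0, 1).  Original rows are retained unchanged; a
    class already at the target is passed through untouched.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    classes, counts = np.unique(y, return_counts=True)
    over = classes[counts > target_per_class]
    if over.size:
        raise ValueError(
            f"class {over[0]!r} has more rows ({counts.max()}) than the target "
            f"{target_per_class}; SMOTE only oversamples"
        )
    X_parts = [X]
    y_parts = [y]
    for cls, count in zip(classes, counts):
        need = target_per_class - count
        if need == 0:
            continue
        if count < 2:
            raise ValueError(f"class {cls!r} has a single member; SMOTE needs a neighbour")
        Xc = X[y == cls]
        k = min(k_neighbors, count - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, count, size=need)
        pick = neigh[base, rng.integers(0, k, size=need)]
        u = rng.random(need)[:, None]
        X_parts.append(Xc[base] + u * (Xc[pick] - Xc[base]))
        y_parts.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(X_parts), np.concatenate(y_parts)


def _encode_labels(y: np.ndarray, class_order: Sequence[str]):
    """Map labels to integer codes in the fixed display order.

    Encoding before fitting makes one-vs-one vote ties resolve to the
    lowest class index in that order, independent of the labels'
    lexicographic order.
    """
    lut = {c: i for i, c in enumerate(class_order)}
    return np.array([lut[v] for v in y]), np.asarray(class_order)


def _resolve_class_order(y: np.ndarray) -> List[str]:
    present = set(np.unique(y).tolist())
    if present <= set(DISPLAY_ORDER):
        return [c for c in DISPLAY_ORDER if c in present]
    return sorted(present, key=str)


def train_predict(
    spec_or_estimator,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: Optional[int] = None,
):
    """Fit one classifier and predict labels (+ per-class scores).

    Returns ``(labels, scores, class_order)``; ``scores`` holds
    per-class decision values — one-vs-one vote counts for SVMs,
    averaged neighbour votes for the k-NN family.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    if X_test.shape[1] != X_train.shape[1]:
        raise ValueError(
            f"test feature count {X_test.shape[1]} != train feature count {X_train.shape[1]}"
        )
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    class_order = _resolve_class_order(y_train)
    y_enc, classes = _encode_labels(y_train, class_order)
    if isinstance(spec_or_estimator, ClassifierSpec):
        est = make_estimator(spec_or_estimator, X_train.shape[1], seed=seed)
    else:
        est = clone(spec_or_estimator)
    est.fit(X_train, y_enc)
    pred = est.predict(X_test)
    final = est.steps[-1][1] if isinstance(est, Pipeline) else est
    if hasattr(final, "predict_proba") and not isinstance(final, SVC):
        scores = est.predict_proba(X_test)
    elif isinstance(final, SVC):
        scores = est.decision_function(X_test)  # OvR-aggregated vote values
    else:
        scores = None
    return classes[pred], scores, list(classes)


@dataclass
class CVReport:
    """Summary of repeated stratified k-fold evaluation."""

    rep_accuracies: List[float]
    confusion: np.ndarray  # row-normalized, percent
    class_order: List[str]
    n_repetitions: int
    folds: int
    confusion_counts: np.ndarray = field(default=None)  # pooled raw counts

    @property
    def std(self) -> float:
        return float(np.std(self.rep_accuracies, ddof=1)) if len(self.rep_accuracies) > 1 else 0.0

    @property
    def median(self) -> float:
        return float(np.median(self.rep_accuracies))

    @property
    def mean(self) -> float:
        return float(np.mean(self.rep_accuracies))

    @property
    def max(self) -> float:
        return float(np.max(self.rep_accuracies))

    @property
    def min(self) -> float:
        return float(np.min(self.rep_accuracies))

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "Standard deviation": self.std,
                "Median accuracy": self.median,
                "Mean accuracy": self.mean,
                "Maximum accuracy": self.max,
                "Minimum accuracy": self.min,
            }
        )

    def confusion_frame(self, as_int: bool = False) -> pd.DataFrame:
        cm = np.round(self.confusion).astype(int) if as_int else self.confusion
        return pd.DataFrame(cm, index=self.class_order, columns=self.class_order)

    def to_dict(self) -> dict:
        return {
            "n_repetitions": self.n_repetitions,
            "folds": self.folds,
            "rep_accuracies": [float(a) for a in self.rep_accuracies],
            "summary": {k: float(v) for k, v in self.summary().items()},
            "class_order": list(self.class_order),
            "confusion_percent": self.confusion.tolist(),
            "confusion_counts": self.confusion_counts.tolist()
            if self.confusion_counts is not None
            else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def evaluate(
    spec_or_estimator,
    X: np.ndarray,
    y: np.ndarray,
    n_repetitions: int = 10,
    folds: int = 10,
    seed: int = 0,
    smote_within_folds: Optional[int] = None,
) -> CVReport:
    """Repeated stratified k-fold cross-validation.

    Each repetition is an independent stratified ``folds``-fold CV
    with its own shuffle; the repetition accuracy is the mean over its
    folds.  Per-fold predictions are pooled into one confusion matrix.

    ``smote_within_folds`` optionally applies SMOTE to the *training
    split of every fold* (to the given per-class target) instead of
    expecting pre-balanced data — the leakage-free variant of the
    balance-then-split protocol, with different absolute numbers.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has only {counts.min()} rows, fewer than "
            f"{folds} folds; balance the classes first (e.g. with smote_balance)"
        )
    if smote_within_folds is not None and smote_within_folds < counts.max():
        raise ValueError(
            f"smote_within_folds target {smote_within_folds} is below the largest "
            f"class ({counts.max()} rows)"
        )
    class_order = _resolve_class_order(y)
    n_classes = len(class_order)
    lut = {c: i for i, c in enumerate(class_order)}
    y_idx = np.array([lut[v] for v in y])
    pooled = np.zeros((n_classes, n_classes), dtype=np.int64)
    rep_accuracies = []
    root = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_repetitions)]
    for rep, rep_seed in enumerate(rep_seeds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        fold_accs = []
        for fold_i, (tr, te) in enumerate(skf.split(X, y)):
            X_tr, y_tr = X[tr], y[tr]
            if smote_within_folds is not None:
                X_tr, y_tr = smote_balance(
                    X_tr, y_tr, smote_within_folds,
                    rng=np.random.default_rng([rep_seed, fold_i]),
                )
            pred, _, _ = train_predict(
                spec_or_estimator, X_tr, y_tr, X[te], seed=rep_seed * 131 + fold_i
            )
            pred_idx = np.array([lut[v] for v in pred])
            fold_accs.append(float((pred_idx == y_idx[te]).mean()))
            np.add.at(pooled, (y_idx[te], pred_idx), 1)
        rep_accuracies.append(float(np.mean(fold_accs)) * 100.0)
    row_sums = pooled.sum(axis=1, keepdims=True)
    confusion = np.divide(
        pooled * 100.0, row_sums, out=np.zeros_like(pooled, dtype=float), where=row_sums > 0
    )
    return CVReport(
        rep_accuracies=rep_accuracies,
        confusion=confusion,
        class_order=class_order,
        n_repetitions=n_repetitions,
        folds=folds,
        confusion_counts=pooled,
    )
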