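"""Tile-level histology classification.

Four classifiers — 1-nearest-neighbor, linear SVM, RBF SVM, and a boosted
decision-tree ensemble with per-round random undersampling (RUSBoost) — are
trained on the retained texture features under stratified 8-fold
cross-validation. Each prediction is a probability profile over the 16
tissue classes; background may participate as a 17th training class, in
which case tissue probabilities are renormalized.

Standardization and feature filtering are always fit on the training fold
only; the fold plan is deterministic given the seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

log = logging.getLogger(__name__)

MODEL_NAMES = ("1NN", "linSVM", "rbfSVM", "ensembleTree")


@dataclass
class ProbabilityProfile:
    """Per-tile class probabilities; prediction = argmax, ties to lowest id."""

    tile_id: str
    class_ids: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-9):
            raise ValueError(f"tile {self.tile_id}: probabilities sum to {self.probs.sum()}")

    @property
    def predicted(self) -> int:
        return int(self.class_ids[int(np.argmax(self.probs))])


@dataclass
class FoldPlan:
    """Stratified fold assignment: tile index -> fold."""

    k: int
    assignment: np.ndarray

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.assignment == fold
        return np.flatnonzero(~test), np.flatnonzero(test)


def stratified_kfold(labels: np.ndarray, k: int = 8, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan; per-class fold counts differ by at most one.

    Classes with fewer than k members are allowed (some folds then miss
    them) but trigger a warning.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    classes, counts = np.unique(labels, return_counts=True)
    thin = classes[counts < k]
    if len(thin):
        warnings.warn(
            f"classes {thin.tolist()} have fewer than {k} tiles; "
            "some folds will not contain them",
            stacklevel=2,
        )
    # Round-robin within each shuffled class: per-class fold counts differ by
    # at most one, and classes thinner than k are still assigned somewhere.
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    offset = 0
    for c in classes:
        members = np.flatnonzero(labels == c)
        rng.shuffle(members)
        assignment[members] = (np.arange(len(members)) + offset) % k
        offset += len(members)  # stagger so small classes spread over folds
    return FoldPlan(k, assignment)


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost (SAMME) over decision trees with random undersampling.

    Each boosting round draws a class-balanced training subset — every class
    undersampled to the minority count, sampling weighted by the current
    boosting distribution — so majority classes cannot dominate any round.
    Per-round class counts are kept in ``round_class_counts_``.
    """

    def __init__(self, n_estimators: int = 50, max_depth: int = 8, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RUSBoostClassifier":
        rng = np.random.default_rng(self.random_state)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, n_classes = len(y), len(self.classes_)
        if n_classes < 2:
            raise ValueError("training data contains a single class")
        w = np.full(n, 1.0 / n)
        self.estimators_: list[DecisionTreeClassifier] = []
        self.estimator_weights_: list[float] = []
        self.round_class_counts_: list[dict] = []
        min_count = int(np.bincount(y_idx).min())
        for _ in range(self.n_estimators):
            idx_parts = []
            for c in range(n_classes):
                members = np.flatnonzero(y_idx == c)
                p = w[members] / w[members].sum()
                take = rng.choice(members, size=min_count, replace=len(members) < min_count, p=p)
                idx_parts.append(take)
            idx = np.concatenate(idx_parts)
            self.round_class_counts_.append(
                {int(self.classes_[c]) if np.issubdtype(self.classes_.dtype, np.integer) else self.classes_[c]: min_count
                 for c in range(n_classes)}
            )
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth, random_state=int(rng.integers(2**31))
            )
            tree.fit(X[idx], y_idx[idx])
            pred = tree.predict(X)
            err = float(w[pred != y_idx].sum())
            if err >= 1.0 - 1.0 / n_classes:
                continue  # worse than chance: discard round
            err = max(err, 1e-10)
            alpha = np.log((1.0 - err) / err) + np.log(n_classes - 1.0)
            self.estimators_.append(tree)
            self.estimator_weights_.append(alpha)
            w *= np.exp(alpha * (pred != y_idx))
            w /= w.sum()
        if not self.estimators_:  # degenerate data: fall back to one tree
            tree = DecisionTreeClassifier(max_depth=self.max_depth, random_state=self.random_state)
            tree.fit(X, y_idx)
            self.estimators_ = [tree]
            self.estimator_weights_ = [1.0]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        score = np.zeros((len(X), len(self.classes_)))
        for tree, alpha in zip(self.estimators_, self.estimator_weights_):
            proba = np.zeros_like(score)
            proba[:, tree.classes_] = tree.predict_proba(X)
            score += alpha * proba
        score /= score.sum(axis=1, keepdims=True)
        return score

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def make_model(name: str, seed: int = 0, rbf_c: float = 10.0):
    """Instantiate one of the four tile/patient classifiers."""
    if name == "1NN":
        return KNeighborsClassifier(n_neighbors=1)
    if name == "linSVM":
        return SVC(kernel="linear", C=1.0, probability=True, class_weight="balanced",
                   random_state=seed)
    if name == "rbfSVM":
        # Probabilities via Platt-calibrated decision values with pairwise
        # coupling (libsvm's internal scheme).
        return SVC(kernel="rbf", C=rbf_c, gamma="scale", probability=True,
                   class_weight="balanced", random_state=seed)
    if name == "ensembleTree":
        return RUSBoostClassifier(random_state=seed)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


@dataclass
class FittedTileModel:
    scaler: StandardScaler
    model: object
    class_ids: np.ndarray
    tissue_only: bool = True

    def predict_profiles(self, X: np.ndarray, tile_ids: list[str]) -> list[ProbabilityProfile]:
        Xs = self.scaler.transform(X)
        probs = self.model.predict_proba(Xs)
        model_classes = np.asarray(self.model.classes_)
        profiles = []
        for i, tid in enumerate(tile_ids):
            p = probs[i]
            cls = model_classes
            if self.tissue_only and 16 in cls:
                keep = cls != 16  # drop background, renormalize over tissue
                p, cls = p[keep], cls[keep]
                s = p.sum()
                p = p / s if s > 0 else np.full(len(p), 1.0 / len(p))
            profiles.append(ProbabilityProfile(tid, cls.copy(), p / p.sum()))
        return profiles


def train_tile_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    model: str = "rbfSVM",
    seed: int = 0,
) -> FittedTileModel:
    """Fit one tile classifier; features are z-scored with training statistics."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training fold contains a single class")
    scaler = StandardScaler().fit(features)
    clf = make_model(model, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)  # SVC probability deprecation
        clf.fit(scaler.transform(features), labels)
    return FittedTileModel(scaler, clf, np.unique(labels))


def cross_validate_tiles(
    features: np.ndarray,
    labels: np.ndarray,
    tile_ids: list[str] | None = None,
    model: str = "rbfSVM",
    k: int = 8,
    seed: int = 0,
) -> tuple[list[ProbabilityProfile], np.ndarray, float]:
    """Stratified k-fold CV; returns out-of-fold profiles, fold accuracies
    and the mean CV accuracy."""
    labels = np.asarray(labels)
    n = len(labels)
    if tile_ids is None:
        tile_ids = [f"tile_{i}" for i in range(n)]
    plan = stratified_kfold(labels, k=k, seed=seed)
    profiles: list[ProbabilityProfile | None] = [None] * n
    fold_acc = np.zeros(k)
    for fold in range(k):
        tr, te = plan.train_test(fold)
        fitted = train_tile_classifier(features[tr], labels[tr], model=model, seed=seed)
        fitted.tissue_only = False  # evaluate over all trained classes
        fold_profiles = fitted.predict_profiles(features[te], [tile_ids[i] for i in te])
        preds = np.array([p.predicted for p in fold_profiles])
        fold_acc[fold] = float((preds == labels[te]).mean())
        for i, prof in zip(te, fold_profiles):
            profiles[i] = prof
    log.info("%s %d-fold CV accuracy: mean %.4f (folds %s)", model, k, fold_acc.mean(),
             np.round(fold_acc, 3))
    return list(profiles), fold_acc, float(fold_acc.mean())


@dataclass
class TileEvaluation:
    class_ids: np.ndarray
    confusion: np.ndarray  # rows = truth, cols = prediction
    accuracy: float
    per_class: dict[int, dict[str, float]] = field(default_factory=dict)


def evaluate_tiles(predictions: np.ndarray, truth: np.ndarray,
                   class_ids: np.ndarray | None = None) -> TileEvaluation:
    """Confusion matrix, overall accuracy and one-vs-rest per-class metrics.

    Classes absent from the truth get NaN (undefined) metrics rather than 0.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if class_ids is None:
        class_ids = np.unique(np.concatenate([truth, predictions]))
    idx = {c: i for i, c in enumerate(class_ids)}
    m = len(class_ids)
    conf = np.zeros((m, m), dtype=int)
    for t, p in zip(truth, predictions):
        conf[idx[t], idx[p]] += 1
    accuracy = float(np.trace(conf) / conf.sum())
    per_class: dict[int, dict[str, float]] = {}
    for c in class_ids:
        i = idx[c]
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        if tp + fn == 0:  # class absent from truth
            per_class[int(c)] = {"recall": np.nan, "precision": np.nan, "f1": np.nan}
            continue
        recall = tp / (tp + fn)
        precision = tp / (tp + fp) if tp + fp > 0 else np.nan
        f1 = (2 * precision * recall / (precision + recall)
              if precision and not np.isnan(precision) and precision + recall > 0 else
              (0.0 if not np.isnan(precision) else np.nan))
        per_class[int(c)] = {"recall": float(recall), "precision": float(precision), "f1": float(f1)}
    return TileEvaluation(np.asarray(class_ids), conf, accuracy, per_class)
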