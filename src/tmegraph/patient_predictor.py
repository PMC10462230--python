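"""Patient-level treatment-response prediction from TME graph features.

The (pair, feature) columns are ranked by ReliefF, the top eight are kept,
and a classifier predicts pCR (positive) vs RD (negative) under
leave-one-out cross-validation. Feature ranking, selection and
standardization happen inside every LOO fold, so the left-out patient never
influences the fitted model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.preprocessing import StandardScaler

from .classes import class_by_id
from .histology_map import HistologyMap, render_map
from .tile_classifier import make_model
from .tme_graph import build_pair_graph, find_clusters

log = logging.getLogger(__name__)

POSITIVE, NEGATIVE = "pCR", "RD"
TOP_K = 8


@dataclass
class ReliefFWeights:
    weights: np.ndarray

    @property
    def ranking(self) -> np.ndarray:
        """Column indices sorted by descending weight, ties by column order."""
        return np.argsort(-self.weights, kind="stable")


def relieff_rank(
    matrix: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 10,
    seed: int = 0,
) -> ReliefFWeights:
    """Classic multi-class ReliefF importance weights.

    Every instance is used (m = n). Features are range-normalized to [0, 1];
    differences use the Manhattan metric. For each instance the k nearest
    same-class neighbors ("hits") decrease the weight of features on which
    they differ and the k nearest neighbors of every other class ("misses")
    increase it, miss contributions weighted by the class prior relative to
    the complement of the instance's class. Weights lie in [-1, 1]; a
    constant column gets exactly 0.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    # canonical row order: weights do not depend on instance ordering
    order = np.lexsort(X.T)
    X, y = X[order], y[order]
    n, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        raise ValueError("ReliefF needs >= 2 instances per class")
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    rng_span = X.max(axis=0) - X.min(axis=0)
    span = np.where(rng_span > 0, rng_span, 1.0)
    Xn = (X - X.min(axis=0)) / span

    if k_neighbors >= counts.min():
        warnings.warn(
            f"k_neighbors={k_neighbors} >= smallest class size {counts.min()}; clamping",
            stacklevel=2,
        )
    dist = cdist(Xn, Xn, metric="cityblock")
    w = np.zeros(d)
    for i in range(n):
        hit_term = np.zeros(d)
        miss_term = np.zeros(d)
        for c in classes:
            members = np.flatnonzero((y == c) & (np.arange(n) != i))
            if members.size == 0:
                continue
            k = min(k_neighbors, members.size)
            nearest = members[np.argsort(dist[i, members], kind="stable")[:k]]
            diffs = np.abs(Xn[nearest] - Xn[i]).mean(axis=0)
            if c == y[i]:
                hit_term = diffs
            else:
                miss_term += priors[c] / (1.0 - priors[y[i]]) * diffs
        w += miss_term - hit_term
    return ReliefFWeights(w / n)


def select_top(weights: ReliefFWeights, k: int = TOP_K) -> np.ndarray:
    """Indices of the k highest-weight columns (ties by column order)."""
    if k > len(weights.weights):
        raise ValueError(f"k={k} exceeds column count {len(weights.weights)}")
    return weights.ranking[:k]


@dataclass
class PatientPredictions:
    patient_ids: list[str]
    truth: np.ndarray  # 'pCR' / 'RD'
    p_positive: np.ndarray  # probability of pCR
    predicted: np.ndarray
    selected_columns: list[np.ndarray]  # per-fold top-k indices


def loo_predict(
    matrix: np.ndarray,
    labels: np.ndarray,
    model: str = "rbfSVM",
    k_top: int = TOP_K,
    k_neighbors: int = 10,
    seed: int = 0,
    patient_ids: list[str] | None = None,
    global_selection: bool = False,
) -> PatientPredictions:
    """Leave-one-out prediction with in-fold ReliefF feature selection.

    ``global_selection=True`` ranks features once on the full matrix
    (leaky; provided for comparison only).
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 patients for LOO")
    if patient_ids is None:
        patient_ids = [f"P{i:03d}" for i in range(n)]

    global_top = None
    if global_selection:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            global_top = select_top(relieff_rank(X, y, k_neighbors, seed), k_top)

    p_pos = np.zeros(n)
    predicted = np.empty(n, dtype=object)
    selected: list[np.ndarray] = []
    for i in range(n):
        tr = np.arange(n) != i
        y_tr = y[tr]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"training set single-class after leaving out {patient_ids[i]}")
        if global_top is not None:
            top = global_top
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                top = select_top(relieff_rank(X[tr], y_tr, k_neighbors, seed),
                                 min(k_top, X.shape[1]))
        selected.append(top)
        X_tr = X[tr][:, top]
        # canonical training order: predictions invariant to patient ordering
        # (libsvm's probability calibration is sensitive to row order)
        row_order = np.lexsort(X_tr.T)
        X_tr, y_fit = X_tr[row_order], y_tr[row_order]
        scaler = StandardScaler().fit(X_tr)
        clf = make_model(model, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)  # SVC probability deprecation
            clf.fit(scaler.transform(X_tr), y_fit)
        proba = clf.predict_proba(scaler.transform(X[i : i + 1, top]))[0]
        cls_index = {c: j for j, c in enumerate(clf.classes_)}
        p_pos[i] = proba[cls_index[POSITIVE]]
        predicted[i] = POSITIVE if p_pos[i] >= 0.5 else NEGATIVE
    acc = float((predicted == y).mean())
    log.info("LOO-CV %s: accuracy %.4f over %d patients", model, acc, n)
    return PatientPredictions(list(patient_ids), y, p_pos, predicted.astype(str), selected)


@dataclass
class BinaryEvaluation:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    roc_points: np.ndarray  # (fpr, tpr) rows
    auc: float


def _roc(p_positive: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC via a threshold sweep over the unique scores plus endpoints;
    AUC by the trapezoid rule."""
    pos = truth == POSITIVE
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    thresholds = np.concatenate([[np.inf], np.unique(p_positive)[::-1], [-np.inf]])
    pts = []
    for t in thresholds:
        call = p_positive >= t
        tpr = (call & pos).sum() / n_pos
        fpr = (call & ~pos).sum() / n_neg
        pts.append((fpr, tpr))
    pts = np.array(sorted(set(map(tuple, pts))))
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


def evaluate_binary(
    predicted: np.ndarray,
    truth: np.ndarray,
    p_positive: np.ndarray | None = None,
) -> BinaryEvaluation:
    """Confusion counts and metrics with pCR as the positive class."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    present = set(truth)
    if present != {POSITIVE, NEGATIVE}:
        raise ValueError(f"truth must contain both classes; found {sorted(present)}")
    tp = int(((predicted == POSITIVE) & (truth == POSITIVE)).sum())
    fn = int(((predicted == NEGATIVE) & (truth == POSITIVE)).sum())
    tn = int(((predicted == NEGATIVE) & (truth == NEGATIVE)).sum())
    fp = int(((predicted == POSITIVE) & (truth == NEGATIVE)).sum())
    n = tp + fn + tn + fp
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if tp + fp and precision + sensitivity > 0 else 0.0)
    if p_positive is not None:
        roc_points, auc = _roc(np.asarray(p_positive, dtype=float), truth)
    else:
        roc_points, auc = np.zeros((0, 2)), float("nan")
    return BinaryEvaluation(tp, fp, tn, fn, accuracy, sensitivity, specificity,
                            precision, f1, roc_points, auc)


def counts_to_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Accuracy/Sensitivity/Specificity/Precision/F1 from confusion counts,
    as percentages."""
    n = tp + fn + tn + fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp)
    return {
        "accuracy": 100.0 * (tp + tn) / n,
        "sensitivity": 100.0 * sens,
        "specificity": 100.0 * spec,
        "precision": 100.0 * prec,
        "f1": 100.0 * 2 * prec * sens / (prec + sens),
    }


def attention_map(
    hmap: HistologyMap,
    selected_pairs: list[tuple[int, int]],
    radius: float | None = None,
    palette: dict[int, tuple[int, int, int]] | None = None,
    highlight: tuple[int, int, int] = (255, 255, 0),
    cell_px: int = 1,
) -> np.ndarray:
    """Overlay highlighting cells whose clusters are nodes of any selected
    pair's TME graph (blended 50% with the highlight color)."""
    base = render_map(hmap, palette=palette, cell_px=1)
    mask = np.zeros(hmap.grid.shape, dtype=bool)
    for a, b in selected_pairs:
        ca = find_clusters(hmap, class_by_id(a))
        cb = find_clusters(hmap, class_by_id(b))
        tme = build_pair_graph(ca, cb, radius=radius or 3 * 224)
        for v in tme.graph:
            for r, c in tme.graph.nodes[v]["cells"]:
                mask[r, c] = True
    out = base.copy()
    hl = np.array(highlight, dtype=float)
    out[mask] = ((base[mask].astype(float) + hl) / 2).astype(np.uint8)
    if cell_px > 1:
        out = np.kron(out, np.ones((cell_px, cell_px, 1), dtype=np.uint8))
    return out
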