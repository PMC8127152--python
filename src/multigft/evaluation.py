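"""Edge-recovery metrics, Dice subject consistency, and the cross-validated
classification harness with hyper-parameter grid search."""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeRecoveryMetrics:
    precision: float
    recall: float
    f_measure: float
    tp: int
    fp: int
    fn: int
    tn: int


def _as_edge_vector(edges, n: int) -> np.ndarray:
    """Accept a boolean upper-triangle vector or a set of (i, j) pairs."""
    m = n * (n - 1) // 2
    if isinstance(edges, (set, frozenset, list)) and (
        not edges or isinstance(next(iter(edges)), tuple)
    ):
        iu, ju = np.triu_indices(n, k=1)
        lookup = {(int(i), int(j)): e for e, (i, j) in enumerate(zip(iu, ju))}
        vec = np.zeros(m, dtype=bool)
        for i, j in edges:
            a, b = (i, j) if i < j else (j, i)
            vec[lookup[(a, b)]] = True
        return vec
    vec = np.asarray(edges, dtype=bool).ravel()
    if vec.size != m:
        raise ValueError(f"edge vector has {vec.size} entries, expected {m}")
    return vec


def edge_recovery(predicted, truth, n: int) -> EdgeRecoveryMetrics:
    """Precision/recall/F over upper-triangle node pairs.

    Degenerate conventions: empty truth -> recall 1; empty prediction ->
    precision 1; F = 0 when precision + recall = 0.
    """
    pred = _as_edge_vector(predicted, n)
    true = _as_edge_vector(truth, n)
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return EdgeRecoveryMetrics(precision, recall, f, tp, fp, fn, tn)


def dice_similarity(edges_a, edges_b, n: int) -> float:
    """Dice similarity coefficient DSC = 2 TP / (2 TP + FP + FN) between two
    binary edge sets; symmetric (FP and FN swap roles).  Two empty sets are
    identical networks, so DSC = 1 (logged)."""
    a = _as_edge_vector(edges_a, n)
    b = _as_edge_vector(edges_b, n)
    tp = int(np.sum(a & b))
    fp = int(np.sum(~a & b))
    fn = int(np.sum(a & ~b))
    if tp + fp + fn == 0:
        logger.info("DSC of two empty edge sets defined as 1.0")
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


@dataclass(frozen=True)
class ConsistencyResult:
    dsc_values: np.ndarray
    group_mean: float
    method_tag: str = ""


def group_consistency(
    networks: list[np.ndarray], n: int, mode: str = "pairwise", method_tag: str = ""
) -> ConsistencyResult:
    """Dice consistency of a group of binarized networks.

    ``mode='pairwise'`` (default) averages DSC over all unordered subject
    pairs; ``mode='consensus'`` scores each subject against the majority-vote
    consensus network.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    vecs = [_as_edge_vector(net, n) for net in networks]
    if mode == "pairwise":
        vals = np.array(
            [dice_similarity(a, b, n) for a, b in itertools.combinations(vecs, 2)]
        )
    elif mode == "consensus":
        consensus = np.mean(vecs, axis=0) > 0.5
        vals = np.array([dice_similarity(v, consensus, n) for v in vecs])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ConsistencyResult(vals, float(vals.mean()), method_tag)


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    accuracy_sd: float
    sensitivity: float
    sensitivity_sd: float
    specificity: float
    specificity_sd: float
    n_repeats: int
    n_folds: int
    positive_label: str


def classify_groups(
    features: np.ndarray,
    labels,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    positive_label: str | None = None,
    C: float = 1.0,
) -> ClassificationReport:
    """Repeated stratified k-fold CV with a linear SVM.

    ``features`` is subjects x features (e.g. concatenated upper-triangle
    Laplacian entries per paradigm).  Sensitivity is the recall of the
    positive class (first label in sorted order unless given); specificity
    the recall of the other class.  Fully seeded: per-repeat fold shuffles
    derive from ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"exactly 2 classes required, got {classes.size}")
    pos = positive_label if positive_label is not None else classes[0]
    if pos not in classes:
        raise ValueError(f"positive label {pos!r} not among classes {classes}")
    min_class = int(min(np.sum(y == c) for c in classes))
    if min_class < n_folds:
        warnings.warn(
            f"smallest class has {min_class} members; reducing folds "
            f"from {n_folds} to {min_class}",
            stacklevel=2,
        )
        n_folds = min_class
    accs, sens, spes = [], [], []
    for rep in range(n_repeats):
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        y_pred = np.empty_like(y)
        for train, test in cv.split(X, y):
            clf = LinearSVC(C=C)
            clf.fit(X[train], y[train])
            y_pred[test] = clf.predict(X[test])
        accs.append(float(np.mean(y_pred == y)))
        sens.append(float(np.mean(y_pred[y == pos] == pos)))
        neg_mask = y != pos
        spes.append(float(np.mean(y_pred[neg_mask] == y[neg_mask])))
    return ClassificationReport(
        float(np.mean(accs)), float(np.std(accs, ddof=1)) if n_repeats > 1 else 0.0,
        float(np.mean(sens)), float(np.std(sens, ddof=1)) if n_repeats > 1 else 0.0,
        float(np.mean(spes)), float(np.std(spes, ddof=1)) if n_repeats > 1 else 0.0,
        n_repeats, n_folds, str(pos),
    )


@dataclass(frozen=True)
class GridSearchResult:
    best_alpha: float
    best_beta: float
    best_cutoff: int
    best_accuracy: float
    surface: list[dict]  # long format: alpha, beta, cutoff, mean_acc, sd_acc


def grid_search(
    feature_builder,
    labels,
    alpha_grid,
    beta_grid,
    cutoff_grid,
    seed: int = 0,
    n_folds: int = 10,
    n_repeats: int = 10,
) -> GridSearchResult:
    """Exhaustive (alpha, beta, cutoff) search scored by mean CV accuracy.

    ``feature_builder(alpha, beta, cutoff)`` returns the subjects x features
    matrix for one hyper-parameter triple (typically: learn the per-subject
    networks at (alpha, beta), vectorize the Laplacians and append the
    low-band node-energy profile at the given cutoff).  Cells whose builder
    raises are recorded as failed and skipped.  Ties break toward smaller
    alpha/beta ratio, then smaller cutoff.
    """
    if not (len(alpha_grid) and len(beta_grid) and len(cutoff_grid)):
        raise ValueError("grids must be non-empty")
    surface = []
    best = None
    for beta in sorted(beta_grid):
        for alpha in sorted(alpha_grid):
            for cutoff in sorted(cutoff_grid):
                try:
                    feats = feature_builder(alpha, beta, cutoff)
                    rep = classify_groups(
                        feats, labels, n_folds=n_folds, n_repeats=n_repeats, seed=seed
                    )
                except Exception as exc:  # solver failure in a cell
                    logger.warning(
                        "grid cell (alpha=%g, beta=%g, l=%d) failed: %s",
                        alpha, beta, cutoff, exc,
                    )
                    surface.append(
                        dict(alpha=alpha, beta=beta, cutoff=cutoff,
                             mean_acc=np.nan, sd_acc=np.nan, failed=True)
                    )
                    continue
                surface.append(
                    dict(alpha=alpha, beta=beta, cutoff=cutoff,
                         mean_acc=rep.accuracy, sd_acc=rep.accuracy_sd, failed=False)
                )
                key = (rep.accuracy, -alpha / beta, -cutoff)
                if best is None or key > best[0]:
                    best = (key, alpha, beta, cutoff, rep.accuracy)
    if best is None:
        raise RuntimeError("every grid cell failed")
    return GridSearchResult(best[1], best[2], best[3], best[4], surface)
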