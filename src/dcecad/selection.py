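"""Feature ranking (ReliefF) and sequential backward wrapper selection.

ReliefF scores each feature by how well it separates a sample from its
nearest *misses* (nearest neighbours of other classes) relative to its
nearest *hits* (same class): features differing between classes gain
weight, features differing within a class lose it.  Distances are Manhattan
on min-max-scaled features, so the weights are scale invariant and lie in
[-1, 1].

The wrapper stage then greedily removes one feature at a time — the one
whose removal most decreases stratified-CV misclassification of the
wrapped classifier — stopping when no single removal decreases it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["relieff_weights", "sequential_backward_select", "SelectionReport"]


def _minmax_scale(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (X - lo) / rng


def relieff_weights(X: np.ndarray, y: np.ndarray, k: int = 10) -> np.ndarray:
    """ReliefF feature weights with m = n iterations and k neighbours.

    Multi-class miss contributions are weighted by class prior as in the
    standard ReliefF formulation; for two classes this reduces to the
    plain nearest-miss average.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("relieff_weights requires >= 2 classes")
    if k >= counts.min():
        raise ValueError(f"k={k} must be smaller than the smallest class count {counts.min()}")
    n, d = X.shape
    Xs = _minmax_scale(X)
    priors = dict(zip(classes, counts / n))
    by_class = {c: np.where(y == c)[0] for c in classes}
    W = np.zeros(d)
    for i in range(n):
        diffs = np.abs(Xs - Xs[i])              # (n, d)
        dist = diffs.sum(axis=1)
        ci = y[i]
        # k nearest hits, excluding the sample itself
        hits = by_class[ci][by_class[ci] != i]
        hit_idx = hits[np.argsort(dist[hits], kind="stable")[:k]]
        W -= diffs[hit_idx].mean(axis=0) / n
        p_not = 1.0 - priors[ci]
        for c in classes:
            if c == ci:
                continue
            miss = by_class[c]
            miss_idx = miss[np.argsort(dist[miss], kind="stable")[:k]]
            W += (priors[c] / p_not) * diffs[miss_idx].mean(axis=0) / n
    return W


@dataclass
class SelectionReport:
    weights: np.ndarray | None
    trace: list = field(default_factory=list)   # (removed_feature, criterion_after)
    selected: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "relieff_weights": None if self.weights is None else self.weights.tolist(),
            "elimination_trace": [
                {"removed": int(f), "criterion": float(c)} for f, c in self.trace
            ],
            "selected": [int(i) for i in self.selected],
        }


def _default_wrapped_classifier():
    # the stage-2 Gaussian-kernel SVM with default hyperparameters
    return make_pipeline(StandardScaler(), SVC(kernel="rbf"))


def sequential_backward_select(
    X: np.ndarray,
    y: np.ndarray,
    classifier=None,
    cv_folds: int = 5,
    seed: int = 0,
    relieff_k: int | None = 10,
) -> SelectionReport:
    """Greedy backward elimination on CV misclassification rate.

    At each step every single-feature removal is scored by stratified
    ``cv_folds``-fold CV misclassification (fixed fold seed); the removal
    that most decreases the criterion is applied.  The search stops when no
    removal strictly decreases it.  Surviving feature indices are returned
    in their original order, alongside the ReliefF ranking (logged for
    comparison, not used as the elimination criterion).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 features to select from")
    classifier = classifier or _default_wrapped_classifier()
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)

    def criterion(feature_idx: list[int]) -> float:
        scores = cross_val_score(classifier, X[:, feature_idx], y, cv=skf)
        return 1.0 - float(scores.mean())

    weights = None
    if relieff_k is not None:
        counts = np.unique(y, return_counts=True)[1]
        k = min(relieff_k, int(counts.min()) - 1)
        if k >= 1:
            weights = relieff_weights(X, y, k=k)

    current = list(range(X.shape[1]))
    best = criterion(current)
    trace: list[tuple[int, float]] = []
    while len(current) > 1:
        cands = [(criterion([f for f in current if f != drop]), i)
                 for i, drop in enumerate(current)]
        (cand_crit, cand_pos) = min(cands)  # ties -> lowest criterion, then first feature
        if cand_crit < best:
            removed = current.pop(cand_pos)
            best = cand_crit
            trace.append((removed, cand_crit))
        else:
            break
    return SelectionReport(weights=weights, trace=trace, selected=current)
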