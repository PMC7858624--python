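"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity from first principles, independently of
the implementation path it checks.
"""

from __future__ import annotations

import numpy as np


def auroc_pairwise(scores, labels) -> float:
    """AUROC by exhaustive pairwise comparison; ties credited 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def roc_points_from_eta_sweep(p0, p1, labels) -> set[tuple[float, float]]:
    """All (FPR, TPR) operating points of the likelihood-ratio decision
    y_hat = 1{p1/p0 >= eta}, by sweeping eta over every achievable ratio."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    labels = np.asarray(labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(p0 > 0, p1 / p0, np.inf)
    etas = sorted(set(ratios)) + [np.inf]
    pts = {(1.0, 1.0)}  # eta = 0: everything positive
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    for eta in etas:
        if eta == np.inf:
            yhat = (p0 == 0) & (p1 > 0)
        else:
            yhat = ratios >= eta
        tpr = (yhat & (labels == 1)).sum() / n_pos
        fpr = (yhat & (labels == 0)).sum() / n_neg
        pts.add((float(fpr), float(tpr)))
    pts.add((0.0, 0.0))
    return pts


def roc_points_from_ranking(scores, labels) -> set[tuple[float, float]]:
    """All (FPR, TPR) points obtained by thresholding a score ranking."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    pts = {(0.0, 0.0), (1.0, 1.0)}
    for thr in set(scores):
        yhat = scores >= thr
        pts.add((float((yhat & (labels == 0)).sum() / n_neg),
                 float((yhat & (labels == 1)).sum() / n_pos)))
    return pts


def ward_bruteforce(X: np.ndarray):
    """Agglomerate rows of X under Ward's objective, recomputing the merge
    cost from scratch at every step.

    Returns (merge heights in order, partitions), where partitions[S] is the
    set of clusters (frozensets of row indices) remaining with S clusters.
    Heights follow the convention height = sqrt(2 * delta-SSE).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    partitions = {n: {frozenset(c) for c in clusters}}
    while len(clusters) > 1:
        best, best_pair = np.inf, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = X[clusters[a]].mean(axis=0)
                cb = X[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                delta = (na * nb) / (na + nb) * float(((ca - cb) ** 2).sum())
                if delta < best:
                    best, best_pair = delta, (a, b)
        a, b = best_pair
        heights.append(np.sqrt(2 * best))
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        partitions[len(clusters)] = {frozenset(c) for c in clusters}
    return heights, partitions


def saturation_epochs_bruteforce(trace, patience: int, tol: float = 0.0):
    """First epoch e such that no epoch in (e - patience, e] improved the
    running-best accuracy by more than tol; None if the trace never
    saturates. Window-scan formulation, independent of the online stopper."""
    improved = []
    best = -np.inf
    for acc in trace:
        improved.append(acc > best + tol)
        if acc > best + tol:
            best = acc
    for e in range(1, len(trace) + 1):
        window = improved[e - patience:e] if e >= patience else [True]
        if not any(window):
            return e
    return None
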