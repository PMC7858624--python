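"""Slide-level aggregation of patch probabilities.

A slide's class confidence is the channel-wise sum of its patches' class
probabilities: p_hat_y = sum over patches of p_y(patch). The slide decision
is a likelihood-ratio test y_hat = 1{p_hat_1 / p_hat_0 >= eta}; sweeping
eta traces the ROC curve, and the monotone surrogate score
p_hat_1 / (p_hat_0 + p_hat_1) induces the identical ROC by ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "SlideConfidence", "SlideDecision", "slide_confidence",
    "slide_lr_decision", "slide_score", "score_slide", "compute_auroc",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """AUROC is undefined when only one class is present."""


@dataclass(frozen=True)
class SlideConfidence:
    """Per-class summed patch probabilities for one slide."""

    p_hat: np.ndarray  # (n_classes,)
    n_patches: int

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise ValueError("a slide needs at least one patch")
        if np.any(np.asarray(self.p_hat) < -1e-9):
            raise ValueError("confidences must be nonnegative")


@dataclass(frozen=True)
class SlideDecision:
    y_hat: int
    eta: float


def slide_confidence(patch_probs: np.ndarray) -> SlideConfidence:
    """Channel-wise sum of a (n_patches, n_classes) probability matrix.

    With normalized rows, sum_y p_hat_y == n_patches (conservation).
    """
    P = np.asarray(patch_probs, dtype=float)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("patch_probs must be a non-empty (n_patches, n_classes) matrix")
    return SlideConfidence(P.sum(axis=0), P.shape[0])


def slide_lr_decision(conf: SlideConfidence, eta: float) -> SlideDecision:
    """Likelihood-ratio decision y_hat = 1{p_hat_1 / p_hat_0 >= eta}.

    p_hat_0 = 0 with p_hat_1 > 0 decides positive for any finite eta.
    """
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    p0, p1 = float(conf.p_hat[0]), float(conf.p_hat[1])
    if p0 == 0.0 and p1 == 0.0:
        raise ValueError("degenerate confidence: p_hat_0 = p_hat_1 = 0")
    if p0 == 0.0:
        y = 1
    else:
        y = int(p1 / p0 >= eta)
    return SlideDecision(y, float(eta))


def slide_score(conf: SlideConfidence) -> float:
    """Monotone surrogate of the likelihood ratio for thresholdless ROC:
    p_hat_1 / (p_hat_0 + p_hat_1), strictly increasing in p_hat_1/p_hat_0."""
    p0, p1 = float(conf.p_hat[0]), float(conf.p_hat[1])
    tot = p0 + p1
    if tot <= 0:
        raise ValueError("degenerate confidence: p_hat_0 + p_hat_1 = 0")
    return p1 / tot


def score_slide(model, slide) -> float:
    """Convenience: patch probabilities -> confidence -> surrogate score."""
    from supercohort.model import predict_patch

    return slide_score(slide_confidence(predict_patch(model, slide.pixels)))


def compute_auroc(scores, labels) -> float:
    """AUROC as the normalized Mann-Whitney U statistic (ties credit 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise UndefinedMetricError("labels must contain both classes 0 and 1")
    return float(roc_auc_score(labels, scores))
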