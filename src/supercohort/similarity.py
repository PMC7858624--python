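"""Cohort-similarity matrices.

Four N x N matrices quantify pairwise morphological similarity:

* ``detection_C``: entry (i, j) is the slide-level detection AUROC on target
  cohort i of the model trained on source cohort j, averaged over
  sub-datasets (cross-cohort validation).
* ``disc_negative`` / ``disc_positive`` / ``disc_general``: entry (i, j) is
  the mean predicted probability that patches originating from cohort i
  come from cohort j, under a cohort-discrimination model trained on
  negative, positive, or all slides. Rows (origin cohorts) sum to 1.

The discrimination tasks are finite-sample surrogates of the H-divergence
between cohort patch distributions: cohorts a classifier cannot separate
are morphologically close, so pooling their data resembles enlarging one
cohort's dataset rather than adding irrelevant information.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from supercohort.inference import compute_auroc, score_slide
from supercohort.model import (
    AugmentationConfig,
    TrainedPatchModel,
    TrainingConfig,
    TrainingRecord,
    assign_patch_labels,
    predict_patch,
    train_patch_model,
)
from supercohort.prep import SubDataset, build_discrimination_splits

__all__ = [
    "SimilarityMatrix", "cross_cohort_detection_matrix",
    "train_cohort_discriminator", "discrimination_confidence_matrix",
    "hdivergence_proxy", "evaluation_patch_budget",
]

KINDS = ("detection_C", "disc_negative", "disc_positive", "disc_general")


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    kind: str
    cohort_names: list[str]
    row_semantics: str = "origin/target cohort i"
    col_semantics: str = "source/predicted cohort j"

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("similarity matrix must be square")
        if V.shape[0] != len(self.cohort_names):
            raise ValueError("cohort_names length must match matrix size")
        if len(set(self.cohort_names)) != len(self.cohort_names):
            raise ValueError("cohort names must be unique")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.kind == "detection_C":
            if V.min() < -1e-9 or V.max() > 1 + 1e-9:
                raise ValueError("detection matrix entries must be AUROCs in [0, 1]")
        else:
            if not np.allclose(V.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("discrimination matrix rows must sum to 1")
        self.values = V

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.cohort_names,
                     columns=self.cohort_names).to_csv(path)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"kind": self.kind, "row_semantics": self.row_semantics,
                       "col_semantics": self.col_semantics}, fh, indent=2)

    @classmethod
    def from_csv(cls, path: str, kind: str | None = None) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        meta = {}
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            pass
        return cls(df.to_numpy(), kind or meta.get("kind", "detection_C"),
                   [str(c) for c in df.columns],
                   meta.get("row_semantics", "origin/target cohort i"),
                   meta.get("col_semantics", "source/predicted cohort j"))


def evaluation_patch_budget(n_cohorts: int, slides_per_cohort: int,
                            n_subdatasets: int = 5,
                            patches_per_slide: int = 100) -> int:
    """Total patches consumed building one discrimination matrix. At the
    full-scale defaults: 12 cohorts x 9 slides x 5 sub-datasets x 100
    patches = 54,000 (negative/positive), 18 slides -> 108,000 (general)."""
    return n_cohorts * slides_per_cohort * n_subdatasets * patches_per_slide


# ---------------------------------------------------------------------------
# Detection matrix C
# ---------------------------------------------------------------------------

def cross_cohort_detection_matrix(
    models: dict[tuple[int, int], TrainedPatchModel],
    subdatasets: list[SubDataset],
    cohorts: list[int] | None = None,
    role: str = "validation",
) -> SimilarityMatrix:
    """Cross-cohort validation of single-cohort detection models.

    ``models[(j, sub_index)]`` is the detection model trained on source
    cohort j in that sub-dataset. Entry (i, j) is the AUROC of model j on
    target cohort i's slides (``role`` defaults to validation, the set used
    for aggregating cohorts), averaged over sub-datasets.
    """
    if cohorts is None:
        cohorts = subdatasets[0].cohorts
    n = len(cohorts)
    acc = np.zeros((n, n))
    for sub in subdatasets:
        for jj, j in enumerate(cohorts):
            key = (j, sub.index)
            if key not in models:
                raise ValueError(f"missing model for cohort {j}, sub-dataset {sub.index}")
            model = models[key]
            for ii, i in enumerate(cohorts):
                slides = getattr(sub, role)[i]
                scores = [score_slide(model, s) for s in slides]
                labels = [s.label for s in slides]
                acc[ii, jj] += compute_auroc(scores, labels)
    acc /= len(subdatasets)
    return SimilarityMatrix(acc, "detection_C", [str(c) for c in cohorts],
                            row_semantics="target (validation) cohort i",
                            col_semantics="source (train) cohort j")


# ---------------------------------------------------------------------------
# Discrimination models and confidence matrices
# ---------------------------------------------------------------------------

def train_cohort_discriminator(
    subdataset: SubDataset,
    condition: str,
    cfg: TrainingConfig,
    aug: AugmentationConfig | None = None,
    cohorts: list[int] | None = None,
) -> tuple[TrainedPatchModel, TrainingRecord]:
    """Train one cohort-of-origin classifier on slides passing the condition
    filter (negative / positive / general)."""
    if cohorts is None:
        cohorts = subdataset.cohorts
    if len(cohorts) < 2:
        raise ValueError("cohort discrimination needs at least 2 cohorts")
    split = build_discrimination_splits([subdataset], condition)[0]
    classes = {c: k for k, c in enumerate(cohorts)}
    train = assign_patch_labels(split.pooled("train"), "discrimination", classes)
    val = assign_patch_labels(split.pooled("validation"), "discrimination", classes)
    return train_patch_model(train, val, f"discrimination_{condition}", cfg,
                             aug, n_classes=len(cohorts))


def discrimination_confidence_matrix(
    models: list[tuple[TrainedPatchModel, SubDataset]],
    condition: str,
    patches_per_slide: int = 100,
    seed: int = 0,
    role: str = "validation",
    per_slide_mean: bool = False,
) -> SimilarityMatrix:
    """Confusion/confidence matrix of cohort-discrimination models.

    For every (model, sub-dataset) pair, ``patches_per_slide`` patches are
    sampled from each eligible slide (with replacement, with a warning, when
    a slide holds fewer); entry (i, j) is the mean predicted probability of
    cohort j over all sampled patches originating from cohort i, pooled
    across sub-datasets (``per_slide_mean=True`` averages per slide first).
    """
    split_label = {"negative": (0,), "positive": (1,), "general": (0, 1)}[condition]
    cohorts = models[0][1].cohorts
    n = len(cohorts)
    sums = np.zeros((n, n))
    counts = np.zeros(n)
    warned = False
    rng = np.random.default_rng(seed)
    for model, sub in models:
        if model.n_classes != n:
            raise ValueError("model n_classes does not match cohort count")
        for ii, i in enumerate(cohorts):
            for slide in getattr(sub, role)[i]:
                if slide.label not in split_label:
                    continue
                npz = len(slide.patches)
                if npz >= patches_per_slide:
                    idx = rng.choice(npz, size=patches_per_slide, replace=False)
                else:
                    if not warned:
                        warnings.warn(
                            f"slides hold fewer than {patches_per_slide} patches; "
                            "sampling with replacement")
                        warned = True
                    idx = rng.choice(npz, size=patches_per_slide, replace=True)
                probs = predict_patch(model, slide.pixels[idx])
                if per_slide_mean:
                    sums[ii] += probs.mean(axis=0)
                    counts[ii] += 1
                else:
                    sums[ii] += probs.sum(axis=0)
                    counts[ii] += probs.shape[0]
    values = sums / counts[:, None]
    return SimilarityMatrix(values, f"disc_{condition}", [str(c) for c in cohorts],
                            row_semantics="origin cohort i",
                            col_semantics="predicted cohort j")


def hdivergence_proxy(binary_error_rate: float) -> float:
    """Empirical H-divergence estimate 2 * (1 - 2 * error) from the best
    achievable pairwise discrimination error; 0 = indistinguishable cohorts,
    2 = perfectly distinguishable."""
    if not 0.0 <= binary_error_rate <= 0.5:
        raise ValueError("binary error rate must be in [0, 0.5]")
    return 2.0 * (1.0 - 2.0 * binary_error_rate)
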