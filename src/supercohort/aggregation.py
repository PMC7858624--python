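"""Super-cohort construction and the performance / training-time trade-off.

Cohorts are agglomerated by Ward's method on the Euclidean distances between
a similarity matrix's *column* vectors. Cutting the dendrogram at S groups
(undoing the S-1 highest merges) yields a super-cohort partition; one
detection model is trained per super-cohort per sub-dataset on the pooled
member training slides. A partition's training time t(T) is the sum over
super-cohorts of the mean training epochs across sub-dataset trials.

Partition selection (CI gate): among all evaluated (matrix kind, S)
configurations whose mean AUROC is at least the cohort-specific (S = N)
reference's lower 95% confidence bound, report the one with minimum total
training time and the one with best mean AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import ward
from scipy.stats import t as t_dist

from supercohort.inference import compute_auroc, score_slide
from supercohort.model import (
    AugmentationConfig, TrainedPatchModel, TrainingConfig, TrainingRecord,
    assign_patch_labels, train_patch_model,
)
from supercohort.prep import SubDataset
from supercohort.similarity import SimilarityMatrix

__all__ = [
    "Dendrogram", "SuperCohortPartition", "PartitionEvaluation",
    "SelectionResult", "build_dendrogram", "cut_to_supercohorts",
    "derive_model_seed", "train_supercohort_models", "evaluate_partition",
    "mean_ci", "select_partitions",
]


@dataclass
class Dendrogram:
    """Ward linkage over N cohorts; scipy linkage matrix + provenance."""

    linkage: np.ndarray  # (N-1, 4) scipy format
    kind: str
    cohort_names: list[str]

    @property
    def n(self) -> int:
        return len(self.cohort_names)

    def to_newick(self) -> str:
        n = self.n
        heights = np.zeros(2 * n - 1)
        labels = {i: self.cohort_names[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            node = n + k
            heights[node] = h
            la = f"{labels[a]}:{h - heights[a]:g}"
            lb = f"{labels[b]}:{h - heights[b]:g}"
            labels[node] = f"({la},{lb})"
        return labels[2 * n - 2] + ";"


@dataclass(frozen=True)
class SuperCohortPartition:
    """Disjoint cover of all cohorts by S groups."""

    S: int
    groups: tuple[tuple[int, ...], ...]
    provenance: tuple[str, int] = ("", 0)  # (dendrogram kind, S)

    def __post_init__(self) -> None:
        flat = [c for g in self.groups for c in g]
        if len(flat) != len(set(flat)):
            raise ValueError("super-cohort groups must be disjoint")
        if len(self.groups) != self.S:
            raise ValueError("number of groups must equal S")

    @property
    def cohorts(self) -> tuple[int, ...]:
        return tuple(sorted(c for g in self.groups for c in g))

    def group_of(self, cohort: int) -> tuple[int, ...]:
        for g in self.groups:
            if cohort in g:
                return g
        raise KeyError(cohort)


@dataclass
class PartitionEvaluation:
    """Per-cohort test AUROCs and the training-time accounting of one
    partition: total epochs = sum over super-cohorts of mean epochs."""

    partition: SuperCohortPartition
    per_cohort_auroc: dict[int, float]
    mean_auroc: float
    ci_halfwidth: float
    total_training_time_epochs: float
    per_group_mean_epochs: dict[tuple[int, ...], float] = field(default_factory=dict)


def build_dendrogram(matrix: SimilarityMatrix) -> Dendrogram:
    """Ward/Euclidean agglomeration of the matrix's column vectors."""
    V = np.asarray(matrix.values, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("similarity matrix contains non-finite entries")
    # observation j = the j-th column vector
    Z = ward(V.T.copy())
    return Dendrogram(Z, matrix.kind, list(matrix.cohort_names))


def cut_to_supercohorts(dendrogram: Dendrogram, S: int) -> SuperCohortPartition:
    """The S groups obtained by undoing the S-1 highest merges."""
    n = dendrogram.n
    if not 1 <= S <= n:
        raise ValueError(f"S must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k in range(n - S):  # linkage rows are height-sorted
        a, b = int(dendrogram.linkage[k, 0]), int(dendrogram.linkage[k, 1])
        parent[find(a)] = n + k
        parent[find(b)] = n + k
    groups: dict[int, list[int]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(leaf)
    sorted_groups = tuple(sorted(tuple(sorted(g)) for g in groups.values()))
    return SuperCohortPartition(S, sorted_groups, (dendrogram.kind, S))


def derive_model_seed(master_seed: int, group: tuple[int, ...], sub_index: int) -> int:
    """Seed for one super-cohort model; depends only on (master seed, member
    set, sub-dataset), so the S = N singleton path and the single-cohort path
    are bit-identical, as are shared groups across different S sweeps."""
    ss = np.random.SeedSequence((int(master_seed), int(sub_index), *sorted(group)))
    return int(ss.generate_state(1)[0] % 2**31)


def train_supercohort_models(
    partition: SuperCohortPartition,
    subdatasets: list[SubDataset],
    cfg: TrainingConfig,
    aug: AugmentationConfig | None = None,
    master_seed: int = 0,
    cache: dict | None = None,
) -> dict[tuple[int, ...], dict[int, tuple[TrainedPatchModel, TrainingRecord]]]:
    """One detection model per super-cohort per sub-dataset, trained on the
    pooled member training slides (validated on pooled validation slides).

    ``cache`` (keyed by (member set, sub_index)) lets an S sweep reuse
    models for groups shared between cuts.
    """
    out: dict = {}
    for group in partition.groups:
        per_sub: dict[int, tuple[TrainedPatchModel, TrainingRecord]] = {}
        for sub in subdatasets:
            key = (tuple(sorted(group)), sub.index)
            if cache is not None and key in cache:
                per_sub[sub.index] = cache[key]
                continue
            train = assign_patch_labels(sub.pooled("train", group), "detection")
            val = assign_patch_labels(sub.pooled("validation", group), "detection")
            seed = derive_model_seed(master_seed, group, sub.index)
            model, record = train_patch_model(
                train, val, "detection", cfg.with_seed(seed), aug, n_classes=2)
            per_sub[sub.index] = (model, record)
            if cache is not None:
                cache[key] = (model, record)
        out[tuple(sorted(group))] = per_sub
    return out


def evaluate_partition(
    models: dict[tuple[int, ...], dict[int, tuple[TrainedPatchModel, TrainingRecord]]],
    partition: SuperCohortPartition,
    subdatasets: list[SubDataset],
    role: str = "test",
    level: float = 0.95,
) -> PartitionEvaluation:
    """Score each cohort with its super-cohort's model on that cohort's
    slides (mean AUROC over sub-datasets); CI over the per-cohort means."""
    per_cohort: dict[int, float] = {}
    for cohort in partition.cohorts:
        group = tuple(sorted(partition.group_of(cohort)))
        if group not in models:
            raise ValueError(f"no models for super-cohort {group}")
        aurocs = []
        for sub in subdatasets:
            model, _ = models[group][sub.index]
            slides = getattr(sub, role)[cohort]
            scores = [score_slide(model, s) for s in slides]
            labels = [s.label for s in slides]
            aurocs.append(compute_auroc(scores, labels))
        per_cohort[cohort] = float(np.mean(aurocs))

    values = list(per_cohort.values())
    if len(values) >= 2:
        mean, hw = mean_ci(values, level)
    else:
        mean, hw = float(values[0]), 0.0

    per_group_epochs = {
        group: float(np.mean([rec.epochs_trained for _, rec in per_sub.values()]))
        for group, per_sub in models.items()
        if group in {tuple(sorted(g)) for g in partition.groups}
    }
    total = float(sum(per_group_epochs.values()))
    return PartitionEvaluation(partition, per_cohort, mean, hw, total, per_group_epochs)


def mean_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Mean and t-distribution confidence halfwidth:
    t_{(1+level)/2, n-1} * sd / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    q = float(t_dist.ppf((1 + level) / 2, df=n - 1))
    return mean, q * sd / np.sqrt(n)


_KIND_ORDER = {"detection_C": 0, "disc_negative": 1, "disc_positive": 2,
               "disc_general": 3, "": 4}


@dataclass
class SelectionResult:
    qualifying: list[tuple[str, int]]
    min_time_choice: tuple[str, int] | None
    best_performance_choice: tuple[str, int] | None
    threshold: float
    empty: bool = False


def select_partitions(
    evaluations: dict[tuple[str, int], PartitionEvaluation],
    reference: PartitionEvaluation,
    two_sided_gate: bool = False,
) -> SelectionResult:
    """CI-gated selection across all evaluated (matrix kind, S) partitions.

    A configuration qualifies when its mean AUROC is >= the reference's
    lower confidence bound (mean - halfwidth); ``two_sided_gate`` also
    requires it below the upper bound (the looser "within the CI" reading).
    Ties broken by smaller S, then matrix-kind order C, D_n, D_p, D_g.
    """
    lo = reference.mean_auroc - reference.ci_halfwidth
    hi = reference.mean_auroc + reference.ci_halfwidth

    def ok(ev: PartitionEvaluation) -> bool:
        if ev.mean_auroc < lo:
            return False
        return not (two_sided_gate and ev.mean_auroc > hi)

    qualifying = sorted(
        (key for key, ev in evaluations.items() if ok(ev)),
        key=lambda k: (k[1], _KIND_ORDER.get(k[0], 9), k[0]))
    if not qualifying:
        return SelectionResult([], None, None, lo, empty=True)

    def tie_key(k):
        return (k[1], _KIND_ORDER.get(k[0], 9), k[0])

    min_time = min(qualifying, key=lambda k: (
        evaluations[k].total_training_time_epochs, *tie_key(k)))
    best_val = max(evaluations[k].mean_auroc for k in qualifying)
    best_perf = sorted((k for k in qualifying
                        if evaluations[k].mean_auroc == best_val), key=tie_key)[0]
    return SelectionResult(list(qualifying), min_time, best_perf, lo)
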