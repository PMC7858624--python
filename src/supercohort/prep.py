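"""Resampled sub-datasets and cohort-discrimination splits.

Each cohort contributes five (by default) independently resampled
sub-datasets, each made of a balanced train set and a balanced held-out set
that is halved into validation and test. Three criteria hold within every
sub-dataset:

1. train and held-out sets do not overlap at the patient level;
2. per patient, at most one positive and one negative slide appear
   (max two slides per patient);
3. validation and test sets each contain equal class counts.

Slides may recur *between* sub-datasets (sampling with replacement between
sub-datasets) but never within one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from supercohort.synthetic import MultiCohortDataset, SyntheticSlide

__all__ = [
    "SubDataset", "CohortTooSmallError", "sample_subdatasets",
    "build_discrimination_splits", "validate_subdataset", "total_slide_slots",
]


class CohortTooSmallError(ValueError):
    """A cohort cannot supply one sub-dataset's slide demand."""


@dataclass
class SubDataset:
    """One resampled split. ``train``/``validation``/``test`` map cohort id
    to its slide list; ``task`` records what the split feeds."""

    index: int
    train: dict[int, list[SyntheticSlide]]
    validation: dict[int, list[SyntheticSlide]]
    test: dict[int, list[SyntheticSlide]]
    task: str = "cancer_detection"

    @property
    def cohorts(self) -> list[int]:
        return sorted(self.train)

    def pooled(self, role: str, cohorts=None) -> list[SyntheticSlide]:
        d = getattr(self, role)
        keys = sorted(d) if cohorts is None else sorted(cohorts)
        return [s for c in keys for s in d[c]]

    def to_manifest(self) -> pd.DataFrame:
        rows = []
        for role in ("train", "validation", "test"):
            for c, slides in sorted(getattr(self, role).items()):
                for s in slides:
                    rows.append({"slide_id": s.slide_id, "cohort": c,
                                 "role": role, "sub_index": self.index})
        return pd.DataFrame(rows)


def total_slide_slots(n_cohorts: int, n_subdatasets: int = 5,
                      n_train: int = 36, n_heldout: int = 36) -> int:
    """Total slide slots across all sub-datasets under the sampling scheme
    (train + held-out per cohort per sub-dataset). With 12 cohorts, 5
    sub-datasets and 36+36 slides this is 4,320."""
    return n_cohorts * n_subdatasets * (n_train + n_heldout)


def _sample_one_cohort(
    slides: list[SyntheticSlide],
    n_train_pos: int, n_train_neg: int,
    n_heldout_pos: int, n_heldout_neg: int,
    rng: np.random.Generator,
    cohort_id: int,
) -> tuple[list, list, list]:
    """Sample one cohort's train/val/test slides under the three criteria."""
    by_patient: dict[str, dict[int, list[SyntheticSlide]]] = {}
    for s in slides:
        by_patient.setdefault(s.patient_id, {}).setdefault(s.label, []).append(s)

    patients = sorted(by_patient)
    rng.shuffle(patients)

    need = {"train": [n_train_pos, n_train_neg],
            "held": [n_heldout_pos, n_heldout_neg]}
    picked = {"train": [], "held": []}
    for pid in patients:
        # criterion 2: at most one slide per class from this patient
        offer = {}
        for label, ls in by_patient[pid].items():
            offer[label] = ls[int(rng.integers(len(ls)))] if len(ls) > 1 else ls[0]
        # criterion 1: the whole patient goes to train xor held-out
        for pool in ("train", "held"):
            useful = [lab for lab in offer if need[pool][1 - lab] > 0]
            if useful:
                for lab in useful:
                    picked[pool].append(offer[lab])
                    need[pool][1 - lab] -= 1
                break
        if all(v == 0 for v in need["train"] + need["held"]):
            break

    if any(v > 0 for v in need["train"] + need["held"]):
        raise CohortTooSmallError(
            f"cohort {cohort_id} cannot supply the sub-dataset demand "
            f"(missing train pos/neg {need['train']}, held-out {need['held']})"
        )

    train = picked["train"]
    # criterion 3: halve held-out into validation/test, stratified by class
    val, test = [], []
    for lab in (1, 0):
        group = [s for s in picked["held"] if s.label == lab]
        rng.shuffle(group)
        half = len(group) // 2
        val.extend(group[:half])
        test.extend(group[half:])
    return train, val, test


def sample_subdatasets(
    dataset: MultiCohortDataset,
    n_subdatasets: int = 5,
    n_train_pos: int = 18,
    n_train_neg: int = 18,
    n_heldout_pos: int = 18,
    n_heldout_neg: int = 18,
    seed: int = 0,
) -> list[SubDataset]:
    """Sample the resampled sub-datasets; deterministic given seed.

    Raises :class:`CohortTooSmallError` naming the cohort when a cohort
    cannot meet one sub-dataset's demand.
    """
    subs = []
    for idx in range(1, n_subdatasets + 1):
        train, val, test = {}, {}, {}
        for c in range(dataset.n_cohorts):
            rng = np.random.default_rng(np.random.SeedSequence((seed, idx, c)))
            train[c], val[c], test[c] = _sample_one_cohort(
                dataset.cohorts[c], n_train_pos, n_train_neg,
                n_heldout_pos, n_heldout_neg, rng, c)
        subs.append(SubDataset(idx, train, val, test))
    return subs


def build_discrimination_splits(
    subdatasets: list[SubDataset],
    condition: str,
) -> list[SubDataset]:
    """Filter detection sub-datasets into cohort-discrimination splits.

    ``negative``/``positive`` keep only slides of that class (18 training
    slides per cohort at defaults); ``general`` keeps both classes (36).
    The validation/test halving is inherited.
    """
    keep = {"negative": (0,), "positive": (1,), "general": (0, 1)}
    if condition not in keep:
        raise ValueError(f"condition must be negative|positive|general, got {condition!r}")
    labels = keep[condition]

    out = []
    for sub in subdatasets:
        def filt(d):
            return {c: [s for s in slides if s.label in labels]
                    for c, slides in d.items()}
        out.append(SubDataset(sub.index, filt(sub.train), filt(sub.validation),
                              filt(sub.test), task=f"discrimination_{condition}"))
    return out


@dataclass
class ValidationReport:
    criteria: dict[str, bool]
    offenders: dict[str, list] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.criteria.values())


def validate_subdataset(sub: SubDataset) -> ValidationReport:
    """Report-only check of the three sampling criteria."""
    criteria, offenders = {}, {}

    train_pat = {s.patient_id for c in sub.train for s in sub.train[c]}
    held = [s for c in sub.validation for s in sub.validation[c]]
    held += [s for c in sub.test for s in sub.test[c]]
    overlap = sorted({s.patient_id for s in held} & train_pat)
    criteria["patient_disjoint"] = not overlap
    if overlap:
        offenders["patient_disjoint"] = overlap

    counts: dict[tuple[str, int], int] = {}
    dupes: dict[str, int] = {}
    all_slides = [s for role in ("train", "validation", "test")
                  for c in getattr(sub, role) for s in getattr(sub, role)[c]]
    seen_ids = [s.slide_id for s in all_slides]
    for s in all_slides:
        counts[(s.patient_id, s.label)] = counts.get((s.patient_id, s.label), 0) + 1
    bad = sorted({pid for (pid, lab), n in counts.items() if n > 1})
    bad_slides = len(seen_ids) != len(set(seen_ids))
    criteria["max_one_slide_per_patient_per_class"] = not bad and not bad_slides
    if bad:
        offenders["max_one_slide_per_patient_per_class"] = bad

    def class_counts(d):
        labs = [s.label for c in d for s in d[c]]
        return labs.count(1), labs.count(0)

    vp, vn = class_counts(sub.validation)
    tp, tn = class_counts(sub.test)
    balanced = vp == vn and tp == tn
    criteria["balanced_val_test"] = balanced
    if not balanced:
        offenders["balanced_val_test"] = [("validation", vp, vn), ("test", tp, tn)]

    return ValidationReport(criteria, offenders)
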