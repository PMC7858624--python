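"""Canonical desk-scale study configurations.

``three_pair_config`` is the 6-cohort fixture used across the test suite,
the examples, and the reproduction script: three strongly separated planted
pairs ((0,1), (2,3), (4,5)), so the ground-truth partition at S = 3 is the
pairs themselves. Pair merges sit at height 0.02 while the upper merges sit
at 4 and 6: pair members are near-duplicate cohorts (the
morphologically-indistinguishable-cohorts premise) while cross-pair
parameter distances are two orders of magnitude larger ("strong
separation").
"""

from __future__ import annotations

from supercohort.experiment import ExperimentConfig
from supercohort.synthetic import GenerationConfig

THREE_PAIR_TREE = ((0, 1, 0.02), (((2, 3, 0.02), (4, 5, 0.02), 4.0)), 6.0)


def three_pair_config(seed: int, outdir: str = "results",
                      **overrides) -> ExperimentConfig:
    """Desk-profile config for the planted three-pair fixture."""
    gen = GenerationConfig(
        n_pos_slides=40, n_neg_slides=40, patches_per_slide=12,
        tumor_fraction=0.7, patch_size=16, sigma_walk=0.5,
        cancer_effect=1.5, shared_cancer_weight=0.3,
        min_slides_per_class=28)
    base = dict(
        seed=seed, n_cohorts=6, layout=THREE_PAIR_TREE, generation=gen,
        n_subdatasets=5, n_train_pos=12, n_train_neg=12,
        n_heldout_pos=16, n_heldout_neg=16, profile="desk",
        eval_patches_per_slide=12, outdir=outdir)
    base.update(overrides)
    return ExperimentConfig(**base)
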