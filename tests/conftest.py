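import numpy as np
import pytest

import supercohort as sc
from supercohort.experiment import ExperimentConfig, run_experiment
from supercohort.fixtures import three_pair_config
from supercohort.synthetic import GenerationConfig


@pytest.fixture(scope="session")
def two_cohort_dataset():
    """Two well-separated cohorts, small slides: cheap unit-test corpus."""
    h = sc.generate_planted_hierarchy(2, (0, 1, 4.0), seed=0)
    gen = GenerationConfig(n_pos_slides=12, n_neg_slides=12, patches_per_slide=8,
                           patch_size=16)
    return sc.generate_dataset(h, gen, seed=7)


@pytest.fixture(scope="session")
def two_cohort_subdatasets(two_cohort_dataset):
    return sc.sample_subdatasets(two_cohort_dataset, n_subdatasets=2,
                                 n_train_pos=4, n_train_neg=4,
                                 n_heldout_pos=4, n_heldout_neg=4, seed=3)


@pytest.fixture(scope="session")
def tiny_training_config():
    return sc.TrainingConfig.desk(iterations_per_epoch=25, max_epochs=12,
                                  val_patches_per_epoch=256)


@pytest.fixture(scope="session")
def trained_detector(two_cohort_subdatasets, tiny_training_config):
    """One detection model on cohort 0 of the two-cohort corpus."""
    sub = two_cohort_subdatasets[0]
    train = sc.assign_patch_labels(sub.train[0], "detection")
    val = sc.assign_patch_labels(sub.validation[0], "detection")
    return sc.train_patch_model(train, val, "detection",
                                tiny_training_config.with_seed(5))


def micro_config(seed: int, outdir: str) -> ExperimentConfig:
    """Smallest config that exercises the full pipeline (2 cohorts)."""
    gen = GenerationConfig(n_pos_slides=8, n_neg_slides=8, patches_per_slide=6,
                           patch_size=12)
    return ExperimentConfig(
        seed=seed, n_cohorts=2, layout=(0, 1, 3.0), generation=gen,
        n_subdatasets=2, n_train_pos=3, n_train_neg=3,
        n_heldout_pos=4, n_heldout_neg=4, profile="desk",
        eval_patches_per_slide=6, outdir=outdir)


@pytest.fixture(scope="session")
def fixture_result(tmp_path_factory):
    """Full pipeline on the planted three-pair fixture, seed 0."""
    out = tmp_path_factory.mktemp("three_pair")
    cfg = three_pair_config(seed=0, outdir=str(out))
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def recovery_dendrograms(tmp_path_factory, fixture_result):
    """Dendrograms of all four matrix kinds for five fixture seeds."""
    per_seed = {0: fixture_result.dendrograms}
    for seed in (1, 2, 3, 4):
        out = tmp_path_factory.mktemp(f"recovery{seed}")
        cfg = three_pair_config(seed=seed, outdir=str(out))
        res = run_experiment(cfg, until="aggregate")
        per_seed[seed] = res.dendrograms
    return per_seed


def planted_pair_labels():
    return [0, 0, 1, 1, 2, 2]


def groups_to_labels(groups, n=6):
    lab = np.zeros(n, dtype=int)
    for gi, g in enumerate(groups):
        for c in g:
            lab[c] = gi
    return lab
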