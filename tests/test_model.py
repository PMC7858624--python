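"""Patch model: augmentation, labeling, training protocol, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import supercohort as sc
from supercohort.model import (
    AugmentationConfig, SaturationStopper, TrainingConfig, augment_batch,
    augment_patch, patch_descriptors, _photometric, _hsv_jitter_numpy,
)
from oracles import saturation_epochs_bruteforce


class TestAugmentation:
    def test_identity_config_is_exact_identity(self):
        rng = np.random.default_rng(0)
        pix = rng.random((4, 16, 16, 3)).astype(np.float32)
        out = augment_batch(pix, AugmentationConfig.identity(), rng)
        np.testing.assert_array_equal(out, pix)

    def test_rotation_four_times_restores(self):
        rng = np.random.default_rng(1)
        pix = rng.random((16, 16, 3)).astype(np.float32)
        out = pix
        for _ in range(4):
            out = np.rot90(out, k=1, axes=(0, 1))
        np.testing.assert_array_equal(out, pix)
        # and the 90-degree transform applied by the augmenter is exact
        cfg = AugmentationConfig(rotations=(90,), horizontal_flip=False,
                                 max_brightness_delta=0, max_saturation_delta=0,
                                 max_hue_delta=0, max_contrast_delta=0)
        aug = augment_batch(pix[None], cfg, np.random.default_rng(0))[0]
        np.testing.assert_array_equal(aug, np.rot90(pix, k=1, axes=(0, 1)))

    def test_max_brightness_on_all_ones_stays_clipped(self):
        pix = np.ones((2, 8, 8, 3), dtype=np.float32)
        cfg = AugmentationConfig(rotations=(0,), horizontal_flip=False)
        out = augment_batch(pix, cfg, np.random.default_rng(2))
        assert out.max() <= 1.0 and out.min() >= 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1),
           st.floats(0, 64 / 255), st.floats(0, 0.25),
           st.floats(0, 0.04), st.floats(0, 0.75))
    def test_closure_pixels_stay_in_unit_range(self, seed, db, ds_, dh, dc):
        """Any composition of allowed transforms keeps pixels in [0, 1]."""
        rng = np.random.default_rng(seed)
        pix = rng.random((3, 8, 8, 3)).astype(np.float32)
        cfg = AugmentationConfig(max_brightness_delta=db, max_saturation_delta=ds_,
                                 max_hue_delta=dh, max_contrast_delta=dc)
        out = augment_batch(augment_batch(pix, cfg, rng), cfg, rng)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_numba_kernel_matches_numpy_reference(self):
        rng = np.random.default_rng(3)
        x = rng.random((20, 8, 8, 3)).astype(np.float32)
        db = rng.uniform(-0.2, 0.2, 20)
        dh = rng.uniform(-0.04, 0.04, 20)
        ds_ = rng.uniform(-0.25, 0.25, 20)
        dc = 1 + rng.uniform(-0.7, 0.7, 20)
        fused = _photometric(x.copy(), db, dh, ds_, dc)
        ref = np.clip(x + db[:, None, None, None].astype(np.float32), 0, 1)
        ref = _hsv_jitter_numpy(ref, dh, ds_)
        mean = ref.mean(axis=(1, 2), keepdims=True)
        ref = np.clip(mean + (ref - mean) * dc[:, None, None, None].astype(np.float32), 0, 1)
        np.testing.assert_allclose(fused, ref, atol=5e-6)

    def test_augment_patch_preserves_metadata(self, two_cohort_dataset):
        patch = two_cohort_dataset.cohorts[0][0].patches[0]
        out = augment_patch(patch, AugmentationConfig(), np.random.default_rng(0))
        assert out.slide_id == patch.slide_id
        assert out.assigned_label == patch.assigned_label


class TestAssignPatchLabels:
    def test_detection_labels_are_slide_labels_not_latent(self, two_cohort_dataset):
        pos_slides = two_cohort_dataset.slides(0, label=1)
        stream = sc.assign_patch_labels(pos_slides, "detection")
        assert set(stream.labels) == {1}  # even though ~30% are latent-normal
        latent = [p.latent_state for s in pos_slides for p in s.patches]
        assert "normal" in latent

    def test_discrimination_labels_are_cohort_classes(self, two_cohort_dataset):
        slides = (two_cohort_dataset.slides(0) + two_cohort_dataset.slides(1))
        stream = sc.assign_patch_labels(slides, "discrimination")
        assert set(stream.labels) == {0, 1}
        np.testing.assert_array_equal(stream.labels, stream.cohort_ids)


class TestStoppingRule:
    def test_constant_trace_stops_after_one_plus_patience(self):
        stopper = SaturationStopper(patience=5)
        for e in range(1, 20):
            if stopper.update(0.5):
                break
        assert e == 6

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
           st.integers(1, 6), st.sampled_from([0.0, 0.005, 0.02]))
    def test_online_stopper_matches_bruteforce_window_scan(self, trace,
                                                           patience, tol):
        stopper = SaturationStopper(patience, tol)
        stopped_at = None
        for acc in trace:
            if stopper.update(acc):
                stopped_at = stopper.epoch
                break
        expected = saturation_epochs_bruteforce(trace, patience, tol)
        if expected is not None and expected <= len(trace):
            assert stopped_at == expected
        else:
            assert stopped_at is None


class TestTraining:
    def test_epoch_patch_budget(self):
        cfg = TrainingConfig()
        assert cfg.batch_size * cfg.iterations_per_epoch == 32_000

    def test_separable_data_reaches_high_accuracy(self, two_cohort_subdatasets,
                                                  tiny_training_config):
        """Two distant cohorts are near-perfectly discriminable."""
        sub = two_cohort_subdatasets[0]
        train = sc.assign_patch_labels(sub.pooled("train"), "discrimination")
        val = sc.assign_patch_labels(sub.pooled("validation"), "discrimination")
        model, rec = sc.train_patch_model(train, val, "discrimination",
                                          tiny_training_config.with_seed(2))
        assert rec.best_val_accuracy >= 0.95

    def test_training_is_deterministic(self, two_cohort_subdatasets):
        sub = two_cohort_subdatasets[0]
        train = sc.assign_patch_labels(sub.train[0], "detection")
        val = sc.assign_patch_labels(sub.validation[0], "detection")
        cfg = TrainingConfig.desk(iterations_per_epoch=10, max_epochs=3,
                                  patience_epochs=1, val_patches_per_epoch=64,
                                  seed=9)
        m1, r1 = sc.train_patch_model(train, val, "detection", cfg)
        m2, r2 = sc.train_patch_model(train, val, "detection", cfg)
        np.testing.assert_array_equal(m1.mlp.W1, m2.mlp.W1)
        assert r1.trace == r2.trace

    def test_empty_stream_rejected(self, two_cohort_subdatasets,
                                   tiny_training_config):
        sub = two_cohort_subdatasets[0]
        val = sc.assign_patch_labels(sub.validation[0], "detection")
        empty = sc.PatchSet(np.zeros((0, 16, 16, 3), np.float32),
                            np.zeros(0, np.int64), np.zeros(0, np.int64), [])
        with pytest.raises(ValueError):
            sc.train_patch_model(empty, val, "detection", tiny_training_config)

    def test_truncation_flag_on_max_epochs(self, two_cohort_subdatasets):
        sub = two_cohort_subdatasets[0]
        train = sc.assign_patch_labels(sub.train[0], "detection")
        val = sc.assign_patch_labels(sub.validation[0], "detection")
        cfg = TrainingConfig.desk(iterations_per_epoch=5, max_epochs=2,
                                  val_patches_per_epoch=64, seed=0)
        with pytest.warns(UserWarning, match="max_epochs"):
            _, rec = sc.train_patch_model(train, val, "detection", cfg)
        assert rec.truncated and rec.epochs_trained == 2


class TestPrediction:
    def test_rows_sum_to_one_and_deterministic(self, trained_detector,
                                               two_cohort_dataset):
        model, _ = trained_detector
        pix = two_cohort_dataset.cohorts[0][0].pixels
        probs = sc.predict_patch(model, pix)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        dup = sc.predict_patch(model, np.stack([pix[0], pix[0]]))
        np.testing.assert_array_equal(dup[0], dup[1])

    def test_shape_mismatch_rejected(self, trained_detector):
        model, _ = trained_detector
        with pytest.raises(ValueError, match="shape"):
            sc.predict_patch(model, np.zeros((1, 8, 8, 3), np.float32))

    def test_features_finite_and_duplicate_rows_identical(self, trained_detector,
                                                          two_cohort_dataset):
        model, _ = trained_detector
        pix = two_cohort_dataset.cohorts[0][0].pixels
        F = sc.extract_features(model, pix)
        assert F.shape == (pix.shape[0], model.feature_dim)
        assert np.all(np.isfinite(F))
        dup = sc.extract_features(model, np.stack([pix[0], pix[0]]))
        np.testing.assert_array_equal(dup[0], dup[1])

    def test_features_separate_distant_cohorts(self, trained_detector,
                                               two_cohort_dataset):
        """20 sampled patches/slide: between-cohort feature distance exceeds
        within-cohort distance for well-separated cohorts."""
        model, _ = trained_detector
        rng = np.random.default_rng(4)
        feats = {}
        for c in (0, 1):
            pix = np.concatenate([
                s.pixels[rng.choice(len(s.patches),
                                    size=min(20, len(s.patches)), replace=False)]
                for s in two_cohort_dataset.slides(c)[:6]])
            feats[c] = sc.extract_features(model, pix)
        within = np.linalg.norm(
            feats[0][:30, None] - feats[0][None, 30:60], axis=2).mean()
        between = np.linalg.norm(
            feats[0][:30, None] - feats[1][None, :30], axis=2).mean()
        assert between > within
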