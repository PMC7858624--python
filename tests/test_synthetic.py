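"""Generator: planted hierarchy, Brownian cohort parameters, slides."""

import numpy as np
import pytest
from scipy.stats import spearmanr, ttest_ind

import supercohort as sc
from supercohort.synthetic import GenerationConfig, dataset_digest


class TestPlantedHierarchy:
    def test_explicit_pairs_partition(self):
        h = sc.generate_planted_hierarchy(4, ((0, 1), (2, 3)), seed=0)
        assert h.partition_at(2) == ((0, 1), (2, 3))

    def test_partition_boundaries(self):
        h = sc.generate_planted_hierarchy(12, "balanced", seed=1)
        assert h.partition_at(12) == tuple((c,) for c in range(12))
        assert h.partition_at(1) == (tuple(range(12)),)

    def test_random_layout_deterministic(self):
        a = sc.generate_planted_hierarchy(3, "random", seed=7)
        b = sc.generate_planted_hierarchy(3, "random", seed=7)
        assert a.merges == b.merges

    @pytest.mark.parametrize("layout", ["balanced", "random"])
    @pytest.mark.parametrize("n", [2, 5, 8])
    def test_heights_nondecreasing_and_leaves(self, layout, n):
        h = sc.generate_planted_hierarchy(n, layout, seed=3)
        heights = h.node_heights()
        for k, (a, b, hh) in enumerate(h.merges):
            assert hh >= heights[a] and hh >= heights[b]
        assert h.partition_at(n) == tuple((c,) for c in range(n))

    def test_rejects_single_cohort(self):
        with pytest.raises(ValueError):
            sc.generate_planted_hierarchy(1, "balanced", seed=0)

    def test_newick_roundtrips_via_dendropy(self):
        import dendropy

        h = sc.generate_planted_hierarchy(6, ((0, 1, 0.25),
                                              ((2, 3, 0.25), (4, 5, 0.25), 4.0),
                                              6.0), seed=0)
        tree = dendropy.Tree.get(data=h.to_newick(), schema="newick")
        leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        assert leaves == [str(i) for i in range(6)]
        # patristic distance between leaves 0 and 1 equals 2 * pair height
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.patristic_distance(taxa["0"], taxa["1"]) == pytest.approx(0.5)


class TestCohortParams:
    def test_zero_walk_collapses_thetas(self):
        h = sc.generate_planted_hierarchy(4, "balanced", seed=0)
        params = sc.derive_cohort_params(h, sigma_walk=0.0, seed=1)
        for p in params[1:]:
            np.testing.assert_allclose(p.theta, params[0].theta)

    def test_shared_cancer_weight_one_gives_common_direction(self):
        h = sc.generate_planted_hierarchy(4, "balanced", seed=0)
        params = sc.derive_cohort_params(h, shared_cancer_weight=1.0, seed=1)
        for p in params[1:]:
            np.testing.assert_allclose(p.cancer_direction,
                                       params[0].cancer_direction)

    def test_sibling_cohorts_closer_than_cross_root(self):
        # (0,1) share an immediate parent; 0 and 2 sit across the root
        h = sc.generate_planted_hierarchy(4, ((0, 1, 1.0), (2, 3, 1.0), 4.0),
                                          seed=0)
        near, far = [], []
        for seed in range(200):
            params = sc.derive_cohort_params(h, sigma_walk=1.0, seed=seed)
            near.append(((params[0].theta - params[1].theta) ** 2).sum())
            far.append(((params[0].theta - params[2].theta) ** 2).sum())
        assert np.mean(near) < np.mean(far)

    def test_distance_tracks_tree_path_length(self):
        """Planted similarity: Spearman(path length, mean squared theta
        distance) > 0.8 across >= 200 seeds."""
        h = sc.generate_planted_hierarchy(6, "random", seed=5)
        pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        sq = np.zeros(len(pairs))
        for seed in range(200):
            params = sc.derive_cohort_params(h, sigma_walk=1.0, seed=seed)
            for k, (i, j) in enumerate(pairs):
                sq[k] += ((params[i].theta - params[j].theta) ** 2).sum()
        paths = [h.path_length(i, j) for i, j in pairs]
        rho = spearmanr(paths, sq / 200).statistic
        assert rho > 0.8

    def test_negative_sigma_rejected(self):
        h = sc.generate_planted_hierarchy(2, "balanced", seed=0)
        with pytest.raises(ValueError):
            sc.derive_cohort_params(h, sigma_walk=-1.0, seed=0)


class TestGenerateSlide:
    @pytest.fixture()
    def params(self):
        h = sc.generate_planted_hierarchy(2, "balanced", seed=0)
        return sc.derive_cohort_params(h, seed=2)[0]

    @pytest.mark.parametrize("label,fraction,expected_cancer", [
        (1, 1.0, 10), (0, 0.6, 0), (1, 0.6, 6), (1, 0.25, 2), (1, 0.0, 0),
    ])
    def test_latent_cancer_count_is_rounded_fraction(self, params, label,
                                                     fraction, expected_cancer):
        rng = np.random.default_rng(0)
        slide = sc.generate_slide(params, label, 10, fraction, rng)
        n_cancer = sum(p.latent_state == "cancer" for p in slide.patches)
        assert n_cancer == expected_cancer
        assert all(p.assigned_label == label for p in slide.patches)

    def test_pixels_in_unit_range(self, params):
        rng = np.random.default_rng(1)
        slide = sc.generate_slide(params, 1, 12, 0.7, rng)
        pix = slide.pixels
        assert pix.min() >= 0.0 and pix.max() <= 1.0

    def test_bad_fraction_rejected(self, params):
        with pytest.raises(ValueError):
            sc.generate_slide(params, 1, 5, 1.2, np.random.default_rng(0))


class TestGenerateDataset:
    def test_counts_and_unique_patients(self, two_cohort_dataset):
        for c in (0, 1):
            slides = two_cohort_dataset.cohorts[c]
            assert sum(s.label == 1 for s in slides) == 12
            assert sum(s.label == 0 for s in slides) == 12
        pids = [s.patient_id for c in (0, 1)
                for s in two_cohort_dataset.cohorts[c]]
        assert len(pids) == len(set(pids))

    def test_deterministic_digest(self):
        h = sc.generate_planted_hierarchy(2, "balanced", seed=0)
        gen = GenerationConfig(n_pos_slides=3, n_neg_slides=3,
                               patches_per_slide=4, patch_size=12)
        d1 = sc.generate_dataset(h, gen, seed=11)
        d2 = sc.generate_dataset(h, gen, seed=11)
        assert dataset_digest(d1) == dataset_digest(d2)

    def test_demand_exceeding_supply_rejected(self):
        h = sc.generate_planted_hierarchy(2, "balanced", seed=0)
        gen = GenerationConfig(n_pos_slides=5, n_neg_slides=5,
                               min_slides_per_class=10)
        with pytest.raises(ValueError, match="demand"):
            sc.generate_dataset(h, gen, seed=0)

    def test_zero_cancer_effect_makes_classes_indistinguishable(self):
        h = sc.generate_planted_hierarchy(2, "balanced", seed=0)
        gen = GenerationConfig(n_pos_slides=20, n_neg_slides=20,
                               patches_per_slide=6, patch_size=12,
                               cancer_effect=0.0)
        ds = sc.generate_dataset(h, gen, seed=13)
        pos = np.concatenate([s.pixels.reshape(len(s.patches), -1).mean(axis=1)
                              for s in ds.slides(0, label=1)])
        neg = np.concatenate([s.pixels.reshape(len(s.patches), -1).mean(axis=1)
                              for s in ds.slides(0, label=0)])
        assert ttest_ind(pos, neg).pvalue > 0.01

    def test_two_slides_per_patient_mode(self):
        h = sc.generate_planted_hierarchy(2, "balanced", seed=0)
        gen = GenerationConfig(n_pos_slides=6, n_neg_slides=6,
                               patches_per_slide=4, patch_size=12,
                               two_slides_per_patient=True)
        ds = sc.generate_dataset(h, gen, seed=1)
        for c in (0, 1):
            by_pid = {}
            for s in ds.cohorts[c]:
                by_pid.setdefault(s.patient_id, []).append(s.label)
            for labels in by_pid.values():
                assert sorted(labels) == [0, 1]

    def test_save_load_roundtrip(self, tmp_path, two_cohort_dataset):
        prefix = str(tmp_path / "ds")
        sc.synthetic.save_dataset(two_cohort_dataset, prefix)
        loaded = sc.synthetic.load_dataset(prefix)
        assert dataset_digest(loaded) == dataset_digest(two_cohort_dataset)
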