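"""Ward dendrograms, super-cohort cuts, CI machinery, partition selection."""

import numpy as np
import pytest

from supercohort.aggregation import (
    Dendrogram, PartitionEvaluation, SuperCohortPartition, build_dendrogram,
    cut_to_supercohorts, mean_ci, select_partitions,
)
from supercohort.similarity import SimilarityMatrix
from oracles import ward_bruteforce


def detection_matrix(values):
    V = np.asarray(values, dtype=float)
    return SimilarityMatrix(V, "detection_C",
                            [f"c{i}" for i in range(V.shape[0])])


class TestWard:
    def test_identical_columns_merge_first_at_zero_height(self):
        V = np.array([[0.9, 0.9, 0.1],
                      [0.8, 0.8, 0.2],
                      [0.1, 0.1, 0.9]])
        d = build_dendrogram(detection_matrix(V))
        a, b, h = d.linkage[0, 0], d.linkage[0, 1], d.linkage[0, 2]
        assert {int(a), int(b)} == {0, 1}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_two_cohorts_single_merge(self):
        d = build_dendrogram(detection_matrix([[1.0, 0.2], [0.3, 0.9]]))
        assert d.linkage.shape == (1, 4)

    def test_planted_two_pair_matrix_merges_pairs_first(self):
        """Two tight column pairs, large between-pair separation: the first
        two merges are the planted pairs (checked against all pairings)."""
        V = np.array([[0.95, 0.93, 0.10, 0.12],
                      [0.94, 0.96, 0.11, 0.10],
                      [0.10, 0.12, 0.97, 0.95],
                      [0.12, 0.09, 0.94, 0.96]])
        d = build_dendrogram(detection_matrix(V))
        first_two = {frozenset({int(d.linkage[k, 0]), int(d.linkage[k, 1])})
                     for k in range(2)}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}
        assert cut_to_supercohorts(d, 2).groups == ((0, 1), (2, 3))

    def test_nonfinite_matrix_rejected(self):
        m = SimilarityMatrix(np.array([[1.0, np.nan], [0.2, 0.9]]),
                             "detection_C", ["a", "b"])
        with pytest.raises(ValueError, match="finite"):
            build_dendrogram(m)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_agreement_with_bruteforce_ward(self, n):
        """Merge heights and every cut partition match a from-scratch Ward
        agglomeration, over 100 random matrices."""
        rng = np.random.default_rng(2024)
        for _ in range(100 // 3 + 1):
            V = rng.random((n, n))
            d = build_dendrogram(detection_matrix(V))
            heights, partitions = ward_bruteforce(V.T)
            np.testing.assert_allclose(sorted(d.linkage[:, 2]), sorted(heights),
                                       rtol=1e-9)
            for S in range(1, n + 1):
                got = {frozenset(g) for g in cut_to_supercohorts(d, S).groups}
                assert got == partitions[S]


class TestCuts:
    @pytest.fixture()
    def dend(self):
        rng = np.random.default_rng(5)
        return build_dendrogram(detection_matrix(rng.random((6, 6))))

    def test_boundary_cuts(self, dend):
        assert cut_to_supercohorts(dend, 1).groups == (tuple(range(6)),)
        assert cut_to_supercohorts(dend, 6).groups == tuple((c,) for c in range(6))

    def test_out_of_range_rejected(self, dend):
        for S in (0, 7):
            with pytest.raises(ValueError):
                cut_to_supercohorts(dend, S)

    def test_partition_invariants_all_cuts(self, dend):
        for S in range(1, 7):
            part = cut_to_supercohorts(dend, S)
            flat = sorted(c for g in part.groups for c in g)
            assert flat == list(range(6))
            assert len(part.groups) == S

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            SuperCohortPartition(2, ((0, 1), (1, 2)))


class TestMeanCI:
    def test_constant_vector_zero_halfwidth(self):
        mean, hw = mean_ci([0.7, 0.7, 0.7])
        assert mean == pytest.approx(0.7)
        assert hw == pytest.approx(0.0)

    def test_two_point_closed_form(self):
        # t_{0.975, 1} = 12.7062; sd = 0.7071; hw = 12.7062 * 0.7071/1.4142
        mean, hw = mean_ci([0.0, 1.0], level=0.95)
        assert mean == pytest.approx(0.5)
        assert hw == pytest.approx(12.7062 * np.sqrt(0.5) / np.sqrt(2), rel=1e-4)

    def test_halfwidth_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=4)
        sd = base.std(ddof=1)
        hws = []
        for n in (4, 8, 16, 64):
            # same sample sd by construction: tile and rescale
            v = np.resize(base, n)
            v = (v - v.mean()) / v.std(ddof=1) * sd
            hws.append(mean_ci(v)[1])
        assert all(a > b for a, b in zip(hws, hws[1:]))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            mean_ci([0.5])


def make_eval(kind, S, mean, hw, epochs):
    part = SuperCohortPartition(S, tuple((i,) for i in range(S)), (kind, S))
    return PartitionEvaluation(part, {i: mean for i in range(S)}, mean, hw,
                               epochs)


class TestSelectPartitions:
    def test_threshold_arithmetic(self):
        ref = make_eval("", 3, 0.96, 0.02, 30.0)
        evals = {("detection_C", 2): make_eval("detection_C", 2, 0.95, 0.01, 20.0),
                 ("detection_C", 1): make_eval("detection_C", 1, 0.93, 0.01, 10.0)}
        sel = select_partitions(evals, ref)
        assert ("detection_C", 2) in sel.qualifying
        assert ("detection_C", 1) not in sel.qualifying

    def test_reference_configuration_always_qualifies(self):
        ref = make_eval("", 3, 0.9, 0.05, 30.0)
        evals = {("detection_C", 3): make_eval("detection_C", 3, 0.9, 0.05, 30.0)}
        sel = select_partitions(evals, ref)
        assert sel.qualifying == [("detection_C", 3)]

    def test_min_time_and_best_performance_choices(self):
        ref = make_eval("", 4, 0.90, 0.05, 40.0)
        evals = {
            ("detection_C", 2): make_eval("detection_C", 2, 0.88, 0.01, 15.0),
            ("disc_negative", 3): make_eval("disc_negative", 3, 0.95, 0.01, 25.0),
            ("disc_general", 4): make_eval("disc_general", 4, 0.80, 0.01, 12.0),
        }
        sel = select_partitions(evals, ref)
        assert ("disc_general", 4) not in sel.qualifying
        assert sel.min_time_choice == ("detection_C", 2)
        assert sel.best_performance_choice == ("disc_negative", 3)

    def test_tie_break_smaller_s_then_kind_order(self):
        ref = make_eval("", 2, 0.5, 0.3, 99.0)
        evals = {
            ("disc_positive", 3): make_eval("disc_positive", 3, 0.9, 0.01, 10.0),
            ("disc_negative", 2): make_eval("disc_negative", 2, 0.9, 0.01, 10.0),
            ("detection_C", 2): make_eval("detection_C", 2, 0.9, 0.01, 10.0),
        }
        sel = select_partitions(evals, ref)
        assert sel.min_time_choice == ("detection_C", 2)
        assert sel.best_performance_choice == ("detection_C", 2)

    def test_empty_qualifying_flagged(self):
        ref = make_eval("", 2, 0.99, 0.001, 10.0)
        evals = {("detection_C", 1): make_eval("detection_C", 1, 0.5, 0.01, 5.0)}
        sel = select_partitions(evals, ref)
        assert sel.empty and sel.min_time_choice is None

    def test_two_sided_gate_excludes_above_upper_bound(self):
        ref = make_eval("", 2, 0.90, 0.02, 10.0)
        evals = {("detection_C", 2): make_eval("detection_C", 2, 0.95, 0.01, 5.0)}
        assert select_partitions(evals, ref).qualifying
        assert not select_partitions(evals, ref, two_sided_gate=True).qualifying
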