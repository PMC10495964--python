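"""Unit tests for contingency building, Jaccard matching and the J-score."""

import numpy as np
import pytest

from jscore import (
    BaselineSpec,
    LabelPair,
    bidirectional_match,
    build_contingency,
    expected_baseline,
    j_score,
    jaccard_matrix,
    match_similarity_table,
    round_score,
    uniform_baseline,
)


class TestLabelPair:
    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            LabelPair([1, 2, 3], [1, 2])

    def test_rejects_empty(self):
        with pytest.raises(ValueError, match="empty"):
            LabelPair([], [])

    @pytest.mark.parametrize("bad", [None, float("nan")])
    def test_rejects_missing_labels(self, bad):
        with pytest.raises(ValueError, match="missing"):
            LabelPair(["a", bad], ["x", "y"])

    def test_single_sample_is_legal(self):
        assert j_score(LabelPair(["a"], ["x"])).J == 1.0


class TestContingency:
    def test_worked_example_counts(self, stray_pair):
        ct = build_contingency(stray_pair)
        frame = ct.to_frame()
        assert list(frame.index) == ["Ta", "Tb", "Tc"]
        assert list(frame.columns) == ["K1", "K2", "K3", "K4"]
        assert frame.loc["Tc"].tolist() == [0, 0, 40, 20]
        assert ct.class_sizes.tolist() == [10, 30, 60]
        assert ct.cluster_sizes.tolist() == [10, 30, 40, 20]
        assert ct.n == 100

    def test_identical_labels_give_diagonal(self):
        labels = np.repeat(["a", "b", "c"], [3, 5, 2])
        ct = build_contingency(LabelPair(labels, labels))
        assert np.array_equal(ct.counts, np.diag([3, 5, 2]))

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            t = rng.integers(0, 3, size=n)
            k = rng.integers(0, 3, size=n)
            ct = build_contingency(LabelPair(t, k))
            for i, lab_t in enumerate(ct.row_labels):
                for j, lab_k in enumerate(ct.col_labels):
                    expected = len(
                        set(np.flatnonzero(t == lab_t)) & set(np.flatnonzero(k == lab_k))
                    )
                    assert ct.counts[i, j] == expected


class TestJaccardMatrix:
    def test_worked_example_values(self, stray_pair):
        jm = jaccard_matrix(build_contingency(stray_pair)).to_frame()
        assert jm.loc["Tc", "K3"] == pytest.approx(40 / 60)
        assert jm.loc["Tc", "K4"] == pytest.approx(20 / 60)
        assert jm.loc["Ta", "K1"] == 1.0
        assert jm.loc["Ta", "K2"] == 0.0  # disjoint sets

    def test_bounds_and_zero_pattern(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            t = rng.integers(0, 4, size=25)
            k = rng.integers(0, 4, size=25)
            ct = build_contingency(LabelPair(t, k))
            jm = jaccard_matrix(ct)
            assert np.all((jm.values >= 0) & (jm.values <= 1))
            assert np.array_equal(jm.values == 0, ct.counts == 0)


class TestBidirectionalMatch:
    def test_stray_cluster_detected(self, stray_pair):
        m = bidirectional_match(jaccard_matrix(build_contingency(stray_pair)))
        assert m.class_to_cluster["Tc"] == ("K3", pytest.approx(2 / 3))
        assert m.cluster_to_class["K4"] == ("Tc", pytest.approx(1 / 3))
        assert m.stray_clusters == {"K4"}
        assert m.split_classes == {"Tc"}

    def test_merged_clusters_all_point_to_largest(self, merged_pair):
        m = bidirectional_match(jaccard_matrix(build_contingency(merged_pair)))
        assert {k for k, _ in m.class_to_cluster.values()} == {"K1"}
        assert m.stray_clusters == {"K2"}
        assert m.cluster_to_class["K1"][0] == "Tc"
        assert m.cluster_to_class["K2"][0] == "Tc"
        assert m.split_classes == {"Tc"}

    def test_perfect_partition_is_bijective(self):
        labels = np.repeat(["a", "b", "c"], [4, 6, 2])
        clusters = np.repeat(["z", "y", "x"], [4, 6, 2])
        m = bidirectional_match(jaccard_matrix(build_contingency(LabelPair(labels, clusters))))
        forward = {t: k for t, (k, _) in m.class_to_cluster.items()}
        backward = {k: t for k, (t, _) in m.cluster_to_class.items()}
        assert forward == {"a": "z", "b": "y", "c": "x"}
        assert backward == {v: k for k, v in forward.items()}
        assert not m.stray_clusters and not m.split_classes

    def test_ties_break_to_first_sorted_label(self):
        # class "a" overlaps clusters "x" and "y" with equal Jaccard index
        pair = LabelPair(["a", "a", "b", "b"], ["x", "y", "x", "y"])
        m = bidirectional_match(jaccard_matrix(build_contingency(pair)))
        assert m.class_to_cluster["a"][0] == "x"
        assert m.cluster_to_class["x"][0] == "a"


class TestJScore:
    @pytest.mark.parametrize(
        "fixture, expected",
        [
            ("stray_pair", 0.77),
            ("stray_split_pair", 0.75),
            ("merged_pair", 0.39),
            ("merged_split_pair", 0.38),
        ],
    )
    def test_worked_example_scores(self, request, fixture, expected):
        pair = request.getfixturevalue(fixture)
        assert round_score(j_score(pair).J) == expected

    def test_components_of_stray_example(self, stray_pair):
        s = j_score(stray_pair)
        assert s.R == pytest.approx(0.8)
        assert s.P == pytest.approx(0.7333, abs=1e-4)

    def test_swapping_columns_swaps_r_and_p(self, stray_pair):
        s = j_score(stray_pair)
        sw = j_score(stray_pair.swapped())
        assert (sw.R, sw.P) == (pytest.approx(s.P), pytest.approx(s.R))
        assert sw.J == pytest.approx(s.J)

    def test_relabeled_identity_scores_one(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 4, size=50)
        renamed = np.array([f"cluster_{x}" for x in t], dtype=object)
        assert j_score(LabelPair(t, renamed)).J == pytest.approx(1.0)

    def test_j_between_r_and_p(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            t = rng.integers(0, 5, size=30)
            k = rng.integers(0, 5, size=30)
            s = j_score(LabelPair(t, k))
            assert min(s.R, s.P) - 1e-12 <= s.J <= max(s.R, s.P) + 1e-12


class TestSimilarityTableMatching:
    def test_consistent_with_jaccard_matching(self, stray_pair):
        jm = jaccard_matrix(build_contingency(stray_pair))
        direct = bidirectional_match(jm)
        generic = match_similarity_table(jm.to_frame())
        assert generic.class_to_cluster == direct.class_to_cluster
        assert generic.cluster_to_class == direct.cluster_to_class
        assert generic.stray_clusters == direct.stray_clusters
        assert generic.split_classes == direct.split_classes

    def test_identity_matrix_matches_diagonally(self):
        m = match_similarity_table(np.eye(2), row_labels=["a", "b"], col_labels=["x", "y"])
        assert m.class_to_cluster == {"a": ("x", 1.0), "b": ("y", 1.0)}
        assert not m.stray_clusters

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        s = rng.random((3, 2))
        m = match_similarity_table(s)
        for i in range(3):
            best = max(range(2), key=lambda j: (s[i, j], -j))
            assert m.class_to_cluster[i] == (best, pytest.approx(s[i, best]))
        for j in range(2):
            best = max(range(3), key=lambda i: (s[i, j], -i))
            assert m.cluster_to_class[j] == (best, pytest.approx(s[best, j]))

    def test_rejects_empty_and_non_finite(self):
        with pytest.raises(ValueError, match="empty"):
            match_similarity_table(np.empty((0, 0)))
        with pytest.raises(ValueError, match="finite"):
            match_similarity_table(np.array([[1.0, np.nan]]))


class TestBaselines:
    def test_closed_form_components(self):
        res = expected_baseline(BaselineSpec([10, 90], [50, 50], 100))
        assert res.i0t == pytest.approx([0.0909, 0.4737], abs=5e-5)
        assert res.i0k == pytest.approx([0.4737, 0.4737], abs=5e-5)
        assert res.J0 == pytest.approx(0.4537, abs=5e-5)

    def test_single_block_baseline_is_one(self):
        assert expected_baseline(BaselineSpec([7], [7], 7)).J0 == pytest.approx(1.0)
        assert uniform_baseline(1, 1) == 1.0

    @pytest.mark.parametrize(
        "nt, nk, expected", [(3, 3, 0.2), (10, 10, 1 / 19), (2, 4, 0.2)]
    )
    def test_uniform_closed_form(self, nt, nk, expected):
        assert uniform_baseline(nt, nk) == pytest.approx(expected)

    def test_uniform_case_matches_general_formula(self):
        for nt, nk in [(2, 2), (3, 5), (4, 4)]:
            n = 4 * nt * nk
            spec = BaselineSpec([n // nt] * nt, [n // nk] * nk, n)
            assert expected_baseline(spec).J0 == pytest.approx(uniform_baseline(nt, nk))

    def test_uniform_baseline_strictly_decreasing(self):
        for nt in range(1, 12):
            for nk in range(1, 12):
                here = uniform_baseline(nt, nk)
                assert uniform_baseline(nt + 1, nk) < here
                assert uniform_baseline(nt, nk + 1) < here

    def test_size_vector_validation(self):
        with pytest.raises(ValueError, match="sum to N"):
            BaselineSpec([10, 80], [50, 50], 100)
        with pytest.raises(ValueError, match="positive"):
            BaselineSpec([0, 100], [50, 50], 100)
        with pytest.raises(ValueError, match="positive"):
            uniform_baseline(0, 3)


def test_round_score_rounds_half_away_from_zero():
    assert round_score(0.765) == 0.77
    assert round_score(0.7649) == 0.76
    assert round_score(0.125) == 0.13
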