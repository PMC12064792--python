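"""Confusion-matrix grouping: similarity, distances, linkage, dendrograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trapexpert.grouping import (
    ConfusionMatrix,
    GroupAssignment,
    agglomerative_cluster,
    distance_from_similarity,
    export_dendrogram,
    group_species,
    similarity_from_confusion,
)

from conftest import random_distance_matrix
from oracles import best_partition_by_within_distance, brute_force_linkage


class TestConfusionMatrix:
    def test_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            ConfusionMatrix(("a", "b"), np.zeros((2, 3)))

    def test_rejects_negative_entry_naming_position(self):
        with pytest.raises(ValueError, match="row 1"):
            ConfusionMatrix(("a", "b"), [[1, 0], [-2, 1]])

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="duplicate"):
            ConfusionMatrix(("a", "a"), np.eye(2))

    def test_csv_round_trip(self, tmp_path):
        cm = ConfusionMatrix(("deer", "boar"), [[8, 2], [1, 9]])
        cm.to_csv(tmp_path / "cm.csv")
        back = ConfusionMatrix.read_csv(tmp_path / "cm.csv")
        assert back.labels == cm.labels
        np.testing.assert_array_equal(back.counts, cm.counts)


class TestSimilarity:
    @pytest.mark.parametrize(
        "counts, expected, zero_rows",
        [
            ([[8, 2], [0, 10]], [[0.8, 0.2], [0.0, 1.0]], set()),
            (np.diag([5, 7, 9]), np.eye(3), set()),
            ([[0, 0], [3, 1]], [[0, 0], [0.75, 0.25]], {0}),
        ],
    )
    def test_row_normalisation(self, counts, expected, zero_rows):
        labels = tuple(f"s{i}" for i in range(len(np.asarray(counts))))
        sm = similarity_from_confusion(ConfusionMatrix(labels, counts))
        np.testing.assert_allclose(sm.values, expected)
        assert sm.zero_rows == zero_rows

    @given(st.integers(2, 10), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_nonzero_rows_sum_to_one(self, n, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(n, n))
        sm = similarity_from_confusion(
            ConfusionMatrix(tuple(f"s{i}" for i in range(n)), counts)
        )
        sums = sm.values.sum(axis=1)
        for i in range(n):
            if i in sm.zero_rows:
                assert sums[i] == 0.0
            else:
                assert abs(sums[i] - 1.0) < 1e-9


class TestDistance:
    def test_identity_similarity_gives_unit_off_diagonal(self):
        sm = similarity_from_confusion(
            ConfusionMatrix(("a", "b", "c"), np.diag([1, 2, 3]))
        )
        d = distance_from_similarity(sm)
        np.testing.assert_allclose(d, 1 - np.eye(3))

    def test_symmetrisation(self):
        from trapexpert.grouping import SimilarityMatrix

        sm = SimilarityMatrix(("a", "b"), [[0.8, 0.2], [0.4, 0.6]])
        d = distance_from_similarity(sm)
        assert d[0, 1] == d[1, 0] == pytest.approx(1 - (0.2 + 0.4) / 2)
        assert d[0, 0] == d[1, 1] == 0.0


class TestAgglomerativeCluster:
    def two_pair_matrix(self):
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0.0)
        return d

    def test_two_tight_pairs_recovered_at_k2(self):
        d = self.two_pair_matrix()
        _, ga = agglomerative_cluster(d, 2)
        found = {frozenset(i for i, g in enumerate(ga.assignment) if g == gid)
                 for gid in range(2)}
        assert found == best_partition_by_within_distance(d, 2)

    def test_k_equals_n_gives_singletons(self):
        d = self.two_pair_matrix()
        _, ga = agglomerative_cluster(d, 4)
        assert sorted(ga.assignment) == [0, 1, 2, 3]

    def test_k1_single_cluster(self):
        _, ga = agglomerative_cluster(self.two_pair_matrix(), 1)
        assert set(ga.assignment) == {0}

    @pytest.mark.parametrize("k", [0, 5])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError, match="k must be"):
            agglomerative_cluster(self.two_pair_matrix(), k)

    def test_nan_rejected(self):
        d = self.two_pair_matrix()
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            agglomerative_cluster(d, 2)

    def test_heights_monotone(self):
        rng = np.random.default_rng(5)
        tree, _ = agglomerative_cluster(random_distance_matrix(rng, 12), 3)
        heights = tree.heights
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    @pytest.mark.parametrize("seed", range(30))
    @pytest.mark.parametrize("discretize", [False, True])
    def test_merge_sequence_matches_brute_force(self, seed, discretize):
        """Average-linkage merges (incl. tie-breaks) equal a naive
        re-averaging reference; discretized matrices force exact ties."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        d = random_distance_matrix(rng, n, discretize=discretize)
        tree, _ = agglomerative_cluster(d, 1)
        expected = brute_force_linkage(d, "average")
        for ours, ref in zip(tree.merges, expected):
            assert ours[:2] == ref[:2]
            assert ours[1] == ref[1]
            assert ours[2] == pytest.approx(ref[2], abs=1e-12)

    @pytest.mark.parametrize("linkage", ["complete", "single"])
    def test_other_linkages_match_brute_force(self, linkage):
        rng = np.random.default_rng(77)
        d = random_distance_matrix(rng, 7)
        tree, _ = agglomerative_cluster(d, 1, linkage=linkage)
        for ours, ref in zip(tree.merges, brute_force_linkage(d, linkage)):
            assert ours[:2] == ref[:2]
            assert ours[2] == pytest.approx(ref[2])

    def test_heights_match_scipy_average_linkage(self):
        """Cross-check against scipy's independent implementation on
        tie-free matrices (merge heights and cluster sizes)."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            d = random_distance_matrix(rng, n)
            tree, _ = agglomerative_cluster(d, 1)
            z = linkage(squareform(d, checks=False), method="average")
            np.testing.assert_allclose(tree.to_scipy()[:, 2], z[:, 2], atol=1e-10)
            np.testing.assert_array_equal(tree.to_scipy()[:, 3], z[:, 3])


class TestGroupSpecies:
    def planted_block_confusion(self, rng, blocks):
        labels = [lab for b in blocks for lab in b]
        n = len(labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((n, n), dtype=int)
        for block in blocks:
            for a in block:
                counts[idx[a], idx[a]] = 60
                for b in block:
                    if b != a:
                        counts[idx[a], idx[b]] = 15 + rng.integers(0, 5)
        # light cross-block noise
        for i in range(n):
            for j in range(n):
                if counts[i, j] == 0 and i != j:
                    counts[i, j] = rng.integers(0, 3)
        return ConfusionMatrix(tuple(labels), counts)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_three_blocks_recovered(self, seed):
        rng = np.random.default_rng(seed)
        blocks = [["a1", "a2"], ["b1", "b2"], ["c1", "c2"]]
        cm = self.planted_block_confusion(rng, blocks)
        ga = group_species(cm, 3)
        found = {frozenset(ga.members(g)) for g in range(3)}
        assert found == {frozenset(b) for b in blocks}
        # exhaustive-partition oracle agrees
        d = distance_from_similarity(similarity_from_confusion(cm))
        oracle = best_partition_by_within_distance(d, 3)
        oracle_labels = {frozenset(cm.labels[i] for i in blk) for blk in oracle}
        assert found == oracle_labels

    def test_perfect_classifier_gives_singletons(self):
        cm = ConfusionMatrix(tuple("abcd"), np.diag([5, 5, 5, 5]))
        ga = group_species(cm, 4)
        assert all(len(ga.members(g)) == 1 for g in range(4))

    def test_background_excluded_before_clustering(self):
        labels = ("a", "b", "background")
        counts = np.array([[8, 2, 0], [2, 8, 0], [1, 1, 8]])
        ga = group_species(ConfusionMatrix(labels, counts), 2,
                           background_label="background")
        assert "background" not in ga.labels
        assert len(ga.labels) == 2

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        cm = self.planted_block_confusion(rng, [["a1", "a2"], ["b1", "b2"], ["c1", "c2"]])
        ga = group_species(cm, 3)
        perm = list(rng.permutation(cm.n))
        ga_p = group_species(cm.permuted(perm), 3)
        for lab in cm.labels:
            # same co-membership structure regardless of input order
            mates = {m for m in ga.members(ga.group_of(lab))}
            mates_p = {m for m in ga_p.members(ga_p.group_of(lab))}
            assert mates == mates_p

    def test_zero_row_species_assigned_with_warning(self):
        labels = ("a1", "a2", "b1", "b2", "ghost")
        counts = np.zeros((5, 5), dtype=int)
        counts[:2, :2] = [[8, 2], [2, 8]]
        counts[2:4, 2:4] = [[9, 1], [1, 9]]
        counts[2, 4] = 3  # b1 sometimes predicted as ghost
        with pytest.warns(UserWarning, match="ghost"):
            ga = group_species(ConfusionMatrix(labels, counts), 2)
        assert ga.group_of("ghost") == ga.group_of("b1")

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        cm = self.planted_block_confusion(rng, [["a1", "a2"], ["b1", "b2"]])
        assert group_species(cm, 2).assignment == group_species(cm, 2).assignment


class TestGroupAssignment:
    def test_cluster_ids_must_be_contiguous(self):
        with pytest.raises(ValueError, match="no gaps"):
            GroupAssignment(("a", "b"), (0, 2), 3)

    def test_json_round_trip(self, tmp_path):
        ga = GroupAssignment(("a", "b", "c"), (0, 1, 0), 2, ("G0", "G1"))
        ga.to_json(tmp_path / "g.json")
        back = GroupAssignment.from_json(tmp_path / "g.json")
        assert back == ga


class TestNewickExport:
    def test_two_leaf_ultrametric(self):
        from trapexpert.grouping import LinkageTree

        tree = LinkageTree(("a", "b"), ((0, 1, 0.6, 2),))
        assert export_dendrogram(tree) == "(a:0.3,b:0.3);"

    def test_single_leaf(self):
        from trapexpert.grouping import LinkageTree

        assert export_dendrogram(LinkageTree(("a",), ())) == "a;"

    def test_four_leaf_round_trip_topology(self, tmp_path):
        import skbio

        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.2
        np.fill_diagonal(d, 0.0)
        tree, _ = agglomerative_cluster(d, 2, labels=("a", "b", "c", "d"))
        path = tmp_path / "t.nwk"
        export_dendrogram(tree, path)
        parsed = skbio.TreeNode.read(str(path))
        clades = {frozenset(t.name for t in n.tips()) for n in parsed.non_tips()}
        assert frozenset({"a", "b"}) in clades
        assert frozenset({"c", "d"}) in clades
        # ultrametric: both leaves of the {a,b} pair at half the merge height
        tips = {t.name: parsed.distance(t) for t in parsed.tips()}
        assert tips["a"] == pytest.approx(tips["b"])
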