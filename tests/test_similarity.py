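"""Distance metrics, clustering determinism, and partition agreement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qspharm.errors import AnalysisError, ValidationError
from qspharm.interactions import InteractionMatrix
from qspharm.similarity import (
    BitFingerprint,
    DistanceMatrix,
    cosine_distance,
    hierarchical_cluster,
    ligand_vectors,
    pairwise_distances,
    partition_agreement,
    tanimoto_distance,
    target_vectors,
)

binary_vectors = st.lists(st.integers(0, 1), min_size=2, max_size=12).filter(
    lambda v: any(v)
)


class TestCosine:
    def test_identical_vectors_have_distance_zero(self):
        assert cosine_distance([1, 0, 1], [1, 0, 1]) == 0.0

    def test_orthogonal_vectors_have_distance_one(self):
        assert cosine_distance([1, 0, 0], [0, 1, 0]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # 1 - 1/sqrt(2)
        assert cosine_distance([1, 1, 0], [1, 0, 0]) == pytest.approx(
            1 - 1 / np.sqrt(2), abs=1e-12
        )

    def test_zero_vector_is_a_domain_error(self):
        with pytest.raises(AnalysisError):
            cosine_distance([0, 0], [1, 0])

    def test_scale_invariance(self):
        assert cosine_distance([1, 2, 3], [2.5, 5.0, 7.5]) == pytest.approx(
            0.0, abs=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(u=binary_vectors, v=binary_vectors)
    def test_symmetry_and_range_on_binary_inputs(self, u, v):
        if len(u) != len(v):
            u, v = u[: min(len(u), len(v))], v[: min(len(u), len(v))]
            if not any(u) or not any(v):
                return
        d = cosine_distance(u, v)
        assert d == pytest.approx(cosine_distance(v, u))
        assert 0.0 <= d <= 1.0  # nonnegative vectors: cos >= 0


class TestTanimoto:
    def test_identical_fingerprints(self):
        fp = BitFingerprint(8, {1, 3, 5})
        assert tanimoto_distance(fp, fp) == 0.0

    def test_disjoint_fingerprints(self):
        assert tanimoto_distance(
            BitFingerprint(8, {0, 1}), BitFingerprint(8, {2, 3})
        ) == pytest.approx(1.0)

    def test_hand_set_arithmetic(self):
        d = tanimoto_distance(BitFingerprint(8, {1, 2}), BitFingerprint(8, {2, 3}))
        assert d == pytest.approx(2 / 3)

    def test_both_empty_is_a_domain_error(self):
        with pytest.raises(AnalysisError):
            tanimoto_distance(BitFingerprint(8, set()), BitFingerprint(8, set()))

    def test_triangle_inequality_on_random_fingerprints(self):
        rng = np.random.default_rng(7)
        fps = [
            BitFingerprint(20, frozenset(np.nonzero(rng.random(20) < 0.4)[0].tolist()))
            for _ in range(20)
        ]
        fps = [fp for fp in fps if fp.on_bits]
        for a, b, c in itertools.combinations(fps, 3):
            assert tanimoto_distance(a, c) <= (
                tanimoto_distance(a, b) + tanimoto_distance(b, c) + 1e-12
            )


class TestPairwise:
    def test_identical_items_give_zero_matrix(self):
        dm = pairwise_distances([[1, 0, 1], [1, 0, 1]], "cosine", labels=["a", "b"])
        assert np.all(dm.values == 0)

    def test_orthogonal_triplet(self):
        dm = pairwise_distances(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1]], "cosine", labels=list("abc")
        )
        off = dm.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_drug_target_duality_under_transpose(self):
        rng = np.random.default_rng(4)
        dense = (rng.random((6, 8)) < 0.5).astype(float)
        dense[dense.sum(axis=1) == 0, 0] = 1
        assert all(dense.sum(axis=0) > 0)
        entries = {(i, j) for i, j in zip(*np.nonzero(dense))}
        matrix = InteractionMatrix(
            [f"d{i}" for i in range(6)], [f"t{j}" for j in range(8)], entries
        )
        transposed = InteractionMatrix(
            matrix.target_ids, matrix.drug_ids, {(j, i) for i, j in entries}
        )
        _, dvecs = target_vectors(matrix)
        _, lvecs_t = ligand_vectors(transposed)
        dm_rows = pairwise_distances(list(dvecs), "cosine")
        dm_cols = pairwise_distances(list(lvecs_t), "cosine")
        assert np.allclose(dm_rows.values, dm_cols.values)

    def test_element_error_names_both_labels(self):
        with pytest.raises(AnalysisError, match="aa.*bb"):
            pairwise_distances([[1, 0], [0, 0]], "cosine", labels=["aa", "bb"])


class TestHierarchicalClustering:
    def test_closest_pair_merges_first(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]]),
        )
        tree = hierarchical_cluster(dm)
        assert tree.merge_heights[0] == pytest.approx(0.1)
        assert sorted(tree.cut(2), key=len)[0] in ({"C"},)
        assert {"A", "B"} in tree.cut(2)

    def test_planted_blocks_recovered_at_k2(self):
        rng = np.random.default_rng(0)
        block = lambda: rng.random() * 0.05  # noqa: E731
        labels = [f"x{i}" for i in range(6)]
        values = np.zeros((6, 6))
        for i in range(6):
            for j in range(i + 1, 6):
                same = (i < 3) == (j < 3)
                values[i, j] = values[j, i] = block() if same else 0.8 + block()
        tree = hierarchical_cluster(DistanceMatrix(labels, values))
        assert set(tree.cut(2)) == {
            frozenset({"x0", "x1", "x2"}),
            frozenset({"x3", "x4", "x5"}),
        }

    def test_equal_distances_merge_in_lexicographic_order(self):
        labels = ["b", "a", "d", "c"]
        values = np.ones((4, 4)) * 0.5
        np.fill_diagonal(values, 0.0)
        tree = hierarchical_cluster(DistanceMatrix(labels, values))
        # first merge must be the lexicographically smallest pair {a, b}
        first = tree.merge_heights[0]
        assert first == 0.5
        two_leaf = [c for c in tree.cut(3) if len(c) == 2]
        assert frozenset({"a", "b"}) in two_leaf

    def test_heights_non_decreasing_for_average_and_complete(self):
        rng = np.random.default_rng(5)
        x = rng.random((10, 4))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        for linkage in ("average", "complete"):
            tree = hierarchical_cluster(
                DistanceMatrix([str(i) for i in range(10)], d), linkage
            )
            heights = tree.merge_heights
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_matches_scipy_on_tie_free_input(self):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(11)
        x = rng.random((9, 3))
        condensed = pdist(x)
        square = squareform(condensed)
        for linkage in ("average", "complete", "single"):
            tree = hierarchical_cluster(
                DistanceMatrix([f"p{i}" for i in range(9)], square), linkage
            )
            z = hierarchy.linkage(condensed, method=linkage)
            assert np.allclose(sorted(tree.merge_heights), sorted(z[:, 2]))

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]]),
        )
        newick = hierarchical_cluster(dm).to_newick()
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == ["A", "B", "C"]


class TestPartitionAgreement:
    def test_identical_partitions_score_one(self):
        p = {"a": 0, "b": 0, "c": 1}
        assert partition_agreement(p, p) == pytest.approx(1.0)

    def test_singletons_vs_one_cluster_is_chance_level(self):
        labels = [f"x{i}" for i in range(6)]
        singletons = {x: i for i, x in enumerate(labels)}
        lump = {x: 0 for x in labels}
        assert partition_agreement(singletons, lump) == pytest.approx(0.0)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(2)
        labels = [f"x{i}" for i in range(12)]
        a = {x: int(rng.integers(3)) for x in labels}
        b = {x: int(rng.integers(3)) for x in labels}

        # brute-force ARI from pair concordance counts
        n11 = n00 = n10 = n01 = 0
        for x, y in itertools.combinations(labels, 2):
            sa, sb = a[x] == a[y], b[x] == b[y]
            n11 += sa and sb
            n00 += (not sa) and (not sb)
            n10 += sa and not sb
            n01 += (not sa) and sb
        total = n11 + n00 + n10 + n01
        index = n11
        expected = (n11 + n10) * (n11 + n01) / total
        max_index = ((n11 + n10) + (n11 + n01)) / 2
        ari = (index - expected) / (max_index - expected)
        assert partition_agreement(a, b) == pytest.approx(ari, abs=1e-12)

    def test_label_mismatch_is_a_validation_error(self):
        with pytest.raises(ValidationError):
            partition_agreement({"a": 0}, {"b": 0})
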