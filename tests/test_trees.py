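"""UPGMA and split-distance against hand-worked and enumeration oracles."""

import numpy as np
import pytest

import dendropy

from markerrank.errors import (
    IncompatibleTreesError,
    InsufficientDataError,
    InvalidMatrixError,
)
from markerrank.io import newick_string, read_newick, write_newick
from markerrank.simulate import sample_tree
from markerrank.trees import (
    DistanceMatrix,
    identity_to_distance,
    is_ultrametric,
    root_to_leaf_depths,
    split_distance,
    tree_bipartitions,
    upgma,
)

from .oracles import (
    brute_force_split_distance,
    enumerate_unrooted_5taxon_topologies,
    tuple_to_newick,
)


def _tree_from_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


class TestDistanceMatrix:
    def test_identity_conversion(self):
        dm = identity_to_distance({("a", "b"): 100.0, ("a", "c"): 60.0, ("b", "c"): 80.0})
        assert dm.d[dm.labels.index("a"), dm.labels.index("b")] == 0.0
        assert dm.d[dm.labels.index("a"), dm.labels.index("c")] == pytest.approx(0.40)

    def test_missing_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            identity_to_distance({("a", "b"): 99.0}, labels=["a", "b", "c"])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(InvalidMatrixError):
            DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_pair_orientation_irrelevant(self):
        d1 = identity_to_distance({("a", "b"): 90.0})
        d2 = identity_to_distance({("b", "a"): 90.0})
        assert np.allclose(d1.d, d2.d)


class TestUpgma:
    def test_two_taxa_heights(self):
        tree = upgma(DistanceMatrix(["A", "B"], np.array([[0.0, 0.3], [0.3, 0.0]])))
        depths = root_to_leaf_depths(tree)
        assert depths["A"] == pytest.approx(0.15)
        assert depths["B"] == pytest.approx(0.15)

    def test_hand_worked_four_taxon_fixture(self):
        # d(A,B)=2; d(A,C)=d(B,C)=4; d(*,D)=6 -> (((A,B),C),D), heights 1,2,3
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 2.0, 4.0, 6.0],
                [2.0, 0.0, 4.0, 6.0],
                [4.0, 4.0, 0.0, 6.0],
                [6.0, 6.0, 6.0, 0.0],
            ]
        )
        tree = upgma(DistanceMatrix(labels, d))
        expected = _tree_from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        raw, norm = split_distance(tree, expected)
        assert raw == 0
        # merge heights exactly 1, 2, 3: check root-to-leaf depth and
        # internal node depths via the newick string
        depths = root_to_leaf_depths(tree)
        assert all(v == pytest.approx(3.0) for v in depths.values())
        heights = sorted(
            3.0 - _node_depth(tree, n)
            for n in tree.preorder_node_iter()
            if not n.is_leaf()
        )
        assert heights == pytest.approx([1.0, 2.0, 3.0])

    def test_all_equal_distances_collapse_to_star(self):
        n = 5
        labels = [f"g{i}" for i in range(n)]
        d = np.full((n, n), 0.4)
        np.fill_diagonal(d, 0.0)
        tree = upgma(DistanceMatrix(labels, d))
        assert len(tree_bipartitions(tree)) == 0  # star: no non-trivial splits

    def test_output_ultrametric(self, rng):
        n = 9
        # random distances made symmetric
        x = rng.random((n, 2))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        tree = upgma(DistanceMatrix([f"t{i}" for i in range(n)], d))
        assert is_ultrametric(tree)

    def test_recovers_simulated_ultrametric_tree(self):
        for seed in (1, 2, 3):
            true = sample_tree(8, 0.5, seed)
            pdm = true.phylogenetic_distance_matrix()
            taxa = sorted(true.taxon_namespace, key=lambda t: t.label)
            labels = [t.label for t in taxa]
            n = len(labels)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
            rec = upgma(DistanceMatrix(labels, d))
            raw, _ = split_distance(rec, true)
            assert raw == 0

    def test_matches_scipy_average_linkage_heights(self, rng):
        # independent cross-check: cophenetic heights from scipy UPGMA
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        n = 7
        x = rng.random((n, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(n)]
        tree = upgma(DistanceMatrix(labels, d))
        coph = squareform(cophenet(average(squareform(d))))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in range(n):
            for j in range(i + 1, n):
                got = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                assert got == pytest.approx(coph[i, j]), (i, j)


def _node_depth(tree, node):
    d = 0.0
    while node.parent_node is not None:
        d += node.edge.length or 0.0
        node = node.parent_node
    return d


class TestSplitDistance:
    def test_identical_trees(self):
        t = _tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert split_distance(t, t) == (0, 0.0)

    def test_four_taxon_alternative_topologies(self):
        t1 = _tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = _tree_from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        raw, norm = split_distance(t1, t2)
        assert raw == 2
        assert norm == 1.0

    def test_all_five_taxon_topology_pairs_match_oracle(self):
        tuples = enumerate_unrooted_5taxon_topologies()
        assert len(tuples) == 15
        labels = {"A", "B", "C", "D", "E"}
        trees = [_tree_from_newick(tuple_to_newick(t)) for t in tuples]
        for i in range(15):
            for j in range(15):
                raw, _ = split_distance(trees[i], trees[j])
                assert raw == brute_force_split_distance(tuples[i], tuples[j], labels)

    def test_leaf_set_mismatch_rejected(self):
        t1 = _tree_from_newick("((A:1,B:1):1,C:1);")
        t2 = _tree_from_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(IncompatibleTreesError):
            split_distance(t1, t2)

    def test_symmetric_and_zero_iff_equal_splits(self):
        for s1 in (1, 2):
            for s2 in (3, 4):
                t1 = sample_tree(12, 0.3, s1)
                t2 = sample_tree(12, 0.3, s2)
                r12, _ = split_distance(t1, t2)
                r21, _ = split_distance(t2, t1)
                assert r12 == r21
                if r12 == 0:
                    assert tree_bipartitions(t1) == tree_bipartitions(t2)

    def test_cross_check_against_dendropy(self):
        # dendropy's RF on shared taxon namespace as an independent route
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(
            data=newick_string(sample_tree(10, 0.4, 5)) + "\n",
            schema="newick", taxon_namespace=tns,
        )
        t2 = dendropy.Tree.get(
            data=newick_string(sample_tree(10, 0.4, 6)) + "\n",
            schema="newick", taxon_namespace=tns,
        )
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        got, _ = split_distance(t1, t2)
        assert got == expected

    def test_rf_self_zero_on_random_20_leaf_trees(self):
        for seed in range(10):
            t = sample_tree(20, 0.5, seed)
            assert split_distance(t, t) == (0, 0.0)


class TestNewickRoundTrip:
    def test_round_trip_preserves_splits_and_depths(self, tmp_path):
        t = sample_tree(50, 0.7, 9)
        path = tmp_path / "t.nwk"
        write_newick(t, path)
        back = read_newick(path)
        raw, _ = split_distance(t, back)
        assert raw == 0
        d1 = root_to_leaf_depths(t)
        d2 = root_to_leaf_depths(back)
        assert all(abs(d1[k] - d2[k]) < 1e-9 for k in d1)
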