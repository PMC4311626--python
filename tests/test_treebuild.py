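"""Neighbor joining, bootstrap consensus, patristic matrices, newick I/O."""

import numpy as np
import pytest

from mirrortree import (
    DistanceMatrix,
    InputError,
    bootstrap_trees,
    consensus_collapse,
    from_newick,
    nj_tree,
    patristic_matrix,
    read_newick,
    to_newick,
    write_newick,
)
from mirrortree.treebuild import BootstrapSet
from tests.conftest import (
    family_from_strings,
    graph_splits,
    graph_to_newick,
    path_walk_distances,
    random_additive_tree,
    tree_splits,
)


class TestNeighborJoining:
    def test_four_taxon_worked_example(self):
        # distances of the tree ((A:1,B:2):1,C:3,D:4)
        D = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [
                    [0, 3, 5, 6],
                    [3, 0, 6, 7],
                    [5, 6, 0, 7],
                    [6, 7, 7, 0],
                ],
                dtype=float,
            ),
        )
        tree = nj_tree(D)
        assert tree_splits(tree) == {frozenset({"C", "D"})}
        np.testing.assert_allclose(patristic_matrix(tree).values, D.values,
                                   atol=1e-9)

    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
        )
        tree = nj_tree(D)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_too_few_taxa(self):
        D = DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(InputError, match="at least 3"):
            nj_tree(D)

    def test_additive_eight_leaf_round_trip(self, rng):
        labels, adj = random_additive_tree(rng, 8)
        D = DistanceMatrix(labels, path_walk_distances(labels, adj))
        tree = nj_tree(D)
        np.testing.assert_allclose(patristic_matrix(tree).values, D.values,
                                   atol=1e-9)
        assert tree_splits(tree) == graph_splits(labels, adj)

    def test_matches_skbio_on_additive_matrices(self, rng):
        """Independent library cross-check of the agglomeration."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        for _ in range(10):
            labels, adj = random_additive_tree(rng, 7)
            vals = path_walk_distances(labels, adj)
            vals = (vals + vals.T) / 2  # exact symmetry for skbio
            ours = tree_splits(nj_tree(DistanceMatrix(labels, vals)))
            sk_tree = skbio_nj(skbio.DistanceMatrix(vals, ids=labels))
            ref = sorted(labels)[0]
            theirs = set()
            n = len(labels)
            for node in sk_tree.non_tips(include_self=True):
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = frozenset(labels) - side
                if 2 <= len(side) <= n - 2:
                    theirs.add(side)
            assert ours == theirs


class TestPatristic:
    def test_two_leaf_tree(self):
        tree = from_newick("(A:0.1,B:0.2);")
        P = patristic_matrix(tree)
        assert P.values[0, 1] == pytest.approx(0.3, abs=1e-12)
        assert P.values[0, 0] == 0.0

    def test_matches_path_walk_oracle(self, rng):
        labels, adj = random_additive_tree(rng, 5)
        tree = from_newick(graph_to_newick(labels, adj))
        np.testing.assert_allclose(
            patristic_matrix(tree).values,
            path_walk_distances(labels, adj),
            atol=1e-12,
        )

    def test_triangle_inequality(self, rng):
        labels, adj = random_additive_tree(rng, 7)
        P = patristic_matrix(from_newick(graph_to_newick(labels, adj)))
        v = P.values
        n = len(labels)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-12

    def test_missing_branch_length_errors(self):
        tree = from_newick("(A:0.1,B);")
        with pytest.raises(InputError, match="missing branch length.*B"):
            patristic_matrix(tree)


class TestNewick:
    def test_two_leaf_round_trip_is_identity(self):
        s = "(A:0.1,B:0.2);\n"
        assert to_newick(from_newick(s)) == s

    def test_nested_with_supports_round_trip(self):
        s = "((A:0.1,B:0.2)75:0.05,(C:0.3,D:0.4)90:0.06);\n"
        assert to_newick(from_newick(s)) == s

    def test_malformed_raises(self):
        with pytest.raises(InputError, match="parse error"):
            from_newick("((A,B;")

    def test_file_round_trip(self, tmp_path):
        tree = from_newick("((A:1,B:2)50:0.5,C:3,D:4);")
        write_newick(tree, tmp_path / "t.nwk")
        back = read_newick(tmp_path / "t.nwk")
        assert to_newick(back) == to_newick(tree)


def _alignment_family(rng, n=6, length=120):
    from mirrortree.simulate import reference_config, make_family_pair

    fam, _ = make_family_pair(
        reference_config(seed=int(rng.integers(2**31)), n_organisms=n,
                         seq_length=length)
    )
    return fam


class TestBootstrap:
    def test_replicate_count_and_determinism(self, rng):
        fam = _alignment_family(rng)
        bs1 = bootstrap_trees(fam, B=10, seed=3)
        bs2 = bootstrap_trees(fam, B=10, seed=3)
        assert bs1.B == len(bs1.replicates) == 10
        assert [to_newick(t) for t in bs1.replicates] == [
            to_newick(t) for t in bs2.replicates
        ]

    def test_different_seeds_differ(self, rng):
        fam = _alignment_family(rng)
        bs1 = bootstrap_trees(fam, B=5, seed=3)
        bs2 = bootstrap_trees(fam, B=5, seed=4)
        assert [to_newick(t) for t in bs1.replicates] != [
            to_newick(t) for t in bs2.replicates
        ]

    def test_invariant_alignment_gives_identical_topologies(self):
        # every column identical => resampling cannot change the distances
        fam = family_from_strings(
            {"A": "AC" * 10, "B": "AD" * 10, "C": "CE" * 10, "D": "CF" * 10}
        )
        bs = bootstrap_trees(fam, B=8, seed=0, correction="none")
        topo = {frozenset(s) for s in tree_splits(bs.replicates[0])}
        for t in bs.replicates[1:]:
            assert {frozenset(s) for s in tree_splits(t)} == topo


class TestConsensus:
    def _identical_set(self, newick, B=10):
        return BootstrapSet(replicates=[from_newick(newick) for _ in range(B)],
                            B=B, seed=0)

    def test_identical_replicates_full_support(self):
        bs = self._identical_set("((A:1,B:1)x:1,(C:1,D:1)y:1,E:1);")
        cons = consensus_collapse(bs, threshold_pct=45)
        # splits are normalized to the side excluding leaf A
        assert tree_splits(cons) == {
            frozenset({"C", "D", "E"}),
            frozenset({"C", "D"}),
        }
        labels = [
            nd.label
            for nd in cons.preorder_node_iter()
            if nd.label and not nd.is_leaf()
        ]
        assert all(lab == "100" for lab in labels)

    def test_even_conflict_collapses_above_fifty(self):
        trees = [from_newick("((A,B),(C,D));") for _ in range(5)] + [
            from_newick("((A,C),(B,D));") for _ in range(5)
        ]
        bs = BootstrapSet(replicates=trees, B=10, seed=0)
        assert tree_splits(consensus_collapse(bs, threshold_pct=51)) == set()
        # at 45% the better-ranked of the two conflicting splits survives
        assert len(tree_splits(consensus_collapse(bs, threshold_pct=45))) == 1

    def test_threshold_zero_collapses_nothing(self):
        bs = self._identical_set("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        assert tree_splits(consensus_collapse(bs, 0)) == tree_splits(
            consensus_collapse(bs, 45)
        )

    def test_higher_threshold_is_contraction(self, rng):
        fam = _alignment_family(rng, n=8, length=60)
        bs = bootstrap_trees(fam, B=30, seed=1, correction="none")
        prev = None
        for t in (0, 30, 45, 60, 80, 100):
            splits = tree_splits(consensus_collapse(bs, t))
            if prev is not None:
                assert splits <= prev
            prev = splits

    def test_supports_respect_threshold(self, rng):
        fam = _alignment_family(rng, n=8, length=60)
        bs = bootstrap_trees(fam, B=20, seed=2, correction="none")
        cons = consensus_collapse(bs, threshold_pct=45)
        for nd in cons.preorder_node_iter():
            if nd.label and not nd.is_leaf():
                assert float(nd.label) >= 45
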