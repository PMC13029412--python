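"""UPGMA against hand-execution and scipy; Newick round trips; concordance."""
import numpy as np
import pytest

import fam111kit as fk
from fam111kit.phylogeny import DistanceMatrix, from_newick, to_newick, upgma

from _oracles import cophenetic


def random_distance_matrix(rng, n):
    x = rng.uniform(0.1, 2.0, size=(n, n))
    d = (x + x.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=[f"t{i:02d}" for i in range(n)], d=d)


class TestUpgma:
    def test_two_taxon_cherry(self):
        D = DistanceMatrix(ids=["A", "B"], d=np.array([[0, 0.4], [0.4, 0]]))
        tree = upgma(D)
        assert tree.height == pytest.approx(0.2)
        assert to_newick(tree) == "(A:0.2,B:0.2);"

    def test_hand_executed_four_taxa(self):
        d = np.array(
            [
                [0, 2, 4, 6],
                [2, 0, 4, 6],
                [4, 4, 0, 6],
                [6, 6, 6, 0],
            ],
            dtype=float,
        )
        tree = upgma(DistanceMatrix(ids=list("ABCD"), d=d))
        heights = sorted(n.height for n in tree.walk() if not n.is_leaf)
        assert heights == pytest.approx([1.0, 2.0, 3.0])
        assert to_newick(tree) == "(((A:1,B:1):1,C:2):1,D:3);"

    def test_input_order_invariance(self):
        rng = np.random.default_rng(31)
        D = random_distance_matrix(rng, 7)
        base = to_newick(upgma(D))
        for _ in range(5):
            perm = rng.permutation(7)
            D2 = DistanceMatrix(
                ids=[D.ids[i] for i in perm], d=D.d[np.ix_(perm, perm)]
            )
            assert to_newick(upgma(D2)) == base

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], d=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], d=np.array([[0, -1], [-1, 0]]))
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(ids=["a"], d=np.zeros((1, 1))))

    def test_ultrametric_output(self):
        """Leaves at height 0, heights monotone, three-point condition."""
        rng = np.random.default_rng(37)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            tree = upgma(random_distance_matrix(rng, n))
            for node in tree.walk():
                if node.is_leaf:
                    assert node.height == 0.0
                else:
                    assert len(node.children) == 2
                    assert all(node.height >= c.height - 1e-12 for c in node.children)
            coph = cophenetic(tree)
            labels = tree.leaf_labels()
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    for k in range(j + 1, len(labels)):
                        ds = sorted(
                            [
                                coph[frozenset((labels[i], labels[j]))],
                                coph[frozenset((labels[i], labels[k]))],
                                coph[frozenset((labels[j], labels[k]))],
                            ]
                        )
                        assert ds[2] - ds[1] <= 1e-9

    def test_matches_scipy_average_linkage(self):
        """Cophenetic distances equal scipy's average-linkage clustering."""
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(41)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            D = random_distance_matrix(rng, n)
            tree = upgma(D)
            coph = cophenetic(tree)
            Z = linkage(squareform(D.d), method="average")
            sp = squareform(cophenet(Z))
            for i in range(n):
                for j in range(i + 1, n):
                    assert coph[frozenset((D.ids[i], D.ids[j]))] == pytest.approx(
                        sp[i, j]
                    )

    def test_recovers_generating_tree_from_ultrametric_input(self, family17):
        """UPGMA on true cophenetic distances reproduces the generating tree."""
        _, _, _, truth = family17
        coph = cophenetic(truth.tree)
        labels = truth.tree.leaf_labels()
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = coph[frozenset((labels[i], labels[j]))]
        rebuilt = upgma(DistanceMatrix(ids=labels, d=d))
        assert to_newick(rebuilt) == to_newick(truth.tree)


class TestNewick:
    def test_branch_length_formatting(self):
        D = DistanceMatrix(ids=["A", "B"], d=np.array([[0, 0.4], [0.4, 0]]))
        assert to_newick(upgma(D)) == "(A:0.2,B:0.2);"

    def test_round_trip_random_trees(self):
        """parse(to_newick(t)) is isomorphic to t: same leaves, same
        cophenetic distances (up to serialization precision)."""
        rng = np.random.default_rng(43)
        for _ in range(100):
            n = int(rng.integers(3, 10))
            tree = upgma(random_distance_matrix(rng, n))
            again = from_newick(to_newick(tree, precision=9))
            assert sorted(again.leaf_labels()) == sorted(tree.leaf_labels())
            c1, c2 = cophenetic(tree), cophenetic(again)
            assert all(abs(c1[k] - c2[k]) < 1e-6 for k in c1)

    def test_round_trip_through_dendropy(self):
        """An independent Newick reader sees the same ultrametric tree."""
        import dendropy

        rng = np.random.default_rng(47)
        tree = upgma(random_distance_matrix(rng, 8))
        text = to_newick(tree, precision=9)
        dt = dendropy.Tree.get(data=text, schema="newick")
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in dt.leaf_node_iter()
        }
        assert sorted(depths) == sorted(tree.leaf_labels())
        assert max(depths.values()) - min(depths.values()) < 1e-9
        assert max(depths.values()) == pytest.approx(tree.height)


class TestCladeConcordance:
    def leaf(self, label):
        return fk.TreeNode(label=label)

    def node(self, a, b, h):
        return fk.TreeNode(children=(a, b), height=h)

    def test_separated_classes_monophyletic(self):
        tree = self.node(
            self.node(self.leaf("A1"), self.leaf("A2"), 1),
            self.node(self.leaf("B1"), self.leaf("B2"), 1),
            2,
        )
        classes = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        report = fk.clade_concordance(tree, classes)
        assert report["is_monophyletic"].all()

    def test_interleaved_classes_not_monophyletic(self):
        tree = self.node(
            self.node(self.leaf("A1"), self.leaf("B1"), 1),
            self.node(self.leaf("A2"), self.leaf("B2"), 1),
            2,
        )
        classes = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        report = fk.clade_concordance(tree, classes)
        assert not report["is_monophyletic"].any()
        assert (report["smallest_clade_size"] == 4).all()

    def test_synthetic_family_concordant(self, family17, pipeline17):
        _, _, taxonomy, _ = family17
        tree = upgma(pipeline17["D"])
        report = fk.clade_concordance(tree, taxonomy)
        assert report["is_monophyletic"].all()

    def test_scrambled_labels_break_monophyly(self):
        spec = fk.FamilySpec(seed=17, scramble_classes=True)
        records, taxonomy, truth = fk.evolve_family(spec)
        report = fk.clade_concordance(truth.tree, taxonomy)
        assert not report["is_monophyletic"].all()
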