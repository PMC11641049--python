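"""p-distance, neighbor joining, bootstrap and Newick serialization."""

import numpy as np
import pytest

from cccflux.phylo import (
    DistanceMatrix,
    PhyloError,
    Tree,
    TreeNode,
    bootstrap_support,
    nj_tree,
    p_distance,
    read_newick,
    write_newick,
)
from cccflux.signatures import AlignedFamily
from cccflux.synthetic import SequenceGeneratorConfig, generate_sequence_family


def family_of(rows: dict) -> AlignedFamily:
    ids = list(rows)
    return AlignedFamily(ids=ids, rows=[rows[i] for i in ids], reference_id=ids[0])


class TestPDistance:
    def test_identical_sequences(self):
        d = p_distance(family_of({"a": "MKTL", "b": "MKTL"}))
        assert d.values[0, 1] == 0.0

    def test_fully_different(self):
        d = p_distance(family_of({"a": "AAAA", "b": "CCCC"}))
        assert d.values[0, 1] == 1.0

    def test_half_different_toy_pair(self):
        d = p_distance(family_of({"a": "AAAA", "b": "AABB"}))
        assert d.values[0, 1] == 0.5

    def test_pairwise_deletion_ignores_gap_columns(self):
        d = p_distance(family_of({"a": "A-CD", "b": "ABCD"}))
        assert d.values[0, 1] == 0.0

    def test_complete_deletion_drops_any_gapped_column(self):
        fam = family_of({"a": "AXCD", "b": "AYCD", "c": "A-CD"})
        dp = p_distance(fam, "pairwise")
        dc = p_distance(fam, "complete")
        assert dp.values[0, 1] == pytest.approx(0.25)
        assert dc.values[0, 1] == 0.0  # the polymorphic column is gapped in c

    def test_no_comparable_columns_names_pair(self):
        with pytest.raises(PhyloError, match="a.*b"):
            p_distance(family_of({"a": "A--", "b": "--C", "c": "ABC"}))

    def test_column_permutation_invariance(self, rng):
        rows = {"a": "MKTLVNQW", "b": "MKTAVNQW", "c": "MATLVNEW"}
        perm = rng.permutation(8)
        permuted = {k: "".join(v[i] for i in perm) for k, v in rows.items()}
        d1 = p_distance(family_of(rows))
        d2 = p_distance(family_of(permuted))
        assert np.allclose(d1.values, d2.values)


def additive_matrix_4taxon():
    # unrooted tree: A,B joined (2,3), C,D joined (4,5), internal edge 1
    labels = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ],
        dtype=float,
    )
    return DistanceMatrix(labels, d)


def hand_built_5taxon_tree() -> Tree:
    d = TreeNode(name="D", length=0.4)
    e = TreeNode(name="E", length=0.5)
    de = TreeNode(length=0.2, children=[d, e])
    c = TreeNode(name="C", length=0.3)
    cde = TreeNode(length=0.1, children=[c, de])
    a = TreeNode(name="A", length=0.1)
    b = TreeNode(name="B", length=0.2)
    return Tree(TreeNode(children=[a, b, cde]))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = nj_tree(d)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_additive_four_taxon_exact_recovery(self):
        tree = nj_tree(additive_matrix_4taxon())
        splits = {frozenset(k) for k in tree.splits()}
        assert frozenset("AB") in splits or frozenset("CD") in splits
        recovered = tree.path_length_matrix()
        want = additive_matrix_4taxon()
        assert np.allclose(recovered.values, want.values, atol=1e-12)

    def test_additive_five_taxon_path_lengths_match(self):
        truth = hand_built_5taxon_tree()
        d = truth.path_length_matrix()
        tree = nj_tree(d)
        assert np.allclose(tree.path_length_matrix().values, d.values, atol=1e-12)
        assert set(map(frozenset, tree.splits())) == set(map(frozenset, truth.splits()))

    def test_matches_reference_implementation_topology(self, rng):
        # independent oracle: scikit-bio's neighbor joining on a noisy matrix
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sk_nj

        base = hand_built_5taxon_tree().path_length_matrix()
        noisy = base.values + rng.uniform(0, 0.02, base.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        ours = nj_tree(DistanceMatrix(base.labels, noisy))
        sk_tree = sk_nj(skbio.DistanceMatrix(noisy, base.labels))
        names = set(base.labels)
        sk_splits = set()
        for node in sk_tree.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < len(names) - 1:
                side = below if min(names) in below else frozenset(names - below)
                sk_splits.add(side)
        our_splits = set(ours.splits())
        assert our_splits == sk_splits

    def test_requires_three_labels(self):
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(PhyloError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))


class TestBootstrap:
    def test_planted_classes_get_high_support(self):
        family, truth = generate_sequence_family(
            SequenceGeneratorConfig(n_kcc=5, n_nkcc=5, mutation_rate=0.05), seed=11
        )
        tree = bootstrap_support(family, n_reps=100, seed=3)
        nkcc_side = frozenset(s for s, c in truth["classes"].items() if c == "NKCC_like")
        kcc_side = frozenset(truth["classes"]) - nkcc_side
        splits = tree.splits()
        all_leaves = frozenset(truth["classes"])
        anchor = min(all_leaves)
        key = kcc_side if anchor in kcc_side else nkcc_side
        assert key in splits
        assert splits[key].support > 90

    def test_single_replicate_supports_are_binary(self):
        family, _ = generate_sequence_family(
            SequenceGeneratorConfig(n_kcc=3, n_nkcc=3, mutation_rate=0.05), seed=5
        )
        tree = bootstrap_support(family, n_reps=1, seed=1)
        supports = {n.support for n in tree.splits().values()}
        assert supports <= {0.0, 100.0}

    def test_identical_sequences_give_zero_length_star(self):
        fam = family_of({k: "MKTLVNQW" for k in "abcd"})
        tree = nj_tree(p_distance(fam))
        lengths = [leaf.length for leaf in tree.root.leaves()]
        assert max(lengths) == 0.0

    def test_same_seed_reproducible(self):
        family, _ = generate_sequence_family(
            SequenceGeneratorConfig(n_kcc=3, n_nkcc=3), seed=5
        )
        t1 = bootstrap_support(family, n_reps=20, seed=9)
        t2 = bootstrap_support(family, n_reps=20, seed=9)
        assert write_newick(t1) == write_newick(t2)


def random_tree(rng, n_leaves: int) -> Tree:
    nodes = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.01, 1))) for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(length=float(rng.uniform(0.01, 1)),
                          children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return Tree(TreeNode(children=nodes))


def trees_equal(a: TreeNode, b: TreeNode) -> bool:
    if a.name != b.name or abs(a.length - b.length) > 1e-9:
        return False
    if (a.support is None) != (b.support is None):
        return False
    if a.support is not None and abs(a.support - b.support) > 1e-9:
        return False
    if len(a.children) != len(b.children):
        return False
    return all(trees_equal(x, y) for x, y in zip(a.children, b.children))


class TestNewick:
    def test_three_taxon_form(self):
        d = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        text = write_newick(nj_tree(d))
        assert text == "(A:1,B:2,C:3);"

    def test_round_trip_random_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            tree = random_tree(rng, int(rng.integers(3, 12)))
            again = read_newick(write_newick(tree))
            assert trees_equal(tree.root, again.root)

    def test_reserved_characters_quoted(self):
        tree = Tree(
            TreeNode(children=[
                TreeNode(name="A (weird)", length=1.0),
                TreeNode(name="B's", length=2.0),
                TreeNode(name="C", length=3.0),
            ])
        )
        text = write_newick(tree)
        assert "'A (weird)'" in text and "'B''s'" in text
        again = read_newick(text)
        assert trees_equal(tree.root, again.root)

    def test_supports_survive_round_trip(self):
        inner = TreeNode(length=0.5, support=97.0,
                         children=[TreeNode(name="A", length=1), TreeNode(name="B", length=2)])
        tree = Tree(TreeNode(children=[inner, TreeNode(name="C", length=3),
                                       TreeNode(name="D", length=4)]))
        again = read_newick(write_newick(tree))
        assert trees_equal(tree.root, again.root)

    def test_phylip_output_shape(self):
        d = additive_matrix_4taxon()
        text = d.to_phylip()
        assert text.splitlines()[0].strip() == "4"
        assert len(text.splitlines()) == 5
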