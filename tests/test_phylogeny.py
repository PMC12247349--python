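"""NJ correctness, clade-context rules, subgroup and subfamily refinement."""

import numpy as np
import pytest
import skbio

from ap2erf.align import DistanceMatrix
from ap2erf.family import FamilyCall
from ap2erf.io_formats import SequenceRecord, newick_string
from ap2erf.phylogeny import (
    Tree,
    TreeNode,
    assign_subgroups,
    best_reference_hits,
    clade_context,
    midpoint_root,
    nj_tree,
    resolve_single_domain_overrides,
)


def random_additive_tree(rng, n_leaves):
    """Random binary tree with uniform branch lengths; returns (tree, labels)."""
    nodes = [TreeNode(label=f"L{i}", length=rng.uniform(0.1, 1.0))
             for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=rng.uniform(0.1, 1.0))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for n in nodes:
        root.add(n)
    return Tree(root)


def path_distances(tree):
    """Leaf-to-leaf path-length matrix of a tree."""
    leaves = tree.root.leaves()
    labels = [l.label for l in leaves]

    def depth_map(leaf):
        d, node = {}, leaf
        acc = 0.0
        while node is not None:
            d[id(node)] = acc
            acc += node.length
            node = node.parent
        return d

    maps = [depth_map(l) for l in leaves]
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # distance through the lowest common ancestor
            node = leaves[j]
            acc = 0.0
            while id(node) not in maps[i]:
                acc += node.length
                node = node.parent
            d[i, j] = d[j, i] = acc + maps[i][id(node)]
    return labels, d


def splits(tree):
    """Nontrivial leaf bipartitions (as frozensets of one side)."""
    all_leaves = frozenset(tree.leaf_labels)
    out = set()
    stack = list(tree.root.children)
    while stack:
        node = stack.pop()
        stack.extend(node.children)
        if node.is_leaf:
            continue
        side = frozenset(l.label for l in node.leaves())
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(min(side, all_leaves - side, key=sorted))
    return out


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(dm)
        lengths = {l.label: l.length for l in tree.root.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}
        assert newick_string(tree) == "(A:1,B:1,C:3);"

    def test_additive_four_taxon_topology(self):
        # ((A,B),(C,D)) with internal edge 1: additive matrix by hand
        d = np.array(
            [
                [0, 2, 5, 6],
                [2, 0, 5, 6],
                [5, 5, 0, 3],
                [6, 6, 3, 0],
            ],
            float,
        )
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        assert frozenset({"A", "B"}) in splits(tree) or frozenset({"C", "D"}) in splits(tree)

    @pytest.mark.parametrize("trial", range(10))
    def test_recovers_random_additive_trees(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(6, 11))
        true = random_additive_tree(rng, n)
        labels, d = path_distances(true)
        est = nj_tree(DistanceMatrix(labels, d))
        assert splits(est) == splits(true)

    def test_agrees_with_skbio_on_additive_matrix(self):
        rng = np.random.default_rng(77)
        true = random_additive_tree(rng, 8)
        labels, d = path_distances(true)
        ours = nj_tree(DistanceMatrix(labels, d))
        sk = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        sk_splits = set()
        all_l = frozenset(labels)
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(all_l) - 2:
                sk_splits.add(min(side, all_l - side, key=sorted))
        assert splits(ours) == sk_splits

    def test_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("ABCD"), d)
        s1 = newick_string(nj_tree(dm))
        s2 = newick_string(nj_tree(dm))
        assert s1 == s2

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))


def build_tree(spec):
    """Tiny literal tree builder: spec is nested tuples of labels."""

    def rec(node_spec, parent):
        if isinstance(node_spec, str):
            parent.add(TreeNode(node_spec), 1.0)
        else:
            inner = parent.add(TreeNode(), 1.0)
            for child in node_spec:
                rec(child, inner)

    root = TreeNode()
    for child in spec:
        rec(child, root)
    return Tree(root)


class TestCladeContext:
    def test_unanimous_majority(self):
        tree = build_tree((("g", ("r1", "r2", "r3")), "out1", "out2"))
        refs = {"r1": "IX", "r2": "IX", "r3": "IX"}
        assert clade_context(tree, "g", refs) == "IX"

    def test_plurality(self):
        tree = build_tree((("g", ("r1", "r2", "r3")), "out1", "out2"))
        refs = {"r1": "V", "r2": "VI-L", "r3": "VI-L"}
        assert clade_context(tree, "g", refs) == "VI-L"

    def test_three_way_tie_is_none(self):
        tree = build_tree((("g", ("r1", "r2", "r3")), "out1", "out2"))
        refs = {"r1": "III", "r2": "IX", "r3": "X"}
        assert clade_context(tree, "g", refs) is None

    def test_missing_gene_raises(self):
        tree = build_tree(("a", "b", "c"))
        with pytest.raises(KeyError):
            clade_context(tree, "zz", {})

    def test_whole_tree_context_excluded_by_default(self):
        # the only ancestor holding >= 3 refs is the root: no context
        tree = build_tree(("g", ("r1", "x"), ("r2", "r3")))
        refs = {"r1": "IX", "r2": "IX", "r3": "IX"}
        assert clade_context(tree, "g", refs) is None
        assert clade_context(tree, "g", refs, include_root=True) == "IX"


class TestAssignSubgroups:
    def _setup(self):
        tree = build_tree((("g1", ("r1", "r2", "r3")), ("g2", ("r4", "r5", "r6")), "pad"))
        refs = {"r1": "VI-L", "r2": "VI-L", "r3": "VI-L",
                "r4": "III", "r5": "III", "r6": "III"}
        return tree, refs

    def test_tree_overrides_blast(self):
        tree, refs = self._setup()
        best = {"g1": ("r9", "V")}
        (a,) = assign_subgroups(["g1"], best, tree, refs)
        assert a.final_subgroup == "VI-L" and a.reclassified

    def test_agreement_not_reclassified(self):
        tree, refs = self._setup()
        best = {"g2": ("r4", "III")}
        (a,) = assign_subgroups(["g2"], best, tree, refs)
        assert a.final_subgroup == "III" and not a.reclassified

    def test_no_context_falls_back_to_blast(self):
        tree, refs = self._setup()
        best = {"pad": ("r1", "IX")}
        (a,) = assign_subgroups(["pad"], best, tree, refs)
        assert a.final_subgroup == "IX" and not a.reclassified

    def test_unassigned_reported_not_raised(self):
        tree, refs = self._setup()
        (a,) = assign_subgroups(["pad"], {}, tree, refs)
        assert a.final_subgroup is None

    def test_idempotent(self):
        tree, refs = self._setup()
        best = {"g1": ("r9", "V"), "g2": ("r4", "III")}
        first = assign_subgroups(["g1", "g2"], best, tree, refs)
        best2 = {a.gene_id: ("x", a.final_subgroup) for a in first}
        second = assign_subgroups(["g1", "g2"], best2, tree, refs)
        assert [a.final_subgroup for a in first] == [a.final_subgroup for a in second]


def call(gene, subfam, count=1, b3=False):
    return FamilyCall(
        gene_id=gene, species="s", subfamily=subfam,
        subfamily_basis="domain_architecture", ap2_domain_count=count, has_b3=b3,
    )


class TestSingleDomainOverrides:
    def test_single_domain_gene_inside_ap2_clade_overridden(self):
        tree = build_tree(
            (("q", ("a1", "a2", "a3")), ("e1", "e2", ("e3", "e4")))
        )
        calls = [call("q", "ERF")] + [call(f"a{i}", "AP2", count=2) for i in (1, 2, 3)]
        calls += [call(f"e{i}", "ERF") for i in (1, 2, 3, 4)]
        final = {c.gene_id: c for c in resolve_single_domain_overrides(calls, tree)}
        assert final["q"].subfamily == "AP2"
        assert final["q"].subfamily_basis == "tree_override"

    def test_single_domain_gene_in_erf_clade_stays_erf(self):
        tree = build_tree(
            (("q", ("e1", "e2", "e3")), ("a1", "a2", ("a3", "e4")))
        )
        calls = [call("q", "ERF")] + [call(f"a{i}", "AP2", count=2) for i in (1, 2, 3)]
        calls += [call(f"e{i}", "ERF") for i in (1, 2, 3, 4)]
        final = {c.gene_id: c for c in resolve_single_domain_overrides(calls, tree)}
        assert final["q"].subfamily == "ERF"

    def test_outgroup_gene_becomes_soloist(self):
        # q hangs between the AP2 and ERF clades, inside neither
        tree = build_tree(
            ("q", ("a1", "a2", "a3"), ("e1", "e2", "e3"))
        )
        calls = [call("q", "ERF")] + [call(f"a{i}", "AP2", count=2) for i in (1, 2, 3)]
        calls += [call(f"e{i}", "ERF") for i in (1, 2, 3)]
        final = {c.gene_id: c for c in resolve_single_domain_overrides(calls, tree)}
        assert final["q"].subfamily == "Soloist"

    def test_non_erf_calls_untouched(self):
        tree = build_tree(("a1", "r1", ("e1", "e2")))
        calls = [call("a1", "AP2", count=2), call("r1", "RAV", b3=True),
                 call("e1", "ERF"), call("e2", "ERF")]
        final = resolve_single_domain_overrides(calls, tree)
        assert {c.gene_id: c.subfamily for c in final}["a1"] == "AP2"
        assert {c.gene_id: c.subfamily for c in final}["r1"] == "RAV"


class TestMidpointRoot:
    def test_preserves_leaves_and_path_lengths(self):
        rng = np.random.default_rng(13)
        tree = random_additive_tree(rng, 7)
        labels, d = path_distances(tree)
        rerooted = midpoint_root(tree)
        labels2, d2 = path_distances(rerooted)
        order = [labels2.index(l) for l in labels]
        assert sorted(labels) == sorted(labels2)
        assert np.allclose(d, d2[np.ix_(order, order)])

    def test_root_balances_longest_path(self):
        rng = np.random.default_rng(21)
        tree = midpoint_root(random_additive_tree(rng, 9))
        labels, d = path_distances(tree)
        # depth of the two farthest leaves from the new root differ by at most
        # the length of the edge the midpoint landed on
        i, j = np.unravel_index(np.argmax(d), d.shape)
        leaf_depth = {}
        for leaf in tree.root.leaves():
            acc, node = 0.0, leaf
            while node.parent is not None:
                acc += node.length
                node = node.parent
            leaf_depth[leaf.label] = acc
        assert abs(leaf_depth[labels[i]] - leaf_depth[labels[j]]) < 1e-9


class TestBestReferenceHits:
    def test_picks_closest_by_alignment_score(self):
        refs = [SequenceRecord("ref1", "MKVAGAHDLLIV"),
                SequenceRecord("ref2", "WWWWCCCCPPPP")]
        groups = {"ref1": "IX", "ref2": "III"}
        hits = best_reference_hits(
            [SequenceRecord("q", "MKVAGAHDLLIC")], refs, groups
        )
        assert hits["q"] == ("ref1", "IX")
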