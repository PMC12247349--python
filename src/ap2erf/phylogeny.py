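"""Neighbor-joining trees and the tree-dependent classification steps.

The tree drives three decisions downstream of domain architecture:

* single-AP2-domain genes that nest inside the AP2-subfamily clade are
  overridden into the AP2 subfamily;
* single-AP2-domain genes that group with neither the AP2 nor the ERF
  clades are designated Soloist;
* ERF subgroup labels taken from closest-reference hits are refined by
  tree placement (e.g. V/VII hits reclassified to VI-L).

Manual tree curation is replaced by a deterministic clade-context rule:
walk from a leaf toward the root and, at the first ancestor carrying at
least ``k`` reference leaves, take the plurality reference label (ties give
no context). The root itself is excluded by default: an NJ root is merely
the final join point, so a context spanning the entire tree carries no
grouping signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import AlignmentScoring, DistanceMatrix, global_align
from .family import FamilyCall
from .io_formats import SequenceRecord

__all__ = [
    "TreeNode",
    "Tree",
    "SubgroupAssignment",
    "nj_tree",
    "clade_context",
    "assign_subgroups",
    "resolve_single_domain_overrides",
    "best_reference_hits",
]


class TreeNode:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode", length: float | None = None) -> "TreeNode":
        if length is not None:
            child.length = length
        child.parent = self
        self.children.append(child)
        return child

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out


class Tree:
    """Rooted view of an NJ tree; the root is the final join point."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._leaf_index: dict[str, TreeNode] = {}
        for leaf in root.leaves():
            if leaf.label in self._leaf_index:
                raise ValueError(f"duplicate leaf label {leaf.label!r}")
            self._leaf_index[leaf.label] = leaf

    def leaf(self, label: str) -> TreeNode:
        try:
            return self._leaf_index[label]
        except KeyError:
            raise KeyError(f"leaf {label!r} not in tree") from None

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def __contains__(self, label: str) -> bool:
        return label in self._leaf_index


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    At each step the pair minimizing the Q-criterion is joined (ties broken
    by the smallest (i, j) index pair in the current node ordering); branch
    lengths follow the standard two-point formulas with negative lengths
    clamped to zero.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in dm.labels]
    while len(nodes) > 2:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic arg-min with (i, j) tie-break
        flat = int(np.argmin(q))
        best = q.flat[flat]
        ties = np.argwhere(np.isclose(q, best, rtol=0, atol=1e-12))
        i, j = min((int(a), int(b)) for a, b in ties if a < b)
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        parent.add(nodes[i], li)
        parent.add(nodes[j], lj)
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        dnew = np.maximum(dnew, 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        d = d2
    # attach the remaining edge; the root is the internal node of the pair
    a, b = nodes
    if a.is_leaf and not b.is_leaf:
        a, b = b, a
    a.add(b, max(d[0, 1], 0.0))
    a.length = 0.0
    return Tree(a)


def _adjacency(tree: Tree) -> dict[TreeNode, list[tuple[TreeNode, float]]]:
    adj: dict[TreeNode, list[tuple[TreeNode, float]]] = {}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in node.children:
            adj.setdefault(node, []).append((child, child.length))
            adj.setdefault(child, []).append((node, child.length))
            stack.append(child)
    return adj


def _farthest(adj, start: TreeNode) -> tuple[TreeNode, float, dict[TreeNode, TreeNode]]:
    dist = {start: 0.0}
    came: dict[TreeNode, TreeNode] = {}
    stack = [start]
    best, best_d = start, 0.0
    while stack:
        node = stack.pop()
        for nbr, w in adj.get(node, []):
            if nbr in dist:
                continue
            dist[nbr] = dist[node] + w
            came[nbr] = node
            stack.append(nbr)
            if nbr.is_leaf and dist[nbr] > best_d:
                best, best_d = nbr, dist[nbr]
    return best, best_d, came


def midpoint_root(tree: Tree) -> Tree:
    """Re-root at the midpoint of the longest leaf-to-leaf path.

    The NJ root is just the final join point; midpoint rooting gives the
    deterministic, rooting-artifact-free view the clade rules operate on.
    """
    adj = _adjacency(tree)
    u, _, _ = _farthest(adj, tree.root)
    v, diameter, came = _farthest(adj, u)
    if diameter == 0:
        return tree
    # walk back from v toward u, locating the midpoint edge
    path = [v]
    while path[-1] is not u:
        path.append(came[path[-1]])
    half = diameter / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):  # v -> u direction
        w = a.length if b is a.parent else b.length
        if acc + w >= half - 1e-12:
            # midpoint on edge (a, b), at (half - acc) from a
            child = a if b is a.parent else b
            return _reroot_on_edge(child, half - acc if child is a else w - (half - acc))
        acc += w
    return tree


def _reroot_on_edge(child: TreeNode, dist_from_child: float) -> Tree:
    """New root on the edge above ``child``, ``dist_from_child`` from it."""
    edge_len = child.length
    dist_from_child = min(max(dist_from_child, 0.0), edge_len)
    old_parent = child.parent
    if old_parent is None:
        return Tree(child)
    root = TreeNode()
    old_parent.children.remove(child)
    root.add(child, dist_from_child)
    # reverse the parent chain above the edge
    prev = root
    carry = edge_len - dist_from_child
    node: TreeNode | None = old_parent
    while node is not None:
        upper = node.parent
        upper_len = node.length
        if upper is not None:
            upper.children.remove(node)
        node.parent = None
        prev.add(node, carry)
        prev, carry = node, upper_len
        node = upper
    # splice out any internal node left with a single child
    _splice_single_child_nodes(root)
    return Tree(root)


def _splice_single_child_nodes(root: TreeNode) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        changed = True
        while changed:
            changed = False
            for i, child in enumerate(node.children):
                if not child.is_leaf and len(child.children) == 1:
                    grand = child.children[0]
                    grand.length += child.length
                    grand.parent = node
                    node.children[i] = grand
                    changed = True
                    break
        stack.extend(node.children)


@dataclass(frozen=True)
class SubgroupAssignment:
    gene_id: str
    blast_subgroup: str | None
    tree_subgroup: str | None
    final_subgroup: str | None
    reclassified: bool


def clade_context(
    tree: Tree,
    gene_id: str,
    reference_labels: Mapping[str, str],
    k: int = 3,
    include_root: bool = False,
) -> str | None:
    """Plurality reference label at the first ancestor holding >= k references.

    Returns None when no qualifying ancestor exists below the root (or at
    all, with ``include_root``) or when the plurality is tied.
    """
    node = tree.leaf(gene_id)
    ancestor = node.parent
    while ancestor is not None:
        if ancestor.parent is None and not include_root:
            break
        labels = [
            reference_labels[leaf.label]
            for leaf in ancestor.leaves()
            if leaf.label in reference_labels and leaf.label != gene_id
        ]
        if len(labels) >= k:
            counts: dict[str, int] = {}
            for lab in labels:
                counts[lab] = counts.get(lab, 0) + 1
            ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                return None
            return ranked[0][0]
        ancestor = ancestor.parent
    return None


def assign_subgroups(
    genes: Sequence[str],
    best_hits: Mapping[str, tuple[str, str]],
    tree: Tree,
    reference_labels: Mapping[str, str],
    k: int = 3,
) -> list[SubgroupAssignment]:
    """Two-step subgroup assignment: closest-reference label, tree refinement.

    The tree context overrides the similarity-based label when it exists and
    differs; genes with neither evidence are reported unassigned (final None)
    rather than raising.
    """
    out: list[SubgroupAssignment] = []
    for gene in genes:
        blast = best_hits.get(gene, (None, None))[1]
        ctx = (
            clade_context(tree, gene, reference_labels, k=k)
            if gene in tree
            else None
        )
        if ctx is not None and ctx != blast:
            final, reclass = ctx, blast is not None
        else:
            final, reclass = blast, False
        out.append(
            SubgroupAssignment(
                gene_id=gene,
                blast_subgroup=blast,
                tree_subgroup=ctx,
                final_subgroup=final,
                reclassified=reclass and final != blast,
            )
        )
    return out


def resolve_single_domain_overrides(
    provisional_calls: list[FamilyCall], tree: Tree, k: int = 3
) -> list[FamilyCall]:
    """Finalize single-AP2-domain genes against the whole-family tree.

    References are architecture-certain genes: two-domain genes vote "AP2",
    provisional ERF genes vote "ERF". A provisional-ERF gene in an
    AP2-context becomes AP2 (basis tree_override); one with no context at
    all becomes Soloist; an ERF context keeps it ERF.
    """
    refs: dict[str, str] = {}
    for call in provisional_calls:
        if call.ap2_domain_count >= 2:
            refs[call.gene_id] = "AP2"
        elif call.subfamily == "ERF":
            refs[call.gene_id] = "ERF"
    final: list[FamilyCall] = []
    for call in provisional_calls:
        if call.subfamily != "ERF" or call.gene_id not in tree:
            final.append(call)
            continue
        ctx = clade_context(tree, call.gene_id, refs, k=k)
        if ctx == "AP2":
            final.append(
                replace(call, subfamily="AP2", subfamily_basis="tree_override")
            )
        elif ctx is None:
            final.append(
                replace(call, subfamily="Soloist", subfamily_basis="tree_override")
            )
        else:
            final.append(call)
    return final


def best_reference_hits(
    queries: Iterable[SequenceRecord],
    references: Iterable[SequenceRecord],
    reference_subgroups: Mapping[str, str],
    scoring: AlignmentScoring | None = None,
) -> dict[str, tuple[str, str]]:
    """Closest reference per query by global alignment score.

    Stands in for a BLASTP best-hit search against a labeled reference set;
    score ties go to the lexicographically smaller reference id.
    """
    scoring = scoring or AlignmentScoring()
    refs = sorted(references, key=lambda r: r.id)
    out: dict[str, tuple[str, str]] = {}
    for q in queries:
        best_id, best_score = None, -np.inf
        for ref in refs:
            score = global_align(q, ref, scoring).score
            if score > best_score:
                best_id, best_score = ref.id, score
        if best_id is not None:
            out[q.id] = (best_id, reference_subgroups[best_id])
    return out
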