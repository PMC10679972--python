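"""Outgroup-rooted maximum-parsimony trees from binary presence matrices.

Each patient's regions are taxa; each mutation key is a binary character
(present/absent).  An artificial all-zero outgroup ("normal") roots the
tree.  With at most 8 taxa the space of unrooted binary topologies is
enumerated exhaustively and each is scored by summed per-character
minimum state changes (Fitch small parsimony, exact for binary
characters); the best topology is rooted at the outgroup.  Branch
lengths count the characters whose state changes map to each edge under
a most-parsimonious reconstruction in which ambiguous changes are pulled
toward the root (maximising trunk attribution), so branch lengths always
sum to the parsimony score.

Trunk / shared / private classification of mutations is defined directly
by presence patterns (all tumour regions / some but not all / exactly
one) and is therefore independent of topology ties.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from .stats import fisher_exact_2x2
from .variant_core import OUTGROUP, BinaryCharacterMatrix

__all__ = [
    "BranchAssignment",
    "PhyloTree",
    "classify_branches",
    "wagner_parsimony",
    "driver_trunk_enrichment",
    "to_newick",
    "parse_newick",
]

MAX_TAXA = 8


@dataclass
class BranchAssignment:
    """Trunk/shared/private class and carrying-region subset per mutation."""

    classes: dict[tuple, str]
    subsets: dict[tuple, frozenset[str]]

    @property
    def counts(self) -> dict[str, int]:
        out = {"trunk": 0, "shared": 0, "private": 0}
        for c in self.classes.values():
            out[c] += 1
        return out


@dataclass
class PhyloTree:
    """A rooted parsimony tree with integer mutation-count branch lengths."""

    tree: dendropy.Tree
    score: int
    n_best_topologies: int = 1

    @property
    def newick(self) -> str:
        return to_newick(self)

    def branch_length_sum(self) -> int:
        return int(
            sum(
                e.length or 0
                for e in self.tree.preorder_edge_iter()
                if e.head_node is not self.tree.seed_node
            )
        )


def classify_branches(matrix: BinaryCharacterMatrix) -> BranchAssignment:
    """Classify each mutation as trunk, shared or private by presence pattern."""
    tumor = matrix.tumor_taxa
    if len(tumor) < 2:
        raise ValueError("need >= 2 tumor regions")
    idx = [matrix.taxa.index(t) for t in tumor]
    sub = matrix.values[idx, :]
    if matrix.characters and (sub.sum(axis=0) == 0).any():
        raise ValueError("all-zero character (absent in every tumor region)")
    classes: dict[tuple, str] = {}
    subsets: dict[tuple, frozenset[str]] = {}
    for j, key in enumerate(matrix.characters):
        carrying = frozenset(t for i, t in enumerate(tumor) if sub[i, j])
        subsets[key] = carrying
        if len(carrying) == len(tumor):
            classes[key] = "trunk"
        elif len(carrying) == 1:
            classes[key] = "private"
        else:
            classes[key] = "shared"
    return BranchAssignment(classes=classes, subsets=subsets)


# ---------------------------------------------------------------------------
# Topology enumeration
#
# A rooted binary topology over taxa indices is a nested structure: a leaf
# is an int, an internal node a 2-tuple.  Unrooted binary topologies over
# n taxa including the outgroup correspond bijectively to rooted binary
# topologies over the n-1 remaining taxa (root = the outgroup attachment).


def _insertions(top, leaf):
    """All topologies from inserting ``leaf`` into each edge of ``top``."""
    yield (top, leaf)  # above the current root
    if isinstance(top, tuple):
        left, right = top
        for sub in _insertions(left, leaf):
            yield (sub, right)
        for sub in _insertions(right, leaf):
            yield (left, sub)


def _rooted_topologies(taxa: Sequence[int]):
    """All rooted binary topologies on the given taxon indices."""
    if len(taxa) == 1:
        yield taxa[0]
        return
    for top in _rooted_topologies(taxa[:-1]):
        yield from _insertions(top, taxa[-1])


def _flatten(top, nodes, children, parent_of, parent):
    """Register node ids postorder; returns the id of ``top``."""
    nid = len(nodes)
    if isinstance(top, tuple):
        nodes.append(None)  # placeholder; fill after children known
        children.append([])
        parent_of.append(parent)
        for child in top:
            cid = _flatten(child, nodes, children, parent_of, nid)
            children[nid].append(cid)
        nodes[nid] = ("internal",)
    else:
        nodes.append(("leaf", top))
        children.append([])
        parent_of.append(parent)
    return nid


class _IndexedTree:
    """Array-indexed rooted tree for vectorised scoring.

    The root has exactly two children: the outgroup leaf and the tumor
    subtree.  Node 0 is the root; leaves carry their taxon index.
    """

    def __init__(self, topology, outgroup_index: int):
        full = (outgroup_index, topology)
        self.nodes: list = []
        self.children: list[list[int]] = []
        self.parent: list[int] = []
        _flatten(full, self.nodes, self.children, self.parent, -1)
        self.n = len(self.nodes)
        self.is_leaf = np.array([n[0] == "leaf" for n in self.nodes])
        self.leaf_taxon = {
            i: n[1] for i, n in enumerate(self.nodes) if n[0] == "leaf"
        }
        self.internal = [i for i in range(self.n) if not self.is_leaf[i]]
        # depth of each node (root = 0); edge depth = depth of head node
        self.depth = np.zeros(self.n, dtype=int)
        for i in range(self.n):
            if self.parent[i] >= 0:
                self.depth[i] = self.depth[self.parent[i]] + 1
        # postorder: children before parents
        self.postorder = self._postorder()

    def _postorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order[::-1]


def _fitch_score(tree: _IndexedTree, leaf_states: np.ndarray) -> np.ndarray:
    """Per-character minimum changes on ``tree`` (vectorised Fitch).

    leaf_states: taxa x characters uint8.  State sets are 2-bit masks
    (bit0 = absent, bit1 = present).
    """
    n_chars = leaf_states.shape[1]
    masks = np.zeros((tree.n, n_chars), dtype=np.uint8)
    changes = np.zeros(n_chars, dtype=np.int64)
    for node in tree.postorder:
        if tree.is_leaf[node]:
            taxon = tree.leaf_taxon[node]
            masks[node] = np.where(leaf_states[taxon] == 1, 2, 1)
        else:
            acc = None
            union = None
            for c in tree.children[node]:
                acc = masks[c] if acc is None else acc & masks[c]
                union = masks[c] if union is None else union | masks[c]
            empty = acc == 0
            changes += empty
            masks[node] = np.where(empty, union, acc)
    return changes


def _assign_changes(
    tree: _IndexedTree, leaf_states: np.ndarray
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Most-parsimonious per-edge change assignment, root-proximal.

    For each character, all assignments of states to internal nodes are
    enumerated (<= 2^7 with 8 taxa); among minimum-change assignments the
    one minimising the total depth of change edges is chosen (changes
    pulled toward the root), ties broken by preferring state 0 at
    shallower nodes.  Returns (per-character min changes, per-edge boolean
    change matrix keyed by head-node id).
    """
    n_chars = leaf_states.shape[1]
    internal = tree.internal
    k = len(internal)
    # enumerate assignments so that shallower internal nodes vary slowest
    # and 0 precedes 1 -> binary counting index doubles as the tie-break
    internal_sorted = sorted(internal, key=lambda i: (tree.depth[i], i))
    n_assign = 1 << k
    assign = np.zeros((n_assign, tree.n), dtype=np.uint8)
    for bit, node in enumerate(internal_sorted):
        assign[:, node] = (np.arange(n_assign) >> (k - 1 - bit)) & 1

    edges = [(tree.parent[i], i) for i in range(tree.n) if tree.parent[i] >= 0]
    changes = np.zeros((n_assign, n_chars), dtype=np.int64)
    depth_cost = np.zeros((n_assign, n_chars), dtype=np.int64)
    edge_diff: dict[int, np.ndarray] = {}
    for par, child in edges:
        pstate = assign[:, par][:, None]  # n_assign x 1
        if tree.is_leaf[child]:
            cstate = leaf_states[tree.leaf_taxon[child]][None, :]
        else:
            cstate = assign[:, child][:, None]
        diff = pstate != cstate  # broadcast to n_assign x n_chars
        diff = np.broadcast_to(diff, (n_assign, n_chars))
        edge_diff[child] = diff
        changes = changes + diff
        depth_cost = depth_cost + diff * int(tree.depth[child])

    min_changes = changes.min(axis=0)
    feasible = changes == min_changes[None, :]
    big = np.iinfo(np.int64).max
    cost = np.where(feasible, depth_cost, big)
    chosen = cost.argmin(axis=0)  # argmin takes the first -> tie-break
    per_edge = {
        child: diff[chosen, np.arange(n_chars)] for child, diff in edge_diff.items()
    }
    return min_changes, per_edge


def _taxon_order_key(node: dendropy.Node):
    labels = sorted(l.taxon.label for l in node.leaf_iter())
    # outgroup sorts first so it is printed first at the root
    return (labels[0] != OUTGROUP, labels)


def wagner_parsimony(matrix: BinaryCharacterMatrix) -> PhyloTree:
    """Exhaustive-search binary-character parsimony tree rooted at the outgroup.

    Enumerates every unrooted binary topology over the taxa, scores each
    with Fitch, keeps the minimum, and maps each character's state
    changes onto edges with the root-proximal rule to obtain integer
    branch lengths.  Raises if there are more than 8 taxa (the search is
    exhaustive by design) or fewer than 3.
    """
    taxa = list(matrix.taxa)
    if OUTGROUP not in taxa:
        raise ValueError("matrix must include the outgroup row")
    if len(taxa) > MAX_TAXA:
        raise ValueError("exhaustive search infeasible beyond 8 taxa")
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa including the outgroup")
    out_idx = taxa.index(OUTGROUP)
    tumor_idx = [i for i in range(len(taxa)) if i != out_idx]
    leaf_states = matrix.values

    best_score: Optional[int] = None
    best_tops: list = []
    for top in _rooted_topologies(tumor_idx):
        itree = _IndexedTree(top, out_idx)
        score = int(_fitch_score(itree, leaf_states).sum())
        if best_score is None or score < best_score:
            best_score = score
            best_tops = [top]
        elif score == best_score:
            best_tops.append(top)
    assert best_score is not None

    # canonical choice among ties: first in enumeration order, which is
    # determined by the matrix's taxon order
    chosen = best_tops[0]
    itree = _IndexedTree(chosen, out_idx)
    _, per_edge = _assign_changes(itree, leaf_states)

    # build the dendropy tree
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)

    def build(nid: int) -> dendropy.Node:
        node = dendropy.Node()
        if itree.is_leaf[nid]:
            node.taxon = ns.get_taxon(taxa[itree.leaf_taxon[nid]])
        for c in itree.children[nid]:
            child = build(c)
            child.edge.length = int(per_edge[c].sum())
            node.add_child(child)
        return node

    tree.seed_node = build(0)
    _sort_children(tree)
    pt = PhyloTree(tree=tree, score=best_score, n_best_topologies=len(best_tops))
    assert pt.branch_length_sum() == best_score
    return pt


def _sort_children(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        node._child_nodes.sort(key=_taxon_order_key)


def to_newick(tree: PhyloTree | dendropy.Tree) -> str:
    """Deterministic Newick with integer branch lengths, outgroup first."""
    t = tree.tree if isinstance(tree, PhyloTree) else tree
    _sort_children(t)

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            label = node.taxon.label
        else:
            label = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
        if node.edge.length is not None and node.parent_node is not None:
            return f"{label}:{int(node.edge.length)}"
        return label

    return render(t.seed_node) + ";"


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string back into a dendropy tree."""
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def driver_trunk_enrichment(
    branches: BranchAssignment, driver_flags: Mapping[tuple, bool]
) -> tuple[dict[str, float], float]:
    """Fisher exact test for driver enrichment on the trunk.

    Builds the 2x2 table (driver vs other) x (trunk vs branch, where
    branch = shared + private) and returns the trunk proportion within
    each group together with the two-sided exact p-value.
    """
    n_driver = sum(1 for k in branches.classes if driver_flags.get(k, False))
    n_other = len(branches.classes) - n_driver
    if n_driver == 0 or n_other == 0:
        raise ValueError("need >= 1 driver and >= 1 non-driver mutation")
    table = np.zeros((2, 2), dtype=int)
    for key, cls in branches.classes.items():
        i = 0 if driver_flags.get(key, False) else 1
        j = 0 if cls == "trunk" else 1
        table[i, j] += 1
    props = {
        "driver_trunk_proportion": table[0, 0] / table[0].sum(),
        "other_trunk_proportion": table[1, 0] / table[1].sum(),
    }
    p = fisher_exact_2x2(table)
    return props, p
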