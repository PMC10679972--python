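"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the algorithms used by the package: parsimony
scores come from split-enumeration of topologies plus exhaustive
internal-state assignment (no Fitch), the Fisher tail from exact
rational hypergeometric sums, and BH from the literal O(m^2) step-up
definition.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# Parsimony


def _rooted_trees_by_splits(leaves: tuple[int, ...]):
    """All rooted binary topologies via unordered split recursion."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    # split: the subset containing the first leaf, versus the rest
    for r in range(len(rest) + 1):
        for pick in itertools.combinations(rest, r):
            left = (first,) + pick
            right = tuple(l for l in rest if l not in pick)
            if not right:
                continue
            if right and right[0] < left[0]:
                continue  # count unordered splits once (first leaf on left)
            for lt in _rooted_trees_by_splits(left):
                for rt in _rooted_trees_by_splits(right):
                    yield (lt, rt)


def _edges_of(topology, outgroup: int):
    """Edge list and leaf/internal node bookkeeping for ((outgroup, rest))."""
    nodes = []
    edges = []

    def walk(sub, parent):
        nid = len(nodes)
        nodes.append(sub if not isinstance(sub, tuple) else None)
        if parent is not None:
            edges.append((parent, nid))
        if isinstance(sub, tuple):
            for child in sub:
                walk(child, nid)
        return nid

    root = len(nodes)
    nodes.append(None)
    walk(outgroup, root)
    walk(topology, root)
    return nodes, edges, root


def parsimony_score_bruteforce(
    leaf_states: np.ndarray, outgroup_index: int
) -> int:
    """Minimum total state changes over all unrooted binary topologies.

    Per topology, per character, minimises over every assignment of 0/1
    states to internal nodes.  leaf_states: taxa x characters.
    """
    taxa = list(range(leaf_states.shape[0]))
    tumor = tuple(t for t in taxa if t != outgroup_index)
    best = None
    for top in _rooted_trees_by_splits(tumor):
        nodes, edges, _root = _edges_of(top, outgroup_index)
        internal = [i for i, v in enumerate(nodes) if v is None]
        n_chars = leaf_states.shape[1]
        score_per_char = np.full(n_chars, np.inf)
        for states in itertools.product((0, 1), repeat=len(internal)):
            smap = dict(zip(internal, states))
            changes = np.zeros(n_chars)
            for a, b in edges:
                sa = (
                    smap[a]
                    if a in smap
                    else leaf_states[nodes[a]]
                )
                sb = (
                    smap[b]
                    if b in smap
                    else leaf_states[nodes[b]]
                )
                changes = changes + (np.asarray(sa) != np.asarray(sb))
            score_per_char = np.minimum(score_per_char, changes)
        total = int(score_per_char.sum())
        if best is None or total < best:
            best = total
    return best


# ---------------------------------------------------------------------------
# Fisher exact


def fisher_2x2_exact_fraction(table) -> float:
    """Two-sided Fisher p via exact rational arithmetic."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = pmf(k)
        if pk <= p_obs:
            total += pk
    return float(total)


def fisher_rx2_exact_fraction(table) -> float:
    """Exact Rx2 Fisher p by full enumeration with rational arithmetic."""
    t = [list(map(int, row)) for row in table]
    rows = [sum(r) for r in t]
    col1 = sum(r[0] for r in t)
    n = sum(rows)

    def prob(a_vec) -> Fraction:
        num = 1
        for ri, ai in zip(rows, a_vec):
            num *= comb(ri, ai)
        return Fraction(num, comb(n, col1))

    obs = prob([r[0] for r in t])
    ranges = [range(0, r + 1) for r in rows]
    total = Fraction(0)
    for a_vec in itertools.product(*ranges):
        if sum(a_vec) != col1:
            continue
        p = prob(a_vec)
        if p <= obs:
            total += p
    return float(total)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_naive(pvalues) -> np.ndarray:
    """Literal O(m^2) BH step-up: q_i = min over j with p_j >= p_i of p_j m / rank_j."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [
            p[j] * m / rank[j] for j in range(m) if p[j] >= p[i] or rank[j] >= rank[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q
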