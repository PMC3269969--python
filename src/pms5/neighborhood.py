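"""The Hamming d-neighborhood B_d(x) and its tree representation T_d(x).

B_d(x) = {y : d_H(x, y) <= d} has the closed-form size
N(l, d) = sum_{i=0}^{d} C(l, i) (|Sigma| - 1)^i.

T_d(x) enumerates B_d(x) without duplicates.  A node is a pair ``(t, p)``
where ``t`` is an l-mer and ``p`` in [0, l] is the rightmost changed position
(1-based, 0 at the root), so that ``t`` agrees with ``x`` everywhere right of
position ``p``.  A child flips one position strictly right of the parent's
``p`` away from ``x``; the tree depth equals d, and a node's depth equals its
Hamming distance from ``x``.  Each member of B_d(x) corresponds to exactly
one node (the positions where it differs from x, flipped left to right).

Nodes are generated lazily during depth-first traversal; the tree is never
materialized.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterator

from .seqcore import DNA, Alphabet, hamming_distance


def neighborhood_size(l: int, d: int, sigma: int = 4) -> int:
    """Exact |B_d(x)| for any l-mer over an alphabet of ``sigma`` symbols."""
    if sigma < 2:
        raise ValueError("alphabet size must be >= 2")
    if not 0 <= d <= l:
        raise ValueError(f"d={d} must be in [0, l={l}]")
    return sum(comb(l, i) * (sigma - 1) ** i for i in range(d + 1))


@dataclass(frozen=True)
class TreeNode:
    """One node (t, p) of T_d(x); ``h`` is its depth = d_H(x, t)."""

    t: str
    p: int  # rightmost changed position, 1-based; 0 for the root
    h: int


def root(x: str) -> TreeNode:
    return TreeNode(t=x, p=0, h=0)


def children(
    node: TreeNode, x: str, d: int, alphabet: Alphabet = DNA
) -> list[TreeNode]:
    """All children of ``node`` in T_d(x), ordered by position then symbol.

    Empty when the node sits at depth d (the tree's depth bound).
    """
    if node.h >= d:
        return []
    t = node.t
    out = []
    for j in range(node.p, len(x)):  # 0-based flip index; child's p = j + 1
        xj = x[j]
        for c in alphabet.symbols:
            if c != xj:
                out.append(TreeNode(t[:j] + c + t[j + 1 :], j + 1, node.h + 1))
    return out


def iter_neighborhood(
    x: str, d: int, alphabet: Alphabet = DNA
) -> Iterator[TreeNode]:
    """Depth-first traversal of T_d(x), yielding every node exactly once."""
    if not 0 <= d <= len(x):
        raise ValueError(f"d={d} must be in [0, l={len(x)}]")
    alphabet.validate(x, "l-mer")
    stack = [root(x)]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(children(node, x, d, alphabet)))


def enumerate_neighborhood(x: str, d: int, alphabet: Alphabet = DNA) -> set[str]:
    """The set B_d(x); cardinality equals ``neighborhood_size``.

    The tree-node/member bijection means the traversal visits each member
    once, so building the set does no duplicate work.
    """
    return {node.t for node in iter_neighborhood(x, d, alphabet)}


def verify_tree_invariants(x: str, d: int, alphabet: Alphabet = DNA) -> int:
    """Walk T_d(x) asserting depth == distance; return the node count.

    Test helper: the returned count must equal ``neighborhood_size`` (the
    bijection) and every visited node must satisfy Property 1 of the tree.
    """
    count = 0
    for node in iter_neighborhood(x, d, alphabet):
        if hamming_distance(x, node.t) != node.h:
            raise AssertionError(f"depth/distance mismatch at {node}")
        count += 1
    return count
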