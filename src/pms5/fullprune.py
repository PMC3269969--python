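"""FULLPRUNE: the common d-neighborhood B_d(x, y, z) by pruned DFS of T_d(x).

B_d(x, y, z) = B_d(x) ∩ B_d(y) ∩ B_d(z) is the basic object of the exact
motif search: the whole algorithm reduces to computing it repeatedly.  The
traversal walks T_d(x) depth-first, emits every node within distance d of
all three strings, and descends into a subtree only when the
integer-feasibility test (:mod:`pms5.ilp`) certifies that the subtree (node
included) can contain an intersection element.

All distances are maintained incrementally: a child differs from its parent
at exactly one position, and a node's suffix always equals the corresponding
suffix of x, so total and prefix distances to x, y, z are O(1) updates from
precomputed mismatch prefix sums.  Per-node work is therefore constant
(beyond building the child's string itself).

``visited_nodes`` counts the nodes whose subtrees are explored, i.e. the
nodes that pass the feasibility test (the root is always counted).  For a
4-letter alphabet every leaf of that explored tree is an intersection
element, which gives the node bound visited_nodes <= 1 + d * |B_d(x,y,z)|
in general and <= d * |B| whenever x itself lies in the intersection (the
regime the search driver reaches after triangle filtering).  For an empty
intersection only the root is visited.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ilp import FeasibilityCache, count_suffix_types, make_key, shared_cache
from .seqcore import DNA, Alphabet, hamming_distance


@dataclass
class IntersectionResult:
    """The intersection elements plus traversal instrumentation."""

    elements: set[str]
    visited_nodes: int


def emit_check(dx: int, dy: int, dz: int, d: int) -> bool:
    """Step 3c of the traversal: output t iff all three distances are <= d."""
    return dx <= d and dy <= d and dz <= d


def fullprune(
    x: str,
    y: str,
    z: str,
    d: int,
    alphabet: Alphabet = DNA,
    cache: FeasibilityCache | None = None,
) -> IntersectionResult:
    """Compute B_d(x, y, z) exactly.

    Parameters
    ----------
    x, y, z
        Equal-length l-mers over ``alphabet``.  ``x`` anchors the tree; the
        result set is invariant under permutations of the three.
    d
        Mismatch budget, 0 <= d <= l.
    cache
        Feasibility memo; defaults to the process-wide shared cache.
    """
    l = len(x)
    if len(y) != l or len(z) != l:
        raise ValueError("x, y, z must have equal length")
    if not 0 <= d <= l:
        raise ValueError(f"d={d} must be in [0, l={l}]")
    if cache is None:
        cache = shared_cache

    counts = count_suffix_types(x, y, z)
    # Prefix mismatch sums against x: mxy[i] = d_H(x[:i], y[:i]).
    mxy = [0] * (l + 1)
    mxz = [0] * (l + 1)
    for i in range(l):
        mxy[i + 1] = mxy[i] + (x[i] != y[i])
        mxz[i + 1] = mxz[i] + (x[i] != z[i])

    elements: set[str] = set()
    visited = 0
    symbols = alphabet.symbols

    # Stack entries: (t, p, dx1, dy1, dz1) with p the rightmost changed
    # position (1-based; suffix t[p:] == x[p:]) and d?1 the prefix distances
    # d_H(?[:p], t[:p]).  Every pushed node has already passed feasibility;
    # the root is pushed unconditionally and checked at expansion time.
    stack: list[tuple[str, int, int, int, int]] = [(x, 0, 0, 0, 0)]
    while stack:
        t, p, dx1, dy1, dz1 = stack.pop()
        visited += 1
        dx = dx1  # suffix of t equals suffix of x
        dy = dy1 + mxy[l] - mxy[p]
        dz = dz1 + mxz[l] - mxz[p]
        if emit_check(dx, dy, dz, d):
            elements.add(t)
        if dx >= d:
            continue  # depth budget exhausted: no children exist
        if p == 0 and not cache(make_key(counts[0], l, d, 0, 0, 0)):
            continue  # root's own subtree provably empty
        for j in range(p, l):
            # Columns p..j-1 of the child's prefix match x (unchanged
            # suffix region), so only the flipped column j moves the
            # prefix distances.
            base_dy1 = dy1 + mxy[j] - mxy[p]
            base_dz1 = dz1 + mxz[j] - mxz[p]
            xj, yj, zj = x[j], y[j], z[j]
            cp = j + 1
            cnt = counts[cp]
            suffix_len = l - cp
            for c in symbols:
                if c == xj:
                    continue
                cdx1 = dx1 + 1
                cdy1 = base_dy1 + (c != yj)
                cdz1 = base_dz1 + (c != zj)
                if cache(make_key(cnt, suffix_len, d, cdx1, cdy1, cdz1)):
                    stack.append((t[:j] + c + t[j + 1 :], cp, cdx1, cdy1, cdz1))
    return IntersectionResult(elements=elements, visited_nodes=visited)


def replay_check(x: str, y: str, z: str, d: int, result: IntersectionResult) -> bool:
    """Recompute all three distances for every emitted element directly.

    Instrumented cross-check used by tests: True iff every reported element
    really lies within distance d of x, y and z.
    """
    return all(
        hamming_distance(t, x) <= d
        and hamming_distance(t, y) <= d
        and hamming_distance(t, z) <= d
        for t in result.elements
    )
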