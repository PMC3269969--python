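"""Integer-feasibility test for subtree pruning in the common-neighborhood DFS.

Given three l-mers x, y, z and a tree node (t, p) of T_d(x), the subtree at
(t, p) contains an element of B_d(x) ∩ B_d(y) ∩ B_d(z) iff there is a suffix
w of length l - p with

    d_H(x1, t1) + d_H(x2, w) <= d     (and likewise for y, z),

where the subscript-1 parts are the length-p prefixes and x2, y2, z2 are the
suffixes.  Each suffix column falls into one of five types by its match
pattern across (x2, y2, z2):

    1 aaa: x=y=z    2 aab: x=y!=z    3 aba: x=z!=y    4 baa: y=z!=x
    5 abc: all three distinct

With n1..n5 the per-type column counts, the existence of w reduces to a
10-variable integer program: N1a counts type-1 columns where w matches all
three; N2a/N2b (type 2) where w matches x=y resp. z; N3a/N3b (type 3) x=z
resp. y; N4a/N4b (type 4) y=z resp. x; N5a/N5b/N5c (type 5) x, y, z.  The
program is feasible iff the three coverage constraints

    N1a + N2a + N3a + N4b + N5a >= R1      (R1 = l - p - d + d_H(x1, t1))
    N1a + N2a + N3b + N4a + N5b >= R2      (R2 = ... y ...)
    N1a + N2b + N3a + N4a + N5c >= R3      (R3 = ... z ...)

can be met under the capacities N1a <= n1, N2a+N2b <= n2, N3a+N3b <= n3,
N4a+N4b <= n4, N5a+N5b+N5c <= n5, all variables non-negative integers.

The whole subproblem is identified by the 8-tuple (n1..n5, R1, R2, R3), so
decisions are memoized in :class:`FeasibilityCache` (a lazy map over reachable
keys rather than a fully materialized (l+1)^5 (d+1)^3 table).

For a 4-letter (or larger) alphabet the reduction is exact: feasibility holds
iff a witness suffix w exists.  For smaller alphabets some allocations are
not realizable as strings, making the test a relaxation -- infeasibility
still implies no witness, so pruning remains safe.
"""

from __future__ import annotations

import json
from typing import NamedTuple


class ILPKey(NamedTuple):
    """The complete input of one feasibility subproblem."""

    n1: int
    n2: int
    n3: int
    n4: int
    n5: int
    r1: int
    r2: int
    r3: int


def classify_column(a: str, b: str, c: str) -> int:
    """Column type in {1..5} of one position across three suffixes."""
    if a == b:
        return 1 if b == c else 2
    if a == c:
        return 3
    if b == c:
        return 4
    return 5


def count_suffix_types(x: str, y: str, z: str) -> list[tuple[int, int, int, int, int]]:
    """Suffix type counts (n1..n5) for every split point p = 0..l.

    ``counts[p]`` covers the columns at 0-based indices p..l-1 (the suffix a
    tree node at position p still controls); ``counts[l]`` is all zeros.
    Built by a single right-to-left sweep.
    """
    l = len(x)
    if len(y) != l or len(z) != l:
        raise ValueError("x, y, z must have equal length")
    counts: list[tuple[int, int, int, int, int]] = [(0, 0, 0, 0, 0)] * (l + 1)
    acc = [0, 0, 0, 0, 0]
    for j in range(l - 1, -1, -1):
        acc[classify_column(x[j], y[j], z[j]) - 1] += 1
        counts[j] = tuple(acc)  # type: ignore[assignment]
    return counts


def make_key(
    counts_p: tuple[int, int, int, int, int],
    suffix_len: int,
    d: int,
    dx1: int,
    dy1: int,
    dz1: int,
) -> ILPKey:
    """Assemble the feasibility key for a node with the given prefix distances.

    Requirements R_i = suffix_len - d + d_H(.1, t1) are clamped below at 0
    (a negative requirement is trivially satisfied).
    """
    base = suffix_len - d
    return ILPKey(
        *counts_p,
        max(0, base + dx1),
        max(0, base + dy1),
        max(0, base + dz1),
    )


def ilp_feasible(key: ILPKey) -> bool:
    """Exact feasibility decision for one key.

    Decision procedure: N1a is saturated at n1 (it serves all three coverage
    constraints and competes with nothing); the three two-way splits
    N2a/N2b, N3a/N3b, N4a/N4b are enumerated with the complement always
    assigned to the sibling (more coverage never hurts); the residual
    deficits must then be absorbable by the three disjoint type-5 variables,
    i.e. sum to at most n5.  O(n2*n3*n4) <= O(l^3) per key, exact against
    brute-force allocation enumeration.
    """
    n1, n2, n3, n4, n5, r1, r2, r3 = key
    if min(n1, n2, n3, n4, n5) < 0:
        raise ValueError(f"negative capacity in {key}")
    r1, r2, r3 = max(0, r1), max(0, r2), max(0, r3)
    if max(r1, r2, r3) > n1 + n2 + n3 + n4 + n5:
        return False
    for n2a in range(n2 + 1):
        n2b = n2 - n2a
        for n3a in range(n3 + 1):
            n3b = n3 - n3a
            for n4a in range(n4 + 1):
                n4b = n4 - n4a
                need = (
                    max(0, r1 - n1 - n2a - n3a - n4b)
                    + max(0, r2 - n1 - n2a - n3b - n4a)
                    + max(0, r3 - n1 - n2b - n3a - n4a)
                )
                if need <= n5:
                    return True
    return False


class FeasibilityCache:
    """Memoized :func:`ilp_feasible`, reusable across FULLPRUNE calls.

    Keys are 8-tuples independent of l and d themselves, so one cache serves
    every problem size in a process.
    """

    def __init__(self) -> None:
        self._table: dict[ILPKey, bool] = {}
        self.hits = 0
        self.misses = 0

    def __call__(self, key: ILPKey) -> bool:
        try:
            value = self._table[key]
            self.hits += 1
            return value
        except KeyError:
            self.misses += 1
            value = ilp_feasible(key)
            self._table[key] = value
            return value

    def __len__(self) -> int:
        return len(self._table)

    def clear(self) -> None:
        self._table.clear()
        self.hits = 0
        self.misses = 0

    def save(self, path: str) -> None:
        """Persist the cache as JSON (list of [key..., value] rows)."""
        rows = [[*k, v] for k, v in self._table.items()]
        with open(path, "w") as fh:
            json.dump(rows, fh)

    def load(self, path: str) -> None:
        with open(path) as fh:
            rows = json.load(fh)
        for row in rows:
            self._table[ILPKey(*row[:8])] = bool(row[8])


#: Process-wide cache shared by default across all traversals.
shared_cache = FeasibilityCache()
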