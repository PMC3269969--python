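"""Column typing and the integer-feasibility decision.

Two independent oracles back the feasibility test: exhaustive enumeration of
all variable allocations, and exhaustive enumeration of witness suffix
strings (exact for a 4-letter alphabet).
"""

import random
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pms5.ilp import (
    FeasibilityCache,
    ILPKey,
    classify_column,
    count_suffix_types,
    ilp_feasible,
    make_key,
)
from pms5.seqcore import hamming_distance


def allocation_bruteforce(key: ILPKey) -> bool:
    """Enumerate every allocation; reference for small capacities only."""
    n1, n2, n3, n4, n5, r1, r2, r3 = key
    for n1a in range(n1 + 1):
        for n2a, n2b in product(range(n2 + 1), repeat=2):
            if n2a + n2b > n2:
                continue
            for n3a, n3b in product(range(n3 + 1), repeat=2):
                if n3a + n3b > n3:
                    continue
                for n4a, n4b in product(range(n4 + 1), repeat=2):
                    if n4a + n4b > n4:
                        continue
                    for n5a, n5b, n5c in product(range(n5 + 1), repeat=3):
                        if n5a + n5b + n5c > n5:
                            continue
                        if (
                            n1a + n2a + n3a + n4b + n5a >= r1
                            and n1a + n2a + n3b + n4a + n5b >= r2
                            and n1a + n2b + n3a + n4a + n5c >= r3
                        ):
                            return True
    return False


def test_classify_column_all_patterns():
    assert classify_column("A", "A", "A") == 1
    assert classify_column("A", "A", "C") == 2
    assert classify_column("A", "C", "A") == 3
    assert classify_column("C", "A", "A") == 4
    assert classify_column("A", "C", "G") == 5


def test_count_suffix_types_examples():
    # columns of (AAAA, AAAC, AACA): types 1, 1, 2, 3
    counts = count_suffix_types("AAAA", "AAAC", "AACA")
    assert counts[0] == (2, 1, 1, 0, 0)
    assert counts[2] == (0, 1, 1, 0, 0)
    assert counts[4] == (0, 0, 0, 0, 0)
    # identical strings: everything type 1
    same = count_suffix_types("ACGT", "ACGT", "ACGT")
    assert all(same[p] == (4 - p, 0, 0, 0, 0) for p in range(5))
    # suffix totals always cover the remaining columns
    assert all(sum(counts[p]) == 4 - p for p in range(5))
    with pytest.raises(ValueError):
        count_suffix_types("AC", "ACG", "AC")


def test_feasible_trivial_cases():
    # x = y = z: type-1 capacity alone meets all three requirements
    for lp in range(1, 8):
        for r in range(lp + 1):
            assert ilp_feasible(ILPKey(lp, 0, 0, 0, 0, r, r, r))
    # three disjoint full requirements on shared type-5 capacity: pigeonhole
    for k in range(1, 6):
        assert not ilp_feasible(ILPKey(0, 0, 0, 0, k, k, k, k))
    # requirement beyond total capacity short-circuits
    assert not ilp_feasible(ILPKey(1, 1, 0, 0, 0, 3, 0, 0))
    with pytest.raises(ValueError):
        ilp_feasible(ILPKey(-1, 0, 0, 0, 0, 0, 0, 0))


@pytest.mark.parametrize("seed", range(4))
def test_feasible_matches_allocation_bruteforce(seed):
    rng = random.Random(seed)
    for _ in range(60):
        key = ILPKey(
            *(rng.randint(0, 3) for _ in range(5)),
            *(rng.randint(0, 6) for _ in range(3)),
        )
        assert ilp_feasible(key) == allocation_bruteforce(key), key


@pytest.mark.parametrize("seed", range(4))
def test_feasible_matches_witness_strings(seed):
    """Feasibility of the node key <=> an actual suffix witness exists (DNA).

    The witness w must satisfy d_H(x2, w) <= d - dx1 (and likewise y, z)
    where dx1, dy1, dz1 are the prefix distances folded into the key.
    """
    rng = random.Random(100 + seed)
    for _ in range(25):
        lp = rng.randint(1, 5)
        d = rng.randint(0, 4)
        x2, y2, z2 = (
            "".join(rng.choice("ACGT") for _ in range(lp)) for _ in range(3)
        )
        dx1, dy1, dz1 = (rng.randint(0, d) for _ in range(3))
        key = make_key(count_suffix_types(x2, y2, z2)[0], lp, d, dx1, dy1, dz1)
        witness = any(
            hamming_distance(x2, w) <= d - dx1
            and hamming_distance(y2, w) <= d - dy1
            and hamming_distance(z2, w) <= d - dz1
            for w in ("".join(t) for t in product("ACGT", repeat=lp))
        )
        assert ilp_feasible(key) == witness, (x2, y2, z2, d, dx1, dy1, dz1)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    st.tuples(*(st.integers(0, 3) for _ in range(5))),
    st.tuples(*(st.integers(0, 6) for _ in range(3))),
    st.integers(0, 7),
    st.integers(0, 4),
)
def test_feasibility_is_monotone(caps, reqs, which, amount):
    """More capacity or less requirement never turns feasible into infeasible."""
    key = ILPKey(*caps, *reqs)
    base = ilp_feasible(key)
    relaxed = list(key)
    if which < 5:
        relaxed[which] += amount
    else:
        relaxed[which] = max(0, relaxed[which] - amount)
    if base:
        assert ilp_feasible(ILPKey(*relaxed))


def test_cache_hits_misses_and_roundtrip(tmp_path):
    cache = FeasibilityCache()
    key = ILPKey(2, 1, 1, 0, 0, 2, 1, 1)
    first = cache(key)
    assert (cache.hits, cache.misses) == (0, 1)
    assert cache(key) == first
    assert (cache.hits, cache.misses) == (1, 1)
    path = tmp_path / "cache.json"
    cache.save(path)
    other = FeasibilityCache()
    other.load(path)
    assert len(other) == 1 and other(key) == first
    assert other.hits == 1  # served from the loaded table


def test_cache_full_sweep_matches_direct():
    """Exhaustive key sweep at small l, d: cached == direct everywhere."""
    cache = FeasibilityCache()
    l, d = 5, 1
    for caps in product(range(l + 1), repeat=5):
        if sum(caps) > l:
            continue
        for reqs in product(range(d + 2), repeat=3):
            key = ILPKey(*caps, *reqs)
            assert cache(key) == ilp_feasible(key)
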