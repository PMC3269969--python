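"""Brute-force reference implementations.

These are definition-level filters used by tests and acceptance checks as
independent ground truth; none of them prunes, anchors on pairs, or touches
the integer-feasibility machinery.  They refuse oversized inputs outright
rather than running slowly.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .neighborhood import enumerate_neighborhood
from .seqcore import DNA, Alphabet, ProblemInstance, extract_lmers, hamming_distance

#: Hard cap on the candidate space an oracle will scan.
MAX_CANDIDATES = 2_000_000

# Full 4^l enumeration is used up to this l; beyond it the candidate space is
# the union of window neighborhoods (every motif lies in one by definition).
_FULL_ENUM_MAX_L = 8


class OracleSizeError(ValueError):
    """The brute-force candidate space is too large to scan."""


def _encode_all(strings: list[str], alphabet: Alphabet) -> np.ndarray:
    lut = {c: i for i, c in enumerate(alphabet.symbols)}
    return np.array([[lut[c] for c in s] for s in strings], dtype=np.uint8)


def _min_dists(cand: np.ndarray, seq: str, alphabet: Alphabet) -> np.ndarray:
    """Min window Hamming distance of every candidate row against ``seq``."""
    lut = {c: i for i, c in enumerate(alphabet.symbols)}
    l = cand.shape[1]
    enc = np.array([lut.get(c, 255) for c in seq], dtype=np.uint8)
    wmat = np.lib.stride_tricks.sliding_window_view(enc, l)
    valid = ~(wmat == 255).any(axis=1)
    out = np.full(len(cand), l + 1, dtype=np.int64)
    if not valid.any():
        return out
    wmat = wmat[valid]
    for start in range(0, len(cand), 50_000):  # chunked: K x W x l bools
        block = cand[start : start + 50_000]
        d = (block[:, None, :] != wmat[None, :, :]).sum(axis=2).min(axis=1)
        out[start : start + 50_000] = d
    return out


def _candidate_space(
    seqs: list[str], l: int, d: int, alphabet: Alphabet
) -> list[str]:
    if alphabet.size**l <= min(MAX_CANDIDATES, alphabet.size**_FULL_ENUM_MAX_L):
        return ["".join(t) for t in product(alphabet.symbols, repeat=l)]
    cands: set[str] = set()
    for s in seqs:
        for _, x in extract_lmers(s, l, alphabet):
            cands |= enumerate_neighborhood(x, d, alphabet)
        if len(cands) > MAX_CANDIDATES:
            raise OracleSizeError(
                f"candidate space exceeds {MAX_CANDIDATES}; not desk-scale"
            )
    return sorted(cands)


def bruteforce_motifs(instance: ProblemInstance) -> set[str]:
    """M_{l,d}(S) = {r : every sequence has a window within distance d}."""
    l, d = instance.l, instance.d
    alphabet = instance.alphabet
    cands = _candidate_space([instance.sequences[0]], l, d, alphabet)
    enc = _encode_all(cands, alphabet)
    keep = np.ones(len(cands), dtype=bool)
    for s in instance.sequences:
        keep &= _min_dists(enc, s, alphabet) <= d
    return {c for c, k in zip(cands, keep) if k}


def bruteforce_quorum(instance: ProblemInstance) -> set[str]:
    """{r : at least q sequences have a window within distance d of r}."""
    l, d, q = instance.l, instance.d, instance.q
    alphabet = instance.alphabet
    cands = _candidate_space(list(instance.sequences), l, d, alphabet)
    enc = _encode_all(cands, alphabet)
    counts = np.zeros(len(cands), dtype=np.int64)
    for s in instance.sequences:
        counts += _min_dists(enc, s, alphabet) <= d
    return {c for c, k in zip(cands, counts >= q) if k}


def bruteforce_intersection(
    x: str, y: str, z: str, d: int, alphabet: Alphabet = DNA
) -> set[str]:
    """B_d(x, y, z) by filtering the enumerated B_d(x)."""
    if len(x) > 10:
        raise OracleSizeError("naive intersection limited to l <= 10")
    return {
        t
        for t in enumerate_neighborhood(x, d, alphabet)
        if hamming_distance(t, y) <= d and hamming_distance(t, z) <= d
    }
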