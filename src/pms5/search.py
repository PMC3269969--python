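"""Exact motif search drivers: the full-quorum search and the q-quorum variant.

The full search (``pms5_find``) finds every (l, d)-motif of S, i.e. every
l-mer within distance d of a window of *each* sequence.  It anchors on the
windows x of s1 (every motif lies in B_d(x) for some window x of s1),
partitions the remaining sequences into pairs (S1, ..., Sp), and for each
pair accumulates the candidate pool

    pool_k = union over windows (y, z) of the pair of  B_d(x, y, z)
           = B_d(x) ∩ M(S_k),

intersecting the pools across pairs into a running pool.  Once the running
pool is small enough (``threshold``), the loop breaks and the survivors are
verified against the sequences not yet consumed.  Correctness does not
depend on the threshold: the running pool after k pairs is always a superset
of the motifs within B_d(x), and verification filters it exactly.

The quorum variant (``qpms_find``) reports l-mers matching at least q of the
n sequences.  It iterates every index triple i < j < k; per triple the
candidate pool equals M({s_i}) ∩ M({s_j}) ∩ M({s_k}) (the union of
B_d(x, y, z) over all window triples), and each candidate is checked for
quorum membership with a global memo.  A literal per-window-triple FULLPRUNE
strategy is provided for cross-checking.

Both drivers skip window combinations whose pairwise distances exceed 2d:
by the triangle inequality the common neighborhood is then empty.  The
distance screens are vectorized with numpy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .fullprune import fullprune
from .neighborhood import enumerate_neighborhood
from .seqcore import DNA, Alphabet, ProblemInstance, extract_lmers, min_hamming

#: Default candidate-pool size below which the pairing loop stops early.
DEFAULT_THRESHOLD = 5000


@dataclass(frozen=True)
class MotifResult:
    """A reported motif with its per-sequence best matches.

    ``per_sequence`` holds one ``(offset, distance)`` per input sequence: the
    leftmost window achieving the minimum Hamming distance (offsets are
    0-based).  ``score`` is the sum of the per-sequence minimum distances --
    the simple ranking score, lower is better.
    """

    motif: str
    score: int
    per_sequence: tuple[tuple[int, int], ...]


def pair_partition(s_star: list[str]) -> list[tuple[str, str]]:
    """Partition s2..sn into consecutive pairs, duplicating the last if odd."""
    if not s_star:
        raise ValueError("cannot partition an empty sequence list")
    padded = list(s_star)
    if len(padded) % 2 == 1:
        padded.append(padded[-1])
    return [(padded[i], padded[i + 1]) for i in range(0, len(padded), 2)]


def verify_candidate(
    r: str, remaining: list[str] | tuple[str, ...], d: int,
    alphabet: Alphabet | None = None,
) -> bool:
    """True iff ``r`` is within distance d of every remaining sequence."""
    return all(min_hamming(r, s, alphabet) <= d for s in remaining)


def score_motif(m: str, sequences: list[str] | tuple[str, ...]) -> int:
    """Sum over sequences of the minimum window Hamming distance to ``m``."""
    if not sequences:
        raise ValueError("sequence set must be non-empty")
    return sum(min_hamming(m, s) for s in sequences)


# ---------------------------------------------------------------------------
# numpy window machinery


class _SeqWindows:
    """Encoded window matrix of one sequence, with invalid windows masked."""

    def __init__(self, seq: str, l: int, alphabet: Alphabet):
        lut = np.full(256, 255, dtype=np.uint8)
        for i, c in enumerate(alphabet.symbols):
            lut[ord(c)] = i
        enc = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        self.matrix = np.lib.stride_tricks.sliding_window_view(enc, l)
        self.valid = ~(self.matrix == 255).any(axis=1)
        self.strings = [seq[i : i + l] for i in range(len(seq) - l + 1)]
        self._lut = lut
        self.l = l

    def encode(self, x: str) -> np.ndarray:
        return self._lut[np.frombuffer(x.encode("ascii"), dtype=np.uint8)]

    def dists(self, x_enc: np.ndarray) -> np.ndarray:
        """Hamming distance of x to every window (invalid windows = l + 1)."""
        out = (self.matrix != x_enc).sum(axis=1)
        out[~self.valid] = self.l + 1
        return out

    def min_dist_and_offset(self, x_enc: np.ndarray) -> tuple[int, int]:
        dv = self.dists(x_enc)
        off = int(np.argmin(dv))  # argmin is the leftmost minimizer
        return int(dv[off]), off


def _build_results(
    motifs: set[str], instance: ProblemInstance, windows: list[_SeqWindows]
) -> list[MotifResult]:
    results = []
    for m in sorted(motifs):
        enc = windows[0].encode(m)
        # stored as (offset, distance); min_dist_and_offset returns (dist, off)
        per_seq = tuple((off, dist) for (dist, off) in
                        (w.min_dist_and_offset(enc) for w in windows))
        score = sum(dist for _, dist in per_seq)
        results.append(MotifResult(motif=m, score=score, per_sequence=per_seq))
    return results


def motif_strings(results: list[MotifResult]) -> list[str]:
    """The motifs of a result list, in reported (lexicographic) order."""
    return [r.motif for r in results]


# ---------------------------------------------------------------------------
# full-quorum search


def pms5_find(
    instance: ProblemInstance, threshold: int = DEFAULT_THRESHOLD
) -> list[MotifResult]:
    """All (l, d)-motifs of the instance, sorted lexicographically.

    ``threshold`` only tunes when the pairing loop hands over to
    verification; the reported set is identical for every positive value.
    """
    if threshold < 1:
        raise ValueError("threshold must be positive")
    l, d = instance.l, instance.d
    alphabet = instance.alphabet
    seqs = list(instance.sequences)
    windows = [_SeqWindows(s, l, alphabet) for s in seqs]

    if instance.n == 1:
        motifs: set[str] = set()
        for _, x in extract_lmers(seqs[0], l, alphabet):
            motifs |= enumerate_neighborhood(x, d, alphabet)
        return _build_results(motifs, instance, windows)

    s_star = seqs[1:]
    pairs = pair_partition(s_star)
    # Window tables for each pair member, mapped back to sequence indices so
    # the numpy matrices are shared with verification.
    pair_idx: list[tuple[int, int]] = []
    padded = s_star + ([s_star[-1]] if len(s_star) % 2 else [])
    for k in range(len(pairs)):
        pair_idx.append((1 + 2 * k, min(1 + 2 * k + 1, len(seqs) - 1)))

    cross_dist: dict[int, np.ndarray] = {}  # pair k -> window distance matrix

    def pair_cross(k: int) -> np.ndarray:
        if k not in cross_dist:
            ia, ib = pair_idx[k]
            wa, wb = windows[ia], windows[ib]
            m = (wa.matrix[:, None, :] != wb.matrix[None, :, :]).sum(axis=2)
            m[~wa.valid, :] = l + 1
            m[:, ~wb.valid] = l + 1
            cross_dist[k] = m
        return cross_dist[k]

    found: set[str] = set()
    seen_x: set[str] = set()
    for _, x in extract_lmers(seqs[0], l, alphabet):
        if x in seen_x:
            continue
        seen_x.add(x)
        x_enc = windows[0].encode(x)
        running: set[str] | None = None
        consumed = 0
        for k in range(len(pairs)):
            ia, ib = pair_idx[k]
            wa, wb = windows[ia], windows[ib]
            da = wa.dists(x_enc)
            db = wb.dists(x_enc)
            cand_a = np.nonzero(da <= 2 * d)[0]
            cand_b = np.nonzero(db <= 2 * d)[0]
            pool: set[str] = set()
            if cand_a.size and cand_b.size:
                cross = pair_cross(k)
                seen_yz: set[tuple[str, str]] = set()
                for i in cand_a:
                    yi = wa.strings[i]
                    row = cross[i]
                    for j in cand_b:
                        if row[j] > 2 * d:
                            continue
                        yz = (yi, wb.strings[j])
                        if yz in seen_yz:
                            continue
                        seen_yz.add(yz)
                        pool |= fullprune(x, yz[0], yz[1], d, alphabet).elements
            running = pool if running is None else (running & pool)
            consumed = min(2 * (k + 1), len(s_star))
            if len(running) < threshold:
                break
        assert running is not None
        if running:
            rem_windows = [windows[1 + i] for i in range(consumed, len(s_star))]
            for r in running:
                r_enc = windows[0].encode(r)
                if all(w.dists(r_enc).min() <= d for w in rem_windows):
                    found.add(r)
    return _build_results(found, instance, windows)


# ---------------------------------------------------------------------------
# quorum search


def _sequence_motif_set(
    seq: str, l: int, d: int, alphabet: Alphabet
) -> frozenset[str]:
    """M({s}) = union of B_d(x) over the windows x of s."""
    out: set[str] = set()
    for _, x in extract_lmers(seq, l, alphabet):
        out |= enumerate_neighborhood(x, d, alphabet)
    return frozenset(out)


def qpms_find(
    instance: ProblemInstance, strategy: str = "pooled"
) -> list[MotifResult]:
    """All l-mers within distance d of at least q of the n sequences.

    With q = n the output coincides with :func:`pms5_find` (computed
    independently, via the triple loop).  For q < 3 there are not enough
    sequences to anchor a triple, so candidates are drawn from the union of
    all per-sequence motif sets and filtered by quorum count directly.

    ``strategy`` selects how a triple's candidate pool is computed:
    ``"pooled"`` (default) uses the set identity
    union_{x,y,z} B_d(x,y,z) = M({s_i}) ∩ M({s_j}) ∩ M({s_k});
    ``"triples"`` runs FULLPRUNE per window triple (after triangle
    screening).  The two are output-identical; "triples" exists as the
    literal pseudocode path for cross-checking.
    """
    if strategy not in ("pooled", "triples"):
        raise ValueError(f"unknown strategy {strategy!r}")
    l, d, q, n = instance.l, instance.d, instance.q, instance.n
    alphabet = instance.alphabet
    seqs = list(instance.sequences)
    windows = [_SeqWindows(s, l, alphabet) for s in seqs]

    match_memo: dict[str, int] = {}

    def match_count(t: str) -> int:
        if t not in match_memo:
            enc = windows[0].encode(t)
            match_memo[t] = sum(int(w.dists(enc).min()) <= d for w in windows)
        return match_memo[t]

    found: set[str] = set()
    if q < 3 or n < 3:
        candidates: set[str] = set()
        for s in seqs:
            candidates |= _sequence_motif_set(s, l, d, alphabet)
        found = {t for t in candidates if match_count(t) >= q}
        return _build_results(found, instance, windows)

    if strategy == "pooled":
        motif_sets = [_sequence_motif_set(s, l, d, alphabet) for s in seqs]
        for i, j, k in combinations(range(n), 3):
            for t in motif_sets[i] & motif_sets[j] & motif_sets[k]:
                if t not in found and match_count(t) >= q:
                    found.add(t)
    else:
        for i, j, k in combinations(range(n), 3):
            wi, wj, wk = windows[i], windows[j], windows[k]
            dij = (wi.matrix[:, None, :] != wj.matrix[None, :, :]).sum(axis=2)
            for a, x in enumerate(wi.strings):
                if not wi.valid[a]:
                    continue
                x_enc = wi.encode(x)
                dk = wk.dists(x_enc)
                for b, y in enumerate(wj.strings):
                    if not wj.valid[b] or dij[a, b] > 2 * d:
                        continue
                    y_enc = wj.encode(y)
                    djk = wk.dists(y_enc)
                    for c in np.nonzero((dk <= 2 * d) & (djk <= 2 * d))[0]:
                        z = wk.strings[c]
                        for t in fullprune(x, y, z, d, alphabet).elements:
                            if t not in found and match_count(t) >= q:
                                found.add(t)
    return _build_results(found, instance, windows)
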