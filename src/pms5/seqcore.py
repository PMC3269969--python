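"""Core alphabet/sequence types and Hamming-distance primitives.

Everything in this package works on plain Python strings over a fixed,
ordered :class:`Alphabet` (DNA by default).  An "l-mer" is simply a string of
length ``l``; a "sequence" is any string of length >= ``l``.  The three
distance notions used throughout are:

* ``hamming_distance(a, b)`` -- mismatch count between equal-length strings;
* ``min_hamming(x, s)`` -- the minimum Hamming distance between l-mer ``x``
  and any length-``l`` window of sequence ``s`` (written d_H-bar(x, s));
* ``max_min_hamming(x, S)`` -- the maximum of ``min_hamming`` over a set of
  sequences (d_H-bar(x, S)).

An l-mer ``x`` is an (l, d)-motif of ``S`` exactly when
``max_min_hamming(x, S) <= d``.

Coordinates are 0-based internally; reported occurrence intervals are 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class AlphabetError(ValueError):
    """A string contains characters outside the declared alphabet."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of distinct symbols.

    The ordering is fixed and used for canonical enumeration order (e.g. the
    order in which neighborhood-tree children are generated).
    """

    symbols: str = "ACGT"

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __contains__(self, char: str) -> bool:
        return char in self.symbols

    def contains_string(self, s: str) -> bool:
        return all(c in self.symbols for c in s)

    def index(self, char: str) -> int:
        return self.symbols.index(char)

    def validate(self, s: str, name: str = "string") -> None:
        bad = sorted(set(s) - set(self.symbols))
        if bad:
            raise AlphabetError(
                f"{name} contains characters {bad!r} outside alphabet "
                f"{self.symbols!r}"
            )


#: The default DNA alphabet.
DNA = Alphabet("ACGT")

#: Binary alphabet, used for small worked examples and tests.
BINARY = Alphabet("01")


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(
            f"hamming_distance needs equal lengths, got {len(a)} and {len(b)}"
        )
    return sum(c1 != c2 for c1, c2 in zip(a, b))


def extract_lmers(
    s: str, l: int, alphabet: Alphabet | None = None
) -> list[tuple[int, str]]:
    """All length-``l`` windows of ``s``, left to right, as (offset, lmer).

    If ``alphabet`` is given, windows containing characters outside it (e.g.
    ``N`` in genomic data) are dropped.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    if l > len(s):
        raise ValueError(f"l={l} exceeds sequence length {len(s)}")
    out = [(i, s[i : i + l]) for i in range(len(s) - l + 1)]
    if alphabet is not None:
        out = [(i, w) for i, w in out if alphabet.contains_string(w)]
    return out


def min_hamming(x: str, s: str, alphabet: Alphabet | None = None) -> int:
    """Minimum Hamming distance between ``x`` and any window of ``s``.

    With ``alphabet`` set, windows containing foreign characters are skipped;
    if no valid window remains the result is ``len(x) + 1`` (a sentinel that
    compares greater than any mismatch budget).
    """
    l = len(x)
    windows = extract_lmers(s, l, alphabet)
    if not windows:
        return l + 1
    return min(hamming_distance(x, w) for _, w in windows)


def max_min_hamming(
    x: str, sequences: list[str] | tuple[str, ...], alphabet: Alphabet | None = None
) -> int:
    """d_H-bar(x, S): the worst per-sequence minimum distance."""
    if not sequences:
        raise ValueError("sequence set must be non-empty")
    return max(min_hamming(x, s, alphabet) for s in sequences)


@dataclass(frozen=True)
class ProblemInstance:
    """One planted-motif search problem: sequences plus (l, d) and quorum q.

    ``q`` defaults to ``n`` (the classic PMS problem: the motif must occur in
    every sequence).  Sequences are uppercased on construction and validated
    against the alphabet unless ``validate_alphabet`` is False, in which case
    windows containing foreign characters are silently unusable as motif
    occurrences.
    """

    sequences: tuple[str, ...]
    l: int
    d: int
    q: int | None = None
    alphabet: Alphabet = field(default=DNA)
    validate_alphabet: bool = True

    def __post_init__(self) -> None:
        seqs = tuple(s.upper() for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        if not seqs:
            raise ValueError("need at least one sequence")
        if self.l < 1:
            raise ValueError("l must be >= 1")
        shortest = min(len(s) for s in seqs)
        if self.l > shortest:
            raise ValueError(
                f"l={self.l} exceeds shortest sequence length {shortest}"
            )
        if not 0 <= self.d <= self.l:
            raise ValueError(f"d={self.d} must be in [0, l]")
        if self.q is None:
            object.__setattr__(self, "q", len(seqs))
        if not 1 <= self.q <= len(seqs):
            raise ValueError(f"q={self.q} must be in [1, n={len(seqs)}]")
        if self.validate_alphabet:
            for i, s in enumerate(seqs):
                self.alphabet.validate(s, name=f"sequence {i}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def m(self) -> int:
        """Length of the longest sequence (sequences may differ in length)."""
        return max(len(s) for s in self.sequences)

    def is_motif(self, x: str) -> bool:
        """Quorum-aware membership test: x matches >= q sequences within d."""
        alpha = None if self.validate_alphabet else self.alphabet
        hits = sum(
            min_hamming(x, s, alpha) <= self.d for s in self.sequences
        )
        return hits >= self.q
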