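"""Planted-instance benchmark generator (the FM model).

The standard benchmark for exact motif search: ``n`` background sequences of
length ``m`` drawn i.i.d. uniform over the DNA alphabet, a uniform random
motif of length ``l``, and in each sequence one occurrence of the motif --
mutated in exactly ``d`` positions -- written at a uniform random offset,
overwriting the background (sequence lengths stay ``m``).  The defaults
n=20, m=600 are the field's standard benchmark condition.

Exact-d mutation is the default; a relaxed mode mutates d positions to
uniformly random bases (possibly the original), giving occurrences within
distance *at most* d.

Determinism contract: one numpy RNG stream seeded from ``seed``, with the
draw order fixed as -- motif; then per sequence: background, offset, mutated
positions, substitutions.  Identical seeds give byte-identical instances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqcore import DNA, Alphabet, ProblemInstance, hamming_distance


@dataclass(frozen=True)
class PlantedInstance:
    """A generated benchmark instance with its ground truth."""

    sequences: tuple[str, ...]
    motif: str
    offsets: tuple[int, ...]
    mutated_positions: tuple[tuple[int, ...], ...]
    l: int
    d: int
    seed: int | None
    exact: bool
    alphabet: Alphabet = field(default=DNA)

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def m(self) -> int:
        return len(self.sequences[0])

    def occurrence(self, i: int) -> str:
        """The planted (mutated) occurrence in sequence i."""
        return self.sequences[i][self.offsets[i] : self.offsets[i] + self.l]

    def to_problem(self, q: int | None = None) -> ProblemInstance:
        return ProblemInstance(
            sequences=self.sequences, l=self.l, d=self.d, q=q,
            alphabet=self.alphabet,
        )

    def check(self) -> None:
        """Assert the planting contract on every sequence."""
        for i in range(self.n):
            dist = hamming_distance(self.motif, self.occurrence(i))
            if self.exact and dist != self.d:
                raise AssertionError(
                    f"sequence {i}: occurrence at distance {dist}, expected {self.d}"
                )
            if not self.exact and dist > self.d:
                raise AssertionError(
                    f"sequence {i}: occurrence at distance {dist} > d={self.d}"
                )


def generate_planted_instance(
    l: int,
    d: int,
    n: int = 20,
    m: int = 600,
    seed: int | None = None,
    exact: bool = True,
    alphabet: Alphabet = DNA,
) -> PlantedInstance:
    """Generate one planted (l, d) instance; see module docstring for model."""
    if not 1 <= l <= m:
        raise ValueError(f"need 1 <= l <= m, got l={l}, m={m}")
    if not 0 <= d <= l:
        raise ValueError(f"need 0 <= d <= l, got d={d}, l={l}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    syms = alphabet.symbols
    k = len(syms)

    motif = "".join(syms[i] for i in rng.integers(0, k, size=l))
    sequences: list[str] = []
    offsets: list[int] = []
    mutated: list[tuple[int, ...]] = []
    for _ in range(n):
        background = rng.integers(0, k, size=m)
        offset = int(rng.integers(0, m - l + 1))
        positions = sorted(int(p) for p in rng.choice(l, size=d, replace=False))
        occ = [alphabet.index(c) for c in motif]
        for p in positions:
            if exact:
                # draw from the k-1 symbols other than the current one
                shift = int(rng.integers(1, k))
                occ[p] = (occ[p] + shift) % k
            else:
                occ[p] = int(rng.integers(0, k))
        background[offset : offset + l] = occ
        sequences.append("".join(syms[i] for i in background))
        offsets.append(offset)
        mutated.append(tuple(positions))

    inst = PlantedInstance(
        sequences=tuple(sequences),
        motif=motif,
        offsets=tuple(offsets),
        mutated_positions=tuple(mutated),
        l=l,
        d=d,
        seed=seed,
        exact=exact,
        alphabet=alphabet,
    )
    inst.check()
    return inst


def write_instance(
    instance: PlantedInstance, fasta_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    """Write the sequences as multi-FASTA plus a JSON ground-truth sidecar.

    FASTA headers carry the sequence index and plant offset.  The sidecar
    (default: ``<fasta>.json``) records motif, offsets, mutated positions,
    seed and parameters so test harnesses can recover the ground truth.
    """
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        for i, s in enumerate(instance.sequences):
            fh.write(f">seq{i} offset={instance.offsets[i]}\n")
            for j in range(0, len(s), 70):
                fh.write(s[j : j + 70] + "\n")
    meta = {
        "motif": instance.motif,
        "offsets": list(instance.offsets),
        "mutated_positions": [list(p) for p in instance.mutated_positions],
        "l": instance.l,
        "d": instance.d,
        "seed": instance.seed,
        "exact": instance.exact,
        "alphabet": instance.alphabet.symbols,
    }
    meta_path = Path(meta_path) if meta_path else fasta_path.with_suffix(
        fasta_path.suffix + ".json"
    )
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_instance(
    fasta_path: str | Path, meta_path: str | Path | None = None
) -> PlantedInstance:
    """Read back an instance written by :func:`write_instance` and verify it."""
    from .io import read_fasta

    fasta_path = Path(fasta_path)
    meta_path = Path(meta_path) if meta_path else fasta_path.with_suffix(
        fasta_path.suffix + ".json"
    )
    with open(meta_path) as fh:
        meta = json.load(fh)
    alphabet = Alphabet(meta["alphabet"])
    sequences = tuple(read_fasta(fasta_path, alphabet=alphabet))
    inst = PlantedInstance(
        sequences=sequences,
        motif=meta["motif"],
        offsets=tuple(meta["offsets"]),
        mutated_positions=tuple(tuple(p) for p in meta["mutated_positions"]),
        l=meta["l"],
        d=meta["d"],
        seed=meta["seed"],
        exact=meta["exact"],
        alphabet=alphabet,
    )
    inst.check()
    return inst
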