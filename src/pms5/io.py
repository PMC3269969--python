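"""FASTA input/output."""

from __future__ import annotations

import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import DNA, Alphabet


def read_fasta(
    path: str | Path,
    alphabet: Alphabet | None = DNA,
    on_invalid: str = "error",
) -> list[str]:
    """Sequences of a multi-FASTA file, in file order, uppercased.

    ``on_invalid`` controls characters outside the alphabet: ``"error"``
    raises; ``"keep"`` passes them through (downstream code then drops the
    windows containing them).  Unequal record lengths are accepted with a
    warning -- the search only needs each sequence to be at least l long.
    """
    if on_invalid not in ("error", "keep"):
        raise ValueError(f"on_invalid must be 'error' or 'keep', got {on_invalid!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seqs = [str(r.seq).upper() for r in records]
    if alphabet is not None and on_invalid == "error":
        for rec, s in zip(records, seqs):
            alphabet.validate(s, name=f"record {rec.id!r}")
    if len({len(s) for s in seqs}) > 1:
        warnings.warn(f"records in {path} have unequal lengths", stacklevel=2)
    return seqs


def write_fasta(
    sequences: list[str] | tuple[str, ...],
    path: str | Path,
    ids: list[str] | None = None,
) -> None:
    if ids is None:
        ids = [f"seq{i}" for i in range(len(sequences))]
    records = [
        SeqRecord(Seq(s), id=name, description="")
        for name, s in zip(ids, sequences)
    ]
    SeqIO.write(records, str(path), "fasta")
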