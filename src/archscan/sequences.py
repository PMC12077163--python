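"""Ungapped domain sequences with provenance coordinates in their parent protein.

Coordinates are 1-based and spans are inclusive throughout the package, so a
span (280, 310) covers 31 residues.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import AMINO_ACIDS, UNKNOWN

_VALID = set(AMINO_ACIDS) | {UNKNOWN}


class SequenceError(ValueError):
    """Raised for malformed domain sequences or spans."""


def span_length(start: int, end: int) -> int:
    """Number of residues in the 1-based inclusive span ``start..end``.

    ``span_length(280, 310) == 31``; ``end < start`` is a domain error.
    """
    if end < start:
        raise SequenceError(f"span end {end} precedes start {start}")
    return end - start + 1


@dataclass(frozen=True)
class DomainSequence:
    """One ungapped domain sequence, optionally located in its parent protein.

    ``parent_span`` gives the 1-based inclusive positions of the domain in the
    full-length protein (e.g. the VosA velvet domain occupies 22-186 of AN1959).
    """

    id: str
    residues: str
    parent_span: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.residues:
            raise SequenceError(f"{self.id}: empty sequence")
        bad = set(self.residues) - _VALID
        if bad:
            raise SequenceError(f"{self.id}: invalid residues {sorted(bad)}")
        if self.parent_span is not None:
            start, end = self.parent_span
            if span_length(start, end) != len(self.residues):
                raise SequenceError(
                    f"{self.id}: parent_span {self.parent_span} does not cover "
                    f"{len(self.residues)} residues"
                )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[DomainSequence]:
    """Read unaligned domain sequences from FASTA.

    A trailing ``/start-end`` in the identifier (the Pfam convention) is parsed
    into ``parent_span``.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, span = _split_span(rec.id)
        out.append(DomainSequence(name, str(rec.seq).upper(), span))
    if not out:
        raise SequenceError(f"{path}: no sequences found")
    return out


def write_fasta(seqs: Iterable[DomainSequence], path: str | Path) -> None:
    records = []
    for s in seqs:
        name = s.id
        if s.parent_span is not None:
            name = f"{s.id}/{s.parent_span[0]}-{s.parent_span[1]}"
        records.append(SeqRecord(Seq(s.residues), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def _split_span(name: str) -> tuple[str, tuple[int, int] | None]:
    if "/" in name:
        stem, _, tail = name.rpartition("/")
        parts = tail.split("-")
        if stem and len(parts) == 2 and all(p.isdigit() for p in parts):
            return stem, (int(parts[0]), int(parts[1]))
    return name, None
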