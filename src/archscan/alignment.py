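"""Alignment model with match/insert column annotation and coordinate maps.

The central object is :class:`MatchAlignment`: rows over a shared column list
in which every column is labelled *match* (a consensus position of the domain
model) or *insert* (residues outside the consensus).  Conservation scoring and
architecture segmentation operate on match columns only; insert residues are
retained as per-row counts between match columns because region lengths are
measured on the ungapped sequence.

Conventions (fixed, Pfam/Stockholm style):

* match columns hold uppercase residues or ``-`` (deletion);
* insert columns hold lowercase residues or ``.`` (not present);
* Stockholm files carry the match annotation as ``#=GC RF`` with ``x`` for
  match and ``.`` for insert columns;
* all public coordinates are 1-based; spans are inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import AMINO_ACIDS, UNKNOWN

_MATCH_CHARS = set(AMINO_ACIDS) | {UNKNOWN, "-"}
_INSERT_CHARS = {c.lower() for c in AMINO_ACIDS} | {UNKNOWN.lower(), "."}


class AlignmentFormatError(ValueError):
    """Raised when an alignment file cannot be interpreted."""


class AlignmentError(ValueError):
    """Raised for structurally invalid alignments."""


class MatchAlignment:
    """Aligned rows over columns labelled match or insert.

    Parameters
    ----------
    ids, rows:
        Row identifiers and aligned strings (all the same length).
    col_is_match:
        One boolean per column.
    insert_counts:
        Optional, only meaningful when the alignment holds match columns only
        (after :func:`strip_insert_columns`): for each row a mapping
        ``slot -> count`` of insert residues, where slot *k* lies between
        match columns *k* and *k+1* (slot 0 precedes the first match column).
    """

    def __init__(self, ids, rows, col_is_match, insert_counts=None):
        self.ids = list(ids)
        self.rows = list(rows)
        self.col_is_match = list(col_is_match)
        self.insert_counts = (
            [dict(d) for d in insert_counts] if insert_counts is not None else None
        )
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no rows")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate row identifiers")
        ncol = len(self.col_is_match)
        for rid, row in zip(self.ids, self.rows):
            if len(row) != ncol:
                raise AlignmentError(
                    f"row {rid!r} spans {len(row)} columns, expected {ncol}"
                )
        for j, is_match in enumerate(self.col_is_match):
            allowed = _MATCH_CHARS if is_match else _INSERT_CHARS
            for rid, row in zip(self.ids, self.rows):
                if row[j] not in allowed:
                    kind = "match" if is_match else "insert"
                    raise AlignmentError(
                        f"row {rid!r}: character {row[j]!r} invalid in {kind} "
                        f"column {j + 1}"
                    )
        if self.insert_counts is not None:
            if any(not m for m in self.col_is_match):
                raise AlignmentError(
                    "insert_counts only apply to match-column-only alignments"
                )
            if len(self.insert_counts) != len(self.rows):
                raise AlignmentError("insert_counts and rows differ in number")
            nm = self.n_match_columns
            for rid, d in zip(self.ids, self.insert_counts):
                for slot, count in d.items():
                    if not 0 <= slot <= nm:
                        raise AlignmentError(f"row {rid!r}: insert slot {slot} out of range")
                    if count < 0:
                        raise AlignmentError(f"row {rid!r}: negative insert count")

    # -- basic views ----------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.col_is_match)

    @property
    def n_match_columns(self) -> int:
        return sum(self.col_is_match)

    @property
    def match_column_positions(self) -> list[int]:
        """Full-alignment column indices (1-based) of the match columns."""
        return [j + 1 for j, m in enumerate(self.col_is_match) if m]

    def row_index(self, row_id: str) -> int:
        try:
            return self.ids.index(row_id)
        except ValueError:
            raise KeyError(f"row {row_id!r} not in alignment") from None

    def ungapped(self, i: int) -> str:
        """Residues of row *i* in order (insert residues uppercased)."""
        return "".join(c.upper() for c in self.rows[i] if c.isalpha())

    def ungapped_length(self, i: int) -> int:
        n = sum(1 for c in self.rows[i] if c.isalpha())
        if self.insert_counts is not None:
            n += sum(self.insert_counts[i].values())
        return n

    def occupancy_map(self, i: int) -> dict[int, int]:
        """Map column (1-based, full column list) -> residue position (1-based).

        Covers every column occupancy of row *i* (match and insert); each
        residue of the row appears in exactly one occupancy, and positions are
        strictly increasing with the column index (colinearity).
        """
        out: dict[int, int] = {}
        pos = 0
        for j, c in enumerate(self.rows[i]):
            if c.isalpha():
                pos += 1
                out[j + 1] = pos
        return out

    def match_column(self, c: int) -> str:
        """Symbols of match column *c* (1-based among match columns)."""
        j = self.match_column_positions[c - 1] - 1
        return "".join(row[j] for row in self.rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MatchAlignment):
            return NotImplemented
        mine = self.insert_counts or [{} for _ in self.rows]
        theirs = other.insert_counts or [{} for _ in other.rows]
        norm = lambda ds: [{k: v for k, v in d.items() if v} for d in ds]
        return (
            self.ids == other.ids
            and self.rows == other.rows
            and self.col_is_match == other.col_is_match
            and norm(mine) == norm(theirs)
        )

    def __repr__(self) -> str:
        return (
            f"MatchAlignment({self.n_rows} rows, {self.n_columns} columns, "
            f"{self.n_match_columns} match)"
        )


def strip_insert_columns(a: MatchAlignment) -> MatchAlignment:
    """Drop insert columns, recording per-row insert residues as slot counts.

    Slot *k* counts insert residues between match columns *k* and *k+1*
    (slot 0 before the first, slot ``n_match`` after the last).  Residues are
    conserved: match occupancies plus insert counts equal the ungapped length
    of every row.  An alignment without insert columns is returned unchanged
    (empty counts).
    """
    if a.insert_counts is not None:
        return a
    match_js = [j for j, m in enumerate(a.col_is_match) if m]
    # slot index for each insert column = number of match columns before it
    slot_of: list[int] = []
    nseen = 0
    for j, m in enumerate(a.col_is_match):
        if m:
            nseen += 1
        else:
            slot_of.append(nseen)
    insert_js = [j for j, m in enumerate(a.col_is_match) if not m]
    new_rows = []
    counts = []
    for row in a.rows:
        new_rows.append("".join(row[j] for j in match_js))
        d: dict[int, int] = {}
        for j, slot in zip(insert_js, slot_of):
            if row[j].isalpha():
                d[slot] = d.get(slot, 0) + 1
        counts.append(d)
    return MatchAlignment(a.ids, new_rows, [True] * len(match_js), counts)


# -- reference maps -----------------------------------------------------------


@dataclass(frozen=True)
class ReferenceMap:
    """Bijection between a reference protein's residue numbers and match columns.

    Residue numbers are 1-based positions in the parent protein; columns are
    1-based match-column indices.  Only match-assigned residues of the
    reference row appear (insert residues consume numbering but map to no
    column; deleted columns map to no residue).
    """

    reference_id: str
    residue_to_column: dict[int, int]
    column_to_residue: dict[int, int]
    column_to_letter: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        inv = {c: r for r, c in self.residue_to_column.items()}
        if inv != self.column_to_residue:
            raise AlignmentError("reference map directions are not mutual inverses")
        residues = sorted(self.residue_to_column)
        cols = [self.residue_to_column[r] for r in residues]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise AlignmentError("reference map is not colinear")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\tcolumn\n")
            for r in sorted(self.residue_to_column):
                fh.write(f"{r}\t{self.residue_to_column[r]}\n")


def build_reference_map(
    a: MatchAlignment, reference_id: str, parent_offset: int = 1
) -> ReferenceMap:
    """Map the reference row's residue numbers to match columns.

    ``parent_offset`` is the parent-protein position of the row's first
    residue (insert residues included in the numbering).
    """
    i = a.row_index(reference_id)
    row = a.rows[i]
    if UNKNOWN in row or UNKNOWN.lower() in row:
        raise AlignmentError(f"reference row {reference_id!r} contains X")
    r2c: dict[int, int] = {}
    letters: dict[int, str] = {}
    pos = 0  # residues consumed, inserts included
    mcol = 0
    for j, c in enumerate(row):
        is_match = a.col_is_match[j]
        if is_match:
            mcol += 1
        if c.isalpha():
            pos += 1
            if is_match:
                number = parent_offset + pos - 1
                r2c[number] = mcol
                letters[mcol] = c.upper()
    if a.insert_counts is not None:
        # stripped alignment: insert residues still advance the numbering
        r2c2: dict[int, int] = {}
        letters = {}
        pos = 0
        counts = a.insert_counts[i]
        for mcol in range(1, a.n_match_columns + 1):
            pos += counts.get(mcol - 1, 0)
            c = a.rows[i][mcol - 1]
            if c.isalpha():
                pos += 1
                r2c2[parent_offset + pos - 1] = mcol
                letters[mcol] = c.upper()
        r2c = r2c2
    c2r = {c: r for r, c in r2c.items()}
    return ReferenceMap(reference_id, r2c, c2r, letters)


# -- I/O ----------------------------------------------------------------------


def _normalize(rows: list[str], col_is_match: list[bool], ids) -> list[str]:
    out = []
    for rid, row in zip(ids, rows):
        chars = []
        for c, m in zip(row, col_is_match):
            if m:
                chars.append("-" if c in ".-" else c.upper())
            else:
                chars.append("." if c in ".-" else c.lower())
        out.append("".join(chars))
    return out


def read_alignment(path: str | Path, dialect: str | None = None) -> MatchAlignment:
    """Read a match-annotated alignment.

    ``dialect`` is ``"stockholm"`` or ``"aligned_fasta"``; inferred from the
    file extension (.sto/.stk vs .fasta/.fa/.afa) when omitted.  Stockholm
    must carry a ``#=GC RF`` line (x/. convention); aligned FASTA encodes
    match columns as uppercase/``-`` and insert columns as lowercase/``.``.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "stockholm":
        return _read_stockholm(path)
    if dialect == "aligned_fasta":
        return _read_aligned_fasta(path)
    raise AlignmentFormatError(f"unknown dialect {dialect!r}")


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".sto", ".stk", ".stockholm"}:
        return "stockholm"
    if suffix in {".fasta", ".fa", ".afa", ".aln"}:
        return "aligned_fasta"
    raise AlignmentFormatError(f"cannot infer alignment dialect from {path.name!r}")


def _read_stockholm(path: Path) -> MatchAlignment:
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    rf = aln.column_annotations.get("reference_annotation")
    if rf is None:
        raise AlignmentFormatError(f"{path}: missing #=GC RF match annotation")
    col_is_match = [c not in ".~" for c in rf]
    ids = [rec.id for rec in aln]
    rows = _normalize([str(rec.seq) for rec in aln], col_is_match, ids)
    return MatchAlignment(ids, rows, col_is_match)


def _read_aligned_fasta(path: Path) -> MatchAlignment:
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq) for rec in aln]
    ncol = len(rows[0])
    col_is_match = []
    for j in range(ncol):
        column = [row[j] for row in rows]
        upper = any(c.isupper() or c == "-" for c in column)
        lower = any(c.islower() or c == "." for c in column)
        if upper and lower:
            raise AlignmentFormatError(
                f"{path}: column {j + 1} mixes match (upper/-) and insert "
                f"(lower/.) characters"
            )
        col_is_match.append(upper)
    rows = _normalize(rows, col_is_match, ids)
    return MatchAlignment(ids, rows, col_is_match)


def write_alignment(a: MatchAlignment, path: str | Path, dialect: str | None = None) -> None:
    """Write an alignment; round-trips losslessly through :func:`read_alignment`.

    Insert-count annotations of stripped alignments are not serialized; write
    the full alignment when inserts must survive a round trip.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "stockholm":
        records = [
            SeqRecord(Seq(row), id=rid, description="") for rid, row in zip(a.ids, a.rows)
        ]
        aln = MultipleSeqAlignment(records)
        aln.column_annotations["reference_annotation"] = "".join(
            "x" if m else "." for m in a.col_is_match
        )
        AlignIO.write(aln, str(path), "stockholm")
    elif dialect == "aligned_fasta":
        with open(path, "w") as fh:
            for rid, row in zip(a.ids, a.rows):
                fh.write(f">{rid}\n{row}\n")
    else:
        raise AlignmentFormatError(f"unknown dialect {dialect!r}")
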