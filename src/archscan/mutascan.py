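"""Alanine-scan planning and cross-protein residue correspondence.

Conserved-column calls are turned into an ordered list of X->A substitution
candidates on a chosen reference protein (the way the velvet study replaced
each of the 30 conserved dimerization residues of VelB by alanine), and
reference maps of several proteins over the same alignment are joined into a
correspondence table (e.g. VelB G240 <-> VosA G96 <-> VeA G83).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .alignment import ReferenceMap
from .architecture import ArchitectureTemplate
from .conservation import ConservationProfile, call_conserved


class ScanError(ValueError):
    """Raised for invalid scan-planning inputs."""


@dataclass(frozen=True)
class MutagenesisCandidate:
    """One proposed X->A substitution on the reference protein.

    Native alanines are never candidates (they are skipped, not 'substituted');
    glycines and every other residue are retained, matching the G->A exchanges
    of the study.  ``consensus_mismatch`` flags reference residues that differ
    from the column consensus (references can diverge, as VeA's I180 does from
    the leucine consensus).
    """

    residue_number: int
    wild_type: str
    region: str
    column: int
    bits: float
    identity_pct: float
    substitution: str = "A"
    consensus_mismatch: bool = False


def plan_alanine_scan(
    cp: ConservationProfile,
    rm: ReferenceMap,
    template: ArchitectureTemplate,
    regions: tuple[str, ...] = ("alpha", "beta"),
    bits_threshold: float | None = None,
) -> list[MutagenesisCandidate]:
    """Candidates = conserved columns inside the named regions, mapped onto the
    reference residue numbering; unmapped (deleted) columns and native alanines
    are excluded; ordered by residue number.  An empty plan is not an error.
    """
    for name in regions:
        template.region(name)  # raises on unknown region
    if template.n_columns != cp.n_columns:
        raise ScanError(
            f"template covers {template.n_columns} columns, profile has {cp.n_columns}"
        )
    wanted = set()
    for name in regions:
        wanted.update(template.columns_of(name))
    candidates = []
    for col in call_conserved(cp, bits_threshold):
        if col not in wanted:
            continue
        residue_number = rm.column_to_residue.get(col)
        if residue_number is None:
            continue
        wt = rm.column_to_letter.get(col, "?")
        if wt == "A":
            continue
        consensus_res = cp.consensus[col - 1][0]
        candidates.append(
            MutagenesisCandidate(
                residue_number=residue_number,
                wild_type=wt,
                region=template.region_of_column(col),
                column=col,
                bits=float(cp.bits[col - 1]),
                identity_pct=100.0 * cp.identity_fraction(col, wt),
                consensus_mismatch=wt != consensus_res,
            )
        )
    return sorted(candidates, key=lambda c: c.residue_number)


def plan_to_frame(plan: list[MutagenesisCandidate]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "residue": c.residue_number,
                "wt": c.wild_type,
                "region": c.region,
                "column": c.column,
                "bits": c.bits,
                "identity_pct": c.identity_pct,
                "substitution": c.substitution,
                "consensus_mismatch": c.consensus_mismatch,
            }
            for c in plan
        ],
        columns=[
            "residue", "wt", "region", "column", "bits", "identity_pct",
            "substitution", "consensus_mismatch",
        ],
    )


@dataclass(frozen=True)
class CorrespondenceRow:
    """Residue correspondence of several reference proteins at one column.

    ``entries`` maps reference id -> (residue number, residue letter); a
    reference with a deletion at the column is reported as absent (None).
    """

    column: int
    entries: dict


def correspondence_table(
    maps: list[ReferenceMap], columns: list[int]
) -> list[CorrespondenceRow]:
    """One row per requested match column with each reference's residue."""
    if not maps:
        raise ScanError("at least one reference map required")
    max_col = max(max(m.column_to_residue, default=0) for m in maps)
    rows = []
    for col in columns:
        if col < 1 or col > max_col:
            raise ScanError(f"column {col} outside alignment columns 1..{max_col}")
        entries = {}
        for m in maps:
            num = m.column_to_residue.get(col)
            if num is None:
                entries[m.reference_id] = None
            else:
                entries[m.reference_id] = (num, m.column_to_letter.get(col, "?"))
        rows.append(CorrespondenceRow(column=col, entries=entries))
    return rows


def correspondence_to_frame(rows: list[CorrespondenceRow]) -> pd.DataFrame:
    ids = sorted({rid for row in rows for rid in row.entries})
    records = []
    for row in rows:
        rec = {"column": row.column}
        for rid in ids:
            entry = row.entries.get(rid)
            rec[f"{rid}_residue"] = entry[0] if entry else None
            rec[f"{rid}_aa"] = entry[1] if entry else None
        records.append(rec)
    return pd.DataFrame.from_records(records)
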