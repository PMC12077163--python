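"""Segmentation of the conservation profile into the velvet architecture.

The velvet domain decomposes into five ordered regions over match columns:
an N-terminal DNA-binding region, a poorly conserved variable region, and a
C-terminal dimerization region made of an alpha-subunit and a beta-subunit
separated by a flexible linker.  Segmentation thresholds the smoothed JSD
track: the two above-threshold super-blocks are the DNA-binding and
dimerization regions, the span between them is the variable region, and the
lowest-conservation internal valley of the dimerization block is the linker.

Region lengths are measured on the ungapped sequence: match occupancies
inside the region plus insert residues attached between its match columns,
so variable regions can reach hundreds of residues although the match-column
span is fixed, and a fully deleted region has length 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import MatchAlignment, strip_insert_columns
from .conservation import ConservationProfile

REGION_ORDER = ("dna_binding", "variable", "alpha", "linker", "beta")


class SegmentationError(RuntimeError):
    """Raised when the conservation track does not yield the expected blocks."""

    def __init__(self, message: str, runs=None):
        super().__init__(message)
        self.runs = runs or []


class TemplateError(ValueError):
    """Raised for invalid architecture templates."""


@dataclass(frozen=True)
class Region:
    """1-based inclusive match-column span; empty iff ``end == start - 1``."""

    name: str
    start: int
    end: int

    @property
    def n_columns(self) -> int:
        return self.end - self.start + 1

    @property
    def empty(self) -> bool:
        return self.end == self.start - 1


@dataclass(frozen=True)
class ArchitectureTemplate:
    """Ordered regions jointly covering all match columns."""

    regions: tuple[Region, ...]
    provenance: str = "inferred"  # or "user-supplied"

    def __post_init__(self):
        names = tuple(r.name for r in self.regions)
        if names != REGION_ORDER:
            raise TemplateError(f"regions must be {REGION_ORDER} in order, got {names}")
        pos = 0
        for r in self.regions:
            if r.end < r.start - 1:
                raise TemplateError(f"{r.name}: invalid span {r.start}..{r.end}")
            if r.start != pos + 1:
                raise TemplateError(
                    f"{r.name} starts at column {r.start}, expected {pos + 1} "
                    "(regions must tile the columns without gap or overlap)"
                )
            pos = max(pos, r.end)
        if pos < 1:
            raise TemplateError("template covers no columns")

    @property
    def n_columns(self) -> int:
        return self.regions[-1].end

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise TemplateError(f"unknown region {name!r}")

    def columns_of(self, name: str) -> range:
        r = self.region(name)
        return range(r.start, r.end + 1)

    def region_of_column(self, column: int) -> str:
        for r in self.regions:
            if r.start <= column <= r.end:
                return r.name
        raise TemplateError(f"column {column} outside template")

    @classmethod
    def from_spans(cls, spans: dict[str, tuple[int, int]], provenance="user-supplied"):
        regions = tuple(Region(n, *spans[n]) for n in REGION_ORDER)
        return cls(regions, provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [r.name for r in self.regions],
                "start_column": [r.start for r in self.regions],
                "end_column": [r.end for r in self.regions],
                "n_columns": [r.n_columns for r in self.regions],
                "provenance": self.provenance,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SegmentationParams:
    """Knobs of the threshold-and-valley segmentation."""

    tau: float | None = None      # global threshold; None = percentile midpoint rule
    percentile_lo: float = 20.0
    percentile_hi: float = 80.0
    merge_gap: int = 5            # merge above-threshold runs closer than this
    min_block: int = 10           # discard runs shorter than this
    valley_width: int = 5         # minimal linker valley width

    def validate(self) -> "SegmentationParams":
        if self.merge_gap < 0 or self.min_block < 1 or self.valley_width < 1:
            raise TemplateError("segmentation parameters out of range")
        if not 0 <= self.percentile_lo < self.percentile_hi <= 100:
            raise TemplateError("percentiles must satisfy 0 <= lo < hi <= 100")
        return self


def _runs_above(track: np.ndarray, tau: float) -> list[tuple[int, int]]:
    runs = []
    start = None
    for j, v in enumerate(track):
        if v > tau and start is None:
            start = j
        elif v <= tau and start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, len(track) - 1))
    return runs


def _merge_runs(runs, gap: int):
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(list(run))
    return [tuple(r) for r in merged]


def segment_regions(
    cp: ConservationProfile, params: SegmentationParams | None = None
) -> ArchitectureTemplate:
    """Infer the five-region architecture from the smoothed JSD track.

    Exactly two above-threshold super-blocks are expected (DNA-binding, then
    dimerization); anything else raises :class:`SegmentationError` carrying
    the run list, in which case a user-supplied template can be imposed
    instead.  Leading/trailing columns outside the super-blocks are absorbed
    into the flanking region so the template tiles all match columns.
    """
    params = (params or SegmentationParams()).validate()
    if cp.n_columns < 50:
        raise SegmentationError(f"profile too short to segment ({cp.n_columns} columns)")
    track = cp.jsd_smoothed
    if params.tau is not None:
        tau = params.tau
    else:
        lo = np.percentile(track, params.percentile_lo)
        hi = np.percentile(track, params.percentile_hi)
        tau = 0.5 * (lo + hi)
    runs = _merge_runs(_runs_above(track, tau), params.merge_gap)
    runs = [r for r in runs if r[1] - r[0] + 1 >= params.min_block]
    if len(runs) != 2:
        raise SegmentationError(
            f"expected 2 conserved super-blocks, found {len(runs)} "
            f"(tau={tau:.4g})",
            runs=[(a + 1, b + 1) for a, b in runs],
        )
    (s1, e1), (s2, e2) = runs
    s1, e2 = 0, cp.n_columns - 1  # absorb profile ends into the outer blocks

    # split the dimerization block at its lowest internal valley
    block = track[s2 : e2 + 1]
    lo = np.percentile(block, params.percentile_lo)
    hi = np.percentile(block, params.percentile_hi)
    tau2 = 0.5 * (lo + hi)
    valleys = [
        (a, b)
        for a, b in _runs_above(-block, -tau2)  # runs strictly below tau2
        if b - a + 1 >= params.valley_width and a > 0 and b < len(block) - 1
    ]
    if not valleys:
        raise SegmentationError(
            "no internal valley wide enough to place the linker",
            runs=[(s2 + 1, e2 + 1)],
        )
    means = [block[a : b + 1].mean() for a, b in valleys]
    va, vb = valleys[int(np.argmin(means))]

    return ArchitectureTemplate(
        regions=(
            Region("dna_binding", s1 + 1, e1 + 1),
            Region("variable", e1 + 2, s2),
            Region("alpha", s2 + 1, s2 + va),
            Region("linker", s2 + va + 1, s2 + vb + 1),
            Region("beta", s2 + vb + 2, e2 + 1),
        ),
        provenance="inferred",
    )


def region_lengths(a: MatchAlignment, t: ArchitectureTemplate) -> pd.DataFrame:
    """Per-sequence, per-region residue counts.

    Counts match occupancies in the region's columns plus insert residues in
    slots strictly between its match columns; boundary slots are assigned to
    the region of the match column on their left (slot 0 to the first
    region), so region lengths sum to the ungapped sequence length.
    """
    a = strip_insert_columns(a)
    if t.n_columns != a.n_match_columns:
        raise TemplateError(
            f"template covers {t.n_columns} columns, alignment has "
            f"{a.n_match_columns}"
        )
    records = []
    for i, rid in enumerate(a.ids):
        row = a.rows[i]
        counts = a.insert_counts[i] if a.insert_counts else {}
        for r in t.regions:
            length = sum(1 for j in range(r.start - 1, r.end) if row[j].isalpha())
            for slot, cnt in counts.items():
                owner = max(slot, 1)  # slot 0 belongs to the first region
                if r.start <= owner <= r.end:
                    length += cnt
            records.append({"sequence_id": rid, "region": r.name, "length": length})
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class LengthDistribution:
    """Binned residue-length distribution of one region (left-closed bins)."""

    region: str
    edges: np.ndarray       # bin edges; bin i covers [edges[i], edges[i+1])
    counts: np.ndarray
    percentages: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.edges[:-1].astype(int),
                "bin_hi": self.edges[1:].astype(int),
                "count": self.counts.astype(int),
                "percent": self.percentages,
            }
        )


@dataclass(frozen=True)
class RangeMass:
    """Fraction of sequences whose region length lies in the inclusive [lo, hi]."""

    region: str
    lo: int
    hi: int
    n: int
    fraction: float

    @property
    def percent(self) -> int:
        return int(round(100.0 * self.fraction))


DEFAULT_BIN_WIDTH = {"variable": 20, "linker": 5}


def length_distribution(
    records: pd.DataFrame,
    region: str,
    bin_width: int | None = None,
    range_of_interest: tuple[int, int] | None = None,
):
    """Bin the lengths of one region; optionally report an inclusive range mass.

    Returns ``(LengthDistribution, RangeMass | None)``.  Bins are left-closed,
    right-open, of the given width starting at 0 (defaults: 20 for the
    variable region, 5 for the linker, 10 otherwise).
    """
    lengths = records.loc[records["region"] == region, "length"].to_numpy()
    if lengths.size == 0:
        raise TemplateError(f"no records for region {region!r}")
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTH.get(region, 10)
    top = (int(lengths.max()) // bin_width + 1) * bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    dist = LengthDistribution(
        region=region,
        edges=edges,
        counts=counts,
        percentages=100.0 * counts / lengths.size,
    )
    mass = None
    if range_of_interest is not None:
        lo, hi = range_of_interest
        frac = float(np.mean((lengths >= lo) & (lengths <= hi)))
        mass = RangeMass(region, lo, hi, lengths.size, frac)
    return dist, mass
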