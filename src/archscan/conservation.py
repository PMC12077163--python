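"""Per-column conservation scoring of a match alignment.

For every match column the scorer computes the residue frequency distribution,
the Jensen-Shannon divergence (JSD) against a background distribution, a
gap-penalized and window-smoothed variant of the JSD, the information content
in bits, and the consensus residue with its identity fraction.

JSD is the bounded, symmetrized divergence

    JS_lambda(p, q) = lambda * KL(p || m) + (1 - lambda) * KL(q || m),
    m = lambda * p + (1 - lambda) * q,

with logarithms base 2, so scores lie in [0, 1] and higher means more
conserved.  The defaults (lambda = 1/2, gap penalty multiplicative in the
non-gap fraction, smoothing over a 3-column flank with weight 1/2) follow the
standard conservation-scoring practice for protein alignments.

Information content is ``log2(20) - H(p)`` (sequence-logo letter-height
scale); the optional small-sample correction subtracts ``19 / (2 ln 2 n)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._alphabet import AMINO_ACIDS, N_AA, resolve_background
from .alignment import MatchAlignment, strip_insert_columns

LOG2_20 = float(np.log2(N_AA))


class DistributionError(ValueError):
    """Raised for inputs that are not valid probability distributions."""


def _check_distribution(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise DistributionError(f"{name} is not a distribution summing to 1")
    return p


def jsd_score(p, q, lam: float = 0.5) -> float:
    """Jensen-Shannon divergence between distributions *p* and *q* (base 2).

    Symmetric in its arguments at ``lam = 1/2`` and bounded by 1.
    """
    p = _check_distribution(p, "p")
    q = _check_distribution(q, "q")
    if not 0.0 < lam < 1.0:
        raise DistributionError(f"lambda must lie in (0, 1), got {lam}")
    m = lam * p + (1.0 - lam) * q
    kl_pm = np.sum(np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / m), 0.0))
    kl_qm = np.sum(np.where(q > 0, q * np.log2(np.where(q > 0, q, 1.0) / m), 0.0))
    return float(lam * kl_pm + (1.0 - lam) * kl_qm)


def gap_penalize(score: float, gap_fraction: float) -> float:
    """Down-weight a column score by its gap content: ``score * (1 - gap_fraction)``."""
    if not 0.0 <= gap_fraction <= 1.0:
        raise DistributionError(f"gap fraction {gap_fraction} outside [0, 1]")
    return score * (1.0 - gap_fraction)


def window_smooth(scores, w: int = 3, lam_w: float = 0.5) -> np.ndarray:
    """Blend each score with the mean of its up-to-``2w`` flanking columns.

    ``s'_i = (1 - lam_w) * s_i + lam_w * sum(flank) / (2w)``; the flank covers
    *w* columns each side, truncated at the ends of the profile (missing
    neighbours contribute nothing, and the normalizer stays ``2w``, so end
    columns are pulled toward zero).  ``lam_w = 0`` is the identity.
    """
    if w < 0 or int(w) != w:
        raise DistributionError(f"window w must be a nonnegative integer, got {w}")
    if not 0.0 <= lam_w <= 1.0:
        raise DistributionError(f"window weight {lam_w} outside [0, 1]")
    s = np.asarray(scores, dtype=float)
    if w == 0 or lam_w == 0.0:
        return s.copy()
    kernel = np.ones(2 * w + 1)
    kernel[w] = 0.0
    flank_sum = np.convolve(s, kernel, mode="full")[w : w + len(s)]
    return (1.0 - lam_w) * s + lam_w * flank_sum / (2.0 * w)


def information_content(p_c, n_obs: int, correct_small_sample: bool = False) -> float:
    """Column information content in bits, floored at 0.

    ``log2(20) - H(p_c)`` minus the small-sample correction
    ``19 / (2 ln 2 n_obs)`` when requested.
    """
    p = _check_distribution(p_c, "p_c")
    if n_obs < 1:
        raise DistributionError(f"n_obs must be >= 1, got {n_obs}")
    h = -np.sum(np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0))
    e_n = (N_AA - 1) / (2.0 * np.log(2.0) * n_obs) if correct_small_sample else 0.0
    return float(max(LOG2_20 - h - e_n, 0.0))


def column_distribution(column: str, weights=None):
    """Residue distribution of one column of symbols.

    Gaps (``-``) and ``X`` count toward the gap fraction, not the residue
    frequencies.  Optional per-row weights are renormalized.  An all-gap
    column yields a flagged (None) distribution.

    Returns ``(p_c, gap_fraction, n_obs)``.
    """
    n = len(column)
    if n == 0:
        raise DistributionError("empty column")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise DistributionError("weights must be nonnegative with positive sum")
    counts = np.zeros(N_AA)
    gap_w = 0.0
    n_obs = 0
    for c, wi in zip(column.upper(), w):
        if c in ("-", ".", "X"):
            gap_w += wi
        else:
            try:
                counts[AMINO_ACIDS.index(c)] += wi
            except ValueError:
                raise DistributionError(f"invalid residue {c!r}") from None
            n_obs += 1
    gap_fraction = float(gap_w / w.sum())
    if counts.sum() == 0:
        return None, gap_fraction, 0
    return counts / counts.sum(), gap_fraction, n_obs


@dataclass
class ConservationParams:
    """Knobs of the conservation scorer (all recorded in output metadata)."""

    background: str = "uniform"  # or "blosum62", or a 20-vector
    lam: float = 0.5             # JSD mixture weight
    window: int = 3              # smoothing flank width (columns each side)
    window_weight: float = 0.5   # smoothing blend weight
    small_sample_correction: bool = False
    bits_threshold: float = 2.0  # conserved-column call

    def validate(self) -> "ConservationParams":
        if not 0.0 < self.lam < 1.0:
            raise DistributionError(f"lam must lie in (0, 1), got {self.lam}")
        if self.window < 0 or int(self.window) != self.window:
            raise DistributionError(f"window must be a nonnegative integer")
        if not 0.0 <= self.window_weight <= 1.0:
            raise DistributionError("window_weight outside [0, 1]")
        if self.bits_threshold < 0:
            raise DistributionError("bits_threshold must be >= 0")
        resolve_background(self.background)
        return self


@dataclass
class ConservationProfile:
    """Per-match-column conservation tracks of one alignment."""

    freqs: np.ndarray          # (n_cols, 20); zero rows where undefined
    gap_fraction: np.ndarray   # (n_cols,)
    n_obs: np.ndarray          # non-gap residue count per column
    jsd_raw: np.ndarray
    jsd_penalized: np.ndarray
    jsd_smoothed: np.ndarray
    bits: np.ndarray
    consensus: list            # (residue | None, identity fraction of rows)
    undefined: np.ndarray      # all-gap columns, scored 0
    n_rows: int
    background: np.ndarray
    params: ConservationParams

    @property
    def n_columns(self) -> int:
        return len(self.bits)

    def identity_fraction(self, column: int, residue: str) -> float:
        """Fraction of rows carrying exactly *residue* at 1-based match *column*."""
        idx = AMINO_ACIDS.index(residue)
        c = column - 1
        return float(self.freqs[c, idx] * self.n_obs[c] / self.n_rows)

    def to_frame(self) -> pd.DataFrame:
        cons_res = [r if r is not None else "-" for r, _ in self.consensus]
        cons_id = [f for _, f in self.consensus]
        return pd.DataFrame(
            {
                "column": np.arange(1, self.n_columns + 1),
                "consensus": cons_res,
                "identity": cons_id,
                "gap_fraction": self.gap_fraction,
                "n_obs": self.n_obs,
                "jsd_raw": self.jsd_raw,
                "jsd_penalized": self.jsd_penalized,
                "jsd_smoothed": self.jsd_smoothed,
                "bits": self.bits,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def conservation_profile(
    a: MatchAlignment,
    params: ConservationParams | None = None,
    weights=None,
) -> ConservationProfile:
    """Score every match column of *a* (insert columns are stripped first)."""
    params = (params or ConservationParams()).validate()
    a = strip_insert_columns(a)
    q = resolve_background(params.background)
    ncol = a.n_match_columns
    nrow = a.n_rows

    if weights is None:
        w = np.ones(nrow)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (nrow,) or np.any(w < 0) or w.sum() <= 0:
            raise DistributionError("weights must be nonnegative with positive sum")

    # byte-level encoding keeps this fast on thousands of rows
    mat = np.frombuffer("".join(a.rows).encode("ascii"), dtype=np.uint8)
    mat = mat.reshape(nrow, ncol)
    lut = np.full(256, -1, dtype=np.int8)
    for k, aa in enumerate(AMINO_ACIDS):
        lut[ord(aa)] = k
    codes = lut[mat]  # -1 for '-' and 'X'

    counts = np.zeros((ncol, N_AA))
    for k in range(N_AA):
        counts[:, k] = ((codes == k) * w[:, None]).sum(axis=0)
    gap_w = ((codes == -1) * w[:, None]).sum(axis=0)
    n_obs = (codes >= 0).sum(axis=0)

    totals = counts.sum(axis=1)
    undefined = totals == 0
    freqs = np.zeros_like(counts)
    np.divide(counts, totals[:, None], out=freqs, where=~undefined[:, None])
    gap_fraction = gap_w / w.sum()

    jsd_raw = np.zeros(ncol)
    bits = np.zeros(ncol)
    for j in range(ncol):
        if undefined[j]:
            continue
        jsd_raw[j] = jsd_score(freqs[j], q, params.lam)
        bits[j] = information_content(
            freqs[j], n_obs[j], params.small_sample_correction
        )
    jsd_penalized = jsd_raw * (1.0 - gap_fraction)
    jsd_smoothed = window_smooth(jsd_penalized, params.window, params.window_weight)

    consensus = []
    weighted_rows = w.sum()
    for j in range(ncol):
        if undefined[j]:
            consensus.append((None, 0.0))
        else:
            k = int(np.argmax(counts[j]))
            consensus.append((AMINO_ACIDS[k], float(counts[j, k] / weighted_rows)))

    return ConservationProfile(
        freqs=freqs,
        gap_fraction=gap_fraction,
        n_obs=n_obs,
        jsd_raw=jsd_raw,
        jsd_penalized=jsd_penalized,
        jsd_smoothed=jsd_smoothed,
        bits=bits,
        consensus=consensus,
        undefined=undefined,
        n_rows=nrow,
        background=q,
        params=params,
    )


def call_conserved(profile: ConservationProfile, bits_threshold: float | None = None) -> list[int]:
    """Match columns (1-based) whose information content strictly exceeds the
    threshold (default 2 bits, the conserved-residue call of the velvet study)."""
    thr = profile.params.bits_threshold if bits_threshold is None else bits_threshold
    if thr < 0:
        raise DistributionError("bits threshold must be >= 0")
    return [j + 1 for j in range(profile.n_columns) if profile.bits[j] > thr]


def logo_matrix(profile: ConservationProfile) -> pd.DataFrame:
    """Sequence-logo letter heights: ``height(a, c) = p_c(a) * bits(c)``.

    Rows are 1-based match columns, columns the 20 residues; each row sums to
    the column's information content.
    """
    heights = profile.freqs * profile.bits[:, None]
    return pd.DataFrame(
        heights, index=np.arange(1, profile.n_columns + 1), columns=list(AMINO_ACIDS)
    )


def residue_identity(a: MatchAlignment, column: int, residue: str) -> float:
    """Percent of rows carrying exactly *residue* at 1-based match *column*.

    Gaps count in the denominator, so an all-gap column scores 0%.
    """
    if residue not in AMINO_ACIDS:
        raise DistributionError(f"unknown residue {residue!r}")
    a = strip_insert_columns(a)
    if not 1 <= column <= a.n_match_columns:
        raise DistributionError(f"column {column} outside 1..{a.n_match_columns}")
    symbols = a.match_column(column)
    return 100.0 * symbols.count(residue) / a.n_rows
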