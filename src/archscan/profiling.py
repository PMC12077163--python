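"""Position-specific profile construction and affine-gap profile alignment.

A :class:`Profile` holds per-match-column log-odds scores in bits against a
background distribution, built from a seed alignment with Dirichlet-style
pseudocounts.  :func:`align_to_profile` runs a global (in both the profile
and the sequence) affine-gap dynamic program maximizing the bit score, a
desk-scale stand-in for aligning sequences against a profile HMM of the
domain.  A single affine penalty pair (``gap_open``, ``gap_extend``, in bits)
is shared by insertions and deletions; a gap run of length L costs
``gap_open + (L - 1) * gap_extend``.

No E-value statistics are computed; :func:`score_filter` applies a plain
bit-score threshold to screen candidate domain sequences.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._alphabet import AMINO_ACIDS, N_AA, encode_residues, resolve_background
from .alignment import MatchAlignment, strip_insert_columns
from .sequences import DomainSequence


class ProfileError(ValueError):
    """Raised for invalid profile construction inputs."""


@dataclass
class Profile:
    """Per-column log-base-2 odds scores (bits) versus a background."""

    log_odds: np.ndarray        # (n_columns, 20)
    background: np.ndarray      # (20,)
    pseudocount_weight: float
    gap_open: float = 4.0
    gap_extend: float = 0.25

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ProfileError("gap penalties must be nonnegative")
        if not np.all(np.isfinite(self.log_odds)):
            raise ProfileError("log-odds must be finite (use a positive pseudocount)")

    @property
    def n_columns(self) -> int:
        return self.log_odds.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[k] for k in self.log_odds.argmax(axis=1))

    def scores_for(self, residues: str) -> np.ndarray:
        """Per-(residue, column) match scores; X scores 0 in every column."""
        codes = encode_residues(residues)
        s = np.zeros((len(residues), self.n_columns))
        known = codes >= 0
        s[known] = self.log_odds[:, codes[known]].T
        return s

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alphabet": AMINO_ACIDS,
            "log_odds": self.log_odds.tolist(),
            "background": self.background.tolist(),
            "pseudocount_weight": self.pseudocount_weight,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Profile":
        d = json.loads(Path(path).read_text())
        return cls(
            log_odds=np.asarray(d["log_odds"], dtype=float),
            background=np.asarray(d["background"], dtype=float),
            pseudocount_weight=d["pseudocount_weight"],
            gap_open=d["gap_open"],
            gap_extend=d["gap_extend"],
        )


def henikoff_weights(a: MatchAlignment) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff), normalized to sum n."""
    a = strip_insert_columns(a)
    w = np.zeros(a.n_rows)
    for c in range(1, a.n_match_columns + 1):
        col = a.match_column(c)
        residues = [x for x in col if x not in ("-", "X")]
        if not residues:
            continue
        kinds = set(residues)
        r = len(kinds)
        counts = {k: residues.count(k) for k in kinds}
        for i, x in enumerate(col):
            if x not in ("-", "X"):
                w[i] += 1.0 / (r * counts[x])
    if w.sum() == 0:
        return np.ones(a.n_rows)
    return w * (a.n_rows / w.sum())


def build_profile(
    seed: MatchAlignment,
    pseudocount_weight: float = 1.0,
    background="uniform",
    gap_open: float = 4.0,
    gap_extend: float = 0.25,
    sequence_weighting: bool = False,
) -> Profile:
    """Build a log-odds profile from a seed alignment's match columns.

    Column frequencies are ``(counts + w * background) / (n_eff + w)`` with
    *n_eff* the (weighted) non-gap count of the column; log-odds are
    ``log2(freq / background)``.  Row order is irrelevant, and sequence
    weighting (position-based) is off by default.
    """
    if seed.n_rows < 2:
        raise ProfileError("seed alignment needs at least 2 rows")
    if pseudocount_weight <= 0:
        raise ProfileError("pseudocount weight must be positive")
    q = resolve_background(background)
    seed = strip_insert_columns(seed)
    weights = henikoff_weights(seed) if sequence_weighting else np.ones(seed.n_rows)

    ncol = seed.n_match_columns
    counts = np.zeros((ncol, N_AA))
    n_eff = np.zeros(ncol)
    for i, row in enumerate(seed.rows):
        for j, c in enumerate(row):
            if c not in ("-", "X"):
                counts[j, AMINO_ACIDS.index(c)] += weights[i]
                n_eff[j] += weights[i]
    freqs = (counts + pseudocount_weight * q) / (n_eff + pseudocount_weight)[:, None]
    return Profile(
        log_odds=np.log2(freqs / q),
        background=q,
        pseudocount_weight=pseudocount_weight,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


@dataclass(frozen=True)
class AlignmentPath:
    """Sequence of match/insert/delete steps with the total bit score.

    ``states`` is a string over {M, I, D}: M consumes a profile column and a
    residue, D a column only, I a residue only.
    """

    states: str
    bit_score: float

    def validate(self, n_columns: int, n_residues: int) -> "AlignmentPath":
        cols = self.states.count("M") + self.states.count("D")
        res = self.states.count("M") + self.states.count("I")
        if cols != n_columns or res != n_residues:
            raise ProfileError(
                f"path consumes {cols} columns / {res} residues, expected "
                f"{n_columns} / {n_residues}"
            )
        return self


_NEG = -np.inf


def align_to_profile(p: Profile, s: DomainSequence | str) -> AlignmentPath:
    """Globally align a sequence to the profile, maximizing the bit score.

    Affine penalties from the profile; ties broken deterministically with
    preference match > delete > insert.
    """
    residues = s.residues if isinstance(s, DomainSequence) else s
    if not residues:
        raise ProfileError("cannot align an empty sequence")
    n, m = len(residues), p.n_columns
    score = p.scores_for(residues)  # (n, m)
    open_, ext = p.gap_open, p.gap_extend

    # Gotoh, vectorized over columns within each residue row.  D rows obey a
    # prefix-max recurrence and are computed with an accumulated maximum.
    M = np.full((n + 1, m + 1), _NEG)
    D = np.full((n + 1, m + 1), _NEG)
    I = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if m >= 1:
        D[0, 1:] = -(open_ + ext * np.arange(m))
    I[1:, 0] = -(open_ + ext * np.arange(n))

    j_idx = np.arange(1, m + 1)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], D[i - 1]), I[i - 1])
        M[i, 1:] = score[i - 1] + best_prev[:-1]
        I[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], D[i - 1, 1:]) - open_, I[i - 1, 1:] - ext
        )
        I[i, 0] = -(open_ + ext * (i - 1))
        # D[i, j] = max_{k < j} (entry[k] + ext*k) - open_ - ext*(j-1),
        # entry = best non-D state in the same row
        entry = np.maximum(M[i, :-1], I[i, :-1]) + ext * np.arange(m)
        D[i, 1:] = np.maximum.accumulate(entry) - open_ - ext * (j_idx - 1)

    end_scores = (M[n, m], D[n, m], I[n, m])
    order = "MDI"
    state = order[int(np.argmax(end_scores))]
    # honour the M > D > I preference under float ties
    best = max(end_scores)
    for st, sc in zip(order, end_scores):
        if sc >= best - 1e-9:
            state = st
            break
    states = _traceback(M, D, I, score, open_, ext, state, n, m)
    return AlignmentPath(states, float(best)).validate(m, n)


def _traceback(M, D, I, score, open_, ext, state, i, j) -> str:
    tol = 1e-9
    out = []
    while i > 0 or j > 0:
        out.append(state)
        if state == "M":
            cands = (("M", M[i - 1, j - 1]), ("D", D[i - 1, j - 1]), ("I", I[i - 1, j - 1]))
            i, j = i - 1, j - 1
        elif state == "D":
            cands = (
                ("M", M[i, j - 1] - open_),
                ("D", D[i, j - 1] - ext),
                ("I", I[i, j - 1] - open_),
            )
            j -= 1
        else:
            cands = (
                ("M", M[i - 1, j] - open_),
                ("D", D[i - 1, j] - open_),
                ("I", I[i - 1, j] - ext),
            )
            i -= 1
        if i == 0 and j == 0:
            break
        best = max(v for _, v in cands)
        for st, v in cands:
            if v >= best - tol:
                state = st
                break
    return "".join(reversed(out))


@dataclass(frozen=True)
class ScoredSequence:
    sequence: DomainSequence
    bit_score: float
    path: AlignmentPath


def score_filter(
    p: Profile, candidates, min_bits: float
) -> list[ScoredSequence]:
    """Retain candidates whose alignment bit score reaches ``min_bits``.

    Order is preserved and scores (with paths) are attached.  This replaces
    the E-value screen of a database search with a plain score threshold.
    """
    if np.isnan(min_bits):
        raise ProfileError("min_bits must not be NaN")
    out = []
    for cand in candidates:
        path = align_to_profile(p, cand)
        if path.bit_score >= min_bits:
            out.append(ScoredSequence(cand, path.bit_score, path))
    return out


def paths_to_alignment(
    p: Profile, seqs: list[DomainSequence], paths: list[AlignmentPath] | None = None
) -> MatchAlignment:
    """Assemble aligned rows (with expanded insert columns) from paths.

    Insert runs between the same pair of match columns are stacked into a
    shared block of insert columns, left-justified and padded with ``.``.
    """
    if paths is None:
        paths = [align_to_profile(p, s) for s in seqs]
    m = p.n_columns
    per_row: list[tuple[list[str], dict[int, list[str]]]] = []
    slot_max = [0] * (m + 1)
    for s, path in zip(seqs, paths):
        path.validate(m, len(s.residues))
        cols: list[str] = []
        inserts: dict[int, list[str]] = {}
        pos = 0
        slot = 0
        for st in path.states:
            if st == "M":
                cols.append(s.residues[pos])
                pos += 1
                slot += 1
            elif st == "D":
                cols.append("-")
                slot += 1
            else:
                inserts.setdefault(slot, []).append(s.residues[pos].lower())
                pos += 1
        for k, run in inserts.items():
            slot_max[k] = max(slot_max[k], len(run))
        per_row.append((cols, inserts))

    col_is_match: list[bool] = []
    for k in range(m + 1):
        col_is_match.extend([False] * slot_max[k])
        if k < m:
            col_is_match.append(True)
    rows = []
    for cols, inserts in per_row:
        chunks = []
        for k in range(m + 1):
            run = inserts.get(k, [])
            chunks.append("".join(run) + "." * (slot_max[k] - len(run)))
            if k < m:
                chunks.append(cols[k])
        rows.append("".join(chunks))
    ids = [s.id for s in seqs]
    return MatchAlignment(ids, rows, col_is_match)
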