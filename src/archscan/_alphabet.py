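"""Amino-acid alphabet and background frequency tables."""
from __future__ import annotations

import numpy as np

#: Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_AA = len(AMINO_ACIDS)
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Degenerate residue: allowed in sequences, excluded from residue counts.
UNKNOWN = "X"

#: Uniform background over the 20 standard residues.
UNIFORM_BACKGROUND = np.full(N_AA, 1.0 / N_AA)

# Marginal residue frequencies underlying the BLOSUM62 substitution matrix,
# in AMINO_ACIDS order (sums to 1.000).
BLOSUM62_BACKGROUND = np.array([
    0.074,  # A
    0.025,  # C
    0.054,  # D
    0.054,  # E
    0.047,  # F
    0.074,  # G
    0.026,  # H
    0.068,  # I
    0.058,  # K
    0.099,  # L
    0.025,  # M
    0.045,  # N
    0.039,  # P
    0.034,  # Q
    0.052,  # R
    0.057,  # S
    0.051,  # T
    0.073,  # V
    0.013,  # W
    0.032,  # Y
])

BACKGROUNDS = {
    "uniform": UNIFORM_BACKGROUND,
    "blosum62": BLOSUM62_BACKGROUND,
}


def resolve_background(background) -> np.ndarray:
    """Accept a named background ('uniform', 'blosum62') or a 20-vector."""
    if background is None:
        return UNIFORM_BACKGROUND.copy()
    if isinstance(background, str):
        try:
            return BACKGROUNDS[background].copy()
        except KeyError:
            raise ValueError(f"unknown background {background!r}") from None
    q = np.asarray(background, dtype=float)
    if q.shape != (N_AA,):
        raise ValueError(f"background must have shape ({N_AA},), got {q.shape}")
    if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("background must be a distribution summing to 1 within 1e-9")
    return q


def encode_residues(residues: str) -> np.ndarray:
    """Encode a residue string as integer indices (X -> -2)."""
    out = np.empty(len(residues), dtype=np.int8)
    for i, ch in enumerate(residues):
        if ch == UNKNOWN:
            out[i] = -2
        else:
            try:
                out[i] = AA_INDEX[ch]
            except KeyError:
                raise ValueError(f"invalid residue {ch!r} at position {i + 1}") from None
    return out
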