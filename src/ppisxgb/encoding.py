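"""Per-residue feature construction.

Every residue is described by 49 numbers: its 20 PSSM log-odds, a one-hot
encoding of its 9-state secondary structure, and a one-hot encoding of its
amino-acid identity, in that fixed column order.  From the L x 49 block two
views are built:

* the **local feature** — the 49-dim rows of a short window centred on the
  residue, concatenated (window 7 -> 343 numbers), with all-zero rows past
  the termini;
* the **global feature** — the whole protein as a fixed 500 x 49 matrix,
  zero-padded below 500 residues and truncated above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AA_INDEX, AA_ORDER, SS_INDEX, SS_ORDER, ProteinRecord

#: Number of feature columns per residue: 20 PSSM + 9 SS + 20 one-hot.
RESIDUE_DIM = 49
#: Column segmentation of the per-residue block.
PSSM_SLICE = slice(0, 20)
SS_SLICE = slice(20, 29)
ONEHOT_SLICE = slice(29, 49)

DEFAULT_WINDOW = 7
DEFAULT_MAX_LEN = 500

PSSM_NORMALIZATIONS = ("identity", "logistic")


@dataclass
class ResidueFeatureBlock:
    """L x 49 matrix with the fixed [PSSM | SS | one-hot] column layout."""

    matrix: np.ndarray
    normalization: str = "identity"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != RESIDUE_DIM:
            raise ValueError(f"feature block must have {RESIDUE_DIM} columns, got {self.matrix.shape}")

    def __len__(self) -> int:
        return self.matrix.shape[0]


def encode_onehot(sequence: str) -> np.ndarray:
    """One-hot encode a sequence over :data:`~ppisxgb.io_formats.AA_ORDER`.

    ``'X'`` (any non-standard residue) yields an all-zero row.
    """
    out = np.zeros((len(sequence), 20))
    for i, aa in enumerate(sequence):
        if aa == "X":
            continue
        j = AA_INDEX.get(aa)
        if j is None:
            raise ValueError(f"unknown amino-acid letter '{aa}' at position {i}")
        out[i, j] = 1.0
    return out


def encode_ss(ss9: str) -> np.ndarray:
    """One-hot encode a 9-state secondary-structure string (:data:`SS_ORDER`)."""
    out = np.zeros((len(ss9), 9))
    for i, s in enumerate(ss9):
        j = SS_INDEX.get(s)
        if j is None:
            raise ValueError(f"unknown secondary-structure code '{s}' at position {i}")
        out[i, j] = 1.0
    return out


def residue_features(record: ProteinRecord, normalization: str = "identity") -> ResidueFeatureBlock:
    """Build the L x 49 per-residue block for one protein.

    ``normalization`` applies to the PSSM segment only: ``"identity"``
    keeps the raw log-odds; ``"logistic"`` squashes them with
    1/(1+e^-x) into (0, 1).
    """
    if record.pssm is None:
        raise ValueError(f"{record.id}: record has no PSSM")
    if record.ss9 is None:
        raise ValueError(f"{record.id}: record has no secondary structure")
    if normalization not in PSSM_NORMALIZATIONS:
        raise ValueError(f"unknown normalization '{normalization}', expected one of {PSSM_NORMALIZATIONS}")
    pssm = record.pssm.scores
    if normalization == "logistic":
        pssm = 1.0 / (1.0 + np.exp(-pssm))
    block = np.concatenate([pssm, encode_ss(record.ss9), encode_onehot(record.sequence)], axis=1)
    return ResidueFeatureBlock(matrix=block, normalization=normalization)


def local_window_feature(
    block: ResidueFeatureBlock, i: int, window_size: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Concatenate the ``window_size`` rows centred at residue ``i``.

    Positions past either terminus contribute all-zero 49-dim rows, so the
    result always has ``window_size * 49`` entries (343 for the default
    window of 7).
    """
    L = len(block)
    if not 0 <= i < L:
        raise IndexError(f"residue index {i} out of range for length {L}")
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError(f"window_size must be odd and >= 1, got {window_size}")
    half = window_size // 2
    out = np.zeros((window_size, RESIDUE_DIM))
    lo, hi = max(0, i - half), min(L, i + half + 1)
    out[lo - (i - half) : hi - (i - half)] = block.matrix[lo:hi]
    return out.ravel()


def local_window_features(block: ResidueFeatureBlock, window_size: int = DEFAULT_WINDOW) -> np.ndarray:
    """Vectorized :func:`local_window_feature` for every residue: L x (window*49)."""
    L = len(block)
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError(f"window_size must be odd and >= 1, got {window_size}")
    half = window_size // 2
    padded = np.zeros((L + 2 * half, RESIDUE_DIM))
    padded[half : half + L] = block.matrix
    windows = np.lib.stride_tricks.sliding_window_view(padded, (window_size, RESIDUE_DIM))
    return windows[:, 0].reshape(L, window_size * RESIDUE_DIM).copy()


def global_feature(block: ResidueFeatureBlock, max_len: int = DEFAULT_MAX_LEN) -> np.ndarray:
    """Fixed-size ``max_len`` x 49 view of the whole protein.

    Shorter proteins are zero-padded; longer ones are truncated at
    ``max_len`` (the local features still use the full block).
    """
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")
    L = len(block)
    out = np.zeros((max_len, RESIDUE_DIM))
    n = min(L, max_len)
    out[:n] = block.matrix[:n]
    return out
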