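"""Amino-acid alphabet, background composition and hydropathy constants.

All modules share the fixed 20-letter alphabet order defined here; sequences
are encoded as integer arrays over that order.  The background composition is
an embedded, approximately proteome-wide (UniProt-like) amino-acid frequency
table so that no external composition files are required.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue order used for every frequency/emission vector.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

GAP_CHARS = frozenset("-.")

# Approximate UniProt-wide amino-acid composition, normalised at import time.
_BACKGROUND_RAW = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

BACKGROUND = np.array([_BACKGROUND_RAW[a] for a in AMINO_ACIDS], dtype=float)
BACKGROUND /= BACKGROUND.sum()

#: Kyte-Doolittle hydropathy index per residue.
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as an int array over :data:`AMINO_ACIDS`.

    Raises ``ValueError`` on any symbol outside the 20-letter alphabet.
    """
    try:
        return np.array([AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - trivial message path
        raise ValueError(f"illegal residue symbol {exc.args[0]!r}") from None


def decode(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in codes)
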