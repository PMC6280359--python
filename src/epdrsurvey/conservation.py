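"""Per-column conservation statistics: frequencies, information content,
consensus and conserved-column detection — the quantitative core of a
sequence logo.

Information content per column is ``IC_j = log2(20) - H_j`` with ``H_j`` the
Shannon entropy of the gap-excluded residue frequencies, so a pure column
scores log2(20) ~ 4.32 bits and a uniform column scores 0.  Gaps never enter
the frequencies; column occupancy is reported separately, which keeps IC
bounded and matches common logo practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, GAP_CHARS
from .hmm import SeedAlignment

__all__ = [
    "ConservationProfile",
    "column_profile",
    "conserved_columns",
    "logo_matrix",
]

MAX_IC_BITS = math.log2(20.0)


@dataclass
class ConservationProfile:
    """Column-wise residue frequencies and information content (bits)."""

    frequencies: np.ndarray        # (n_columns, 20), rows sum to 1 (or 0)
    occupancy: np.ndarray          # (n_columns,) fraction of non-gap rows
    information: np.ndarray        # (n_columns,) IC in bits
    n_sequences: int

    @property
    def n_columns(self) -> int:
        return self.frequencies.shape[0]

    def consensus(self) -> list[tuple[str, float]]:
        """Per column: (most frequent residue, its frequency)."""
        idx = self.frequencies.argmax(axis=1)
        return [
            (AMINO_ACIDS[a], float(self.frequencies[j, a]))
            for j, a in enumerate(idx)
        ]

    def frequency_of(self, residue: str, column: int) -> float:
        return float(self.frequencies[column - 1, AMINO_ACIDS.index(residue)])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: column, residue, frequency, IC, logo height."""
        heights = logo_matrix(self)
        rows = []
        for j in range(self.n_columns):
            for a, aa in enumerate(AMINO_ACIDS):
                rows.append((j + 1, aa, self.frequencies[j, a],
                             self.information[j], heights[j, a]))
        return pd.DataFrame(
            rows, columns=["column", "residue", "frequency", "ic", "height"]
        )


def column_profile(
    aln: SeedAlignment,
    group: Iterable[str] | None = None,
    small_sample_correction: bool = False,
) -> ConservationProfile:
    """Conservation profile of an alignment (optionally an id subset).

    Frequencies are computed over non-gap residues only.  The optional
    small-sample correction subtracts the standard (s-1)/(2 ln2 n) bias term
    from the information content (clamped at zero); it is off by default
    because the family groups analysed here are much larger than the
    alphabet.
    """
    sub = aln if group is None else aln.subset(group)
    if sub.n_rows == 0:
        raise ValueError("empty sequence group")
    n_cols = sub.n_columns
    counts = np.zeros((n_cols, 20))
    gap_counts = np.zeros(n_cols)
    for row in sub.rows:
        for j, c in enumerate(row):
            if c in GAP_CHARS:
                gap_counts[j] += 1
            else:
                counts[j, AMINO_ACIDS.index(c)] += 1
    totals = counts.sum(axis=1)
    freqs = np.zeros_like(counts)
    occupied = totals > 0
    freqs[occupied] = counts[occupied] / totals[occupied, None]

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = np.where(occupied, MAX_IC_BITS - entropy, 0.0)
    if small_sample_correction:
        with np.errstate(divide="ignore"):
            e_n = np.where(totals > 0, 19.0 / (2.0 * math.log(2) * totals), 0.0)
        ic = np.maximum(ic - e_n, 0.0)
    return ConservationProfile(
        frequencies=freqs,
        occupancy=totals / sub.n_rows,
        information=ic,
        n_sequences=sub.n_rows,
    )


def conserved_columns(
    profile: ConservationProfile, residue: str, min_freq: float = 0.9
) -> list[int]:
    """1-based columns where ``residue`` reaches frequency >= ``min_freq``."""
    if not 0.0 < min_freq <= 1.0:
        raise ValueError("min_freq must lie in (0, 1]")
    a = AMINO_ACIDS.index(residue)
    return [int(j) + 1 for j in np.flatnonzero(profile.frequencies[:, a] >= min_freq)]


def logo_matrix(profile: ConservationProfile) -> np.ndarray:
    """Per-column letter heights ``height_aj = f_aj * IC_j`` (IC scaling)."""
    return profile.frequencies * profile.information[:, None]
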