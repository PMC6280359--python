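"""Cysteine-profile typing and sequence-feature annotation.

The family's typology rests on the occupancy of six canonical reference
columns by cysteine: three universal positions (23, 94, 186) plus
profile-specific extras — profile 1 adds 148, profile 2 adds 24/107/148 and
profile 3 adds 107.  A sequence's occupancy vector over those six columns is
compared against the three templates; strict mode demands an exact match
while tolerant mode accepts the unique nearest template within a Hamming
distance budget (deviant family members have lost or gained individual
cysteines without obscuring their type).

Feature annotation covers N-glycosylation sequons (N-X-S/T, X != P), their
residue offsets upstream of the second universal cysteine, a hydropathy-based
signal-peptide heuristic, and length summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import KYTE_DOOLITTLE
from .mapping import ColumnMap

__all__ = [
    "CanonicalColumns",
    "ProfileCall",
    "GlycoSite",
    "SignalPeptideCall",
    "occupied_columns",
    "call_profile",
    "scan_sequons",
    "glyco_offsets",
    "detect_signal_peptide",
    "length_stats",
]


@dataclass(frozen=True)
class CanonicalColumns:
    """The conserved-cysteine column system of the reference alignment."""

    universal: tuple[int, ...] = (23, 94, 186)
    profile1_extra: tuple[int, ...] = (148,)
    profile2_extra: tuple[int, ...] = (24, 107, 148)
    profile3_extra: tuple[int, ...] = (107,)
    proline_column: int = 150

    @property
    def all_columns(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.universal) | set(self.profile1_extra)
                            | set(self.profile2_extra)
                            | set(self.profile3_extra)))

    @property
    def templates(self) -> dict[str, frozenset[int]]:
        u = set(self.universal)
        return {
            "1": frozenset(u | set(self.profile1_extra)),
            "2": frozenset(u | set(self.profile2_extra)),
            "3": frozenset(u | set(self.profile3_extra)),
        }

    @property
    def second_universal(self) -> int:
        return sorted(self.universal)[1]


DEFAULT_CANONICAL = CanonicalColumns()


@dataclass(frozen=True)
class ProfileCall:
    """Assignment of one sequence to a conserved-cysteine profile."""

    sequence_id: str
    occupied: tuple[int, ...]          # canonical columns carrying a C
    assigned: str                      # "1" | "2" | "3" | "atypical"
    distance: int                      # Hamming distance to nearest template
    missing: tuple[int, ...]           # template columns without a C
    extra: tuple[int, ...]             # occupied columns outside the template
    proline_at_150: bool | None = None


@dataclass(frozen=True)
class GlycoSite:
    """One N-glycosylation sequon: N-X-S/T with X != P."""

    n_index: int                       # 1-based residue index of the N
    sequon: str                        # the tripeptide
    column: int | None = None          # reference column of the N, if mapped
    offset: int | None = None          # residues upstream of the Cys-94 residue


@dataclass(frozen=True)
class SignalPeptideCall:
    present: bool
    span: tuple[int, int] | None
    window_hydropathy: float
    flagged_short: bool = False


def occupied_columns(
    seq: str, colmap: ColumnMap,
    canon: CanonicalColumns = DEFAULT_CANONICAL,
) -> dict[int, bool]:
    """Occupancy vector: canonical column -> does a cysteine map there?"""
    inverse = {c: r for r, c in colmap.mapping.items()}
    out = {}
    for col in canon.all_columns:
        res = inverse.get(col)
        out[col] = bool(res is not None and seq[res - 1] == "C")
    return out


def call_profile(
    vec: Mapping[int, bool] | Iterable[int],
    strict: bool = False,
    max_distance: int = 1,
    canon: CanonicalColumns = DEFAULT_CANONICAL,
    sequence_id: str = "seq",
) -> ProfileCall:
    """Assign a cysteine profile from a canonical-column occupancy vector.

    ``vec`` is either a column -> bool mapping over exactly the canonical
    columns or the set of occupied columns.  Strict mode assigns only exact
    template matches; tolerant mode (default) assigns the unique nearest
    template within ``max_distance``, with ties and larger deviations
    reported as ``atypical``.
    """
    if isinstance(vec, Mapping):
        if set(vec) != set(canon.all_columns):
            raise ValueError("occupancy vector must cover the canonical columns")
        occupied = frozenset(c for c, v in vec.items() if v)
    else:
        occupied = frozenset(vec)
        if not occupied <= set(canon.all_columns):
            raise ValueError("occupied columns outside the canonical set")

    distances = {
        p: len(occupied ^ template) for p, template in canon.templates.items()
    }
    best = min(distances.values())
    nearest = sorted(p for p, d in distances.items() if d == best)
    if len(nearest) == 1 and (best == 0 if strict else best <= max_distance):
        assigned = nearest[0]
    else:
        assigned = "atypical"
    template = canon.templates[nearest[0]]
    return ProfileCall(
        sequence_id=sequence_id,
        occupied=tuple(sorted(occupied)),
        assigned=assigned,
        distance=best,
        missing=tuple(sorted(template - occupied)),
        extra=tuple(sorted(occupied - template)),
    )


def scan_sequons(seq: str) -> list[GlycoSite]:
    """All N-X-S/T sequons (X != P), overlapping allowed, 1-based N index."""
    sites = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in ("S", "T"):
            sites.append(GlycoSite(n_index=i + 1, sequon=seq[i:i + 3]))
    return sites


def glyco_offsets(
    sites: Sequence[GlycoSite], colmap: ColumnMap,
    canon: CanonicalColumns = DEFAULT_CANONICAL,
) -> tuple[list[int], bool]:
    """Sequon offsets upstream of the second universal cysteine residue.

    Returns ``(offsets, cys_mapped)``: positive residue-count differences
    (cys residue index minus N index), sorted ascending; when the cysteine
    column has no residue in this sequence the list is empty and the flag is
    False (a warning condition, not an error).
    """
    cys_res = colmap.residue_at_column(canon.second_universal)
    if cys_res is None:
        return [], False
    offsets = sorted(
        cys_res - s.n_index for s in sites if cys_res - s.n_index > 0
    )
    return offsets, True


def detect_signal_peptide(
    seq: str, window: int = 8, hydropathy_min: float = 2.5,
    search_limit: int = 30, cleavage_range: tuple[int, int] = (15, 30),
) -> SignalPeptideCall:
    """Heuristic signal-peptide detector.

    A signal peptide is called when some ``window``-long stretch starting
    within the first ``search_limit`` residues has mean Kyte-Doolittle
    hydropathy >= ``hydropathy_min`` and a cleavage-permissive small residue
    (A/G/S) occurs downstream of that stretch within ``cleavage_range``.
    """
    if len(seq) < window:
        return SignalPeptideCall(present=False, span=None,
                                 window_hydropathy=float("nan"),
                                 flagged_short=True)
    kd = np.array([KYTE_DOOLITTLE[c] for c in seq[:search_limit + window]])
    best_mean = -np.inf
    lo, hi = cleavage_range
    small = {"A", "G", "S"}
    call_span = None
    for start in range(0, min(search_limit - window + 1,
                              len(seq) - window + 1)):
        mean = float(kd[start:start + window].mean())
        best_mean = max(best_mean, mean)
        if mean < hydropathy_min:
            continue
        first = max(lo, start + window + 1)
        for p in range(first, min(hi, len(seq)) + 1):
            if seq[p - 1] in small:
                if call_span is None:
                    call_span = (1, p)
                break
    return SignalPeptideCall(
        present=call_span is not None,
        span=call_span,
        window_hydropathy=best_mean,
    )


def length_stats(
    sequences, calls: Mapping[str, ProfileCall] | None = None
) -> dict:
    """Length summary (n, median, quartiles) with a per-profile breakdown."""
    from .hmm import as_pairs

    pairs = as_pairs(sequences)
    if not pairs:
        raise ValueError("length_stats needs a non-empty sequence set")

    def _summary(lengths: list[int]) -> dict:
        arr = np.sort(np.array(lengths, dtype=float))
        return {
            "n": int(arr.size),
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
        }

    out = _summary([len(s) for _, s in pairs])
    if calls is not None:
        by_profile: dict[str, list[int]] = {}
        for sid, seq in pairs:
            call = calls.get(sid)
            if call is not None:
                by_profile.setdefault(call.assigned, []).append(len(seq))
        out["per_profile"] = {p: _summary(v) for p, v in sorted(by_profile.items())}
    return out
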