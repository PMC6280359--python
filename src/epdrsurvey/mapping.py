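"""Reference-column coordinate mapping, alignment trimming and redundancy
filtering.

All downstream residue typing is expressed in the 1-based column space of the
reference alignment that the profile model was built from.  A hit's Viterbi
state path assigns each match-emitted residue to the source column of the
corresponding match state; insert-state residues are unmapped and delete
states consume a column without a residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import GAP_CHARS
from .hmm import DomainHit, ProfileHMM, SeedAlignment, as_pairs

__all__ = [
    "ColumnMap",
    "TrimSpec",
    "map_to_columns",
    "trim_alignment",
    "deduplicate",
    "filter_by_coverage",
]


@dataclass(frozen=True)
class ColumnMap:
    """Partial, strictly increasing residue-index -> reference-column map."""

    sequence_id: str
    mapping: Mapping[int, int]

    def __post_init__(self):
        items = sorted(self.mapping.items())
        cols = [c for _, c in items]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("mapped columns must increase with residue index")

    def column_of(self, residue_index: int) -> int | None:
        return self.mapping.get(residue_index)

    def residue_at_column(self, column: int) -> int | None:
        """Residue index mapped to ``column``, or None (inverse lookup)."""
        for r, c in self.mapping.items():
            if c == column:
                return r
        return None

    def mapped_columns(self) -> set[int]:
        return set(self.mapping.values())

    def __len__(self):
        return len(self.mapping)


@dataclass(frozen=True)
class TrimSpec:
    """Occupancy-based column trimming rule with optional explicit tail drop."""

    occupancy_threshold: float = 0.5
    drop_columns: tuple[int, int] | None = None   # inclusive 1-based range

    def __post_init__(self):
        if not 0.0 <= self.occupancy_threshold <= 1.0:
            raise ValueError("occupancy threshold must lie in (0, 1]")


def map_to_columns(hit: DomainHit, hmm: ProfileHMM) -> ColumnMap:
    """Express a hit's matched residues in reference-column coordinates."""
    mapping: dict[int, int] = {}
    max_res = 0
    for op, level, res_idx in hit.path:
        if op == "M":
            mapping[res_idx] = int(hmm.column_map[level - 1])
        if op in ("M", "I"):
            max_res = max(max_res, res_idx)
    if hit.span[1] and max_res != hit.span[1]:
        raise ValueError(f"hit path inconsistent with span for {hit.sequence_id}")
    return ColumnMap(sequence_id=hit.sequence_id, mapping=mapping)


def trim_alignment(
    aln: SeedAlignment, spec: TrimSpec
) -> tuple[SeedAlignment, dict[int, int]]:
    """Remove low-occupancy columns; returns the trimmed alignment and an
    old-column -> new-column renumbering map over retained columns."""
    occ = aln.occupancy()
    keep = occ >= spec.occupancy_threshold
    if spec.occupancy_threshold == 0.0:
        keep = np.ones_like(keep, dtype=bool)
    if spec.drop_columns is not None:
        lo, hi = spec.drop_columns
        keep[lo - 1:hi] = False
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        raise ValueError("trimming removed every column")
    renumbering = {int(old) + 1: new + 1 for new, old in enumerate(kept)}
    rows = tuple("".join(row[j] for j in kept) for row in aln.rows)
    return SeedAlignment(ids=aln.ids, rows=rows), renumbering


def _pairwise_identity(map_a: ColumnMap, seq_a: str,
                       map_b: ColumnMap, seq_b: str) -> float:
    """Ungapped identity over the columns mapped in both sequences."""
    inv_a = {c: r for r, c in map_a.mapping.items()}
    shared = 0
    same = 0
    for res_b, col in map_b.mapping.items():
        res_a = inv_a.get(col)
        if res_a is None:
            continue
        shared += 1
        if seq_a[res_a - 1] == seq_b[res_b - 1]:
            same += 1
    return same / shared if shared else 0.0


@dataclass
class ClusterReport:
    """Dedup outcome: representative -> members (including itself)."""

    clusters: dict[str, list[str]] = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return list(self.clusters)

    @property
    def removed(self) -> list[str]:
        return [m for rep, members in self.clusters.items()
                for m in members if m != rep]


def deduplicate(
    sequences,
    colmaps: Mapping[str, ColumnMap],
    identity_threshold: float = 0.97,
) -> tuple[list[tuple[str, str]], ClusterReport]:
    """Greedy redundancy removal at a pairwise-identity threshold.

    Sequences are visited longest first (ties by id); each joins the first
    existing cluster whose representative it matches at >= threshold
    identity over shared mapped columns, else founds a new cluster.  The
    longest sequence of each cluster (its founder) is retained.  At a
    threshold of exactly 1.0 only fully identical mapped regions collapse.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity threshold must lie in (0, 1]")
    pairs = as_pairs(sequences)
    order = sorted(pairs, key=lambda p: (-len(p[1]), p[0]))
    report = ClusterReport()
    reps: list[tuple[str, str]] = []
    for sid, seq in order:
        home = None
        for rep_id, rep_seq in reps:
            ident = _pairwise_identity(colmaps[rep_id], rep_seq,
                                       colmaps[sid], seq)
            if ident >= identity_threshold:
                home = rep_id
                break
        if home is None:
            reps.append((sid, seq))
            report.clusters[sid] = [sid]
        else:
            report.clusters[home].append(sid)
    keep = set(report.retained)
    retained = [(sid, seq) for sid, seq in pairs if sid in keep]
    return retained, report


def alignment_from_colmaps(
    sequences, colmaps: Mapping[str, ColumnMap], n_columns: int
) -> SeedAlignment:
    """Rectangular reference-space alignment built from column maps.

    Insert-state residues (unmapped) are dropped, so the result is a gapped
    matrix over the profile's reference columns, suitable for conservation
    profiling and distance computation.
    """
    pairs = as_pairs(sequences)
    rows = []
    for sid, seq in pairs:
        row = ["-"] * n_columns
        for res_idx, col in colmaps[sid].mapping.items():
            row[col - 1] = seq[res_idx - 1]
        rows.append("".join(row))
    return SeedAlignment(ids=tuple(sid for sid, _ in pairs), rows=tuple(rows))


def filter_by_coverage(
    hits: Sequence[DomainHit], hmm: ProfileHMM, min_coverage: float = 0.6
) -> list[DomainHit]:
    """Drop hits whose mapped columns cover too little of the profile,
    mirroring the removal of incomplete domain fragments."""
    return [h for h in hits if h.coverage(hmm) >= min_coverage]
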