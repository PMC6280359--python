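"""Synthetic EPDR-like protein families with planted, recoverable ground truth.

The generator emulates the statistical structure of a secreted ~200-residue
ependymin-domain family: an N-terminal hydrophobic signal peptide, cysteines
planted at the canonical reference columns of one of three conservation
profiles, a conserved proline, N-X-S/T glycosylation sequons, lineage labels
with an optional expanded paralog set, and non-family decoy sequences drawn
from background composition alone.

Every family sequence is realised against a fixed 200-column reference
consensus through a recorded substitution/indel pattern, so the residue ->
reference-column map of each sequence is known exactly (the ``SyntheticTruth``
table).  Divergence is hierarchical: each clade has an ancestor diverged from
the family consensus, and sequences diverge from their clade ancestor, which
plants a recoverable two-clade phylogenetic signal while keeping total
divergence from the consensus at roughly ``mutation_rate``.

Neither the consensus nor the clade ancestors ever carry a cysteine outside
the planted canonical columns, mirroring the strong depletion of free
cysteines in secreted disulphide-bonded proteins; incidental per-sequence
background cysteines remain possible at low frequency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .alphabet import AMINO_ACIDS, AA_INDEX, BACKGROUND, decode

__all__ = [
    "SyntheticConfig",
    "SeqTruth",
    "SyntheticTruth",
    "UNIVERSAL_CYS_COLUMNS",
    "PROFILE_EXTRA_COLUMNS",
    "PROLINE_COLUMN",
    "N_REF_COLUMNS",
    "generate_family",
    "generate_decoys",
    "write_truth",
    "read_truth",
    "cigar_to_colmap",
    "family_alignment",
]

# ---------------------------------------------------------------------------
# Reference-column constants
# ---------------------------------------------------------------------------

N_REF_COLUMNS = 200

#: Cysteine columns shared by every profile.
UNIVERSAL_CYS_COLUMNS = (23, 94, 186)
#: Additional conserved-cysteine columns defining each profile.
PROFILE_EXTRA_COLUMNS = {"1": (148,), "2": (24, 107, 148), "3": (107,)}
#: Conserved proline at the floor of the ligand pocket.
PROLINE_COLUMN = 150

CANONICAL_COLUMNS = tuple(sorted(set(UNIVERSAL_CYS_COLUMNS)
                                 | {c for v in PROFILE_EXTRA_COLUMNS.values()
                                    for c in v}))

#: Fish-type sequon columns: N positions 3 and 27 residues upstream of the
#: column-94 cysteine when no indels intervene.
FISH_SEQUON_COLUMNS = (67, 91)

# Indel-free window guaranteeing that planted fish-type sequon offsets to the
# column-94 cysteine survive in residue coordinates.
_INDEL_FREE_RANGE = set(range(66, 95))

_CYS = AA_INDEX["C"]
_PRO = AA_INDEX["P"]

_BG_NO_C = BACKGROUND.copy()
_BG_NO_C[_CYS] = 0.0
_BG_NO_C /= _BG_NO_C.sum()

_HYDROPHOBIC = np.array([AA_INDEX[a] for a in "LIVFAM"])

# The family consensus is a package constant: deterministic, cysteine-free
# outside canonical columns, proline at the pocket column.
_consensus_rng = np.random.default_rng(118628)
REFERENCE_CONSENSUS = _consensus_rng.choice(20, size=N_REF_COLUMNS, p=_BG_NO_C)
REFERENCE_CONSENSUS[PROLINE_COLUMN - 1] = _PRO
del _consensus_rng

# Hierarchical divergence split: fraction of mutation_rate spent between the
# consensus and each clade ancestor versus within clades.
_CLADE_DIVERGENCE_FRAC = 0.7
_WITHIN_CLADE_FRAC = 0.3
_EXPANSION_ANCESTOR_FRAC = 0.2
_EXPANSION_WITHIN_FRAC = 0.1


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; equal configs (incl. seed) give identical output."""

    n_per_profile: int = 100
    n_decoys: int = 1000
    length_median: int = 213        # mature-protein residues
    length_spread: int = 15         # half inter-quartile width
    signal_len: int = 18
    n_taxa: int = 30
    expansion_taxon: str | None = "Amphimedon_sim"
    expansion_size: int = 17
    sequon_rate: float = 2.0
    mutation_rate: float = 0.4
    indel_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_profile, self.n_decoys, self.n_taxa,
               self.expansion_size) < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.length_median <= self.signal_len:
            raise ValueError("length_median must exceed signal_len")
        if (self.expansion_taxon is not None and self.n_per_profile > 0
                and self.expansion_size > self.n_per_profile):
            raise ValueError("expansion_size cannot exceed n_per_profile")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SeqTruth:
    """Planted ground truth for one generated sequence."""

    id: str
    taxon: str
    true_profile: str               # "1" | "2" | "3" | "decoy"
    true_clade: str                 # "1" | "2" | "none"
    cys_positions: tuple[int, ...]  # 1-based indices of planted canonical C
    sequon_positions: tuple[int, ...]
    signal_span: tuple[int, int] | None
    cigar: str                      # e.g. "18S63M1I130M2D7M11T"


@dataclass
class SyntheticTruth:
    """Truth table for a generated bundle, with column-map reconstruction."""

    records: list[SeqTruth] = field(default_factory=list)

    def __post_init__(self):
        self._by_id = {r.id: r for r in self.records}

    def __len__(self):
        return len(self.records)

    def __getitem__(self, seq_id: str) -> SeqTruth:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def colmap(self, seq_id: str) -> dict[int, int]:
        """Residue-index -> reference-column map recorded at generation."""
        return cigar_to_colmap(self._by_id[seq_id].cigar)

    def taxa(self) -> dict[str, str]:
        return {r.id: r.taxon for r in self.records}


# ---------------------------------------------------------------------------
# CIGAR helpers (S = unaligned leader, M = match column, I = insertion,
# D = deleted column, T = unaligned tail)
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([SMIDT])")


def cigar_to_colmap(cigar: str) -> dict[int, int]:
    """Expand a recorded indel pattern into a residue -> column map."""
    res, col = 0, 0
    mapping: dict[int, int] = {}
    for n_str, op in _CIGAR_RE.findall(cigar):
        n = int(n_str)
        if op in ("S", "T"):
            res += n
        elif op == "M":
            for _ in range(n):
                res += 1
                col += 1
                mapping[res] = col
        elif op == "I":
            res += n
        elif op == "D":
            col += n
    return mapping


def _ops_to_cigar(ops: list[tuple[str, int]]) -> str:
    """Run-length-merge adjacent ops into a CIGAR string."""
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return "".join(f"{n}{op}" for op, n in merged)


def family_alignment(sequences, truth: SyntheticTruth,
                     ids: Iterable[str] | None = None):
    """Reference-space alignment of family sequences from recorded maps.

    Insertions are dropped (they are sequence-specific by construction) and
    deleted columns appear as gaps, giving a rectangular alignment over the
    200 reference columns.
    """
    from .hmm import SeedAlignment, as_pairs

    seq_of = dict(as_pairs(sequences))
    wanted = list(ids) if ids is not None else [
        r.id for r in truth.records if r.true_profile != "decoy"
    ]
    rows = []
    for sid in wanted:
        cmap = truth.colmap(sid)
        row = ["-"] * N_REF_COLUMNS
        seq = seq_of[sid]
        for res_idx, col in cmap.items():
            row[col - 1] = seq[res_idx - 1]
        rows.append("".join(row))
    return SeedAlignment(ids=tuple(wanted), rows=tuple(rows))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _substitute(codes: np.ndarray, rate: float, mutable: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution away from the current residue, cysteine-free."""
    out = codes.copy()
    hit = np.flatnonzero((rng.random(codes.size) < rate) & mutable)
    for j in hit:
        draw = rng.choice(20, p=_BG_NO_C)
        while draw == out[j]:
            draw = rng.choice(20, p=_BG_NO_C)
        out[j] = draw
    return out


def _sample_length(rng: np.random.Generator, median: int, spread: int) -> int:
    """Discretised symmetric length distribution around the median."""
    sigma = spread / 0.6745 if spread > 0 else 0.0
    return max(1, int(round(rng.normal(median, sigma))))


def _signal_peptide(rng: np.random.Generator, signal_len: int) -> str:
    """Hydrophobic signal segment ending in an A-X-A cleavage motif."""
    core_len = max(signal_len - 4, 0)
    core = rng.choice(_HYDROPHOBIC, size=core_len)
    x = rng.choice(20, p=_BG_NO_C)
    while AMINO_ACIDS[x] == "P":
        x = rng.choice(20, p=_BG_NO_C)
    codes = np.concatenate([[AA_INDEX["M"]], core,
                            [AA_INDEX["A"], x, AA_INDEX["A"]]])
    return decode(codes[:signal_len])


def _plant_sequons(codes: np.ndarray, columns: Iterable[int],
                   rng: np.random.Generator) -> None:
    """Write N-X(!=P)-S/T motifs at the given N columns (in place)."""
    for c in columns:
        codes[c - 1] = AA_INDEX["N"]
        if codes[c] in (_PRO, _CYS):
            codes[c] = AA_INDEX["Q"]
        codes[c + 1] = AA_INDEX["S" if rng.random() < 0.5 else "T"]


def _safe_sequon_columns(rng: np.random.Generator, n: int,
                         blocked: set[int]) -> list[int]:
    """Random N columns whose triplet avoids canonical and blocked columns."""
    chosen: list[int] = []
    candidates = [
        c for c in range(2, N_REF_COLUMNS - 2)
        if not ({c, c + 1, c + 2} & blocked)
    ]
    for _ in range(n):
        if not candidates:
            break
        c = int(rng.choice(candidates))
        chosen.append(c)
        candidates = [x for x in candidates if abs(x - c) > 2]
    return sorted(chosen)


def generate_family(config: SyntheticConfig):
    """Generate an EPDR-like bundle: ``(sequences, truth)``.

    ``sequences`` is a list of ``(id, protein)`` pairs containing
    ``3 * n_per_profile`` family members followed by ``n_decoys`` decoys;
    ``truth`` records the planted profile, clade, taxon, feature coordinates
    and the residue -> reference-column map of every family sequence.
    """
    rng = np.random.default_rng(config.seed)
    sequences: list[tuple[str, str]] = []
    records: list[SeqTruth] = []

    if config.n_per_profile == 0 and config.n_decoys == 0:
        return sequences, SyntheticTruth(records=[])

    base_protected = np.ones(N_REF_COLUMNS, dtype=bool)
    for c in CANONICAL_COLUMNS + (PROLINE_COLUMN,):
        base_protected[c - 1] = False
    mutable = base_protected       # True where substitutions are allowed

    m = config.mutation_rate
    clade_anc = {
        "1": _substitute(REFERENCE_CONSENSUS, m * _CLADE_DIVERGENCE_FRAC,
                         mutable, rng),
        "2": _substitute(REFERENCE_CONSENSUS, m * _CLADE_DIVERGENCE_FRAC,
                         mutable, rng),
    }
    expansion_anc = None
    if config.expansion_taxon is not None:
        expansion_anc = _substitute(clade_anc["2"],
                                    m * _EXPANSION_ANCESTOR_FRAC, mutable, rng)

    taxa = [f"taxon{i + 1:02d}" for i in range(max(config.n_taxa, 1))]
    taxon_cycle = 0

    canonical_set = set(CANONICAL_COLUMNS) | {PROLINE_COLUMN}

    for profile in ("1", "2", "3"):
        cys_cols = sorted(set(UNIVERSAL_CYS_COLUMNS)
                          | set(PROFILE_EXTRA_COLUMNS[profile]))
        clade = "1" if profile == "1" else "2"
        for i in range(config.n_per_profile):
            in_expansion = (
                profile == "2" and expansion_anc is not None
                and i < config.expansion_size
            )
            if in_expansion:
                ancestor, within = expansion_anc, m * _EXPANSION_WITHIN_FRAC
                taxon = config.expansion_taxon
            else:
                ancestor, within = clade_anc[clade], m * _WITHIN_CLADE_FRAC
                taxon = taxa[taxon_cycle % len(taxa)]
                taxon_cycle += 1

            codes = _substitute(ancestor, within, mutable, rng)
            for c in cys_cols:
                codes[c - 1] = _CYS
            codes[PROLINE_COLUMN - 1] = _PRO

            # Sequons: fish-type (profile 1) at the canonical upstream
            # offsets; otherwise a Poisson number at random safe columns.
            if profile == "1":
                sequon_cols = list(FISH_SEQUON_COLUMNS)
            else:
                n_seqons = int(rng.poisson(config.sequon_rate))
                sequon_cols = _safe_sequon_columns(
                    rng, n_seqons, canonical_set | _INDEL_FREE_RANGE
                )
            _plant_sequons(codes, sequon_cols, rng)

            # Indels at unprotected columns only; planted features and the
            # sequon->cysteine window never shift or vanish.
            no_indel = set(canonical_set) | _INDEL_FREE_RANGE
            for c in sequon_cols:
                no_indel.update((c, c + 1, c + 2))
            residues: list[int] = []
            ops: list[tuple[str, int]] = [("S", config.signal_len)]
            cys_res: dict[int, int] = {}
            sequon_res: dict[int, int] = {}
            for col in range(1, N_REF_COLUMNS + 1):
                u = rng.random() if col not in no_indel else 1.0
                if u < config.indel_rate / 2.0:        # delete this column
                    ops.append(("D", 1))
                    continue
                residues.append(int(codes[col - 1]))
                ops.append(("M", 1))
                if col in cys_cols:
                    cys_res[col] = len(residues)
                if col in sequon_cols:
                    sequon_res[col] = len(residues)
                if u < config.indel_rate:              # insert after column
                    ins_len = min(int(rng.geometric(0.6)), 3)
                    ins = rng.choice(20, size=ins_len, p=BACKGROUND)
                    residues.extend(int(x) for x in ins)
                    ops.append(("I", ins_len))

            target = _sample_length(rng, config.length_median,
                                    config.length_spread)
            tail_len = max(0, target - len(residues))
            tail = rng.choice(20, size=tail_len, p=BACKGROUND)
            residues.extend(int(x) for x in tail)
            ops.append(("T", tail_len))

            signal = _signal_peptide(rng, config.signal_len)
            seq = signal + decode(np.array(residues, dtype=np.int64))
            offset = config.signal_len
            sid = f"fam_p{profile}_{i:03d}"
            sequences.append((sid, seq))
            records.append(SeqTruth(
                id=sid,
                taxon=taxon,
                true_profile=profile,
                true_clade=clade,
                cys_positions=tuple(offset + cys_res[c] for c in cys_cols),
                sequon_positions=tuple(offset + sequon_res[c]
                                       for c in sorted(sequon_res)),
                signal_span=(1, config.signal_len),
                cigar=_ops_to_cigar(ops),
            ))

    decoy_median = config.length_median + config.signal_len
    for i in range(config.n_decoys):
        length = max(10, _sample_length(rng, decoy_median,
                                        config.length_spread))
        seq = decode(rng.choice(20, size=length, p=BACKGROUND))
        sid = f"decoy_{i:04d}"
        taxon = taxa[taxon_cycle % len(taxa)]
        taxon_cycle += 1
        sequences.append((sid, seq))
        records.append(SeqTruth(
            id=sid, taxon=taxon, true_profile="decoy", true_clade="none",
            cys_positions=(), sequon_positions=(), signal_span=None, cigar="",
        ))

    return sequences, SyntheticTruth(records=records)


def generate_decoys(n: int, length_stats: tuple[int, int] = (213, 15),
                    seed: int = 0) -> list[tuple[str, str]]:
    """Background-composition decoy sequences with no planted scaffold."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    median, spread = length_stats
    out = []
    for i in range(n):
        length = max(10, _sample_length(rng, median, spread))
        out.append((f"decoy_{i:04d}",
                    decode(rng.choice(20, size=length, p=BACKGROUND))))
    return out


# ---------------------------------------------------------------------------
# Truth-table I/O
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = ("id", "taxon", "true_profile", "true_clade",
                  "cys_positions", "sequon_positions", "signal_start",
                  "signal_end", "cigar")


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialise a truth table to TSV (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for r in truth.records:
            start, end = r.signal_span if r.signal_span else ("", "")
            fh.write("\t".join([
                r.id, r.taxon, r.true_profile, r.true_clade,
                ",".join(map(str, r.cys_positions)),
                ",".join(map(str, r.sequon_positions)),
                str(start), str(end), r.cigar,
            ]) + "\n")


def read_truth(path) -> SyntheticTruth:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TRUTH_COLUMNS:
            raise ValueError("unrecognised truth-table header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            row = dict(zip(_TRUTH_COLUMNS, f))
            span = ((int(row["signal_start"]), int(row["signal_end"]))
                    if row["signal_start"] else None)
            records.append(SeqTruth(
                id=row["id"], taxon=row["taxon"],
                true_profile=row["true_profile"],
                true_clade=row["true_clade"],
                cys_positions=tuple(
                    int(x) for x in row["cys_positions"].split(",") if x),
                sequon_positions=tuple(
                    int(x) for x in row["sequon_positions"].split(",") if x),
                signal_span=span,
                cigar=row["cigar"],
            ))
    return SyntheticTruth(records=records)
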