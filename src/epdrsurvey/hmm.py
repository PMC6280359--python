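"""Profile hidden Markov model construction, scoring and E-value calibration.

This module implements a self-contained profile HMM over the 20-letter
amino-acid alphabet, built from a seed multiple alignment, together with
forward (log-odds bit score) and Viterbi (state path) scoring and a Gumbel
E-value calibration against background-composition random sequences.

Model topology
--------------
The core is the classic match/insert/delete architecture: one match state per
well-occupied seed column, insert states emitting the background distribution
(so their emission log-odds is exactly zero), and mute delete states.  The
alignment mode is *glocal*: the whole profile must be traversed (via match or
delete states) while the sequence is matched locally — unaligned N- and
C-terminal flanks are emitted by free flanking states whose per-residue
log-odds contribution is zero.  The forward score therefore aggregates, in
log space, over every (start, state path, end) combination; the Viterbi score
takes the single best one.  Scores are reported in bits:

    S = log2 P(x | profile) - log2 P(x | iid background)

with the flank convention above.  E-values come from a maximum-likelihood
Gumbel fit to the forward scores of random background sequences,

    E(S) = N * exp(-lambda * (S - mu)),  clamped to [0, N],

where N is the size of the searched database.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import gumbel_r

from .alphabet import AMINO_ACIDS, BACKGROUND, GAP_CHARS, encode

__all__ = [
    "SeedAlignment",
    "ProfileHMM",
    "EvalueCalibration",
    "DomainHit",
    "DegenerateAlignmentError",
    "CalibrationError",
    "build_profile",
    "score_sequence",
    "calibrate_evalue",
    "search",
]

_LN2 = math.log(2.0)
_NEG_INF = -np.inf


class DegenerateAlignmentError(ValueError):
    """Raised when a seed alignment yields no usable match states."""


class CalibrationError(RuntimeError):
    """Raised when the random-score distribution cannot support a Gumbel fit."""


def as_pairs(sequences) -> list[tuple[str, str]]:
    """Normalise a sequence collection to ``[(id, sequence), ...]``."""
    if isinstance(sequences, Mapping):
        return list(sequences.items())
    out = []
    for item in sequences:
        if isinstance(item, tuple):
            out.append((item[0], str(item[1])))
        else:  # assume SeqRecord-like
            out.append((item.id, str(item.seq)))
    return out


@dataclass(frozen=True)
class SeedAlignment:
    """A protein multiple alignment with equal-length rows, 1-based columns."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.rows) < 1:
            raise ValueError("alignment needs >= 1 row")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        allowed = set(AMINO_ACIDS) | GAP_CHARS
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - allowed
            if bad:
                raise ValueError(f"row {rid!r} has illegal symbols {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        """Residues (and gaps) of 1-based column ``j``."""
        return "".join(row[j - 1] for row in self.rows)

    def occupancy(self) -> np.ndarray:
        """Fraction of non-gap symbols per column (length ``n_columns``)."""
        mat = np.array([[c not in GAP_CHARS for c in row] for row in self.rows])
        return mat.mean(axis=0)

    def subset(self, ids: Iterable[str]) -> "SeedAlignment":
        wanted = list(ids)
        index = {rid: i for i, rid in enumerate(self.ids)}
        missing = [w for w in wanted if w not in index]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return SeedAlignment(
            ids=tuple(wanted), rows=tuple(self.rows[index[w]] for w in wanted)
        )

    @classmethod
    def from_fasta(cls, path) -> "SeedAlignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids=tuple(ids), rows=tuple(rows))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")


# --------------------------------------------------------------------------
# Profile model
# --------------------------------------------------------------------------

@dataclass
class ProfileHMM:
    """Match/insert/delete profile model with a match-state -> column map.

    ``out_m[j]``, ``out_i[j]``, ``out_d[j]`` (1-based ``j``) are probability
    triples over the transitions leaving level-``j`` states, in slot order
    ``[advance, insert, delete]`` where *advance* means M/D at level ``j+1``
    for ``j < k`` and the end state for ``j == k`` (the delete slot is zero at
    ``j == k``).  ``out_b`` is ``[B->M1, B->D1]``.
    """

    match_emissions: np.ndarray      # (k, 20) probabilities
    background: np.ndarray           # (20,) probabilities
    out_m: np.ndarray                # (k + 1, 3); row 0 unused
    out_i: np.ndarray
    out_d: np.ndarray
    out_b: np.ndarray                # (2,)
    column_map: np.ndarray           # (k,) 1-based source columns, increasing

    def __post_init__(self):
        k = self.n_match_states
        if k < 1:
            raise DegenerateAlignmentError("profile needs >= 1 match state")
        if not np.all(np.diff(self.column_map) > 0):
            raise ValueError("column map must be strictly increasing")
        for name, arr in (("emissions", self.match_emissions),
                          ("out_m", self.out_m[1:]), ("out_i", self.out_i[1:]),
                          ("out_d", self.out_d[1:])):
            if not np.allclose(arr.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
        if not math.isclose(self.out_b.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("begin transitions must sum to 1")
        self._prepare_logs()

    def _prepare_logs(self):
        with np.errstate(divide="ignore"):
            self._lo_em = np.log(self.match_emissions) - np.log(self.background)
            self._ln_m = np.log(self.out_m)
            self._ln_i = np.log(self.out_i)
            self._ln_d = np.log(self.out_d)
            self._ln_b = np.log(self.out_b)

    @property
    def n_match_states(self) -> int:
        return self.match_emissions.shape[0]

    # -- serialisation ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "format": "epdrsurvey-profile/1",
            "alphabet": AMINO_ACIDS,
            "match_emissions": self.match_emissions.tolist(),
            "background": self.background.tolist(),
            "out_m": self.out_m.tolist(),
            "out_i": self.out_i.tolist(),
            "out_d": self.out_d.tolist(),
            "out_b": self.out_b.tolist(),
            "column_map": self.column_map.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ProfileHMM":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "epdrsurvey-profile/1":
            raise ValueError("unrecognised profile serialisation format")
        return cls(
            match_emissions=np.array(payload["match_emissions"]),
            background=np.array(payload["background"]),
            out_m=np.array(payload["out_m"]),
            out_i=np.array(payload["out_i"]),
            out_d=np.array(payload["out_d"]),
            out_b=np.array(payload["out_b"]),
            column_map=np.array(payload["column_map"], dtype=np.int64),
        )


@dataclass(frozen=True)
class EvalueCalibration:
    """Gumbel tail calibration of forward bit scores on random sequences."""

    gumbel_lambda: float   # per bit
    gumbel_mu: float       # bits
    database_size: int
    n_random: int
    seed: int

    def __post_init__(self):
        if self.gumbel_lambda <= 0:
            raise ValueError("gumbel_lambda must be positive")
        if self.n_random < 100:
            raise ValueError("n_random must be >= 100")

    def evalue(self, bit_score: float) -> float:
        raw = self.database_size * math.exp(
            -self.gumbel_lambda * (bit_score - self.gumbel_mu)
        )
        return min(max(raw, 0.0), float(self.database_size))


@dataclass
class DomainHit:
    """Best-per-sequence domain hit with score, E-value and state path."""

    sequence_id: str
    bit_score: float
    e_value: float | None
    span: tuple[int, int]            # 1-based inclusive residue span
    path: tuple[tuple[str, int, int], ...]   # (op, match_level, residue_index)
    passed: bool = False

    def coverage(self, hmm: ProfileHMM) -> float:
        """Fraction of match states realised as match emissions."""
        n_match = sum(1 for op, _, _ in self.path if op == "M")
        return n_match / hmm.n_match_states


# --------------------------------------------------------------------------
# Construction
# --------------------------------------------------------------------------

def _state_path_for_row(row: str, is_match: np.ndarray) -> list[tuple[str, int]]:
    """Seed-row state path as (state, level) pairs, levels 1..k."""
    path = []
    level = 0
    for j, symbol in enumerate(row):
        gap = symbol in GAP_CHARS
        if is_match[j]:
            level += 1
            path.append(("D" if gap else "M", level))
        elif not gap:
            path.append(("I", level))
    return path


def build_profile(
    seed: SeedAlignment,
    match_occupancy_threshold: float = 0.5,
    pseudocount: float = 1.0,
) -> ProfileHMM:
    """Estimate a :class:`ProfileHMM` from a seed alignment.

    Columns whose residue occupancy is >= ``match_occupancy_threshold``
    (inclusive) become match states.  Emissions are
    ``(counts + pseudocount * q) / (n + pseudocount)`` with ``q`` the
    background estimated from all seed residues (Laplace-smoothed);
    transitions are estimated from the observed per-row state paths with a
    uniform ``pseudocount`` spread over each outgoing-transition set.
    """
    if seed.n_rows < 2:
        raise DegenerateAlignmentError("profile estimation needs >= 2 rows")
    occ = seed.occupancy()
    is_match = occ >= match_occupancy_threshold
    k = int(is_match.sum())
    if k == 0:
        raise DegenerateAlignmentError(
            "no column meets the match-state occupancy threshold"
        )
    column_map = np.flatnonzero(is_match) + 1  # 1-based

    # Background from all residues in the seed (Laplace smoothing keeps q > 0).
    counts_q = np.zeros(20)
    for row in seed.rows:
        for c in row:
            if c not in GAP_CHARS:
                counts_q[AMINO_ACIDS.index(c)] += 1
    q = (counts_q + 1.0) / (counts_q.sum() + 20.0)

    # Match emissions.
    em_counts = np.zeros((k, 20))
    match_cols = np.flatnonzero(is_match)
    for row in seed.rows:
        for s, j in enumerate(match_cols):
            c = row[j]
            if c not in GAP_CHARS:
                em_counts[s, AMINO_ACIDS.index(c)] += 1
    emissions = (em_counts + pseudocount * q) / (
        em_counts.sum(axis=1, keepdims=True) + pseudocount
    )

    # Transition counts.  Slot order: [advance, insert, delete]; at the last
    # level the advance slot targets the end state and delete is impossible.
    cm = np.zeros((k + 1, 3))
    ci = np.zeros((k + 1, 3))
    cd = np.zeros((k + 1, 3))
    cb = np.zeros(2)
    for row in seed.rows:
        path = _state_path_for_row(row, is_match)
        # Leading inserts before the first match column are treated as flank
        # (the glocal model emits them for free); drop level-0 inserts.
        path = [(s, lvl) for s, lvl in path if lvl > 0 or s != "I"]
        first = path[0]
        cb[0 if first[0] == "M" else 1] += 1
        for (s1, l1), (s2, l2) in zip(path, path[1:]):
            slot = {"M": 0, "I": 1, "D": 2}[s2] if s2 != "I" else 1
            if s2 in ("M", "D") and l2 != l1 + 1:
                raise AssertionError("non-contiguous seed state path")
            counter = {"M": cm, "I": ci, "D": cd}[s1]
            counter[l1, slot] += 1
        last_s, last_l = path[-1]
        if last_l != k and last_s in ("M", "D"):
            raise AssertionError("seed path does not reach final level")
        {"M": cm, "I": ci, "D": cd}[last_s][k, 0] += 1

    def _norm(counts: np.ndarray) -> np.ndarray:
        probs = np.zeros_like(counts)
        for j in range(1, k + 1):
            n_slots = 2 if j == k else 3   # no delete transition past level k
            c = counts[j, :n_slots] + pseudocount / n_slots
            probs[j, :n_slots] = c / c.sum()
        return probs

    out_b = cb + pseudocount / 2.0
    out_b = out_b / out_b.sum()
    return ProfileHMM(
        match_emissions=emissions,
        background=q,
        out_m=_norm(cm),
        out_i=_norm(ci),
        out_d=_norm(cd),
        out_b=out_b,
        column_map=column_map,
    )


# --------------------------------------------------------------------------
# Scoring
# --------------------------------------------------------------------------

def _dp_matrices(hmm: ProfileHMM, codes: np.ndarray, viterbi: bool):
    """Fill glocal DP matrices in natural-log-odds space.

    Returns ``(M, I, D, end_vec)`` each over (level 0..k, position 0..L);
    ``end_vec[i]`` is the score of finishing the profile with ``i`` residues
    consumed (the free C-terminal flank absorbs the rest).
    """
    k = hmm.n_match_states
    L = len(codes)
    combine = np.maximum if viterbi else np.logaddexp

    lo_em = hmm._lo_em * 1.0
    ln_m, ln_i, ln_d, ln_b = hmm._ln_m, hmm._ln_i, hmm._ln_d, hmm._ln_b

    M = np.full((k + 1, L + 1), _NEG_INF)
    I = np.full((k + 1, L + 1), _NEG_INF)
    D = np.full((k + 1, L + 1), _NEG_INF)

    with np.errstate(invalid="ignore"):
        # Level 1: entry from the free N flank (score 0 at any start point).
        if L:
            M[1, 1:] = lo_em[0, codes] + ln_b[0]
        D[1, :] = ln_b[1]
        _fill_insert(I, M, D, 1, ln_m[1, 1], ln_i[1, 1], ln_d[1, 1], combine, L)

        for j in range(2, k + 1):
            prev = combine(
                combine(M[j - 1, :-1] + ln_m[j - 1, 0], I[j - 1, :-1] + ln_i[j - 1, 0]),
                D[j - 1, :-1] + ln_d[j - 1, 0],
            )
            if L:
                M[j, 1:] = lo_em[j - 1, codes] + prev
            D[j, :] = combine(
                combine(M[j - 1, :] + ln_m[j - 1, 2], I[j - 1, :] + ln_i[j - 1, 2]),
                D[j - 1, :] + ln_d[j - 1, 2],
            )
            _fill_insert(I, M, D, j, ln_m[j, 1], ln_i[j, 1], ln_d[j, 1], combine, L)

        end_vec = combine(
            combine(M[k, :] + ln_m[k, 0], I[k, :] + ln_i[k, 0]),
            D[k, :] + ln_d[k, 0],
        )
    return M, I, D, end_vec


def _fill_insert(I, M, D, j, ln_mi, ln_ii, ln_di, combine, L):
    """Insert-state row via a prefix scan (geometric self-loop decay)."""
    if L == 0:
        return
    base = combine(M[j, :-1] + ln_mi, D[j, :-1] + ln_di)  # entry at i-1
    idx = np.arange(1, L + 1)
    u = base - idx * ln_ii
    if combine is np.maximum:
        acc = np.maximum.accumulate(u)
    else:
        acc = np.logaddexp.accumulate(u)
    I[j, 1:] = acc + idx * ln_ii


def forward_bits(hmm: ProfileHMM, seq: str) -> float:
    """Forward log-odds score in bits (sum over all glocal alignments)."""
    codes = encode(seq)
    if codes.size == 0:
        raise ValueError("empty sequence")
    *_, end_vec = _dp_matrices(hmm, codes, viterbi=False)
    from scipy.special import logsumexp

    return float(logsumexp(end_vec) / _LN2)


def viterbi_path(hmm: ProfileHMM, seq: str):
    """Best glocal alignment: ``(bits, path)``.

    The path is a tuple of ``(op, level, residue_index)`` with op in
    ``{"M", "I", "D"}``; residue_index is 1-based (0 for delete states).
    """
    codes = encode(seq)
    if codes.size == 0:
        raise ValueError("empty sequence")
    M, I, D, end_vec = _dp_matrices(hmm, codes, viterbi=True)
    k = hmm.n_match_states
    L = len(codes)
    ln_m, ln_i, ln_d, ln_b = hmm._ln_m, hmm._ln_i, hmm._ln_d, hmm._ln_b
    lo_em = hmm._lo_em

    i = int(np.argmax(end_vec))
    score = end_vec[i] / _LN2
    # Which final state fed the end transition?
    cands = [
        ("M", M[k, i] + ln_m[k, 0]),
        ("I", I[k, i] + ln_i[k, 0]),
        ("D", D[k, i] + ln_d[k, 0]),
    ]
    state = max(cands, key=lambda t: t[1])[0]
    j = k
    rev: list[tuple[str, int, int]] = []
    while True:
        if state == "M":
            rev.append(("M", j, i))
            i -= 1
            if j == 1:
                break  # entered from begin/flank
            prev = [
                ("M", M[j - 1, i] + ln_m[j - 1, 0]),
                ("I", I[j - 1, i] + ln_i[j - 1, 0]),
                ("D", D[j - 1, i] + ln_d[j - 1, 0]),
            ]
            j -= 1
        elif state == "I":
            rev.append(("I", j, i))
            i -= 1
            prev = [
                ("M", M[j, i] + ln_m[j, 1]),
                ("I", I[j, i] + ln_i[j, 1]),
                ("D", D[j, i] + ln_d[j, 1]),
            ]
        else:  # D
            rev.append(("D", j, 0))
            if j == 1:
                break
            prev = [
                ("M", M[j - 1, i] + ln_m[j - 1, 2]),
                ("I", I[j - 1, i] + ln_i[j - 1, 2]),
                ("D", D[j - 1, i] + ln_d[j - 1, 2]),
            ]
            j -= 1
        state = max(prev, key=lambda t: t[1])[0]
    rev.reverse()
    return float(score), tuple(rev)


def score_sequence(hmm: ProfileHMM, seq, sequence_id: str = "seq") -> DomainHit:
    """Score one sequence: forward bit score plus Viterbi state path/span."""
    if isinstance(seq, tuple):
        sequence_id, seq = seq
    bits = forward_bits(hmm, seq)
    _, path = viterbi_path(hmm, seq)
    residue_idx = [i for op, _, i in path if op in ("M", "I")]
    span = (min(residue_idx), max(residue_idx)) if residue_idx else (0, 0)
    return DomainHit(
        sequence_id=sequence_id, bit_score=bits, e_value=None, span=span, path=path
    )


# --------------------------------------------------------------------------
# Calibration and search
# --------------------------------------------------------------------------

def random_background_sequences(
    n: int, length_model: tuple[float, float], seed: int,
    background: np.ndarray | None = None,
) -> list[str]:
    """i.i.d. background-composition sequences with discretised-normal lengths.

    ``length_model`` is ``(median, half_iqr)``; lengths are rounded normal
    deviates with the matching quartiles, floored at 10 residues.
    """
    rng = np.random.default_rng(seed)
    q = BACKGROUND if background is None else background
    median, spread = length_model
    sigma = spread / 0.6745 if spread > 0 else 0.0
    lengths = np.maximum(10, np.rint(rng.normal(median, sigma, size=n))).astype(int)
    return [
        "".join(np.array(list(AMINO_ACIDS))[rng.choice(20, size=l, p=q)])
        for l in lengths
    ]


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns ``(lambda, mu)`` (lambda = 1/scale)."""
    mu, beta = gumbel_r.fit(np.asarray(scores, dtype=float))
    return 1.0 / beta, float(mu)


def calibrate_evalue(
    hmm: ProfileHMM,
    n_random: int = 1000,
    length_model: tuple[float, float] = (213.0, 15.0),
    seed: int = 0,
    database_size: int | None = None,
) -> EvalueCalibration:
    """Fit a Gumbel law to forward scores of random background sequences."""
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    seqs = random_background_sequences(n_random, length_model, seed,
                                       background=hmm.background)
    scores = np.array([forward_bits(hmm, s) for s in seqs])
    if np.std(scores) < 1e-12:
        raise CalibrationError("random-score distribution is degenerate")
    lam, mu = fit_gumbel(scores)
    return EvalueCalibration(
        gumbel_lambda=lam,
        gumbel_mu=mu,
        database_size=int(database_size if database_size is not None else n_random),
        n_random=n_random,
        seed=seed,
    )


def search(
    hmm: ProfileHMM,
    sequences,
    calibration: EvalueCalibration,
    cutoff: float = 1e-5,
) -> list[DomainHit]:
    """Best-per-sequence domain search at an E-value ``cutoff``.

    Returns hits sorted by E-value ascending, ties broken by id; ``passed``
    flags hits with ``e_value <= cutoff``.
    """
    pairs = as_pairs(sequences)
    hits = []
    for sid, seq in pairs:
        hit = score_sequence(hmm, seq, sequence_id=sid)
        hit.e_value = calibration.evalue(hit.bit_score)
        hit.passed = hit.e_value <= cutoff
        hits.append(hit)
    hits.sort(key=lambda h: (h.e_value, h.sequence_id))
    return hits


def hits_to_tsv(hits: Sequence[DomainHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tbitscore\tevalue\tstart\tend\tpass\n")
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.bit_score:.4f}\t{h.e_value:.6g}\t"
                f"{h.span[0]}\t{h.span[1]}\t{int(h.passed)}\n"
            )
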