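# Methods

This note records the models, parameter choices and numerical conventions
behind `epdrsurvey`, and what the synthetic benchmark does and does not
demonstrate.

## Profile model and scoring

The profile HMM follows the classic match/insert/delete architecture over the
20-letter amino-acid alphabet. From a seed alignment, columns with residue
occupancy ≥ 0.5 (inclusive) become match states. Match emissions are
`(counts + τ·q)/(n + τ)` with a single pseudocount weight `τ = 1` allocated
proportionally to the background `q`; `q` itself is the Laplace-smoothed
residue composition of the seed alignment, which doubles as the null model,
so the package needs no external composition tables. Transitions are counted
from each seed row's implied state path with the same uniform pseudocounting
over each outgoing set. Insert states emit `q`, making their emission
log-odds exactly zero.

Alignment is *glocal*: the profile must be traversed end to end (matches or
deletes) while the sequence is matched locally. Unaligned N-/C-terminal
flanks are free — they contribute zero log-odds per residue — so the forward
score aggregates over every (start, path, end) combination and the Viterbi
score takes the best one. This suits a domain that spans nearly the whole
mature protein with a variable C-terminal tail. Scores are bits:
`S = log₂ P(x|profile) − log₂ P(x|null)` under the flank convention above.

All dynamic programming runs in natural-log space with `-inf` for impossible
cells; the insert self-loop recursion is evaluated as a prefix scan
(`logaddexp.accumulate` after factoring out the geometric decay), which keeps
the whole DP vectorised and stable for sequences up to at least 10,000
residues. Correctness is pinned by a brute-force oracle that enumerates every
path of small models explicitly (tests demand ≤ 1e-9 relative agreement).

**E-values.** A maximum-likelihood Gumbel fit (location μ, inverse scale λ)
to forward scores of `n_random = 1000` background sequences gives
`E(S) = N·exp(−λ(S−μ))`, clamped to `[0, N]`, with `N` the searched database
size. Any monotone calibration preserves the cutoff semantics; the default
cutoff is the survey's `E ≤ 1e-5`, applied to the best hit per sequence.

## Reference-column coordinates

Residue → column maps come from the Viterbi path: match emissions map to the
originating seed column, inserts are unmapped, deletes consume a column.
Coordinates are 1-based and inclusive throughout. Alignment trimming removes
columns below an occupancy threshold (default 0.5) and reports an old→new
renumbering map; classification always uses untrimmed reference numbering, so
the canonical columns keep their identities. Redundancy removal is greedy
(longest first, ties by id) on pairwise ungapped identity over shared mapped
columns, default threshold 0.97; hits mapping fewer than 60% of match states
are discarded as incomplete fragments. Both thresholds are exposed in
`SurveyConfig` — the source data dictate no particular number.

## Cysteine profiles

Templates over the six canonical columns: profile 1 = {23, 94, 148, 186},
profile 2 = {23, 24, 94, 107, 148, 186}, profile 3 = {23, 94, 107, 186};
columns 23/94/186 are universal and a conserved proline sits at column 150.
Strict mode assigns only exact template matches; tolerant mode (default)
assigns the unique nearest template within Hamming distance 1 and labels
everything else atypical — deviant family members have typically lost or
gained a single cysteine without obscuring their type, and sequences missing
more than one canonical cysteine are deliberately left atypical, deferring
their clade membership to the phylogeny stage.

## Feature heuristics

**Sequons.** N-X-S/T with X ≠ P, overlapping allowed. This is the
deterministic core of N-glycosylation site prediction; no likelihood scoring
is attempted. Offsets are reported relative to the residue occupying column
94 (the second universal cysteine), positive = upstream, because the family's
classic fish-type sites sit 3 and 27 residues before that cysteine.

**Signal peptide.** Present when some 8-residue window inside the first 30
residues has mean Kyte–Doolittle hydropathy ≥ 2.5 and a small residue
(A/G/S) occurs downstream of the window within residues 15–30. The threshold
was set from the separation the rule must achieve: hydrophobic signal cores
score ≈ 3.2 on their best window while random background sequences exceed
2.5 in only ~5% of cases; at a laxer 1.6 the background false-positive rate
approaches 30%, which would make the call uninformative. This is a screening
heuristic, not a cleavage-site predictor; accuracy claims are made only on
synthetic data.

## Conservation

Frequencies are computed over non-gap residues only, with occupancy reported
separately; `IC_j = log₂20 − H_j` is then bounded in [0, 4.32] bits
regardless of gap content. No small-sample correction is applied by default
(group sizes here are ≫ 20); a toggle subtracts the standard
`19/(2·ln2·n)` bias term, clamped at zero. "Conserved" calls use a default
frequency threshold of 0.9. Logo matrices are emitted with both
frequency and `f·IC` scaling, since either convention is common.

## Phylogeny

Distances use pairwise deletion; the Poisson correction `d = −ln(1−p)` is on
by default with `p` capped at 0.95 as a saturation guard. Neighbor joining
follows Saitou–Nei with the Q-criterion; ties resolve to the smallest
row-major index pair, and a negative branch length is clamped to zero with
the excess moved to its sibling, keeping their sum. The final three nodes are
resolved by the three-point formulas. Bootstrap support resamples alignment
columns with replacement (default 100 replicates) and scores the fraction of
replicate trees containing each original bipartition.

Clade assignment scans internal edges for the bipartition minimising the
number of misplaced profile-1/profile-2 anchors; among equally good edges
the tightest clade-1 side wins (a deterministic tie-break — the alternatives
differ only in which anchor-free subtrees they attach), and profile-3 or
atypical leaves inherit their side. If no edge beats placing every anchor on
one side, all leaves are left unassigned with a warning. Distance-based NJ
here is a deliberate, desk-scale methodological substitution for
likelihood/Bayesian tree inference: deterministic, fast, and sufficient for
two-clade and expansion logic; it is not presented as a reproduction of
model-based support values.

Expansions: a taxon with ≥ 15 members (strict ≥) is flagged, and maximal
same-taxon monophyletic clades of ≥ 2 leaves are listed as duplication
evidence.

## Synthetic families

The generator realises each family member against a fixed 200-column
reference consensus, recording the exact substitution/indel pattern so that
residue → column maps are known a priori. Defaults mirror the family's
statistics: mature-protein lengths follow a discretised symmetric
distribution with median 213 and half-IQR 15 (the source reports only a
median and a violin-shaped spread); an 18-residue signal peptide with a
hydrophobic core and A-X-A cleavage motif; ~2 sequons per sequence, planted
for profile 1 at the fish-type offsets {3, 27}; 30 taxa with one taxon
("Amphimedon_sim") receiving a 17-member paralog expansion, matching the
largest single-species family reported for a demosponge; per-site divergence
0.4 from the family consensus (within-profile divergence is not reported for
the real family; the value is exposed in `SyntheticConfig`).

Divergence is hierarchical: each clade's ancestor diverges from the consensus
at 0.7× the mutation rate and sequences diverge from their clade ancestor at
0.3×, so total divergence matches the nominal rate while within-clade
distances stay well below between-clade distances — without this structure an
i.i.d. divergence model would carry no recoverable clade signal. The
expansion taxon adds a third level (paralog ancestor at 0.2×, members at
0.1×), producing a tight monophyletic cluster that survives deduplication.
Neither the consensus nor any ancestor carries cysteine outside canonical
columns (mirroring the depletion of free cysteines in disulphide-bonded
secreted proteins); this is also what makes exact conserved-column recovery
testable. Indels (rate 0.02/site) never touch planted features or the
sequon→cysteine window.

**What the benchmark shows — and does not.** Passing tests demonstrate that
each stage recovers exactly what was planted under realistic divergence, and
that the implementations match independent oracles. Real proteomes add
complications the generator does not emulate: fragmentary gene models,
compositional bias, heterogeneous rates across sites and lineages, deep
branches with genuinely weak signal, and alignment error from real aligners.
Accuracy numbers on synthetic data are therefore upper bounds, not field
estimates.

## Problem sizes

The default test bundle is 100 sequences per profile + 1000 decoys
(seed 7), searched against a 200-match-state profile with 1000-sequence
E-value calibration and a 100-replicate bootstrap on the 300-leaf tree; the
full suite exercises this once and reuses it across tests. These sizes were
chosen to match the scale of the real survey (420 family sequences) while
keeping a complete run comfortably on a single CPU.
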