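"""Profile-HMM construction and scoring against independent oracles."""

import math

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import gumbel_r

from epdrsurvey.alphabet import AMINO_ACIDS, BACKGROUND, GAP_CHARS
from epdrsurvey import hmm as H

from helpers import enumerate_path_scores, random_toy_profile

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# build_profile
# ---------------------------------------------------------------------------

def test_identical_ungapped_rows_give_one_match_state_per_column():
    aln = H.SeedAlignment(ids=("a", "b"), rows=("ACDEF", "ACDEF"))
    model = H.build_profile(aln)
    assert model.n_match_states == 5
    assert list(model.column_map) == [1, 2, 3, 4, 5]
    for s, residue in enumerate("ACDEF"):
        assert AMINO_ACIDS[np.argmax(model.match_emissions[s])] == residue


def test_occupancy_threshold_is_inclusive():
    # middle column is 50% gaps: retained at threshold 0.5
    aln = H.SeedAlignment(ids=("a", "b"), rows=("A-C", "AGC"))
    model = H.build_profile(aln, match_occupancy_threshold=0.5)
    assert model.n_match_states == 3
    assert list(model.column_map) == [1, 2, 3]


def test_all_gap_alignment_is_degenerate():
    aln = H.SeedAlignment(ids=("a", "b"), rows=("--", "--"))
    with pytest.raises(H.DegenerateAlignmentError):
        H.build_profile(aln)


def test_emissions_match_hand_computed_pseudocount_formula():
    rows = ("ACDEF", "ACDEF", "ACDEY", "AC-EF", "GCDEF")
    aln = H.SeedAlignment(ids=tuple("abcde"), rows=rows)
    pc = 1.0
    model = H.build_profile(aln, pseudocount=pc)
    # hand-computed Laplace background over all 24 residues
    counts_q = np.zeros(20)
    for row in rows:
        for c in row:
            if c not in GAP_CHARS:
                counts_q[AMINO_ACIDS.index(c)] += 1
    q = (counts_q + 1) / (counts_q.sum() + 20)
    assert np.allclose(model.background, q)
    for s in range(5):
        col = [row[s] for row in rows if row[s] not in GAP_CHARS]
        counts = np.zeros(20)
        for c in col:
            counts[AMINO_ACIDS.index(c)] += 1
        expected = (counts + pc * q) / (len(col) + pc)
        assert np.allclose(model.match_emissions[s], expected, atol=1e-12)


# ---------------------------------------------------------------------------
# score_sequence / forward / viterbi
# ---------------------------------------------------------------------------

def single_state_profile(p_c: float = 0.9) -> H.ProfileHMM:
    em = np.full((1, 20), (1 - p_c) / 19)
    em[0, AMINO_ACIDS.index("C")] = p_c
    out = np.zeros((2, 3))
    out[1] = [0.8, 0.2, 0.0]
    return H.ProfileHMM(
        match_emissions=em,
        background=BACKGROUND.copy(),
        out_m=out.copy(), out_i=out.copy(), out_d=out.copy(),
        out_b=np.array([0.9, 0.1]),
        column_map=np.array([1]),
    )


def test_single_match_state_closed_form():
    model = single_state_profile()
    qc = model.background[AMINO_ACIDS.index("C")]
    em_lo = math.log(0.9 / qc)
    # four paths: M1 emits C; delete+insert emits C; delete with C in
    # either free flank (before or after the core)
    match_path = math.log(0.9) + em_lo + math.log(0.8)
    del_ins_path = math.log(0.1) + math.log(0.2) + math.log(0.8)
    del_path = math.log(0.1) + math.log(0.8)
    expected_bits = logsumexp(
        [match_path, del_ins_path, del_path, del_path]
    ) / LN2
    hit = H.score_sequence(model, "C")
    assert hit.bit_score == pytest.approx(expected_bits, abs=1e-9)
    assert hit.path == (("M", 1, 1),)
    assert hit.span == (1, 1)


def test_background_equal_emissions_cancel_exactly():
    """When every emission equals the null, only transitions contribute."""
    em = np.tile(BACKGROUND, (3, 1))
    out = np.zeros((4, 3))
    out[1:3] = [1 / 3, 1 / 3, 1 / 3]
    out[3] = [0.5, 0.5, 0.0]
    model = H.ProfileHMM(
        match_emissions=em, background=BACKGROUND.copy(),
        out_m=out.copy(), out_i=out.copy(), out_d=out.copy(),
        out_b=np.array([0.5, 0.5]), column_map=np.array([1, 2, 3]),
    )
    s1 = H.forward_bits(model, "AAAA")
    s2 = H.forward_bits(model, "WYWC")
    assert s1 == pytest.approx(s2, abs=1e-9)


@pytest.mark.parametrize("trial", range(8))
def test_forward_and_viterbi_equal_brute_force_enumeration(trial):
    rng = np.random.default_rng(100 + trial)
    model = random_toy_profile(rng, k=int(rng.integers(2, 5)))
    aas = np.array(list(AMINO_ACIDS))
    seq = "".join(aas[rng.integers(0, 20, size=rng.integers(1, 5))])
    weights = enumerate_path_scores(model, seq)
    expected_forward = logsumexp(weights) / LN2
    expected_viterbi = max(weights) / LN2
    assert H.forward_bits(model, seq) == pytest.approx(
        expected_forward, rel=1e-9, abs=1e-9
    )
    vit_bits, _ = H.viterbi_path(model, seq)
    assert vit_bits == pytest.approx(expected_viterbi, rel=1e-9, abs=1e-9)


def test_tripeptide_total_probability_consistency():
    """Forward over all 20^3 tripeptides matches path-structure enumeration."""
    rng = np.random.default_rng(5)
    model = random_toy_profile(rng, k=3)
    aas = list(AMINO_ACIDS)
    # spot-check a deterministic sample of tripeptides (full 8000 is slow)
    picks = [(a, b, c) for a in aas[::7] for b in aas[::9] for c in aas[::5]]
    for a, b, c in picks:
        seq = a + b + c
        expected = logsumexp(enumerate_path_scores(model, seq)) / LN2
        assert H.forward_bits(model, seq) == pytest.approx(expected, rel=1e-9)


def test_forward_at_least_viterbi():
    rng = np.random.default_rng(42)
    model = random_toy_profile(rng, k=4)
    aas = np.array(list(AMINO_ACIDS))
    for _ in range(20):
        seq = "".join(aas[rng.integers(0, 20, size=rng.integers(1, 30))])
        fwd = H.forward_bits(model, seq)
        vit, _ = H.viterbi_path(model, seq)
        assert fwd >= vit - 1e-9


def test_consensus_extension_monotone_on_peaked_profile():
    """Viterbi score grows as consensus residues are appended in order."""
    k = 6
    consensus = "ACDEFG"
    em = np.full((k, 20), 0.01 / 19)
    for s, c in enumerate(consensus):
        em[s, AMINO_ACIDS.index(c)] = 0.99
    em /= em.sum(axis=1, keepdims=True)
    out = np.zeros((k + 1, 3))
    out[1:k] = [0.9, 0.05, 0.05]
    out[k] = [0.95, 0.05, 0.0]
    model = H.ProfileHMM(
        match_emissions=em, background=BACKGROUND.copy(),
        out_m=out.copy(), out_i=out.copy(), out_d=out.copy(),
        out_b=np.array([0.95, 0.05]), column_map=np.arange(1, k + 1),
    )
    scores = [H.viterbi_path(model, consensus[:t])[0] for t in range(1, k + 1)]
    assert all(b >= a for a, b in zip(scores, scores[1:]))


def test_illegal_residue_raises():
    model = single_state_profile()
    with pytest.raises(ValueError):
        H.forward_bits(model, "ACBX")


def test_profile_json_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    model = random_toy_profile(rng, k=3)
    p = tmp_path / "profile.json"
    model.to_json(p)
    back = H.ProfileHMM.from_json(p)
    assert np.allclose(back.match_emissions, model.match_emissions)
    assert np.allclose(back.out_m, model.out_m)
    assert list(back.column_map) == list(model.column_map)
    assert H.forward_bits(back, "ACDEF") == pytest.approx(
        H.forward_bits(model, "ACDEF"), abs=1e-12
    )


# ---------------------------------------------------------------------------
# Calibration and search
# ---------------------------------------------------------------------------

def test_gumbel_fit_recovers_known_parameters():
    lam_true, mu_true = 0.7, 2.0
    scores = gumbel_r.rvs(loc=mu_true, scale=1 / lam_true, size=5000,
                          random_state=np.random.default_rng(11))
    lam, mu = H.fit_gumbel(scores)
    assert lam == pytest.approx(lam_true, rel=0.05)
    assert mu == pytest.approx(mu_true, abs=0.1)


def test_calibration_preconditions_and_determinism():
    rng = np.random.default_rng(8)
    model = random_toy_profile(rng, k=3)
    with pytest.raises(ValueError):
        H.calibrate_evalue(model, n_random=50, seed=1)
    cal1 = H.calibrate_evalue(model, n_random=150, seed=9, database_size=500)
    cal2 = H.calibrate_evalue(model, n_random=150, seed=9, database_size=500)
    assert (cal1.gumbel_lambda, cal1.gumbel_mu) == (cal2.gumbel_lambda,
                                                    cal2.gumbel_mu)


def test_evalue_monotone_and_clamped():
    cal = H.EvalueCalibration(gumbel_lambda=0.5, gumbel_mu=0.0,
                              database_size=1000, n_random=100, seed=0)
    scores = np.linspace(-50, 80, 40)
    evals = [cal.evalue(s) for s in scores]
    assert all(b <= a for a, b in zip(evals, evals[1:]))
    assert max(evals) <= 1000.0
    assert min(evals) >= 0.0


def test_search_empty_database_and_degenerate_cutoff():
    rng = np.random.default_rng(13)
    model = random_toy_profile(rng, k=3)
    cal = H.EvalueCalibration(gumbel_lambda=0.5, gumbel_mu=0.0,
                              database_size=3, n_random=100, seed=0)
    assert H.search(model, [], cal) == []
    hits = H.search(model, {"s1": "ACD", "s2": "WWW", "s3": "KLM"}, cal,
                    cutoff=math.inf)
    assert len(hits) == 3 and all(h.passed for h in hits)
    evs = [h.e_value for h in hits]
    assert evs == sorted(evs)
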