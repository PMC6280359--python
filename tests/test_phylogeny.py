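"""Distances, neighbor joining, bootstrap, clades and expansion detection."""

import io
import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from epdrsurvey.hmm import SeedAlignment
from epdrsurvey.phylogeny import (assign_clades, bipartitions,
                                  bootstrap_support, detect_expansions,
                                  distances_from_matrix, nj_tree,
                                  pairwise_distances, robinson_foulds)
from epdrsurvey.synthetic import family_alignment

from helpers import random_additive_tree


# ---------------------------------------------------------------------------
# pairwise_distances
# ---------------------------------------------------------------------------

def test_identical_pair_distance_zero():
    aln = SeedAlignment(ids=tuple("abc"), rows=("ACDEF", "ACDEF", "WYWYC"))
    d = pairwise_distances(aln, model="p")
    assert d.matrix[0, 1] == 0.0


def test_poisson_closed_form_five_of_hundred():
    row_a = "A" * 100
    row_b = "C" * 5 + "A" * 95
    aln = SeedAlignment(ids=tuple("abc"), rows=(row_a, row_b, "W" * 100))
    p = pairwise_distances(aln, model="p")
    assert p.matrix[0, 1] == pytest.approx(0.05)
    poisson = pairwise_distances(aln, model="poisson")
    assert poisson.matrix[0, 1] == pytest.approx(-math.log(0.95))


def test_distances_equal_brute_force_double_loop():
    rng = np.random.default_rng(9)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    rows = []
    for _ in range(10):
        row = "".join(
            "-" if rng.random() < 0.15 else aas[rng.integers(0, 20)]
            for _ in range(60)
        )
        rows.append(row)
    aln = SeedAlignment(ids=tuple(f"s{i}" for i in range(10)),
                        rows=tuple(rows))
    got = pairwise_distances(aln, model="p")
    for i in range(10):
        for j in range(10):
            shared = [(a, b) for a, b in zip(rows[i], rows[j])
                      if a != "-" and b != "-"]
            expected = (sum(a != b for a, b in shared) / len(shared)
                        if i != j else 0.0)
            assert got.matrix[i, j] == pytest.approx(expected, abs=1e-12)
            assert got.compared_sites[i, j] == (len(shared) if i != j
                                                else got.compared_sites[i, j])


def test_disjoint_gap_patterns_are_an_error():
    aln = SeedAlignment(ids=tuple("abc"), rows=("A--", "-C-", "AC-"))
    with pytest.raises(ValueError):
        pairwise_distances(aln, model="p")


# ---------------------------------------------------------------------------
# nj_tree
# ---------------------------------------------------------------------------

def test_three_taxon_closed_form_branch_lengths():
    ids = ("a", "b", "c")
    mat = np.array([[0.0, 0.3, 0.5],
                    [0.3, 0.0, 0.6],
                    [0.5, 0.6, 0.0]])
    tree = nj_tree(distances_from_matrix(ids, mat))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
    assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
    assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))


@pytest.mark.parametrize("trial", range(10))
def test_nj_recovers_random_additive_topologies(trial):
    rng = np.random.default_rng(300 + trial)
    n = int(rng.integers(6, 11))
    ids, mat, true_splits = random_additive_tree(rng, n)
    tree = nj_tree(distances_from_matrix(ids, mat))
    assert set(bipartitions(tree)) == true_splits


def test_nj_agrees_with_independent_implementation():
    """Cross-check against scikit-bio's neighbor joining on additive input."""
    rng = np.random.default_rng(77)
    ids, mat, _ = random_additive_tree(rng, 9)
    mat = (mat + mat.T) / 2.0      # remove float accumulation asymmetry
    mine = nj_tree(distances_from_matrix(ids, mat))
    theirs = skbio_nj(DistanceMatrix(mat, ids))
    assert set(bipartitions(mine)) == set(bipartitions(theirs))
    assert robinson_foulds(mine, theirs) == 0


def test_nj_needs_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(distances_from_matrix(("a", "b"), np.zeros((2, 2))))


def test_newick_round_trip_preserves_topology():
    rng = np.random.default_rng(12)
    ids, mat, _ = random_additive_tree(rng, 8)
    tree = nj_tree(distances_from_matrix(ids, mat))
    buf = io.StringIO()
    tree.write(buf)
    buf.seek(0)
    back = TreeNode.read(buf)
    assert robinson_foulds(tree, back) == 0


# ---------------------------------------------------------------------------
# bootstrap_support
# ---------------------------------------------------------------------------

def _toy_alignment(rng, n_rows=6, n_cols=40):
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    rows = ["".join(aas[rng.integers(0, 20, size=n_cols)])
            for _ in range(n_rows)]
    return SeedAlignment(ids=tuple(f"t{i}" for i in range(n_rows)),
                         rows=tuple(rows))


def test_single_replicate_supports_are_zero_or_hundred():
    aln = _toy_alignment(np.random.default_rng(1))
    tree = bootstrap_support(aln, reps=1, seed=5)
    supports = [n.support for n in tree.non_tips(include_self=False)
                if hasattr(n, "support")]
    assert supports and all(s in (0.0, 100.0) for s in supports)


def test_duplicated_columns_give_full_support():
    """An alignment of identical repeated columns has no sampling variance."""
    base = ("AAAA", "AAAC", "CCCA", "CCCC", "WWWW", "WWWY")
    rows = tuple(r * 30 for r in base)
    aln = SeedAlignment(ids=tuple(f"t{i}" for i in range(6)), rows=rows)
    tree = bootstrap_support(aln, reps=20, seed=3)
    supports = [n.support for n in tree.non_tips(include_self=False)
                if hasattr(n, "support")]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_reproducible_and_bounded():
    aln = _toy_alignment(np.random.default_rng(2), n_rows=7)
    t1 = bootstrap_support(aln, reps=25, seed=9)
    t2 = bootstrap_support(aln, reps=25, seed=9)
    s1 = sorted(n.support for n in t1.non_tips(include_self=False))
    s2 = sorted(n.support for n in t2.non_tips(include_self=False))
    assert s1 == s2
    assert all(0.0 <= s <= 100.0 for s in s1)


# ---------------------------------------------------------------------------
# assign_clades
# ---------------------------------------------------------------------------

def test_separated_synthetic_tree_assigns_all_leaves(bundle7):
    """Planted clades resolve with zero misplacements; profile 3 -> clade 2."""
    _, sequences, truth = bundle7
    fam_ids = [r.id for r in truth.records if r.true_profile != "decoy"]
    aln = family_alignment(sequences, truth, fam_ids)
    tree = nj_tree(pairwise_distances(aln))
    profiles = {r.id: r.true_profile for r in truth.records}
    labels, info = assign_clades(tree, profiles)
    assert info["misplaced"] == 0
    for rec in truth.records:
        if rec.true_profile == "decoy":
            continue
        assert labels[rec.id] == rec.true_clade


def test_three_leaf_tree_single_anchors():
    mat = np.array([[0.0, 0.2, 0.9],
                    [0.2, 0.0, 0.9],
                    [0.9, 0.9, 0.0]])
    tree = nj_tree(distances_from_matrix(("p1a", "p1b", "p2a"), mat))
    labels, _ = assign_clades(tree, {"p1a": "1", "p2a": "2", "p1b": "3"})
    assert labels["p1a"] == "1" and labels["p2a"] == "2"
    # the third leaf has no anchor: it inherits a side, deterministically
    assert labels["p1b"] in ("1", "2")
    again, _ = assign_clades(tree, {"p1a": "1", "p2a": "2", "p1b": "3"})
    assert again == labels


def test_interleaved_profiles_trigger_warning_path():
    """Every cherry mixes both profiles, so no internal edge separates them."""
    # balanced 8-leaf tree: cherries (x0,x1)(x2,x3)(x4,x5)(x6,x7), each with
    # one profile-1 and one profile-2 leaf; additive path-length distances
    n = 8
    ids = tuple(f"x{i}" for i in range(n))
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if i // 2 == j // 2:
                mat[i, j] = 2.0            # same cherry
            elif i // 4 == j // 4:
                mat[i, j] = 4.0            # same half
            else:
                mat[i, j] = 6.0
    tree = nj_tree(distances_from_matrix(ids, mat))
    profiles = {f"x{i}": ("1" if i % 2 == 0 else "2") for i in range(n)}
    labels, info = assign_clades(tree, profiles)
    assert info["warning"] is not None
    assert set(labels.values()) == {"unassigned"}


def test_leaf_order_permutation_invariance(bundle7):
    _, sequences, truth = bundle7
    ids = ([f"fam_p1_{i:03d}" for i in range(10)]
           + [f"fam_p2_{i:03d}" for i in range(30, 40)])
    profiles = {r.id: r.true_profile for r in truth.records}
    aln = family_alignment(sequences, truth, ids)
    perm_aln = family_alignment(sequences, truth, list(reversed(ids)))
    t1 = nj_tree(pairwise_distances(aln))
    t2 = nj_tree(pairwise_distances(perm_aln))
    l1, _ = assign_clades(t1, profiles)
    l2, _ = assign_clades(t2, profiles)
    assert l1 == l2


# ---------------------------------------------------------------------------
# detect_expansions
# ---------------------------------------------------------------------------

def test_expansion_threshold_is_inclusive_at_fifteen():
    taxa14 = {f"s{i}": "crowded" for i in range(14)}
    taxa15 = {f"s{i}": "crowded" for i in range(15)}
    assert detect_expansions(taxa14, count_threshold=15).expanded == []
    assert detect_expansions(taxa15, count_threshold=15).expanded == ["crowded"]


def test_planted_expansion_forms_monophyletic_clade(bundle7):
    cfg, sequences, truth = bundle7
    fam_ids = [r.id for r in truth.records if r.true_profile != "decoy"]
    aln = family_alignment(sequences, truth, fam_ids)
    tree = nj_tree(pairwise_distances(aln))
    taxa = {i: truth[i].taxon for i in fam_ids}
    report = detect_expansions(taxa, tree, count_threshold=15)
    assert cfg.expansion_taxon in report.expanded
    exp_clades = [c for c in report.clades if c[0] == cfg.expansion_taxon]
    assert exp_clades and max(size for _, size, _ in exp_clades) >= 10


def test_all_distinct_taxa_yield_no_clades():
    rng = np.random.default_rng(31)
    ids, mat, _ = random_additive_tree(rng, 7)
    tree = nj_tree(distances_from_matrix(ids, mat))
    taxa = {sid: f"species_{sid}" for sid in ids}
    report = detect_expansions(taxa, tree, count_threshold=15)
    assert report.clades == [] and report.expanded == []
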