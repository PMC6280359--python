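"""Shared independent oracles and small builders for the test suite.

Everything here deliberately avoids the library's own DP/NJ code paths so it
can serve as an independent cross-check: path scores are found by explicit
enumeration over the state graph, and additive distance matrices are built
by summing branch lengths over an explicitly constructed random tree.
"""

from __future__ import annotations

import numpy as np

from epdrsurvey.alphabet import AMINO_ACIDS
from epdrsurvey import hmm as H


def enumerate_path_scores(model: H.ProfileHMM, seq: str) -> list[float]:
    """Natural-log weight of every (start, core path, end) combination.

    Walks the state graph directly: the free N flank chooses any start
    offset, begin goes to M1/D1, levels advance via match/delete with
    inserts in between, and the end state is reached from level-k states;
    remaining residues are absorbed by the free C flank.
    """
    codes = [AMINO_ACIDS.index(c) for c in seq]
    k = model.n_match_states
    L = len(codes)
    lo = np.log(model.match_emissions) - np.log(model.background)
    with np.errstate(divide="ignore"):
        ln_m, ln_i, ln_d = (np.log(model.out_m), np.log(model.out_i),
                            np.log(model.out_d))
        ln_b = np.log(model.out_b)
    out = {"M": ln_m, "I": ln_i, "D": ln_d}
    results: list[float] = []

    def extend(state: str, level: int, i: int, w: float):
        if state == "E":
            results.append(w)
            return
        trans = out[state][level]
        if level == k:
            extend("E", level, i, w + trans[0])
        elif i < L:
            extend("M", level + 1, i + 1, w + trans[0] + lo[level, codes[i]])
        if i < L:
            extend("I", level, i + 1, w + trans[1])
        if level < k:
            extend("D", level + 1, i, w + trans[2])

    for start in range(L + 1):
        if start < L:
            extend("M", 1, start + 1, ln_b[0] + lo[0, codes[start]])
        extend("D", 1, start, ln_b[1])
    return results


def random_toy_profile(rng: np.random.Generator, k: int) -> H.ProfileHMM:
    """Small random profile built via build_profile on a random alignment."""
    n_rows, n_cols = 5, k + rng.integers(0, 2)
    aas = np.array(list(AMINO_ACIDS))
    rows = []
    for _ in range(n_rows):
        row = "".join(aas[rng.integers(0, 20, size=n_cols)])
        row = "".join("-" if rng.random() < 0.2 else c for c in row)
        rows.append(row)
    aln = H.SeedAlignment(ids=tuple(f"r{i}" for i in range(n_rows)),
                          rows=tuple(rows))
    return H.build_profile(aln, match_occupancy_threshold=0.5, pseudocount=1.0)


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary topology with positive branch lengths.

    Returns ``(ids, matrix, bipartition_keys)`` where ``matrix`` is the exact
    additive (path-length) distance matrix and ``bipartition_keys`` is the
    set of canonical non-trivial splits of the generating topology.
    """
    ids = [f"L{i}" for i in range(n_leaves)]
    # adjacency with branch lengths; nodes 0..n-1 are leaves
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_leaves)}
    groups: list[tuple[int, frozenset[str]]] = [
        (i, frozenset([ids[i]])) for i in range(n_leaves)
    ]
    splits: set[frozenset[str]] = set()
    next_node = n_leaves
    all_leaves = frozenset(ids)
    while len(groups) > 2:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        (na, la), (nb, lb) = groups[i], groups[j]
        parent = next_node
        next_node += 1
        adj[parent] = []
        for child in (na, nb):
            length = float(rng.uniform(0.05, 1.0))
            adj[parent].append((child, length))
            adj[child].append((parent, length))
        merged = la | lb
        if 1 < len(merged) < n_leaves - 1:
            side = merged if len(merged) <= n_leaves - len(merged) else \
                all_leaves - merged
            if len(merged) * 2 == n_leaves:
                side = merged if tuple(sorted(merged)) < \
                    tuple(sorted(all_leaves - merged)) else all_leaves - merged
            splits.add(side)
        groups = [g for x, g in enumerate(groups) if x not in (i, j)]
        groups.append((parent, merged))
    (na, _), (nb, _) = groups
    length = float(rng.uniform(0.05, 1.0))
    adj[na].append((nb, length))
    adj[nb].append((na, length))

    # all-pairs leaf distances by BFS over the tree
    mat = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_leaves):
            mat[src, dst] = dist[dst]
    return ids, mat, splits


def canonical_splits(tree, all_leaves: frozenset[str]) -> set[frozenset[str]]:
    """Canonical non-trivial bipartition keys of a TreeNode (smaller side)."""
    from epdrsurvey.phylogeny import bipartitions

    return set(bipartitions(tree))


def identity_colmaps(pairs):
    """Trivial residue->column identity maps for raw equal-length sequences."""
    from epdrsurvey.mapping import ColumnMap

    return {
        sid: ColumnMap(sid, {i + 1: i + 1 for i in range(len(seq))})
        for sid, seq in pairs
    }
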