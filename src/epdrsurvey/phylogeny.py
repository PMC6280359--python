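"""Distance-based family phylogeny: p/Poisson distances, neighbor joining,
nonparametric bootstrap, two-clade assignment and lineage-expansion detection.

The tree machinery is deliberately distance-based and fully deterministic:
Saitou-Nei neighbor joining with a fixed row-major tie-break, negative branch
lengths clamped to zero with the excess moved to the sibling edge, pairwise
deletion of gapped sites, and an optional Poisson correction
``d = -ln(1 - p)`` with ``p`` capped below saturation.  Branch support comes
from resampling alignment columns with replacement and counting how often
each original bipartition reappears in the replicate trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from skbio import TreeNode

from .alphabet import AMINO_ACIDS, GAP_CHARS
from .hmm import SeedAlignment

__all__ = [
    "DistanceResult",
    "ExpansionReport",
    "pairwise_distances",
    "distances_from_matrix",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "assign_clades",
    "detect_expansions",
    "robinson_foulds",
]

P_CAP = 0.95      # saturation guard before the Poisson log transform


@dataclass
class DistanceResult:
    """Symmetric distance matrix with its model tag and site counts."""

    ids: tuple[str, ...]
    matrix: np.ndarray            # (n, n), zero diagonal
    model: str                    # "p" or "poisson"
    compared_sites: np.ndarray    # (n, n) pairwise-deletion site counts

    def __post_init__(self):
        m = self.matrix
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must be symmetric, zero diagonal")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite distances")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                fh.write(sid + "\t"
                         + "\t".join(f"{x:.6f}" for x in self.matrix[i])
                         + "\n")


def _encode_alignment(aln: SeedAlignment) -> np.ndarray:
    """(n_rows, n_cols) int codes with -1 for gaps."""
    lut = {c: i for i, c in enumerate(AMINO_ACIDS)}
    out = np.full((aln.n_rows, aln.n_columns), -1, dtype=np.int8)
    for r, row in enumerate(aln.rows):
        for j, c in enumerate(row):
            if c not in GAP_CHARS:
                out[r, j] = lut[c]
    return out


def pairwise_distances(
    aln: SeedAlignment, model: str = "poisson",
    columns: np.ndarray | None = None,
) -> DistanceResult:
    """All-pairs distances under pairwise deletion.

    ``p = mismatches / compared columns`` over sites where neither sequence
    is gapped; the Poisson model applies ``d = -ln(1 - min(p, 0.95))``.
    ``columns`` optionally restricts/resamples the 0-based column index set
    (used by the bootstrap).
    """
    if model not in ("p", "poisson"):
        raise ValueError("model must be 'p' or 'poisson'")
    if aln.n_rows < 3:
        raise ValueError("need >= 3 sequences for a phylogeny")
    codes = _encode_alignment(aln)
    if columns is not None:
        codes = codes[:, columns]
    valid = codes >= 0
    compared = (valid.astype(np.float64) @ valid.T.astype(np.float64))
    matches = np.zeros_like(compared)
    for a in range(20):
        hit = (codes == a).astype(np.float64)
        matches += hit @ hit.T
    if np.any(compared[~np.eye(len(codes), dtype=bool)] == 0):
        raise ValueError("a sequence pair shares no compared columns")
    p = 1.0 - matches / compared
    np.fill_diagonal(p, 0.0)
    if model == "poisson":
        d = -np.log(1.0 - np.minimum(p, P_CAP))
    else:
        d = p
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceResult(ids=tuple(aln.ids), matrix=d, model=model,
                          compared_sites=compared)


def distances_from_matrix(ids, matrix, model: str = "p") -> DistanceResult:
    """Wrap a precomputed matrix (e.g. an additive test matrix)."""
    matrix = np.asarray(matrix, dtype=float)
    return DistanceResult(ids=tuple(ids), matrix=matrix, model=model,
                          compared_sites=np.full_like(matrix, np.nan))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch length to 0, moving the excess to its sibling."""
    if li < 0:
        lj += -li
        li = 0.0
    if lj < 0:
        li += -lj
        lj = 0.0
    return li, max(lj, 0.0)


def nj_tree(dist: DistanceResult) -> TreeNode:
    """Saitou-Nei neighbor joining; deterministic row-major tie-break.

    Returns an unrooted topology represented as a :class:`skbio.TreeNode`
    with a trifurcating root; leaf names are the input ids.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dist.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=sid) for sid in dist.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))            # row-major: smallest (i, j) wins ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent.extend([ci, cj])
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        keep = [x for x in range(m) if x != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    # Three-point closed form for the final star resolution.
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode()
    for node, length in ((a, la), (b, lb), (c, lc)):
        node.length = float(max(length, 0.0))
        root.append(node)
    return root


# ---------------------------------------------------------------------------
# Bipartitions, bootstrap, clades
# ---------------------------------------------------------------------------

def _canonical(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    comp = all_leaves - side
    if len(side) != len(comp):
        return side if len(side) < len(comp) else comp
    return side if tuple(sorted(side)) < tuple(sorted(comp)) else comp


def bipartitions(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Non-trivial bipartitions (canonical smaller side) -> defining node."""
    leaves = frozenset(t.name for t in tree.tips())
    out: dict[frozenset[str], TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            out[_canonical(side, leaves)] = node
    return out


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Unweighted RF distance (symmetric difference of bipartition sets)."""
    return len(set(bipartitions(t1)) ^ set(bipartitions(t2)))


def bootstrap_support(
    aln: SeedAlignment,
    reps: int = 100,
    seed: int = 0,
    model: str = "poisson",
    tree: TreeNode | None = None,
) -> TreeNode:
    """Column-resampling bootstrap; annotates the tree's internal nodes.

    Each replicate resamples alignment columns with replacement, rebuilds
    the distance matrix and NJ tree, and scores which original bipartitions
    it contains.  Supports (% of replicates, in [0, 100]) are attached as
    ``node.support`` and as internal-node names for Newick export.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if tree is None:
        tree = nj_tree(pairwise_distances(aln, model=model))
    parts = bipartitions(tree)
    counts = {key: 0 for key in parts}
    rng = np.random.default_rng(seed)
    n_cols = aln.n_columns
    for _ in range(reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_tree = nj_tree(pairwise_distances(aln, model=model, columns=cols))
        rep_parts = set(bipartitions(rep_tree))
        for key in counts:
            if key in rep_parts:
                counts[key] += 1
    for key, node in parts.items():
        support = 100.0 * counts[key] / reps
        node.support = support
        node.name = f"{support:g}"
    return tree


def assign_clades(
    tree: TreeNode, profiles: Mapping[str, str]
) -> tuple[dict[str, str], dict]:
    """Label leaves clade 1 / clade 2 from the best profile-separating edge.

    ``profiles`` maps leaf id -> cysteine profile; profile-1 and profile-2
    leaves anchor the two clades.  The internal edge whose bipartition
    minimises the number of misplaced anchors defines the split; the side
    holding the profile-1 majority becomes clade 1 and every leaf (including
    profile-3 and atypical ones) inherits its side's label.  When no edge
    beats the trivial all-one-side split, every leaf is left unassigned.
    """
    leaves = frozenset(t.name for t in tree.tips())
    p1 = {x for x in leaves if profiles.get(x) == "1"}
    p2 = {x for x in leaves if profiles.get(x) == "2"}
    if not p1 or not p2:
        raise ValueError("need at least one profile-1 and one profile-2 leaf")
    trivial = min(len(p1), len(p2))
    candidates = set(bipartitions(tree))
    if not candidates:
        # no internal edge (e.g. a 3-leaf star): leaf edges are the only splits
        candidates = {frozenset([x]) for x in leaves}
    # Deterministic choice: minimal misplacement, then the tightest clade-1
    # side (ties among zero-misplacement edges differ only in which pure
    # non-anchor subtrees they attach to clade 1), then lexicographic.
    best: tuple[int, int, tuple[str, ...], frozenset[str]] | None = None
    for side in candidates:
        comp = leaves - side
        mis_side1 = len(p1 - side) + len(p2 & side)   # side = clade 1
        mis_comp1 = len(p1 - comp) + len(p2 & comp)   # comp = clade 1
        for clade1, mis in ((side, mis_side1), (comp, mis_comp1)):
            key = (mis, len(clade1), tuple(sorted(clade1)), frozenset(clade1))
            if best is None or key[:3] < best[:3]:
                best = key
    if best is None or best[0] >= trivial:
        labels = {x: "unassigned" for x in leaves}
        return labels, {"separating_edge": None, "misplaced": None,
                        "warning": "no profile-separating edge"}
    mis, _, _, clade1 = best
    labels = {x: ("1" if x in clade1 else "2") for x in leaves}
    return labels, {
        "separating_edge": _canonical(clade1, leaves),
        "misplaced": mis,
        "warning": None,
    }


@dataclass
class ExpansionReport:
    """Per-species family counts plus same-taxon monophyletic clades."""

    counts: dict[str, int]
    expanded: list[str]                       # taxa at/above the threshold
    clades: list[tuple[str, int, tuple[str, ...]]] = field(default_factory=list)
    count_threshold: int = 15


def detect_expansions(
    taxa: Mapping[str, str],
    tree: TreeNode | None = None,
    count_threshold: int = 15,
    clade_min: int = 2,
) -> ExpansionReport:
    """Flag lineage-specific expansions.

    A species is *expanded* when it carries ``count_threshold`` or more
    family members (strict >=).  When a tree is supplied, maximal
    monophyletic same-taxon clades of at least ``clade_min`` leaves are
    listed as evidence of taxon-specific duplication.
    """
    counts: dict[str, int] = {}
    for taxon in taxa.values():
        counts[taxon] = counts.get(taxon, 0) + 1
    expanded = sorted(t for t, c in counts.items() if c >= count_threshold)
    clades: list[tuple[str, int, tuple[str, ...]]] = []
    if tree is not None:
        pure: dict[int, str | None] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                pure[id(node)] = taxa.get(node.name)
            else:
                kinds = {pure[id(ch)] for ch in node.children}
                pure[id(node)] = kinds.pop() if len(kinds) == 1 else None
        for node in tree.preorder(include_self=False):
            taxon = pure.get(id(node))
            if node.is_tip() or taxon is None:
                continue
            parent_pure = (node.parent is not None
                           and pure.get(id(node.parent)) == taxon)
            if parent_pure:
                continue        # not maximal
            members = tuple(sorted(t.name for t in node.tips()))
            if len(members) >= clade_min:
                clades.append((taxon, len(members), members))
        clades.sort(key=lambda x: (-x[1], x[0]))
    return ExpansionReport(counts=counts, expanded=expanded, clades=clades,
                           count_threshold=count_threshold)
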