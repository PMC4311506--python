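"""Distance-based phylogenetics: Kimura two-parameter distances,
neighbor-joining, nonparametric bootstrap and majority-rule consensus.

This mirrors the classic SEQBOOT/DNADIST/NEIGHBOR/CONSENSE chain: pairwise
K2P distances with pairwise deletion of gapped/ambiguous sites, Saitou–Nei
agglomeration with deterministic tie-breaking, column bootstrap with
bipartition supports mapped onto the full-data tree, and strict-majority
consensus.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .seqio import AlignmentMatrix

__all__ = [
    "k2p_distance",
    "estimate_tstv",
    "DistanceMatrix",
    "neighbor_joining",
    "bipartitions",
    "bootstrap_support",
    "majority_rule_consensus",
]

_BASES = "ACGT"
_TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _paired_sites(seq_a: str, seq_b: str):
    """Counts (n_compared, transitions, transversions) with pairwise
    deletion of sites where either sequence is gapped or ambiguous."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    a = seq_a.upper()
    b = seq_b.upper()
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _BASES or y not in _BASES:
            continue
        n += 1
        if x != y:
            if (x, y) in _TRANSITION_PAIRS:
                ts += 1
            else:
                tv += 1
    return n, ts, tv


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura (1980) two-parameter distance.

    With P and Q the transition and transversion fractions over compared
    sites: d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).  Returns NaN when the
    logs are undefined (saturation).
    """
    n, ts, tv = _paired_sites(seq_a, seq_b)
    if n == 0:
        raise ValueError("no comparable sites")
    p, q = ts / n, tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def estimate_tstv(alignment: AlignmentMatrix) -> float:
    """Pooled transition/transversion count ratio over all sequence pairs;
    NaN when no transversions are observed."""
    ts = tv = 0
    seqs = alignment.sequences
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            _, t1, t2 = _paired_sites(seqs[i], seqs[j])
            ts += t1
            tv += t2
    if tv == 0:
        return float("nan")
    return ts / tv


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal; NaN marks
    saturated (undefined) entries."""
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.diag(self.matrix), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.matrix)
        if not np.allclose(self.matrix[finite & finite.T],
                           self.matrix.T[finite & finite.T]):
            raise ValueError("matrix must be symmetric")
        if np.any(self.matrix[finite] < 0):
            raise ValueError("distances must be non-negative")

    @classmethod
    def from_alignment(cls, alignment: AlignmentMatrix) -> "DistanceMatrix":
        n = alignment.n_taxa
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = k2p_distance(alignment.sequences[i], alignment.sequences[j])
                m[i, j] = m[j, i] = d
        return cls(list(alignment.taxa), m)

    def has_na(self) -> bool:
        return bool(np.any(~np.isfinite(self.matrix)))

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)}"]
        w = max(len(t) for t in self.taxa) + 2
        for t, row in zip(self.taxa, self.matrix):
            lines.append(t.ljust(w) + " ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def _clamped_pair(la: float, lb: float) -> tuple[float, float]:
    # negative branch clamped to 0, deficit moved to the sibling edge
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Ties in the Q criterion break to the lowest current index pair;
    negative branch lengths are clamped to zero with the deficit added to
    the sibling edge.  Returns an unrooted tree (trifurcating seed node).
    """
    if dm.has_na():
        raise ValueError("distance matrix contains NA (saturated) entries")
    n0 = len(dm.taxa)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(list(dm.taxa))
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in dm.taxa]
    D = dm.matrix.copy()
    active = list(range(n0))

    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin is row-major: deterministic lowest-index tie-breaking
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        d_ij = sub[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d_ij - li
        li, lj = _clamped_pair(li, lj)
        gi, gj = active[i], active[j]
        parent = dendropy.Node()
        ni, nj = nodes[gi], nodes[gj]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj
        # distances to the new node
        new_row = 0.5 * (D[gi, :] + D[gj, :] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        g_new = D.shape[0] - 1
        D[g_new, :-1] = new_row
        D[:-1, g_new] = new_row
        D[g_new, g_new] = 0.0
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [g_new]

    root = dendropy.Node()
    ga, gb, gc = active
    d_ab, d_ac, d_bc = D[ga, gb], D[ga, gc], D[gb, gc]
    la = 0.5 * (d_ab + d_ac - d_bc)
    lb = 0.5 * (d_ab + d_bc - d_ac)
    lc = 0.5 * (d_ac + d_bc - d_ab)
    for g, length in ((ga, la), (gb, lb), (gc, lc)):
        root.add_child(nodes[g])
        nodes[g].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions, bootstrap, consensus
# ---------------------------------------------------------------------------

def bipartitions(tree: dendropy.Tree,
                 min_branch: float | None = None) -> set[frozenset]:
    """Nontrivial bipartitions as canonical frozensets of leaf labels (the
    side not containing the alphabetically first taxon).  Edges with
    length <= ``min_branch`` (when given) are treated as unresolved."""
    labels = sorted(
        lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon
    )
    full = frozenset(labels)
    ref = labels[0]
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        if min_branch is not None and (nd.edge.length or 0.0) <= min_branch:
            continue
        side = frozenset(
            lf.taxon.label for lf in nd.leaf_iter() if lf.taxon
        )
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            out.add(side)
    return out


def _resample(alignment: AlignmentMatrix, rng: np.random.Generator) -> AlignmentMatrix:
    n = alignment.n_sites
    idx = rng.integers(0, n, size=n)
    return AlignmentMatrix(
        list(alignment.taxa),
        ["".join(s[k] for k in idx) for s in alignment.sequences],
    )


def bootstrap_support(alignment: AlignmentMatrix, n_reps: int,
                      seed: int) -> dendropy.Tree:
    """Column bootstrap of the K2P/NJ analysis.

    Resamples alignment columns with replacement ``n_reps`` times, rebuilds
    the NJ tree for each pseudoreplicate, and writes the percentage of
    replicates containing each internal bipartition onto the full-data NJ
    tree (internal node labels).  Zero-length internal edges of the
    full-data tree are collapsed first (they are unresolved).  Replicates
    whose distance matrix saturates contribute no bipartitions.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    full_tree = neighbor_joining(DistanceMatrix.from_alignment(alignment))
    # collapse unresolved (zero-length) internal edges
    for nd in list(full_tree.preorder_node_iter()):
        if (nd.parent_node is not None and not nd.is_leaf()
                and (nd.edge.length or 0.0) <= 1e-12):
            nd.edge.collapse()
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        rep = _resample(alignment, rng)
        dmat = DistanceMatrix.from_alignment(rep)
        if dmat.has_na():
            continue
        for bp in bipartitions(neighbor_joining(dmat)):
            counts[bp] = counts.get(bp, 0) + 1
    labels = sorted(alignment.taxa)
    full = frozenset(labels)
    ref = labels[0]
    for nd in full_tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter() if lf.taxon)
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            nd.label = f"{100.0 * counts.get(side, 0) / n_reps:g}"
    return full_tree


def supports(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Bipartition -> support value read back from internal node labels."""
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon)
    full, ref = frozenset(labels), labels[0]
    out = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf() or nd.label is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter() if lf.taxon)
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            out[side] = float(nd.label)
    return out


def majority_rule_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Strict-majority (>50%) consensus of trees over one leaf set.

    Bipartitions present in more than half the input trees are retained
    (such sets are always mutually compatible) and assembled into a tree
    with percentage supports as internal node labels; everything else is
    left as polytomies.
    """
    if not trees:
        raise ValueError("no input trees")
    leafsets = [
        frozenset(lf.taxon.label for lf in t.leaf_node_iter() if lf.taxon)
        for t in trees
    ]
    if len(set(leafsets)) != 1:
        raise ValueError("input trees have different leaf sets")
    labels = sorted(leafsets[0])
    counts: dict[frozenset, int] = {}
    for t in trees:
        for bp in bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    m = len(trees)
    majority = {bp: c for bp, c in counts.items() if c * 2 > m}

    tns = dendropy.TaxonNamespace(labels)
    root = dendropy.Node()
    leaf_nodes = {}
    for t in labels:
        nd = dendropy.Node(taxon=tns.get_taxon(t))
        root.add_child(nd)
        leaf_nodes[t] = nd

    full = frozenset(labels)
    # larger splits first so parents exist before children
    for bp in sorted(majority, key=lambda s: (-len(s), sorted(s))):
        # both orientations of the bipartition; group whichever side forms
        # a proper subset of some current node's children
        for side in (bp, full - bp):
            node = root
            # descend to the minimal node containing all of `side`
            descended = True
            while descended:
                descended = False
                for ch in node.child_nodes():
                    ch_leaves = frozenset(
                        lf.taxon.label for lf in ch.leaf_iter() if lf.taxon
                    )
                    if side <= ch_leaves and not ch.is_leaf():
                        node = ch
                        descended = True
                        break
            movable = [
                ch for ch in node.child_nodes()
                if frozenset(
                    lf.taxon.label for lf in ch.leaf_iter() if lf.taxon
                ) <= side
            ]
            covered = frozenset(
                lf.taxon.label
                for ch in movable for lf in ch.leaf_iter() if lf.taxon
            )
            if covered == side and len(movable) < len(node.child_nodes()):
                new = dendropy.Node()
                new.label = f"{100.0 * majority[bp] / m:g}"
                for ch in movable:
                    node.remove_child(ch)
                    new.add_child(ch)
                node.add_child(new)
                break
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree
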