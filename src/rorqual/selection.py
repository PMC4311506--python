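"""Estimation of synonymous/nonsynonymous substitution rates and tests for
lineage-specific acceleration.

Two complementary estimators are provided:

* :func:`ng86_dnds` — the Nei–Gojobori (1986) counting method for a pair of
  in-frame coding sequences: synonymous/nonsynonymous site counts, pathway-
  averaged difference counts, and Jukes–Cantor corrected dN, dS and their
  ratio omega.

* :class:`BranchCodonModel` — maximum-likelihood fitting of the Goldman–Yang
  (1994) codon substitution model with F3X4 equilibrium frequencies on a
  fixed tree, either with a single omega shared by all branches (one-ratio)
  or with a designated foreground branch given its own omega (two-ratio
  branch model).  ``fit()`` returns a :class:`BranchCodonResults` object;
  :func:`branch_test` runs the nested pair and performs the likelihood-ratio
  test, with Benjamini–Hochberg correction available via :func:`bh_fdr`.

The rate matrix follows the usual parameterization: for codons i != j
differing at exactly one position, q_ij is pi_j times kappa for a
transition, times omega if the change is nonsynonymous, and zero for
multi-position changes; Q is rescaled so the mean rate at stationarity is
one, so branch lengths are expected substitutions per codon.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from . import codons as cd

__all__ = [
    "CodonAlignment",
    "ng86_site_counts",
    "ng86_pair_counts",
    "ng86_dnds",
    "NG86Result",
    "f3x4_frequencies",
    "build_rate_matrix",
    "gy94_loglikelihood",
    "BranchCodonModel",
    "BranchCodonResults",
    "BranchTestResult",
    "branch_test",
    "lrt_pvalue",
    "bh_fdr",
    "postfilter_results",
]


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

class CodonAlignment:
    """In-frame aligned coding sequences over the 61 sense codons.

    Rows are taxa; columns are codons.  Codons containing gaps, ambiguity
    codes or stops are stored as -1 and treated as missing data by the
    likelihood machinery.
    """

    def __init__(self, taxa: Sequence[str], codon_matrix: np.ndarray):
        codon_matrix = np.asarray(codon_matrix, dtype=np.int64)
        if codon_matrix.ndim != 2:
            raise ValueError("codon matrix must be 2-D (taxa x codons)")
        if len(taxa) != codon_matrix.shape[0]:
            raise ValueError("taxa/matrix row mismatch")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon ids")
        self.taxa = list(taxa)
        self.codons = codon_matrix
        self._row = {t: i for i, t in enumerate(self.taxa)}

    @classmethod
    def from_sequences(cls, records: Iterable[tuple[str, str]]) -> "CodonAlignment":
        taxa, rows = [], []
        for name, seq in records:
            taxa.append(name)
            rows.append(cd.codon_indices(seq))
        if not rows:
            raise ValueError("empty alignment")
        lengths = {r.size for r in rows}
        if len(lengths) != 1:
            raise ValueError("rows have unequal codon lengths")
        return cls(taxa, np.vstack(rows))

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        from .seqio import read_fasta
        return cls.from_sequences((r.id, r.sequence) for r in read_fasta(path))

    @property
    def n_taxa(self) -> int:
        return self.codons.shape[0]

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self._row[taxon]]

    def sequence(self, taxon: str) -> str:
        return cd.indices_to_seq(self.row(taxon))

    def to_fasta(self, path) -> None:
        from .seqio import SeqRecord, write_fasta
        write_fasta(
            [SeqRecord(t, self.sequence(t)) for t in self.taxa], path
        )


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each codon position contributes the fraction of its three possible
    nucleotide changes that are synonymous; changes creating stop codons
    count as nonsynonymous.  The two counts always sum to 3.
    """
    if codon not in cd.CODON_INDEX:
        raise ValueError(f"not a sense codon: {codon!r}")
    syn = 0.0
    for k in range(3):
        for b in cd.BASES:
            if b == codon[k]:
                continue
            alt = codon[:k] + b + codon[k + 1:]
            if alt in cd.CODON_INDEX and cd.AMINO_ACID[alt] == cd.AMINO_ACID[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def ng86_pair_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts
    between two sense codons.

    All minimal substitution pathways are weighted equally; pathways passing
    through a stop codon are excluded (if every pathway is blocked, all are
    used — the standard fallback for the rare all-stop case).
    """
    if c1 not in cd.CODON_INDEX or c2 not in cd.CODON_INDEX:
        raise ValueError("pair counts require sense codons")
    if c1 == c2:
        return 0.0, 0.0

    def walk(cur: str, remaining: tuple[int, ...], allow_stops: bool):
        # returns list of (syn, nonsyn) per completed pathway
        out = []
        for k in remaining:
            step = cur[:k] + c2[k] + cur[k + 1:]
            if step in cd.STOP_CODONS and not allow_stops:
                continue
            s = 1.0 if (step not in cd.STOP_CODONS
                        and cd.AMINO_ACID.get(cur) == cd.AMINO_ACID.get(step)) else 0.0
            rest = tuple(r for r in remaining if r != k)
            if not rest:
                out.append((s, 1.0 - s))
            else:
                for s2, n2 in walk(step, rest, allow_stops):
                    out.append((s + s2, 1.0 - s + n2))
        return out

    diffs = cd.diff_positions(c1, c2)
    paths = walk(c1, diffs, allow_stops=False)
    if not paths:
        paths = walk(c1, diffs, allow_stops=True)
    syn = sum(p[0] for p in paths) / len(paths)
    non = sum(p[1] for p in paths) / len(paths)
    return syn, non


_JC_LIMIT = 0.75


def _jukes_cantor(p: float) -> float:
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * p)


@dataclass
class NG86Result:
    """Pairwise NG86 estimates.  ``omega`` is NaN when dS is 0 or either
    proportion exceeds the Jukes–Cantor validity range (``saturated``)."""
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ps: float
    pn: float
    ds: float
    dn: float
    omega: float
    n_codons_used: int
    saturated: bool = False


def ng86_dnds(seq_a: str, seq_b: str) -> NG86Result:
    """Nei–Gojobori (1986) dN, dS and omega for two equal-length in-frame
    coding sequences.  Codons with gaps/ambiguity in either sequence are
    excluded pairwise."""
    a = cd.codon_indices(seq_a)
    b = cd.codon_indices(seq_b)
    if a.size != b.size:
        raise ValueError("sequences differ in codon length")
    S = N = Sd = Nd = 0.0
    used = 0
    for ia, ib in zip(a, b):
        if ia < 0 or ib < 0:
            continue
        used += 1
        ca, cb = cd.SENSE_CODONS[ia], cd.SENSE_CODONS[ib]
        s1, n1 = ng86_site_counts(ca)
        s2, n2 = ng86_site_counts(cb)
        S += 0.5 * (s1 + s2)
        N += 0.5 * (n1 + n2)
        sd, nd = ng86_pair_counts(ca, cb)
        Sd += sd
        Nd += nd
    if used == 0:
        raise ValueError("no comparable codons")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    saturated = ps >= _JC_LIMIT or pn >= _JC_LIMIT
    ds = float("nan") if ps >= _JC_LIMIT else (float(_jukes_cantor(ps)) if ps > 0 else 0.0)
    dn = float("nan") if pn >= _JC_LIMIT else (float(_jukes_cantor(pn)) if pn > 0 else 0.0)
    if saturated or ds != ds or ds == 0.0:
        omega = float("nan")
    else:
        omega = dn / ds
    return NG86Result(S, N, Sd, Nd, ps, pn, ds, dn, omega, used, saturated)


# ---------------------------------------------------------------------------
# F3X4 frequencies and the GY94 rate matrix
# ---------------------------------------------------------------------------

def f3x4_frequencies(sequences: Iterable[str] | CodonAlignment) -> np.ndarray:
    """F3X4 codon frequencies: empirical nucleotide frequencies at each of
    the three codon positions, multiplied per codon and renormalized over
    the 61 sense codons.  Gaps and ambiguity codes are ignored."""
    counts = np.zeros((3, 4))
    if isinstance(sequences, CodonAlignment):
        seqs = (sequences.sequence(t) for t in sequences.taxa)
    else:
        seqs = iter(sequences)
    for seq in seqs:
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError("in-frame sequences required")
        for i, ch in enumerate(seq):
            j = cd.BASE_INDEX.get(ch)
            if j is not None:
                counts[i % 3, j] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous nucleotides")
    with np.errstate(invalid="ignore"):
        f = counts / counts.sum(axis=1, keepdims=True)
    f = np.nan_to_num(f, nan=0.25)
    pi = np.array(
        [f[0, cd.BASE_INDEX[c[0]]] * f[1, cd.BASE_INDEX[c[1]]] * f[2, cd.BASE_INDEX[c[2]]]
         for c in cd.SENSE_CODONS]
    )
    if pi.sum() <= 0:
        raise ValueError("degenerate F3X4 frequencies")
    return pi / pi.sum()


@lru_cache(maxsize=1)
def _change_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 tables: single-position change, transition, synonymous."""
    n = cd.N_SENSE
    single = np.zeros((n, n), dtype=bool)
    transit = np.zeros((n, n), dtype=bool)
    synon = np.zeros((n, n), dtype=bool)
    for i, c1 in enumerate(cd.SENSE_CODONS):
        for nb, is_ts, is_syn in cd.neighbor_table()[c1]:
            j = cd.CODON_INDEX[nb]
            single[i, j] = True
            transit[i, j] = is_ts
            synon[i, j] = is_syn
    return single, transit, synon


def _floor_pi(pi: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (cd.N_SENSE,):
        raise ValueError("pi must be a 61-vector")
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def build_rate_matrix(pi: np.ndarray, kappa: float, omega: float,
                      scale: bool = True) -> np.ndarray:
    """GY94/F3X4 instantaneous rate matrix.

    ``scale=True`` rescales so that the expected rate at stationarity is 1
    (branch lengths in expected substitutions per codon)."""
    if kappa <= 0 or omega < 0:
        raise ValueError("require kappa > 0 and omega >= 0")
    pi = _floor_pi(pi)
    single, transit, synon = _change_tables()
    q = np.where(single, np.tile(pi, (cd.N_SENSE, 1)), 0.0)
    q = q * np.where(transit, kappa, 1.0)
    q = q * np.where(synon | ~single, 1.0, omega)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        mean_rate = -float(pi @ np.diag(q))
        if mean_rate <= 0:
            raise ValueError("degenerate rate matrix")
        q = q / mean_rate
    return q


def _flux_fractions(pi: np.ndarray, q: np.ndarray) -> tuple[float, float]:
    """(nonsyn, syn) fractions of total substitution flux under Q."""
    single, _, synon = _change_tables()
    flux = pi[:, None] * q
    total = float(flux[single].sum())
    non = float(flux[single & ~synon].sum())
    return non / total, 1.0 - non / total


class _Eigen:
    """Eigendecomposition of a reversible Q via pi-symmetrization."""

    def __init__(self, pi: np.ndarray, q: np.ndarray):
        sq = np.sqrt(pi)
        sym = (q * sq[:, None]) / sq[None, :]
        sym = 0.5 * (sym + sym.T)
        w, u = np.linalg.eigh(sym)
        self.w = w
        self.left = u.T * sq[None, :]          # B  (rows)
        self.right = (u.T / sq[None, :]).T     # A  (cols): P = A diag(e^{wt}) B

    def pmat(self, t: float) -> np.ndarray:
        p = (self.right * np.exp(self.w * t)) @ self.left
        np.maximum(p, 0.0, out=p)
        return p


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

class _TreeIndex:
    """Flattened edge/topology arrays for a dendropy tree.

    The tree is cloned and derooted (a basal bifurcation is collapsed) so
    every edge length is identifiable.  Edge ``e`` is the edge above node
    ``nodes[e]``; the seed node has no edge.
    """

    def __init__(self, tree: dendropy.Tree, taxa: Sequence[str]):
        t = tree.clone(depth=1)
        if len(t.seed_node.child_nodes()) == 2 and len(t.leaf_nodes()) > 2:
            t.deroot()
        self.tree = t
        self.postorder = [nd for nd in t.postorder_node_iter()]
        self.node_id = {id(nd): i for i, nd in enumerate(self.postorder)}
        self.edges = [nd for nd in self.postorder if nd.parent_node is not None]
        self.edge_id = {id(nd): i for i, nd in enumerate(self.edges)}
        self.lengths = np.array(
            [nd.edge.length if nd.edge.length is not None else 0.1
             for nd in self.edges]
        )
        row = {name: i for i, name in enumerate(taxa)}
        self.leaf_row: dict[int, int] = {}
        for leaf in t.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else leaf.label
            if label not in row:
                raise ValueError(f"tree taxon {label!r} absent from alignment")
            self.leaf_row[id(leaf)] = row[label]
        if len(self.leaf_row) != len(taxa):
            raise ValueError("alignment taxa and tree leaves do not match 1:1")

    def edge_labels(self) -> list[str]:
        out = []
        for nd in self.edges:
            if nd.is_leaf():
                out.append(nd.taxon.label if nd.taxon else str(nd.label))
            else:
                leaves = sorted(
                    lf.taxon.label for lf in nd.leaf_iter() if lf.taxon
                )
                out.append("(" + ",".join(leaves) + ")")
        return out

    def foreground_edges(self, label: str | None) -> np.ndarray:
        """Edge index/indices whose subtree is named ``label`` — a leaf
        taxon label or an internal node label."""
        if label is None:
            return np.zeros(0, dtype=int)
        hits = []
        for nd in self.edges:
            names = {nd.label}
            if nd.taxon is not None:
                names.add(nd.taxon.label)
            if label in names:
                hits.append(self.edge_id[id(nd)])
        if not hits:
            raise ValueError(f"no branch labeled {label!r} in tree")
        return np.array(hits, dtype=int)


class _CodonPruner:
    """Felsenstein pruning with site-pattern compression and analytic
    branch-length derivatives."""

    def __init__(self, aln: CodonAlignment, index: _TreeIndex, pi: np.ndarray):
        self.index = index
        self.pi = _floor_pi(pi)
        patterns, inverse, counts = np.unique(
            aln.codons, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns            # (n_taxa, n_pat)
        self.weights = counts.astype(float)
        self.n_pat = patterns.shape[1]
        # leaf partials: one-hot, all-ones for missing
        self.leaf_partials: dict[int, np.ndarray] = {}
        for nid, r in index.leaf_row.items():
            lp = np.zeros((cd.N_SENSE, self.n_pat))
            obs = patterns[r]
            ok = obs >= 0
            lp[:, ~ok] = 1.0
            lp[obs[ok], np.nonzero(ok)[0]] = 1.0
            self.leaf_partials[nid] = lp

    def _pmats(self, eig_by_edge: list[_Eigen], ts: np.ndarray) -> list[np.ndarray]:
        return [eig_by_edge[e].pmat(ts[e]) for e in range(len(ts))]

    def lnl(self, eig_by_edge: list[_Eigen], ts: np.ndarray,
            want_grad: bool = False,
            q_by_edge: list[np.ndarray] | None = None):
        idx = self.index
        pmats = self._pmats(eig_by_edge, ts)
        down: dict[int, np.ndarray] = {}
        messages: dict[int, np.ndarray] = {}
        for nd in idx.postorder:
            if nd.is_leaf():
                d = self.leaf_partials[id(nd)]
            else:
                d = None
                for ch in nd.child_nodes():
                    m = messages[id(ch)]
                    d = m if d is None else d * m
            down[id(nd)] = d
            if nd.parent_node is not None:
                e = idx.edge_id[id(nd)]
                messages[id(nd)] = pmats[e] @ d
        root = idx.postorder[-1]
        site_l = self.pi @ down[id(root)]
        if np.any(site_l <= 0.0) or not np.all(np.isfinite(site_l)):
            bad = int(np.argmax(~(site_l > 0)))
            if not want_grad:
                return -np.inf
            return -np.inf, np.zeros(len(ts)), bad
        lnl = float(self.weights @ np.log(site_l))
        if not want_grad:
            return lnl
        # outside pass
        grad = np.zeros(len(ts))
        outside: dict[int, np.ndarray] = {id(root): np.tile(self.pi[:, None], (1, self.n_pat))}
        inv_l = self.weights / site_l
        for nd in reversed(idx.postorder):
            if nd.is_leaf():
                continue
            o_v = outside[id(nd)]
            children = nd.child_nodes()
            for ch in children:
                o = o_v
                for sib in children:
                    if sib is not ch:
                        o = o * messages[id(sib)]
                e = idx.edge_id[id(ch)]
                outside[id(ch)] = (pmats[e].T @ o)
                qp = q_by_edge[e] @ pmats[e]
                dl = np.einsum("ip,ij,jp->p", o, qp, down[id(ch)])
                grad[e] = float(inv_l @ dl)
        return lnl, grad, None


def gy94_loglikelihood(alignment: CodonAlignment, tree: dendropy.Tree,
                       kappa: float, omega, codon_freqs: np.ndarray,
                       branch_lengths: np.ndarray | None = None,
                       foreground: str | None = None,
                       omega_foreground: float | None = None) -> float:
    """Log-likelihood of a codon alignment on a tree under GY94/F3X4.

    ``omega`` applies to all branches except those selected by
    ``foreground`` (a leaf or internal-node label), which use
    ``omega_foreground``.  ``branch_lengths`` overrides the tree's own edge
    lengths (ordered as the derooted tree's postorder edges).
    """
    index = _TreeIndex(tree, alignment.taxa)
    pi = _floor_pi(codon_freqs)
    pruner = _CodonPruner(alignment, index, pi)
    ts = index.lengths if branch_lengths is None else np.asarray(branch_lengths, float)
    if np.any(ts < 0):
        raise ValueError("negative branch length")
    fg = set(index.foreground_edges(foreground).tolist())
    q_bg = build_rate_matrix(pi, kappa, omega)
    eig_bg = _Eigen(pi, q_bg)
    if fg:
        if omega_foreground is None:
            raise ValueError("omega_foreground required with foreground")
        q_fg = build_rate_matrix(pi, kappa, omega_foreground)
        eig_fg = _Eigen(pi, q_fg)
    eigs = [eig_fg if e in fg else eig_bg for e in range(len(index.edges))]
    out = pruner.lnl(eigs, ts)
    if out == -np.inf:
        raise ValueError("non-finite site likelihood")
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

_T_MIN, _T_MAX = 1e-7, 50.0
_K_MIN, _K_MAX = 0.05, 100.0
_W_MIN, _W_MAX = 1e-6, 60.0


@dataclass
class BranchCodonResults:
    """Fitted GY94 branch model.

    Attributes mirror a statsmodels results object: point estimates, the
    maximized log-likelihood, convergence diagnostics, and a ``summary()``
    table.  ``branch_table()`` reports per-branch t, omega, dN and dS using
    the codeml site-proportion convention (site fractions taken from the
    omega=1 mutational-opportunity matrix).
    """
    model: "BranchCodonModel"
    two_ratio: bool
    kappa: float
    omega: float
    omega_foreground: float | None
    branch_lengths: np.ndarray
    llf: float
    converged: bool
    n_iter: int

    @property
    def params(self) -> pd.Series:
        d = {"kappa": self.kappa, "omega": self.omega}
        if self.two_ratio:
            d["omega_foreground"] = self.omega_foreground
        return pd.Series(d)

    def _dnds_parts(self, omega: float, t: float) -> tuple[float, float]:
        pi = self.model.pi
        q = build_rate_matrix(pi, self.kappa, omega)
        rho_n, rho_s = _flux_fractions(pi, q)
        q1 = build_rate_matrix(pi, self.kappa, 1.0, scale=False)
        f_n, f_s = _flux_fractions(pi, q1)
        dn = t * rho_n / (3.0 * f_n)
        ds = t * rho_s / (3.0 * f_s)
        return dn, ds

    def branch_table(self) -> pd.DataFrame:
        rows = []
        fg = set(self.model.index.foreground_edges(
            self.model.foreground if self.two_ratio else None).tolist())
        labels = self.model.index.edge_labels()
        for e, t in enumerate(self.branch_lengths):
            omega = self.omega_foreground if e in fg else self.omega
            dn, ds = self._dnds_parts(omega, float(t))
            rows.append(
                {"branch": labels[e], "foreground": e in fg, "t": float(t),
                 "omega": omega, "dN": dn, "dS": ds}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        kind = "two-ratio branch model" if self.two_ratio else "one-ratio model"
        lines = [
            f"GY94/F3X4 {kind}",
            "=" * 46,
            f"log-likelihood      {self.llf:14.4f}",
            f"kappa (ts/tv)       {self.kappa:14.4f}",
            f"omega (background)  {self.omega:14.4f}",
        ]
        if self.two_ratio:
            lines.append(f"omega (foreground)  {self.omega_foreground:14.4f}")
        lines += [
            f"tree length         {float(self.branch_lengths.sum()):14.4f}",
            f"converged           {str(self.converged):>14}",
            f"n codons            {self.model.alignment.n_codons:14d}",
        ]
        return "\n".join(lines)


class BranchCodonModel:
    """GY94/F3X4 codon model on a fixed topology.

    Parameters
    ----------
    alignment : CodonAlignment
    tree : dendropy.Tree
        Topology with (optional) starting branch lengths; branch lengths
        are re-estimated during fitting.
    foreground : str, optional
        Leaf or internal-node label naming the branch allowed its own
        omega in the two-ratio model.
    codon_freqs : array, optional
        61-vector of equilibrium codon frequencies; default F3X4 from the
        alignment.
    """

    def __init__(self, alignment: CodonAlignment, tree: dendropy.Tree,
                 foreground: str | None = None,
                 codon_freqs: np.ndarray | None = None):
        self.alignment = alignment
        self.tree = tree
        self.foreground = foreground
        self.pi = _floor_pi(
            f3x4_frequencies(alignment) if codon_freqs is None else codon_freqs
        )
        self.index = _TreeIndex(tree, alignment.taxa)
        self.pruner = _CodonPruner(alignment, self.index, self.pi)
        self._eig_cache: dict[tuple[float, float], tuple[_Eigen, np.ndarray]] = {}

    # -- likelihood plumbing -------------------------------------------------

    def _eig(self, kappa: float, omega: float) -> tuple[_Eigen, np.ndarray]:
        key = (float(kappa), float(omega))
        hit = self._eig_cache.get(key)
        if hit is None:
            q = build_rate_matrix(self.pi, kappa, omega)
            hit = (_Eigen(self.pi, q), q)
            if len(self._eig_cache) > 64:
                self._eig_cache.clear()
            self._eig_cache[key] = hit
        return hit

    def _assemble(self, kappa, omega, omega_fg, fg_edges):
        n_e = len(self.index.edges)
        eig_bg, q_bg = self._eig(kappa, omega)
        eigs = [eig_bg] * n_e
        qs = [q_bg] * n_e
        for e in fg_edges:
            eig_fg, q_fg = self._eig(kappa, omega_fg)
            eigs[e] = eig_fg
            qs[e] = q_fg
        return eigs, qs

    def loglike(self, kappa: float, omega: float, branch_lengths: np.ndarray,
                omega_foreground: float | None = None) -> float:
        fg = self.index.foreground_edges(
            self.foreground if omega_foreground is not None else None
        )
        eigs, _ = self._assemble(kappa, omega, omega_foreground, fg)
        return self.pruner.lnl(eigs, np.asarray(branch_lengths, float))

    def _objective(self, two_ratio: bool):
        fg = self.index.foreground_edges(self.foreground if two_ratio else None)
        n_shape = 3 if two_ratio else 2

        def unpack(x):
            kappa, omega = x[0], x[1]
            omega_fg = x[2] if two_ratio else None
            ts = x[n_shape:]
            return kappa, omega, omega_fg, ts

        def fun_grad(x):
            kappa, omega, omega_fg, ts = unpack(x)
            eigs, qs = self._assemble(kappa, omega, omega_fg, fg)
            lnl, tgrad, _ = self.pruner.lnl(eigs, ts, want_grad=True, q_by_edge=qs)
            if not np.isfinite(lnl):
                return 1e12, np.zeros_like(x)
            g = np.zeros_like(x)
            g[n_shape:] = tgrad
            # forward differences for the shape parameters
            for i in range(n_shape):
                h = 1e-6 * max(1.0, abs(x[i]))
                xp = x.copy()
                xp[i] += h
                k2, w2, wf2, _ = unpack(xp)
                eigs2, _ = self._assemble(k2, w2, wf2, fg)
                l2 = self.pruner.lnl(eigs2, ts)
                g[i] = (l2 - lnl) / h if np.isfinite(l2) else 0.0
            return -lnl, -g

        return fun_grad, n_shape

    # -- fitting ---------------------------------------------------------------

    def _initial_lengths(self) -> np.ndarray:
        ts = np.clip(self.index.lengths, 0.01, 5.0)
        if np.allclose(ts, 0.1):
            ts = np.full_like(ts, 0.1)
        return ts

    def fit(self, two_ratio: bool | None = None,
            start: dict | None = None,
            omega_starts: Sequence[float] = (0.1, 1.0, 2.0),
            maxiter: int = 300) -> BranchCodonResults:
        """Maximize the likelihood.

        ``two_ratio`` defaults to True when a foreground branch was named.
        ``start`` may carry 'kappa', 'omega', 'omega_foreground' and
        'branch_lengths' to warm-start (used by :func:`branch_test` to seed
        the alternative fit from the null fit); otherwise the best of
        ``omega_starts`` at kappa=2 seeds a single optimization.
        """
        if two_ratio is None:
            two_ratio = self.foreground is not None
        if two_ratio and self.foreground is None:
            raise ValueError("two-ratio fit requires a foreground label")
        fun_grad, n_shape = self._objective(two_ratio)

        ts0 = self._initial_lengths()
        if start is not None:
            kappa0 = float(start.get("kappa", 2.0))
            omega0 = float(start.get("omega", 0.5))
            wfg0 = float(start.get("omega_foreground", omega0)) if two_ratio else None
            if "branch_lengths" in start:
                ts0 = np.asarray(start["branch_lengths"], float)
            x0 = np.r_[[kappa0, omega0] + ([wfg0] if two_ratio else []), ts0]
        else:
            fg = self.index.foreground_edges(self.foreground if two_ratio else None)
            best, best_l = None, -np.inf
            for w0 in omega_starts:
                eigs, _ = self._assemble(2.0, w0, w0, fg)
                l = self.pruner.lnl(eigs, ts0)
                if l > best_l:
                    best, best_l = w0, l
            x0 = np.r_[[2.0, best] + ([best] if two_ratio else []), ts0]

        bounds = ([(_K_MIN, _K_MAX)] + [(_W_MIN, _W_MAX)] * (n_shape - 1)
                  + [(_T_MIN, _T_MAX)] * len(ts0))
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(fun_grad, x0, jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-10,
                                "gtol": 1e-6})
        kappa, omega = float(res.x[0]), float(res.x[1])
        omega_fg = float(res.x[2]) if two_ratio else None
        return BranchCodonResults(
            model=self, two_ratio=two_ratio, kappa=kappa, omega=omega,
            omega_foreground=omega_fg,
            branch_lengths=res.x[n_shape:].copy(),
            llf=-float(res.fun), converged=bool(res.success),
            n_iter=int(res.nit),
        )


# ---------------------------------------------------------------------------
# LRT / FDR / post-filters
# ---------------------------------------------------------------------------

_NESTING_TOL = 1e-4


def lrt_pvalue(lnl_null: float, lnl_alt: float, tol: float = _NESTING_TOL) -> float:
    """Upper-tail chi-square(1) p-value of the likelihood-ratio statistic
    2(lnL_alt - lnL_null), clamped at 0.  A deficit beyond ``tol`` signals
    optimizer failure and raises."""
    delta = lnl_alt - lnl_null
    if delta < -tol:
        raise ValueError(
            f"alternative lnL {lnl_alt} below null {lnl_null}: optimizer failure"
        )
    stat = max(0.0, 2.0 * delta)
    return float(chi2.sf(stat, df=1))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class BranchTestResult:
    """One gene's two-ratio branch test."""
    gene_id: str
    lnl_null: float
    lnl_alt: float
    lrt_stat: float
    p_value: float
    kappa: float
    omega_background: float
    omega_foreground: float
    t_foreground: float
    dn_foreground: float
    ds_foreground: float
    q_value: float | None = None
    filtered: bool = False
    filter_reason: str = ""


def branch_test(alignment: CodonAlignment, tree: dendropy.Tree,
                foreground: str, gene_id: str = "gene",
                codon_freqs: np.ndarray | None = None) -> BranchTestResult:
    """Two-ratio branch test: one-ratio null vs foreground-omega
    alternative, compared by LRT with 1 df.

    The alternative fit is warm-started at the null optimum (which it
    nests), guaranteeing lnL_alt >= lnL_null up to optimizer tolerance.
    """
    model = BranchCodonModel(alignment, tree, foreground=foreground,
                             codon_freqs=codon_freqs)
    null = model.fit(two_ratio=False)
    alt = model.fit(
        two_ratio=True,
        start={"kappa": null.kappa, "omega": null.omega,
               "omega_foreground": null.omega,
               "branch_lengths": null.branch_lengths},
    )
    if alt.llf < null.llf:
        # fall back to the cold-start grid if the warm start stalled
        alt2 = model.fit(two_ratio=True)
        if alt2.llf > alt.llf:
            alt = alt2
        if alt.llf < null.llf - _NESTING_TOL:
            alt = BranchCodonResults(
                model=model, two_ratio=True, kappa=null.kappa,
                omega=null.omega, omega_foreground=null.omega,
                branch_lengths=null.branch_lengths, llf=null.llf,
                converged=null.converged, n_iter=null.n_iter)
    p = lrt_pvalue(null.llf, max(alt.llf, null.llf))
    fg_rows = alt.branch_table().query("foreground")
    t_fg = float(fg_rows["t"].sum())
    dn_fg = float(fg_rows["dN"].sum())
    ds_fg = float(fg_rows["dS"].sum())
    return BranchTestResult(
        gene_id=gene_id, lnl_null=null.llf, lnl_alt=alt.llf,
        lrt_stat=max(0.0, 2.0 * (alt.llf - null.llf)), p_value=p,
        kappa=alt.kappa, omega_background=alt.omega,
        omega_foreground=alt.omega_foreground,
        t_foreground=t_fg, dn_foreground=dn_fg, ds_foreground=ds_fg,
    )


def postfilter_results(results: Iterable[BranchTestResult],
                       ds_max: float = 3.0,
                       omega_max: float = 5.0) -> list[BranchTestResult]:
    """Flag results whose foreground dS exceeds ``ds_max`` or whose
    foreground omega exceeds ``omega_max`` (strict comparisons); flagged
    genes are excluded from the accelerated-gene list downstream."""
    out = []
    for r in results:
        reasons = []
        if r.ds_foreground > ds_max:
            reasons.append(f"dS>{ds_max:g}")
        if r.omega_foreground > omega_max:
            reasons.append(f"dN/dS>{omega_max:g}")
        r.filtered = bool(reasons)
        r.filter_reason = ",".join(reasons)
        out.append(r)
    return out


def run_branch_tests(genes: Iterable[tuple[str, CodonAlignment]],
                     tree: dendropy.Tree, foreground: str,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Branch test across genes with BH correction and the dS/omega
    post-filter; returns one row per gene."""
    results = [branch_test(aln, tree, foreground, gene_id=gid)
               for gid, aln in genes]
    if not results:
        return pd.DataFrame()
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    postfilter_results(results)
    df = pd.DataFrame([vars(r) for r in results])
    df["significant"] = (df["q_value"] < alpha) & ~df["filtered"]
    return df
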