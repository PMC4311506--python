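"""Synthetic-data generators with known ground truth for every pipeline
stage: fragmented multi-sample contig universes, codon alignments evolved
under per-branch omega, within-species polymorphism with outgroup
divergence, K2P nucleotide alignments, and VCF files spanning the hard
filters.

Every generator is a pure function of its config and seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import codons as cd
from .merge import Contig, GeneAnnotation
from .seqio import AlignmentMatrix
from .selection import CodonAlignment, _Eigen, _floor_pi, build_rate_matrix
from .variants import VariantRecord

__all__ = [
    "ContigUniverseConfig",
    "ContigUniverse",
    "simulate_contig_universe",
    "CodonSimConfig",
    "simulate_codon_alignment",
    "PopDivSimConfig",
    "PopDivSim",
    "simulate_pop_div",
    "simulate_nt_alignment",
    "simulate_vcf",
    "VCF_RULES",
]

_NT = np.array(list("ACGT"))

#: Canonical eight-taxon mammal study tree for branch-model simulations
#: (branch lengths in expected substitutions per codon; the cetacean
#: foreground terminal branch is 'minke').
MAMMAL_TREE_NEWICK = (
    "(((human:0.12,mouse:0.15):0.06,(dog:0.1,horse:0.1):0.05):0.04,"
    "((pig:0.09,cow:0.1):0.05,(dolphin:0.08,minke:0.2):0.06):0.04);"
)

#: Compact six-taxon tree used for null-model calibration runs.
SIX_TAXON_TREE_NEWICK = (
    "((a:0.1,b:0.12):0.05,(c:0.09,d:0.11):0.04,(e:0.1,f:0.13):0.05);"
)


def mammal_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data=MAMMAL_TREE_NEWICK, schema="newick")


def random_additive_tree(rng: np.random.Generator, n_taxa: int,
                         lo: float = 0.1, hi: float = 1.0):
    """A random binary topology with uniform(lo, hi) branch lengths.

    Returns (tree, taxa, leaf-to-leaf path-length matrix); the matrix is
    additive by construction, so distance-based reconstruction must invert
    it exactly.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa for an informative topology")
    labels = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in labels]
    dist = np.zeros((n_taxa, n_taxa))
    depth = {id(nd): {i: 0.0} for i, nd in enumerate(nodes)}
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        li, lj = rng.uniform(lo, hi, size=2)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        di = {k: v + li for k, v in depth[id(nodes[i])].items()}
        dj = {k: v + lj for k, v in depth[id(nodes[j])].items()}
        for a, da in di.items():
            for b, db in dj.items():
                dist[a, b] = dist[b, a] = da + db
        depth[id(parent)] = {**di, **dj}
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    la = float(rng.uniform(lo, hi))
    root = dendropy.Node()
    root.add_child(nodes[0])
    root.add_child(nodes[1])
    nodes[0].edge.length = la
    nodes[1].edge.length = 0.0
    da = {k: v + la for k, v in depth[id(nodes[0])].items()}
    db = depth[id(nodes[1])]
    for a, va in da.items():
        for b, vb in db.items():
            dist[a, b] = dist[b, a] = va + vb
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree, labels, dist


def six_taxon_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data=SIX_TAXON_TREE_NEWICK, schema="newick")


def _random_stopfree_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, cd.N_SENSE, size=n_codons)
    return "".join(cd.SENSE_CODONS[i] for i in idx)


# ---------------------------------------------------------------------------
# Contig universe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContigUniverseConfig:
    """A shared gene-bearing genome assembled independently in several
    samples.  Defaults emulate a four-sample resequencing design at desk
    scale: a 150 kb genome with 12 genes, ~3–8 kb contigs separated by
    short assembly gaps, 20% per-sample gene dropout and error-free
    consensus bases."""
    genome_length: int = 150_000
    n_genes: int = 12
    gene_length_range: tuple[int, int] = (450, 900)
    n_samples: int = 4
    dropout_rate: float = 0.2
    fragment_length_range: tuple[int, int] = (3000, 8000)
    per_base_error: float = 0.0
    min_contig_length: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be a probability")
        if not (0.0 <= self.per_base_error <= 1.0):
            raise ValueError("per_base_error must be a probability")
        if self.fragment_length_range[1] > self.genome_length:
            raise ValueError("fragments cannot exceed the genome")
        if self.gene_length_range[1] >= self.fragment_length_range[0]:
            raise ValueError("genes must fit inside single fragments")
        if self.n_genes * (self.gene_length_range[1] + 200) > self.genome_length:
            raise ValueError("infeasible config: genes do not fit the genome")


@dataclass
class ContigUniverse:
    config: ContigUniverseConfig
    genome: str
    genes: list[tuple[str, int, int]]            # (gene_id, start, end)
    samples: dict[str, list[Contig]]
    truth: pd.DataFrame                          # gene_id, sample, contig_id

    def genes_present(self) -> dict[str, set[str]]:
        """gene_id -> samples in which the gene sits wholly on a contig."""
        out: dict[str, set[str]] = {g: set() for g, _, _ in self.genes}
        for _, row in self.truth.iterrows():
            out[row.gene_id].add(row.sample)
        return out


def _sample_names(n: int) -> list[str]:
    if n == 4:
        return ["S30", "S34", "S35", "S37"]
    return [f"S{i + 1}" for i in range(n)]


def simulate_contig_universe(config: ContigUniverseConfig) -> ContigUniverse:
    """Generate per-sample fragmented assemblies of one genome.

    Genes are stop-free coding stretches placed in evenly spaced slots.
    Each sample drops each gene region with probability ``dropout_rate``
    (contigs are clipped around dropped regions), fragments the genome
    into contigs with short inter-contig gaps, and applies independent
    per-base substitution errors.  Contigs shorter than
    ``min_contig_length`` are discarded, mirroring the length cutoff of
    the real pipeline.  A gene is annotated on a contig only when it lies
    entirely inside it.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genome = rng.choice(list("ACGT"), size=cfg.genome_length)

    # place genes in evenly spaced slots
    slot = cfg.genome_length // cfg.n_genes
    genes = []
    lo3, hi3 = cfg.gene_length_range[0] // 3, cfg.gene_length_range[1] // 3
    for k in range(cfg.n_genes):
        length = 3 * int(rng.integers(lo3, hi3 + 1))
        margin = slot - length - 100
        start = k * slot + 50 + int(rng.integers(0, max(margin, 1)))
        gid = f"g{k:03d}"
        cds = _random_stopfree_cds(rng, length // 3)
        genome[start:start + length] = list(cds)
        genes.append((gid, start, start + length))
    genome = "".join(genome)

    samples: dict[str, list[Contig]] = {}
    truth_rows = []
    for name in _sample_names(cfg.n_samples):
        dropped = [
            (s, e) for (g, s, e) in genes if rng.random() < cfg.dropout_rate
        ]
        raw: list[tuple[int, int]] = []
        pos = int(rng.integers(0, 200))
        while pos < cfg.genome_length:
            flen = int(rng.integers(*cfg.fragment_length_range))
            raw.append((pos, min(pos + flen, cfg.genome_length)))
            pos += flen + int(rng.integers(20, 200))
        # clip fragments around dropped gene regions
        frags: list[tuple[int, int]] = []
        for fs, fe in raw:
            pieces = [(fs, fe)]
            for ds, de in dropped:
                nxt = []
                for ps, pe in pieces:
                    if de <= ps or ds >= pe:
                        nxt.append((ps, pe))
                    else:
                        if ps < ds:
                            nxt.append((ps, ds))
                        if de < pe:
                            nxt.append((de, pe))
                pieces = nxt
            frags.extend(pieces)
        contigs = []
        for k, (fs, fe) in enumerate(fr for fr in frags
                                     if fr[1] - fr[0] >= cfg.min_contig_length):
            seq = np.array(list(genome[fs:fe]))
            if cfg.per_base_error > 0:
                hits = np.nonzero(rng.random(seq.size) < cfg.per_base_error)[0]
                for h in hits:
                    choices = [b for b in "ACGT" if b != seq[h]]
                    seq[h] = choices[int(rng.integers(0, 3))]
            seq = "".join(seq)
            cid = f"{name}_c{k:03d}"
            anns = []
            for gid, gs, ge in genes:
                if fs <= gs and ge <= fe and (gs, ge) not in dropped:
                    cds = seq[gs - fs:ge - fs]
                    pep = _translate_until_stop(cds)
                    if len(pep) * 3 < (ge - gs) // 2:
                        continue  # errors destroyed the reading frame
                    anns.append(GeneAnnotation(
                        gene_id=f"{gid}@{name}", contig_id=cid,
                        start=gs - fs, end=ge - fs, strand="+", peptide=pep,
                    ))
                    truth_rows.append(
                        {"gene_id": gid, "sample": name, "contig_id": cid,
                         "genome_start": gs, "genome_end": ge}
                    )
            contigs.append(Contig(id=cid, sample_id=name, sequence=seq,
                                  genes=anns))
        samples[name] = contigs
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "sample", "contig_id", "genome_start", "genome_end"],
    )
    return ContigUniverse(cfg, genome, genes, samples, truth)


def _translate_until_stop(cds: str) -> str:
    pep = []
    for i in range(len(cds) // 3):
        codon = cds[3 * i:3 * i + 3]
        if codon in cd.STOP_CODONS or codon not in cd.CODON_INDEX:
            break
        pep.append(cd.AMINO_ACID[codon])
    return "".join(pep)


# ---------------------------------------------------------------------------
# Codon alignment simulation (GY94 CTMC)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonSimConfig:
    """Codon evolution along a tree under GY94/F3X4.

    ``omega_by_branch`` maps leaf or internal-node labels to omega; the
    ``"*"`` key is the background.  Branch lengths are expected
    substitutions per codon.  ``kappa`` is the conventional
    transition/transversion *rate* ratio.
    """
    tree: dendropy.Tree
    kappa: float = 2.0
    omega_by_branch: dict = field(default_factory=lambda: {"*": 0.3})
    codon_freqs: np.ndarray | None = None
    n_codons: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if any(w < 0 for w in self.omega_by_branch.values()):
            raise ValueError("omega must be non-negative")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


def _node_names(nd: dendropy.Node) -> set:
    names = set()
    if nd.taxon is not None:
        names.add(nd.taxon.label)
    if nd.label is not None:
        names.add(nd.label)
    return names


def simulate_codon_alignment(config: CodonSimConfig) -> tuple[CodonAlignment, dict]:
    """Exact CTMC simulation of codon states down the tree (endpoint
    sampling from the matrix exponential per branch).  Returns the leaf
    alignment and the true parameters."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pi = _floor_pi(cfg.codon_freqs if cfg.codon_freqs is not None
                   else np.full(cd.N_SENSE, 1.0 / cd.N_SENSE))
    omega_bg = cfg.omega_by_branch.get("*", 1.0)
    eigens: dict[float, _Eigen] = {}

    def eig_for(omega: float) -> _Eigen:
        if omega not in eigens:
            eigens[omega] = _Eigen(pi, build_rate_matrix(pi, cfg.kappa, omega))
        return eigens[omega]

    leaves = [lf for lf in cfg.tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    for nd in cfg.tree.preorder_node_iter():
        if nd.parent_node is not None and (nd.edge.length or 0.0) < 0:
            raise ValueError("negative branch length")

    states: dict[int, np.ndarray] = {}
    root = cfg.tree.seed_node
    states[id(root)] = rng.choice(cd.N_SENSE, size=cfg.n_codons, p=pi)
    for nd in cfg.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        t = float(nd.edge.length or 0.0)
        omega = omega_bg
        for name in _node_names(nd):
            if name in cfg.omega_by_branch:
                omega = cfg.omega_by_branch[name]
        parent = states[id(nd.parent_node)]
        if t == 0.0:
            states[id(nd)] = parent.copy()
            continue
        p = eig_for(omega).pmat(t)
        p = p / p.sum(axis=1, keepdims=True)
        child = np.empty_like(parent)
        for s in np.unique(parent):
            mask = parent == s
            child[mask] = rng.choice(cd.N_SENSE, size=int(mask.sum()), p=p[s])
        states[id(nd)] = child

    taxa, rows = [], []
    for lf in leaves:
        taxa.append(lf.taxon.label if lf.taxon else str(lf.label))
        rows.append(states[id(lf)])
    aln = CodonAlignment(taxa, np.vstack(rows))
    truth = {"kappa": cfg.kappa, "omega_by_branch": dict(cfg.omega_by_branch),
             "codon_freqs": pi, "n_codons": cfg.n_codons}
    return aln, truth


# ---------------------------------------------------------------------------
# Polymorphism + divergence (MKT generator)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopDivSimConfig:
    """Within-species polymorphism on a star genealogy plus divergence to
    an outgroup, with separate omega for polymorphic and fixed changes.

    ``theta_per_site`` controls the expected number of segregating
    mutations (Poisson with mean theta * 3 * n_codons); divergence
    likewise for fixed differences on the outgroup lineage.  At most one
    event per codon, so truth counts are exact."""
    n_within: int = 6
    theta_per_site: float = 0.02
    divergence_per_site: float = 0.05
    omega_poly: float = 0.2
    omega_fix: float = 0.2
    n_codons: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_within < 2:
            raise ValueError("need at least 2 within-species haplotypes")
        if min(self.theta_per_site, self.divergence_per_site) < 0:
            raise ValueError("rates must be non-negative")
        if min(self.omega_poly, self.omega_fix) < 0:
            raise ValueError("omega must be non-negative")


@dataclass
class PopDivSim:
    within: list[str]          # haplotype CDS sequences
    outgroup: str
    truth: dict                # realized Dn, Ds, Pn, Ps


def _omega_weighted_mutation(rng: np.random.Generator, codon: str,
                             omega: float) -> tuple[str, bool] | None:
    """Sample one accepted single-nucleotide change of ``codon``;
    nonsynonymous changes accepted with probability min(1, omega),
    synonymous with min(1, 1/omega) — giving a nonsyn:syn flux ratio of
    omega relative to the neutral mutational input.  Returns (new_codon,
    is_nonsyn) or None if nothing was accepted."""
    p_non = min(1.0, omega) if omega > 0 else 0.0
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    for _ in range(200):
        k = int(rng.integers(0, 3))
        b = "ACGT"[int(rng.integers(0, 4))]
        if b == codon[k]:
            continue
        cand = codon[:k] + b + codon[k + 1:]
        if cand not in cd.CODON_INDEX:
            continue
        nonsyn = cd.AMINO_ACID[cand] != cd.AMINO_ACID[codon]
        if rng.random() < (p_non if nonsyn else p_syn):
            return cand, nonsyn
    return None


def simulate_pop_div(config: PopDivSimConfig) -> PopDivSim:
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ancestral = [_random_stopfree_cds(rng, 1) for _ in range(cfg.n_codons)]
    L = 3 * cfg.n_codons
    n_fix = int(rng.poisson(cfg.divergence_per_site * L))
    n_poly = int(rng.poisson(cfg.theta_per_site * L))
    total = min(n_fix + n_poly, cfg.n_codons)
    sites = rng.choice(cfg.n_codons, size=total, replace=False)
    fix_sites = sites[:min(n_fix, total)]
    poly_sites = sites[min(n_fix, total):]

    outgroup = list(ancestral)
    within = [list(ancestral) for _ in range(cfg.n_within)]
    dn = ds = pn = ps = 0
    for s in fix_sites:
        hit = _omega_weighted_mutation(rng, ancestral[s], cfg.omega_fix)
        if hit is None:
            continue
        new, nonsyn = hit
        outgroup[s] = new
        dn += nonsyn
        ds += not nonsyn
    for s in poly_sites:
        hit = _omega_weighted_mutation(rng, ancestral[s], cfg.omega_poly)
        if hit is None:
            continue
        new, nonsyn = hit
        h = int(rng.integers(0, cfg.n_within))
        within[h][s] = new
        pn += nonsyn
        ps += not nonsyn
    return PopDivSim(
        within=["".join(h) for h in within],
        outgroup="".join(outgroup),
        truth={"Dn": dn, "Ds": ds, "Pn": pn, "Ps": ps,
               "omega_poly": cfg.omega_poly, "omega_fix": cfg.omega_fix},
    )


# ---------------------------------------------------------------------------
# K2P nucleotide alignment
# ---------------------------------------------------------------------------

def _k2p_pmatrix(t: float, tstv: float) -> np.ndarray:
    """K2P transition probabilities over ACGT for branch length t
    (expected substitutions/site).  ``tstv`` is the expected
    transition:transversion *count* ratio R = alpha/(2 beta)."""
    beta = 1.0 / (2.0 * (tstv + 1.0))
    alpha = 2.0 * tstv * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    # order ACGT; transitions A<->G, C<->T
    p = np.full((4, 4), p_tv)
    np.fill_diagonal(p, p_same)
    p[0, 2] = p[2, 0] = p[1, 3] = p[3, 1] = p_ts
    return p


def simulate_nt_alignment(tree: dendropy.Tree, tstv: float, n_sites: int,
                          seed: int) -> AlignmentMatrix:
    """I.i.d. sites evolved under K2P with equal base frequencies.

    ``tstv`` is the expected transition/transversion count ratio (0.5
    means every substitution class is equally likely per event, giving
    Ts:Tv counts of 1:2).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if tstv <= 0:
        raise ValueError("tstv must be positive")
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.integers(0, 4, size=n_sites)
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        t = float(nd.edge.length or 0.0)
        parent = states[id(nd.parent_node)]
        if t == 0.0:
            states[id(nd)] = parent.copy()
            continue
        p = _k2p_pmatrix(t, tstv)
        child = np.empty_like(parent)
        for s in range(4):
            mask = parent == s
            if mask.any():
                child[mask] = rng.choice(4, size=int(mask.sum()), p=p[s])
        states[id(nd)] = child
    taxa, seqs = [], []
    for lf in tree.leaf_node_iter():
        taxa.append(lf.taxon.label if lf.taxon else str(lf.label))
        seqs.append("".join(_NT[states[id(lf)]]))
    return AlignmentMatrix(taxa, seqs)


# ---------------------------------------------------------------------------
# VCF fixtures
# ---------------------------------------------------------------------------

VCF_RULES = ("QUAL", "QD", "FS", "MQ0", "MQ0/DP", "MISSING")


def _vcf_record(rng: np.random.Generator, pos: int, n_samples: int,
                rule: str | None) -> VariantRecord:
    qual = 60.0
    info = {"QD": 12.0, "FS": 10.0, "MQ0": 1.0, "DP": 40.0}
    gts = ["0/1"] * n_samples
    if rule == "QUAL":
        qual = 10.0
    elif rule == "QD":
        info["QD"] = 2.0
    elif rule == "FS":
        info["FS"] = 300.0
    elif rule == "MQ0":
        info["MQ0"], info["DP"] = 10.0, 200.0   # ratio 0.05 stays clean
    elif rule == "MQ0/DP":
        info["MQ0"], info["DP"] = 4.0, 20.0     # 4 not > 4; ratio 0.2 fails
    elif rule == "MISSING":
        gts[int(rng.integers(0, n_samples))] = "./."
    ref = str(rng.choice(list("ACGT")))
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return VariantRecord(
        chrom="chr1", pos=pos, ref=ref, alts=(alt,), qual=qual,
        info=info, genotypes=tuple(gts),
        samples=tuple(_sample_names(n_samples)),
    )


def simulate_vcf(n_records: int, violation_plan, seed: int,
                 n_samples: int = 4) -> tuple[list[VariantRecord], list[str]]:
    """Construct variant records with known filter outcomes.

    ``violation_plan`` is either the string ``"one_per_rule"`` (one record
    per rule plus clean records up to ``n_records``), ``"clean"``, or an
    explicit sequence of rule names / None per record.  Returns (records,
    truth labels) where a label is the violated rule or ``"PASS"``.
    """
    rng = np.random.default_rng(seed)
    if violation_plan == "one_per_rule":
        plan = list(VCF_RULES) + [None] * max(0, n_records - len(VCF_RULES))
        plan = plan[:n_records]
    elif violation_plan == "clean":
        plan = [None] * n_records
    else:
        plan = list(violation_plan)
        if len(plan) != n_records:
            raise ValueError("violation plan length mismatch")
    for rule in plan:
        if rule is not None and rule not in VCF_RULES:
            raise ValueError(f"unknown rule {rule!r}")
    records, labels = [], []
    for k, rule in enumerate(plan):
        records.append(_vcf_record(rng, 100 + 10 * k, n_samples, rule))
        labels.append(rule or "PASS")
    return records, labels
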