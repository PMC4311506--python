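"""Multi-sample assembly reconciliation.

Four fragmented single-sample assemblies of the same genome are combined
into one representative assembly: predicted genes are matched across
samples (global peptide alignment standing in for all-vs-all BLASTP, with
the identity/coverage filter), contigs are classified by gene content,
genes are clustered by single linkage over kept matches, and the combined
assembly is built anchored on the best single-sample assembly — anchor
contigs are never truncated, only extended or bridged by overlapping
contigs from other samples; anchor-less clusters contribute a consensus,
and contigs carrying sample-specific genes are appended verbatim.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import GeneMatch, align_peptides

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "Contig",
    "ContigClass",
    "AssemblyStats",
    "match_genes",
    "filter_matches",
    "classify_contigs",
    "cluster_genes",
    "extend_and_bridge",
    "assembly_stats",
    "merge_assemblies",
    "MergeParams",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneAnnotation:
    """A predicted gene on a contig; coordinates 0-based half-open."""
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    peptide: str = ""

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass
class Contig:
    """A sample-tagged assembled sequence with its gene annotations."""
    id: str
    sample_id: str
    sequence: str
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self):
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(
                    f"gene {g.gene_id} exceeds contig {self.id} bounds"
                )

    def __len__(self) -> int:
        return len(self.sequence)


class ContigClass(Enum):
    NO_GENES = "no_genes"
    SAMPLE_SPECIFIC_GENES = "sample_specific_genes"
    SINGLE_GENE = "single_gene"
    MULTI_GENE = "multi_gene"


@dataclass(frozen=True)
class MergeParams:
    min_contig_length: int = 2000
    min_identity: float = 95.0
    cov_low: float = 70.0
    cov_high: float = 130.0
    min_overlap: int = 100
    min_overlap_identity: float = 95.0


# ---------------------------------------------------------------------------
# Matching / filtering / classification / clustering
# ---------------------------------------------------------------------------

def match_genes(genes: Sequence[GeneAnnotation],
                sample_of: Mapping[str, str]) -> list[GeneMatch]:
    """All-vs-all peptide matches over the pooled predicted genes (both
    directions, excluding self), emulating a BLASTP search of every gene
    against the pooled database."""
    out = []
    for gq in genes:
        for gs in genes:
            if gq.gene_id == gs.gene_id:
                continue
            out.append(
                align_peptides(gq.peptide, gs.peptide,
                               query_id=gq.gene_id, subject_id=gs.gene_id)
            )
    return out


def filter_matches(matches: Iterable[GeneMatch],
                   min_identity: float = 95.0,
                   cov_low: float = 70.0,
                   cov_high: float = 130.0) -> list[GeneMatch]:
    """Keep matches with identity strictly above ``min_identity`` and both
    coverages strictly inside (``cov_low``, ``cov_high``) — the symmetric
    reading of the reciprocal coverage filter."""
    return [
        m for m in matches
        if m.identity > min_identity
        and cov_low < m.q_cov < cov_high
        and cov_low < m.s_cov < cov_high
    ]


def _cross_sample_partners(kept_matches: Iterable[GeneMatch],
                           sample_of: Mapping[str, str]) -> set[str]:
    """Gene ids with at least one kept match to another sample's gene."""
    out = set()
    for m in kept_matches:
        if sample_of[m.query_gene] != sample_of[m.subject_gene]:
            out.add(m.query_gene)
            out.add(m.subject_gene)
    return out


def classify_contigs(contigs: Sequence[Contig],
                     kept_matches: Iterable[GeneMatch]) -> dict[str, ContigClass]:
    """Partition contigs into the four classes: no genes; only
    sample-specific genes (no gene has a kept cross-sample match); else by
    gene count (single vs multiple)."""
    sample_of = {g.gene_id: c.sample_id for c in contigs for g in c.genes}
    crossed = _cross_sample_partners(kept_matches, sample_of)
    out = {}
    for c in contigs:
        if not c.genes:
            out[c.id] = ContigClass.NO_GENES
        elif all(g.gene_id not in crossed for g in c.genes):
            out[c.id] = ContigClass.SAMPLE_SPECIFIC_GENES
        elif len(c.genes) == 1:
            out[c.id] = ContigClass.SINGLE_GENE
        else:
            out[c.id] = ContigClass.MULTI_GENE
    return out


def cluster_genes(kept_matches: Iterable[GeneMatch],
                  all_genes: Iterable[str] | None = None) -> list[set[str]]:
    """Connected components (single linkage) of the kept-match graph;
    genes without matches form singleton clusters when ``all_genes`` is
    given."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str):
        for g in (a, b):
            parent.setdefault(g, g)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for m in kept_matches:
        union(m.query_gene, m.subject_gene)
    if all_genes is not None:
        for g in all_genes:
            parent.setdefault(g, g)
    groups: dict[str, set[str]] = {}
    for g in parent:
        groups.setdefault(find(g), set()).add(g)
    return sorted(groups.values(), key=lambda s: sorted(s)[0])


# ---------------------------------------------------------------------------
# Overlap detection (ungapped, k-mer anchored)
# ---------------------------------------------------------------------------

def _best_shift(a: str, b: str, k: int = 16,
                min_overlap: int = 100,
                min_identity: float = 95.0):
    """Best ungapped placement of b against a.

    Returns (shift, overlap_len, identity_pct) where ``shift`` is the
    coordinate of b[0] in a's frame, or None.  Candidate shifts come from
    shared k-mers; identity is evaluated over the full implied overlap.
    Substitution-only overlaps are assumed (no indel handling).
    """
    if len(a) < k or len(b) < k:
        return None
    index: dict[str, list[int]] = {}
    for i in range(0, len(a) - k + 1):
        index.setdefault(a[i:i + k], []).append(i)
    votes: dict[int, int] = {}
    for j in range(0, len(b) - k + 1, k):
        for i in index.get(b[j:j + k], ()):
            s = i - j
            votes[s] = votes.get(s, 0) + 1
    if not votes:
        return None
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    best = None
    for s in sorted(votes, key=lambda s: (-votes[s], s)):
        lo = max(0, s)
        hi = min(len(a), s + len(b))
        olen = hi - lo
        if olen < min_overlap:
            continue
        ident = 100.0 * float(
            (arr_a[lo:hi] == arr_b[lo - s:hi - s]).mean()
        )
        if ident >= min_identity:
            cand = (s, olen, ident)
            if best is None or olen * ident > best[1] * best[2]:
                best = cand
    return best


def _oriented_shift(anchor: str, other: str, **kw):
    """Try both orientations of ``other``; returns (shift, olen, ident,
    oriented_sequence) or None."""
    fwd = _best_shift(anchor, other, **kw)
    rev_seq = revcomp(other)
    rev = _best_shift(anchor, rev_seq, **kw)
    if fwd is None and rev is None:
        return None
    if rev is None or (fwd is not None and fwd[1] * fwd[2] >= rev[1] * rev[2]):
        return (*fwd, other)
    return (*rev, rev_seq)


def _consensus(sequences: list[str], min_overlap: int, min_identity: float) -> str:
    """Column-majority consensus of near-identical contigs.

    The longest contig is the backbone; the others are placed by ungapped
    shift and vote per column (ties to the alphabetically first base).
    Contigs that cannot be placed are ignored.
    """
    ordered = sorted(sequences, key=len, reverse=True)
    backbone = ordered[0]
    placements = [(0, backbone)]
    lo, hi = 0, len(backbone)
    for seq in ordered[1:]:
        hit = _oriented_shift(backbone, seq, min_overlap=min_overlap,
                              min_identity=min_identity)
        if hit is None:
            continue
        s, _, _, oriented = hit
        placements.append((s, oriented))
        lo = min(lo, s)
        hi = max(hi, s + len(oriented))
    length = hi - lo
    votes = np.zeros((5, length), dtype=np.int32)  # ACGT + other
    lookup = {"A": 0, "C": 1, "G": 2, "T": 3}
    for s, seq in placements:
        off = s - lo
        for i, ch in enumerate(seq):
            votes[lookup.get(ch, 4), off + i] += 1
    bases = np.array(list("ACGTN"))
    # argmax ties break to the lowest row index = alphabetically first base
    return "".join(bases[votes.argmax(axis=0)])


# ---------------------------------------------------------------------------
# Extension / bridging
# ---------------------------------------------------------------------------

def extend_and_bridge(anchor_sample: str,
                      contigs: Sequence[Contig],
                      clusters: Sequence[set[str]],
                      classes: Mapping[str, ContigClass] | None = None,
                      params: MergeParams = MergeParams()) -> list[Contig]:
    """Build the combined contig set anchored on ``anchor_sample``.

    Anchor contigs are never truncated.  A clustered non-anchor contig that
    overlaps an anchor contig's end (ungapped, >= ``min_overlap`` bases at
    >= ``min_overlap_identity``%) and protrudes extends it; one that
    overlaps the ends of two anchor contigs consistently bridges them.
    Anchor-less clusters contribute their column-majority consensus;
    non-anchor contigs carrying only sample-specific genes are appended
    verbatim.  Inconsistent bridges are skipped and logged.
    """
    by_id = {c.id: c for c in contigs}
    gene_home = {g.gene_id: c.id for c in contigs for g in c.genes}
    if classes is None:
        classes = {}

    anchor_seqs: dict[str, str] = {
        c.id: c.sequence for c in contigs if c.sample_id == anchor_sample
    }
    kw = dict(min_overlap=params.min_overlap,
              min_identity=params.min_overlap_identity)

    # collect candidate operations from clustered non-anchor contigs
    bridges = []   # (total_overlap, other_id, left_anchor, right_anchor, pieces)
    extensions = []  # (olen*ident, other_id, anchor_id, side, protrusion)
    used_specific: set[str] = set()
    consensus_contigs: list[Contig] = []
    seen_consensus: set[frozenset] = set()

    for cluster in clusters:
        contig_ids = sorted({gene_home[g] for g in cluster if g in gene_home})
        anchor_ids = [cid for cid in contig_ids
                      if by_id[cid].sample_id == anchor_sample]
        other_ids = [cid for cid in contig_ids
                     if by_id[cid].sample_id != anchor_sample]
        if not anchor_ids:
            # sample-specific contigs go in verbatim; other anchor-less
            # clusters contribute a consensus
            specific = [cid for cid in other_ids
                        if classes.get(cid) == ContigClass.SAMPLE_SPECIFIC_GENES]
            for cid in specific:
                used_specific.add(cid)
            rest = [cid for cid in other_ids if cid not in specific]
            key = frozenset(rest)
            if rest and key not in seen_consensus:
                seen_consensus.add(key)
                seq = _consensus([by_id[cid].sequence for cid in rest],
                                 params.min_overlap,
                                 params.min_overlap_identity)
                consensus_contigs.append(
                    Contig(id="consensus_" + rest[0], sample_id="combined",
                           sequence=seq)
                )
            continue
        for oid in other_ids:
            other = by_id[oid]
            hits = []
            for aid in anchor_ids:
                hit = _oriented_shift(anchor_seqs[aid], other.sequence, **kw)
                if hit is not None:
                    hits.append((aid, hit))
            if not hits:
                continue
            if len(hits) >= 2:
                # candidate bridge over the two best-supported anchors
                hits.sort(key=lambda h: -(h[1][1] * h[1][2]))
                (a1, h1), (a2, h2) = hits[0], hits[1]
                s1, o1, _, seq1 = h1
                s2, o2, _, seq2 = h2
                if seq1 == seq2:
                    # same orientation against both anchors; order anchors
                    # along the other contig
                    left, right = ((a1, s1), (a2, s2))
                    if -s2 < -s1:
                        left, right = right, left
                    (la, ls), (ra, rs) = left, right
                    gap_start = -ls + len(anchor_seqs[la])
                    gap_end = -rs
                    if gap_end >= gap_start:
                        bridges.append(
                            (o1 + o2, oid, la, ra,
                             seq1[gap_start:gap_end])
                        )
                        continue
                logger.info("bridge via %s skipped: inconsistent overlaps", oid)
            aid, (s, olen, ident, oriented) = hits[0]
            alen = len(anchor_seqs[aid])
            if s < 0:
                extensions.append(
                    (olen * ident, oid, aid, "left", oriented[: -s])
                )
            if s + len(oriented) > alen:
                extensions.append(
                    (olen * ident, oid, aid, "right",
                     oriented[alen - s:])
                )

    # apply bridges greedily: longest total overlap wins, ties by contig id
    merged_into: dict[str, str] = {}
    order: dict[str, list[str]] = {aid: [aid] for aid in anchor_seqs}
    joined: dict[str, str] = dict(anchor_seqs)
    linkers: dict[str, list[str]] = {aid: [] for aid in anchor_seqs}

    def resolve(aid: str) -> str:
        while aid in merged_into:
            aid = merged_into[aid]
        return aid

    for total, oid, la, ra, linker in sorted(
            bridges, key=lambda b: (-b[0], b[1])):
        la_r, ra_r = resolve(la), resolve(ra)
        if la_r == ra_r:
            logger.info("bridge via %s skipped: anchors already joined", oid)
            continue
        if order[la_r][-1] != la or order[ra_r][0] != ra:
            logger.info("bridge via %s skipped: ends already consumed", oid)
            continue
        joined[la_r] = joined[la_r] + linker + joined[ra_r]
        order[la_r] = order[la_r] + order[ra_r]
        linkers[la_r] = linkers[la_r] + [oid] + linkers[ra_r]
        merged_into[ra_r] = la_r
        del joined[ra_r], order[ra_r], linkers[ra_r]

    # extensions: best per (anchor end) that still is an outer end
    ext_left: dict[str, str] = {}
    ext_right: dict[str, str] = {}
    for score, oid, aid, side, protrusion in sorted(
            extensions, key=lambda e: (-e[0], e[1])):
        root = resolve(aid)
        if side == "left" and order[root][0] == aid and root not in ext_left:
            ext_left[root] = protrusion
        elif side == "right" and order[root][-1] == aid and root not in ext_right:
            ext_right[root] = protrusion

    combined: list[Contig] = []
    for root, seq in joined.items():
        seq = ext_left.get(root, "") + seq + ext_right.get(root, "")
        parts = order[root]
        cid = parts[0] if len(parts) == 1 and root not in ext_left and root not in ext_right else "merged_" + "_".join(parts)
        combined.append(Contig(id=cid, sample_id="combined", sequence=seq))
    combined.extend(consensus_contigs)
    for cid in sorted(used_specific):
        c = by_id[cid]
        combined.append(Contig(id=c.id, sample_id="combined", sequence=c.sequence))
    # anchor contigs in no cluster (e.g. gene-free) are already in `joined`
    return combined


# ---------------------------------------------------------------------------
# Statistics and the orchestrator
# ---------------------------------------------------------------------------

@dataclass
class AssemblyStats:
    n_contigs: int
    max_length: int
    n50: int
    mean_length: float
    total_residues: int
    n_base_count: int
    genome_coverage_fraction: float | None = None


def assembly_stats(contigs: Sequence[Contig] | Sequence[str],
                   genome_size: int | None = None) -> AssemblyStats:
    """Standard assembly summary.  N50 is the largest length L such that
    contigs of length >= L sum to at least half the assembly."""
    seqs = [c.sequence if isinstance(c, Contig) else c for c in contigs]
    if not seqs:
        raise ValueError("empty contig set")
    lengths = sorted((len(s) for s in seqs), reverse=True)
    total = sum(lengths)
    half = total / 2.0
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc >= half:
            n50 = L
            break
    return AssemblyStats(
        n_contigs=len(lengths),
        max_length=lengths[0],
        n50=n50,
        mean_length=total / len(lengths),
        total_residues=total,
        n_base_count=sum(s.upper().count("N") for s in seqs),
        genome_coverage_fraction=(total / genome_size
                                  if genome_size else None),
    )


def merge_assemblies(samples: Mapping[str, Sequence[Contig]],
                     anchor: str,
                     params: MergeParams = MergeParams()) -> dict:
    """Full reconciliation pipeline over per-sample contig sets.

    Returns a dict with the combined contigs, per-contig classification,
    gene clusters, kept matches and assembly statistics.
    """
    if anchor not in samples:
        raise ValueError(f"anchor sample {anchor!r} not among samples")
    contigs = [
        c for contigs_ in samples.values() for c in contigs_
        if len(c) >= params.min_contig_length
    ]
    sample_of = {g.gene_id: c.sample_id for c in contigs for g in c.genes}
    genes = [g for c in contigs for g in c.genes]
    matches = match_genes(genes, sample_of)
    kept = filter_matches(matches, params.min_identity,
                          params.cov_low, params.cov_high)
    classes = classify_contigs(contigs, kept)
    clusters = cluster_genes(kept, all_genes=[g.gene_id for g in genes])
    combined = extend_and_bridge(anchor, contigs, clusters, classes, params)
    return {
        "combined": combined,
        "classes": classes,
        "clusters": clusters,
        "kept_matches": kept,
        "stats": assembly_stats(combined),
        "anchor_stats": assembly_stats(list(samples[anchor])),
    }
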