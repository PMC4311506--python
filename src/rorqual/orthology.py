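"""1:1 orthology by reciprocal best hit (RBH) and codon-alignment
preparation for the selection and MKT stages.

Gene models are first filtered by peptide length (> 100 aa) and gapless
coverage of their best hit (> 70%); orthologs are the mutually unique
top-scoring pairs across two proteomes; ortholog CDS pairs are codon-
aligned by back-translating a global peptide alignment, with gapped codon
columns removed (the stand-in for an alignment-quality filter such as
Gblocks).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import codons as cd
from .align import ScoredHit, score_peptides
from .selection import CodonAlignment

__all__ = [
    "GeneModel",
    "OrthologPair",
    "filter_gene_models",
    "best_hits",
    "reciprocal_best_hits",
    "rbh_from_scores",
    "codon_align_pair",
    "CodonPairAlignment",
    "pivot_orthologs",
]


@dataclass(frozen=True)
class GeneModel:
    """A predicted gene with its peptide and the gapless coverage of its
    best database hit (None when it has no hit)."""
    gene_id: str
    peptide: str
    best_hit_coverage: float | None = None


def filter_gene_models(genes: Iterable[GeneModel],
                       min_peptide_aa: int = 100,
                       min_coverage: float = 70.0) -> list[GeneModel]:
    """Keep genes with peptide length strictly greater than
    ``min_peptide_aa`` and best-hit gapless coverage strictly greater than
    ``min_coverage`` percent."""
    return [
        g for g in genes
        if len(g.peptide) > min_peptide_aa
        and g.best_hit_coverage is not None
        and g.best_hit_coverage > min_coverage
    ]


def best_hits(hits: Iterable[ScoredHit],
              tie_break: str = "drop") -> dict[str, str]:
    """Unique best subject per query.

    ``tie_break='drop'`` removes queries whose top score is tied
    (conservative 1:1); ``'lexicographic'`` keeps the alphabetically first
    subject instead.
    """
    if tie_break not in ("drop", "lexicographic"):
        raise ValueError("tie_break must be 'drop' or 'lexicographic'")
    by_query: dict[str, list[ScoredHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out = {}
    for q, hs in by_query.items():
        top = max(h.score for h in hs)
        winners = sorted(h.subject_id for h in hs if h.score == top)
        if len(winners) == 1:
            out[q] = winners[0]
        elif tie_break == "lexicographic":
            out[q] = winners[0]
    return out


def reciprocal_best_hits(hits_ab: Iterable[ScoredHit],
                         hits_ba: Iterable[ScoredHit],
                         tie_break: str = "drop") -> list[tuple[str, str]]:
    """(a, b) pairs where b is a's unique best hit in B and vice versa."""
    ab = best_hits(hits_ab, tie_break)
    ba = best_hits(hits_ba, tie_break)
    return sorted(
        (a, b) for a, b in ab.items() if ba.get(b) == a
    )


def rbh_from_scores(score_matrix: np.ndarray,
                    a_ids: Sequence[str] | None = None,
                    b_ids: Sequence[str] | None = None,
                    tie_break: str = "drop") -> list[tuple[str, str]]:
    """RBH directly from a (|A| x |B|) score matrix."""
    m = np.asarray(score_matrix, dtype=float)
    if a_ids is None:
        a_ids = [f"a{i}" for i in range(m.shape[0])]
    if b_ids is None:
        b_ids = [f"b{j}" for j in range(m.shape[1])]
    hits_ab = [ScoredHit(a_ids[i], b_ids[j], m[i, j], 0, 0, 0)
               for i in range(m.shape[0]) for j in range(m.shape[1])]
    hits_ba = [ScoredHit(b_ids[j], a_ids[i], m[i, j], 0, 0, 0)
               for i in range(m.shape[0]) for j in range(m.shape[1])]
    return reciprocal_best_hits(hits_ab, hits_ba, tie_break)


@dataclass
class OrthologPair:
    """A 1:1 ortholog pair with in-frame CDS for both genes."""
    gene_a: str
    gene_b: str
    cds_a: str
    cds_b: str

    def __post_init__(self):
        for name, cds in (("cds_a", self.cds_a), ("cds_b", self.cds_b)):
            cd.translate_cds(cds)  # validates frame and internal stops


@dataclass
class CodonPairAlignment:
    """Back-translated codon alignment of an ortholog pair.

    ``aligned_a``/``aligned_b`` are the full gapped aligned CDS;
    ``alignment`` has gap-heavy codon columns removed."""
    pair: OrthologPair
    aligned_a: str
    aligned_b: str
    alignment: CodonAlignment
    n_columns_removed: int


def _backtranslate(peptide_gapped: str, cds: str) -> str:
    out = []
    k = 0
    for ch in peptide_gapped:
        if ch == "-":
            out.append("---")
        else:
            out.append(cds[3 * k: 3 * k + 3])
            k += 1
    return "".join(out)


def codon_align_pair(pair: OrthologPair,
                     gap_threshold: float = 0.0) -> CodonPairAlignment:
    """Codon-align an ortholog pair.

    The peptides are aligned globally, the alignment is back-translated
    onto the CDS, and codon columns whose gap fraction exceeds
    ``gap_threshold`` are removed (0 drops every gapped column).
    """
    from .align import _aligner

    pep_a = cd.translate_cds(pair.cds_a)
    pep_b = cd.translate_cds(pair.cds_b)
    aln = _aligner().align(pep_a, pep_b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    nt_a = _backtranslate(ga, pair.cds_a)
    nt_b = _backtranslate(gb, pair.cds_b)
    keep_a, keep_b = [], []
    removed = 0
    for k in range(len(ga)):
        gaps = (ga[k] == "-") + (gb[k] == "-")
        if gaps / 2.0 > gap_threshold:
            removed += 1
            continue
        keep_a.append(nt_a[3 * k: 3 * k + 3])
        keep_b.append(nt_b[3 * k: 3 * k + 3])
    alignment = CodonAlignment.from_sequences(
        [(pair.gene_a, "".join(keep_a)), (pair.gene_b, "".join(keep_b))]
    )
    return CodonPairAlignment(pair, nt_a, nt_b, alignment, removed)


def pivot_orthologs(proteomes: Mapping[str, Mapping[str, str]],
                    pivot: str,
                    tie_break: str = "drop") -> list[dict[str, str]]:
    """Multi-species 1:1 ortholog sets via a star of pairwise RBH.

    Every non-pivot species is RBH'd against the pivot proteome (scoring
    all peptide pairs with the global aligner) and the per-pivot-gene hits
    are intersected: a set is emitted only when every species contributes
    an ortholog.  Returns one dict species->gene_id per ortholog set.
    """
    if pivot not in proteomes:
        raise ValueError(f"pivot species {pivot!r} missing")
    others = [sp for sp in proteomes if sp != pivot]
    pivot_prot = proteomes[pivot]
    per_species: dict[str, dict[str, str]] = {}
    for sp in others:
        prot = proteomes[sp]
        hits_ab = [score_peptides(pa, pb, a, b)
                   for a, pa in prot.items() for b, pb in pivot_prot.items()]
        hits_ba = [score_peptides(pb, pa, b, a)
                   for a, pa in prot.items() for b, pb in pivot_prot.items()]
        pairs = reciprocal_best_hits(hits_ab, hits_ba, tie_break)
        per_species[sp] = {b: a for a, b in pairs}  # pivot gene -> sp gene
    sets = []
    for pg in sorted(pivot_prot):
        if all(pg in per_species[sp] for sp in others):
            entry = {pivot: pg}
            entry.update({sp: per_species[sp][pg] for sp in others})
            sets.append(entry)
    return sets
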