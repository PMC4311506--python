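"""Global peptide alignment used for gene matching and orthology scoring.

This is the desk-scale counterpart of an all-vs-all BLASTP search: a global
(Needleman–Wunsch) alignment with BLOSUM62 and affine gap costs, summarized
by percent identity and query/subject coverage.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class GeneMatch:
    """A scored correspondence between two predicted genes.

    identity: percent identical residues over columns where both sequences
    have a residue; q_cov/s_cov: percent of query/subject residues aligned
    opposite a residue (not a gap).
    """
    query_gene: str
    subject_gene: str
    identity: float
    q_cov: float
    s_cov: float

    def __post_init__(self):
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be a percentage")
        if self.q_cov < 0 or self.s_cov < 0:
            raise ValueError("coverages must be non-negative")


@dataclass(frozen=True)
class ScoredHit:
    """A scored hit for reciprocal-best-hit orthology."""
    query_id: str
    subject_id: str
    score: float
    identity: float
    q_cov: float
    s_cov: float


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _alignment_summary(query: str, subject: str):
    aln = _aligner().align(query, subject)[0]
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        aligned_cols += qe - qs
        matches += sum(
            1 for a, b in zip(query[qs:qe], subject[ss:se]) if a == b
        )
    return float(aln.score), matches, aligned_cols


def align_peptides(query: str, subject: str,
                   query_id: str = "query",
                   subject_id: str = "subject") -> GeneMatch:
    """Globally align two peptides and report identity/coverage."""
    if not query or not subject:
        raise ValueError("empty peptide sequence")
    _, matches, cols = _alignment_summary(query, subject)
    identity = 100.0 * matches / cols if cols else 0.0
    return GeneMatch(
        query_gene=query_id, subject_gene=subject_id,
        identity=identity,
        q_cov=100.0 * cols / len(query),
        s_cov=100.0 * cols / len(subject),
    )


def score_peptides(query: str, subject: str,
                   query_id: str = "query",
                   subject_id: str = "subject") -> ScoredHit:
    """Like :func:`align_peptides` but also carrying the raw alignment
    score, for best-hit ranking."""
    if not query or not subject:
        raise ValueError("empty peptide sequence")
    score, matches, cols = _alignment_summary(query, subject)
    identity = 100.0 * matches / cols if cols else 0.0
    return ScoredHit(
        query_id=query_id, subject_id=subject_id, score=score,
        identity=identity,
        q_cov=100.0 * cols / len(query),
        s_cov=100.0 * cols / len(subject),
    )
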