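"""The McDonald–Kreitman test.

Per gene, nonsynonymous/synonymous changes are split into within-species
polymorphism (Pn, Ps) and fixed divergence to an outgroup (Dn, Ds); under
neutrality Dn/Ds = Pn/Ps, and a significant excess of nonsynonymous
divergence (equivalently a paucity of nonsynonymous polymorphism) signals
positive selection.  Significance uses a two-sided Fisher exact test on
the 2x2 table; the neutrality index NI = (Pn/Ps)/(Dn/Ds) and
alpha = 1 - NI summarize the direction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import codons as cd
from .selection import ng86_pair_counts

__all__ = [
    "MKTable",
    "classify_changes",
    "fisher_exact_2x2",
    "mk_test",
]


def fisher_exact_2x2(dn: int, ds: int, pn: int, ps: int) -> float:
    """Two-sided Fisher exact p for the table [[Dn, Ds], [Pn, Ps]].

    Sums the probabilities of every table with the same margins whose
    hypergeometric probability does not exceed that of the observed table
    (with a small relative tolerance for float ties).
    """
    for v in (dn, ds, pn, ps):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    dn, ds, pn, ps = int(dn), int(ds), int(pn), int(ps)
    n_total = dn + ds + pn + ps
    row1 = dn + ds
    col1 = dn + pn
    if n_total == 0 or row1 in (0, n_total) or col1 in (0, n_total):
        return 1.0
    k_lo = max(0, row1 + col1 - n_total)
    k_hi = min(row1, col1)
    ks = np.arange(k_lo, k_hi + 1)
    # hypergeometric pmf via log-binomials: C(col1,k) C(n-col1,row1-k) / C(n,row1)
    lg = gammaln
    log_pmf = (
        lg(col1 + 1) - lg(ks + 1) - lg(col1 - ks + 1)
        + lg(n_total - col1 + 1) - lg(row1 - ks + 1)
        - lg(n_total - col1 - row1 + ks + 1)
        - (lg(n_total + 1) - lg(row1 + 1) - lg(n_total - row1 + 1))
    )
    pmf = np.exp(log_pmf)
    p_obs = pmf[dn - k_lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


@dataclass
class MKTable:
    """The 2x2 MKT counts with derived statistics.

    Counts are pathway-averaged and may be fractional for multi-hit
    codons; they are rounded to integers for the Fisher test.
    ``ambiguous`` tallies codons segregating more than two states within
    species, which are excluded from the counts.
    """
    gene_id: str
    dn: float
    ds: float
    pn: float
    ps: float
    ambiguous: int = 0

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (round(self.dn), round(self.ds), round(self.pn), round(self.ps))

    @property
    def p_fisher(self) -> float:
        return fisher_exact_2x2(*self.counts)

    @property
    def ni(self) -> float:
        """Neutrality index (Pn/Ps)/(Dn/Ds); NaN when any denominator
        (Ps, Dn or Ds) is zero."""
        if self.ps == 0 or self.ds == 0 or self.dn == 0:
            return float("nan")
        return (self.pn / self.ps) / (self.dn / self.ds)

    @property
    def alpha(self) -> float:
        """Adaptive fraction of fixed differences, 1 - NI."""
        return 1.0 - self.ni

    @property
    def adaptive_direction(self) -> bool:
        """True when nonsynonymous changes are enriched among fixed
        differences (Dn/Ds > Pn/Ps, compared by cross products)."""
        return self.dn * self.ps > self.pn * self.ds

    def significant(self, alpha_level: float = 0.05) -> bool:
        return self.p_fisher < alpha_level and self.adaptive_direction


def classify_changes(within: Sequence[str], outgroup: str,
                     gene_id: str = "gene") -> MKTable:
    """Count polymorphic and fixed synonymous/nonsynonymous changes.

    Per codon column: two segregating states within species contribute
    polymorphic changes (classified between the two within-species
    codons); a monomorphic column differing from the outgroup contributes
    fixed changes; columns that are both polymorphic and divergent count
    their polymorphic changes only; columns with more than two
    within-species states are excluded and tallied as ambiguous.
    Multi-position differences are apportioned by equal-weight minimal
    pathway enumeration, as in the NG86 counting.
    """
    if len(within) < 2:
        raise ValueError("need at least 2 within-species haplotypes")
    rows = [cd.codon_indices(s) for s in within]
    out_row = cd.codon_indices(outgroup)
    lengths = {r.size for r in rows} | {out_row.size}
    if len(lengths) != 1:
        raise ValueError("sequences differ in length")
    mat = np.vstack(rows)
    dn = ds = pn = ps = 0.0
    ambiguous = 0
    for j in range(mat.shape[1]):
        col = mat[:, j]
        o = out_row[j]
        if np.any(col < 0) or o < 0:
            continue
        states = np.unique(col)
        if states.size == 1:
            if states[0] != o:
                sd, nd = ng86_pair_counts(
                    cd.SENSE_CODONS[states[0]], cd.SENSE_CODONS[o]
                )
                ds += sd
                dn += nd
        elif states.size == 2:
            sd, nd = ng86_pair_counts(
                cd.SENSE_CODONS[states[0]], cd.SENSE_CODONS[states[1]]
            )
            ps += sd
            pn += nd
        else:
            ambiguous += 1
    return MKTable(gene_id=gene_id, dn=dn, ds=ds, pn=pn, ps=ps,
                   ambiguous=ambiguous)


def mk_test(genes: Iterable[tuple[str, Sequence[str], str]],
            alpha_level: float = 0.05) -> pd.DataFrame:
    """McDonald–Kreitman test per gene.

    ``genes`` yields (gene_id, within-species haplotype CDS list, outgroup
    CDS).  A gene is flagged significant when the Fisher p is below
    ``alpha_level`` *and* the direction is adaptive (Dn/Ds > Pn/Ps).
    """
    rows = []
    for gene_id, within, outgroup in genes:
        t = classify_changes(within, outgroup, gene_id=gene_id)
        rows.append({
            "gene_id": t.gene_id, "Dn": t.dn, "Ds": t.ds,
            "Pn": t.pn, "Ps": t.ps, "ambiguous": t.ambiguous,
            "p_fisher": t.p_fisher, "NI": t.ni, "alpha": t.alpha,
            "significant": t.significant(alpha_level),
        })
    return pd.DataFrame(
        rows, columns=["gene_id", "Dn", "Ds", "Pn", "Ps", "ambiguous",
                       "p_fisher", "NI", "alpha", "significant"],
    )
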