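"""Genetic-code tables and codon utilities shared by the selection, MKT and
simulation modules.

Codons are indexed over the 61 sense codons of the standard nuclear code in
TCAG order (the conventional ordering of codon-model software), with stop
codons excluded from the state space.
"""
from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "TCAG"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)

#: 61 sense codons in TCAG product order.
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61

AMINO_ACID = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a->b is a transition."""
    if a == b:
        raise ValueError("identical bases are not a substitution")
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def is_sense(codon: str) -> bool:
    return codon in CODON_INDEX


def translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stops."""
    if codon in STOP_CODONS:
        return "*"
    return AMINO_ACID[codon]


def is_synonymous(c1: str, c2: str) -> bool:
    """Both codons sense and coding for the same amino acid."""
    return is_sense(c1) and is_sense(c2) and AMINO_ACID[c1] == AMINO_ACID[c2]


def diff_positions(c1: str, c2: str) -> tuple[int, ...]:
    return tuple(k for k in range(3) if c1[k] != c2[k])


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS; raises on length or internal stops.

    A single trailing stop codon is tolerated and dropped.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    peptide = []
    n = len(cds) // 3
    for i in range(n):
        codon = cds[3 * i: 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon {i}")
        if codon not in CODON_INDEX:
            raise ValueError(f"unrecognized codon {codon!r} at codon {i}")
        peptide.append(AMINO_ACID[codon])
    return "".join(peptide)


def codon_indices(seq: str) -> np.ndarray:
    """Encode an in-frame, possibly gapped nucleotide sequence as sense-codon
    indices; any codon containing a gap or ambiguity (or a stop) maps to -1
    (missing data)."""
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for i in range(out.size):
        out[i] = CODON_INDEX.get(seq[3 * i: 3 * i + 3], -1)
    return out


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] if i >= 0 else "---" for i in idx)


@lru_cache(maxsize=1)
def neighbor_table() -> dict[str, list[tuple[str, bool, bool]]]:
    """For each sense codon, its single-nucleotide sense neighbors as
    (neighbor, is_transition, is_synonymous)."""
    table: dict[str, list[tuple[str, bool, bool]]] = {}
    for c in SENSE_CODONS:
        entries = []
        for k in range(3):
            for b in BASES:
                if b == c[k]:
                    continue
                nb = c[:k] + b + c[k + 1:]
                if nb in CODON_INDEX:
                    entries.append(
                        (nb, is_transition(c[k], b), is_synonymous(c, nb))
                    )
        table[c] = entries
    return table
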