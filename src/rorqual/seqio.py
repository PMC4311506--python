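"""Readers and writers for the plain-text formats the pipeline touches:
FASTA, Newick, relaxed PHYLIP and (via :mod:`rorqual.variants`) VCF 4.2.

Conventions: all internal intervals are 0-based half-open; '.' gap
characters are normalized to '-' on read; duplicate sequence ids are an
error.
"""
from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import dendropy
from Bio import AlignIO, SeqIO

__all__ = [
    "SeqRecord",
    "AlignmentMatrix",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_phylip_relaxed",
    "write_phylip_relaxed",
]

_NT_ALPHABET = set("ACGTURYSWKMBDHVN-")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")


@dataclass
class SeqRecord:
    """A named sequence."""
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("empty sequence id")

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_alphabet(records: list[SeqRecord], alphabet: str | None):
    if alphabet is None:
        return
    allowed = {"nt": _NT_ALPHABET, "aa": _AA_ALPHABET}[alphabet]
    for r in records:
        bad = set(r.sequence.upper()) - allowed
        if bad:
            raise ValueError(
                f"record {r.id!r}: characters {sorted(bad)} not valid {alphabet}"
            )


def read_fasta(path, alphabet: str | None = None) -> list[SeqRecord]:
    """Read a FASTA file in file order.

    Raises on empty files, duplicate ids, or content before the first
    header.  ``alphabet`` ('nt' or 'aa') optionally validates residues.
    """
    with open(path) as fh:
        head = fh.read(1)
        if head == "":
            raise ValueError(f"{path}: empty FASTA file")
        if head != ">":
            raise ValueError(f"{path}: malformed FASTA (must start with '>')")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SeqRecord(rec.id, str(rec.seq).replace(".", "-"), desc)
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    _validate_alphabet(records, alphabet)
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}"
            if getattr(r, "description", ""):
                header += f" {r.description}"
            fh.write(header + "\n")
            seq = r.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(source) -> dendropy.Tree:
    """Parse a Newick tree from a string or a path.

    Returns a dendropy Tree (the PhyloTree type used package-wide).
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in Newick string")
    compact = "".join(text.split())
    for bad in (",,", "(,", ",)"):
        if bad in compact:
            raise ValueError(f"malformed Newick: empty clade near {bad!r}")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths at 10 significant digits."""
    text = tree.as_string(
        schema="newick",
        real_value_format_specifier=".10g",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return text.strip() + "\n"


# ---------------------------------------------------------------------------
# Relaxed PHYLIP
# ---------------------------------------------------------------------------

@dataclass
class AlignmentMatrix:
    """A multiple sequence alignment: ordered taxa and equal-length rows."""
    taxa: list[str]
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa/sequence count mismatch")
        if len(self.taxa) < 2:
            raise ValueError("an alignment needs at least 2 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    @classmethod
    def from_fasta(cls, path) -> "AlignmentMatrix":
        recs = read_fasta(path)
        return cls([r.id for r in recs], [r.sequence for r in recs])


def read_phylip_relaxed(path) -> AlignmentMatrix:
    """Read a relaxed-name PHYLIP alignment (sequential or interleaved)."""
    try:
        aln = AlignIO.read(str(path), "phylip-relaxed")
    except ValueError as exc:
        raise ValueError(f"{path}: not a valid relaxed PHYLIP file: {exc}") from exc
    return AlignmentMatrix(
        [rec.id for rec in aln],
        [str(rec.seq).replace(".", "-") for rec in aln],
    )


def write_phylip_relaxed(matrix: AlignmentMatrix, path) -> None:
    name_w = max(len(t) for t in matrix.taxa) + 2
    with open(path, "w") as fh:
        fh.write(f" {matrix.n_taxa} {matrix.n_sites}\n")
        for name, seq in zip(matrix.taxa, matrix.sequences):
            fh.write(name.ljust(name_w) + seq + "\n")
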