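"""VCF parsing and the post-calling hard filters.

A multi-sample callset is reduced by fixed annotation thresholds (the GATK
hard-filter convention): a record is discarded when QUAL < 30, QD < 5,
FS > 200, MQ0 > 4 or MQ0/DP > 0.1 (all comparisons strict; an absent
annotation cannot fail its rule), and optionally when any sample genotype
is missing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "HardFilterThresholds",
    "read_vcf",
    "write_vcf",
    "passes_hard_filters",
    "drop_missing",
    "filter_vcf",
]

_NUMERIC_INFO = ("QD", "FS", "MQ0", "DP")


@dataclass
class VariantRecord:
    """One VCF data line: site annotations plus per-sample genotypes.

    ``pos`` is 1-based (the VCF convention); ``qual`` is None when printed
    as '.'; numeric INFO keys absent from the line are simply absent from
    ``info`` (never imputed to zero); other INFO keys are kept as opaque
    strings.
    """
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    vid: str = "."
    info: dict = field(default_factory=dict)
    genotypes: tuple[str, ...] = ()
    samples: tuple[str, ...] = ()

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("POS must be >= 1")
        if not self.alts:
            raise ValueError("ALT must be nonempty")

    @property
    def missing_mask(self) -> tuple[bool, ...]:
        return tuple("." in gt.replace("|", "/").split("/") for gt in self.genotypes)

    @property
    def n_missing(self) -> int:
        return sum(self.missing_mask)

    @property
    def is_indel(self) -> bool:
        return any(len(a) != len(self.ref) for a in self.alts)


def _gt_string(sample) -> str:
    gt = sample.get("GT")
    if gt is None:
        return "./."
    sep = "|" if getattr(sample, "phased", False) else "/"
    return sep.join("." if a is None else str(a) for a in gt)


def read_vcf(path) -> list[VariantRecord]:
    """Read a plain-text VCF 4.x file into :class:`VariantRecord` objects.

    Numeric INFO keys (QD, FS, MQ0, DP) are coerced to float; a key
    missing from a line is absent from the record.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"{path}: not a parseable VCF: {exc}") from exc
    samples = tuple(vf.header.samples)
    records = []
    with vf:
        for rec in vf:
            info: dict = {}
            for key, value in rec.info.items():
                if key in _NUMERIC_INFO:
                    if isinstance(value, tuple):
                        value = value[0]
                    info[key] = float(value)
                else:
                    info[key] = value
            records.append(
                VariantRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    qual=None if rec.qual is None else float(rec.qual),
                    vid=rec.id or ".",
                    info=info,
                    genotypes=tuple(_gt_string(rec.samples[s]) for s in samples),
                    samples=samples,
                )
            )
    return records


def _fmt_info_value(v, as_int: bool = False) -> str:
    if isinstance(v, bool):
        return ""
    if isinstance(v, float):
        if as_int and v == int(v):
            return str(int(v))
        return f"{v:g}"
    if isinstance(v, tuple):
        return ",".join(_fmt_info_value(x) for x in v)
    return str(v)


def write_vcf(records: Sequence[VariantRecord], path,
              samples: Sequence[str] | None = None) -> None:
    """Write records as an uncompressed VCF 4.2 file with a minimal header
    declaring the numeric INFO keys and GT."""
    if samples is None:
        samples = records[0].samples if records else ()
    chroms = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Qual by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">\n')
        fh.write('##INFO=<ID=MQ0,Number=1,Type=Integer,Description="Zero-MQ reads">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            header += ["FORMAT", *samples]
        fh.write("\t".join(header) + "\n")
        for r in records:
            info = ";".join(
                k if _fmt_info_value(v) == ""
                else f"{k}={_fmt_info_value(v, as_int=k in ('MQ0', 'DP'))}"
                for k, v in r.info.items()
            ) or "."
            row = [
                r.chrom, str(r.pos), r.vid, r.ref, ",".join(r.alts),
                "." if r.qual is None else f"{r.qual:g}", ".", info,
            ]
            if samples:
                row += ["GT", *r.genotypes]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Hard filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HardFilterThresholds:
    qual_min: float = 30.0
    qd_min: float = 5.0
    fs_max: float = 200.0
    mq0_max: float = 4.0
    mq0_dp_max: float = 0.1


def passes_hard_filters(
    record: VariantRecord,
    thresholds: HardFilterThresholds = HardFilterThresholds(),
) -> tuple[bool, list[str]]:
    """Evaluate the five annotation rules; returns (passed, violated rules).

    All comparisons are strict, so boundary values (QUAL=30, QD=5, FS=200,
    MQ0=4, MQ0/DP=0.1) pass.  A rule whose annotation is absent is not
    applicable; MQ0/DP with DP absent or zero is likewise skipped (logged).
    """
    t = thresholds
    reasons = []
    if record.qual is not None and record.qual < t.qual_min:
        reasons.append("QUAL")
    qd = record.info.get("QD")
    if qd is not None and qd < t.qd_min:
        reasons.append("QD")
    fs = record.info.get("FS")
    if fs is not None and fs > t.fs_max:
        reasons.append("FS")
    mq0 = record.info.get("MQ0")
    if mq0 is not None and mq0 > t.mq0_max:
        reasons.append("MQ0")
    dp = record.info.get("DP")
    if mq0 is not None:
        if dp is None or dp <= 0:
            logger.debug(
                "%s:%d MQ0 present but DP absent/zero; MQ0/DP rule skipped",
                record.chrom, record.pos,
            )
        elif mq0 / dp > t.mq0_dp_max:
            reasons.append("MQ0/DP")
    return (not reasons), reasons


def drop_missing(records: Iterable[VariantRecord],
                 n_samples: int | None = None) -> list[VariantRecord]:
    """Remove records with at least one missing sample genotype."""
    out = []
    for r in records:
        gts = r.genotypes[:n_samples] if n_samples is not None else r.genotypes
        if not any("." in gt.replace("|", "/").split("/") for gt in gts):
            out.append(r)
    return out


def filter_vcf(path_in, path_out,
               thresholds: HardFilterThresholds = HardFilterThresholds(),
               discard_missing: bool = True) -> dict:
    """Apply the hard filters (and optionally the missingness rule) to a
    VCF file, writing the surviving records in input order.

    Returns summary counts: input, passed, failed_by_rule, and SNV/indel
    tallies of the surviving records.
    """
    records = read_vcf(path_in)
    failed_by_rule: dict[str, int] = {}
    passed = []
    for r in records:
        ok, reasons = passes_hard_filters(r, thresholds)
        if ok and discard_missing and r.n_missing > 0:
            ok, reasons = False, ["MISSING"]
        elif not ok and discard_missing and r.n_missing > 0:
            reasons = reasons + ["MISSING"]
        if ok:
            passed.append(r)
        else:
            for reason in reasons:
                failed_by_rule[reason] = failed_by_rule.get(reason, 0) + 1
    write_vcf(passed, path_out,
              samples=records[0].samples if records else ())
    return {
        "input": len(records),
        "passed": len(passed),
        "failed": len(records) - len(passed),
        "failed_by_rule": failed_by_rule,
        "passed_snv": sum(1 for r in passed if not r.is_indel),
        "passed_indel": sum(1 for r in passed if r.is_indel),
    }
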