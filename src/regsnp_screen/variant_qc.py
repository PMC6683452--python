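"""Variant quality control: structural-variant removal, call-rate and MAF filters.

The screening funnel's first stage keeps only SNVs (indels cannot be genotyped
on the downstream mass-array platform), then drops sites with a per-site call
rate below 90%.  A later stage drops sites whose minor allele frequency is not
above 5%.  Boundary semantics follow the stated inequalities exactly: a call
rate of exactly 0.90 is kept ("less than 90%" removed); a MAF of exactly 0.05
is dropped ("> 5%" kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = [
    "VariantClass",
    "VariantRecord",
    "classify_variant",
    "apply_qc",
    "maf_filter",
    "read_vcf",
    "write_vcf",
    "FilterLedger",
]


class VariantClass(Enum):
    SNV = "SNV"
    INDEL = "INDEL"


@dataclass
class VariantRecord:
    """A located allele substitution with QC metadata.

    ``pos0`` is 0-based; VCF positions are converted exactly once, on read.
    """

    contig: str
    pos0: int
    id: str
    ref: str
    alts: tuple[str, ...]
    call_rate: float
    maf: float | None = None
    variant_class: VariantClass = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.variant_class is None:
            self.variant_class = classify_variant(self.ref, self.alts)
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"call_rate {self.call_rate} outside [0, 1] for {self.id}")
        if self.maf is not None and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf {self.maf} outside [0, 0.5] for {self.id}")

    @property
    def pos1(self) -> int:
        """1-based position for VCF emission / display parity."""
        return self.pos0 + 1


def classify_variant(ref: str, alts: Sequence[str]) -> VariantClass:
    """SNV iff ref and every alt are single bases; INDEL otherwise."""
    if not ref or not alts or any(not a for a in alts):
        raise ValueError("malformed record: empty allele string")
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return VariantClass.SNV
    return VariantClass.INDEL


@dataclass
class FilterLedger:
    """Per-filter removal counts for the funnel report."""

    n_input: int = 0
    n_structural_removed: int = 0
    n_low_call_rate_removed: int = 0
    n_low_maf_removed: int = 0
    n_output: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def apply_qc(
    variants: Sequence[VariantRecord],
    call_rate_min: float = 0.90,
    ledger: FilterLedger | None = None,
) -> list[VariantRecord]:
    """Stage-1 QC: drop structural variants, then sites with call rate below
    ``call_rate_min``.  A call rate exactly at the threshold is kept.
    Preserves input order; idempotent.
    """
    ledger = ledger if ledger is not None else FilterLedger()
    ledger.n_input = len(variants)
    snvs = [v for v in variants if v.variant_class is VariantClass.SNV]
    ledger.n_structural_removed = len(variants) - len(snvs)
    kept = [v for v in snvs if v.call_rate >= call_rate_min]
    ledger.n_low_call_rate_removed = len(snvs) - len(kept)
    ledger.n_output = len(kept)
    return kept


def maf_filter(
    variants: Sequence[VariantRecord],
    maf_min: float = 0.05,
    ledger: FilterLedger | None = None,
) -> list[VariantRecord]:
    """Keep variants with minor allele frequency strictly above ``maf_min``.

    Raises
    ------
    ValueError
        If a record has no MAF populated (names the record).
    """
    for v in variants:
        if v.maf is None:
            raise ValueError(f"variant {v.id} at {v.contig}:{v.pos1} has no MAF")
    kept = [v for v in variants if v.maf > maf_min]
    if ledger is not None:
        ledger.n_low_maf_removed = len(variants) - len(kept)
        ledger.n_output = len(kept)
    return kept


# --- VCF I/O -----------------------------------------------------------------
# INFO keys: CR = per-site call rate, MAF = minor allele frequency.

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CR,Number=1,Type=Float,Description="Per-site genotype call rate">
##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">
"""


def write_vcf(variants: Iterable[VariantRecord], path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Emit records as a minimal VCF v4.2 with CR/MAF INFO keys."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        for contig, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"CR={v.call_rate:.6g}"
            if v.maf is not None:
                info += f";MAF={v.maf:.6g}"
            fh.write(
                f"{v.contig}\t{v.pos1}\t{v.id}\t{v.ref}\t{','.join(v.alts)}"
                f"\t.\t.\t{info}\n"
            )


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF into records, converting POS to 0-based exactly once."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            cr = rec.info.get("CR", 1.0)
            maf = rec.info.get("MAF", None)
            out.append(
                VariantRecord(
                    contig=rec.chrom,
                    pos0=rec.pos - 1,
                    id=rec.id or ".",
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    call_rate=float(cr),
                    maf=None if maf is None else float(maf),
                )
            )
    return out
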