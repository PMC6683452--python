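"""ChIP-seq peak confirmation: intersect motif-supported variants with peaks.

The funnel's final screening stage keeps a motif-overlapping variant only if
the binding-site occurrence supporting it overlaps (≥1 base) a ChIP-seq peak
interval, i.e. the site is experimentally bound, not just sequence-predicted.
A point-overlap mode (SNP position inside a peak) is available as an
alternative semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .motif_scan import AlleleEffect, AlleleEffectCall, MotifOccurrence, SnpContext

__all__ = ["Peak", "CandidateSnp", "read_peaks", "write_peaks", "confirm_candidates"]


@dataclass(frozen=True, order=True)
class Peak:
    """A half-open ChIP-seq peak interval."""

    contig: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.contig}:{self.start}-{self.end} has start >= end")


@dataclass
class CandidateSnp:
    """A screened candidate: motif-overlapping SNV supported by ≥1 peak."""

    variant: object
    effect_call: AlleleEffectCall
    occurrence: MotifOccurrence
    peaks: list[Peak]
    context: SnpContext | None = None


def read_peaks(path: str | Path) -> list[Peak]:
    """Parse a BED3+ file into peaks sorted by (contig, start).

    ``track``/``browser``/``#`` header lines are skipped; malformed lines are
    rejected with their line number.
    """
    peaks: list[Peak] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else ""
            peaks.append(Peak(fields[0], start, end, name))
    peaks.sort(key=lambda p: (p.contig, p.start))
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED3+name."""
    with Path(path).open("w") as fh:
        for p in peaks:
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{p.source or '.'}\n")


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def confirm_candidates(
    motif_calls: Sequence[AlleleEffectCall],
    peaks: Sequence[Peak],
    *,
    snp_overlap: bool = False,
) -> list[CandidateSnp]:
    """Keep motif-overlapping variants whose supporting occurrence intersects
    a peak (default) or whose SNP position lies inside a peak
    (``snp_overlap=True``).  Minimum overlap is one base.

    Only calls whose effect involves a site (preserved / destroyed / created)
    are candidates; ``NO_SITE`` calls never pass.  Output sorted by
    (contig, position); monotone in the peak set.
    """
    by_contig: dict[str, list[Peak]] = {}
    for p in peaks:
        by_contig.setdefault(p.contig, []).append(p)

    out: list[CandidateSnp] = []
    for call in motif_calls:
        if call.effect is AlleleEffect.NO_SITE:
            continue
        occs = call.occurrences_ref_allele or call.occurrences_alt_allele
        v = call.variant
        contig_peaks = by_contig.get(v.contig, ())
        supporting: list[Peak] = []
        chosen_occ = occs[0]
        for occ in occs:
            if snp_overlap:
                hits = [p for p in contig_peaks if p.start <= v.pos0 < p.end]
            else:
                hits = [p for p in contig_peaks if _overlaps(occ.start, occ.end, p.start, p.end)]
            if hits:
                chosen_occ = occ
                supporting = hits
                break
        if supporting:
            out.append(CandidateSnp(v, call, chosen_occ, supporting))
    out.sort(key=lambda c: (c.variant.contig, c.variant.pos0))
    return out
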