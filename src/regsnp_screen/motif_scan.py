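"""Degenerate-consensus motif scanning and allele-effect classification.

NF-κB (p50–p65) recognises the 10-bp degenerate consensus ``GGGRNNYYCC``
(IUPAC: R = A/G, Y = C/T, N = any base).  This module finds every occurrence
of such a consensus on both strands of a reference, relates variants to
occurrences (containment and ±window proximity), and classifies what each
allele of a SNV does to the binding site: preserves it, destroys it, creates
one, or never touches one.

Coordinates are 0-based half-open throughout; VCF positions are converted on
read (see :mod:`regsnp_screen.variant_qc`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "IupacPattern",
    "MotifOccurrence",
    "AlleleEffect",
    "AlleleEffectCall",
    "SnpContext",
    "NFKB_CONSENSUS",
    "compile_pattern",
    "scan",
    "scan_genome",
    "classify_allele_effect",
    "snps_near_occurrences",
    "snps_in_occurrences",
    "context_string",
    "reverse_complement",
]

#: Canonical NF-κB (p50–p65) binding consensus.
NFKB_CONSENSUS = "GGGRNNYYCC"

# IUPAC degenerate symbols supported by the scanner.  Reference 'N' (an
# ambiguous base call) is only matched by a pattern 'N', never by a
# constrained symbol, so ambiguous reference stretches cannot fake a site.
_IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYN", "TGCAYRN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC R/Y/N aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IupacPattern:
    """A degenerate consensus compiled for scanning.

    Attributes
    ----------
    symbols:
        The consensus as written, e.g. ``"GGGRNNYYCC"``.
    base_sets:
        Per-position allowed bases on the forward strand.
    """

    symbols: str
    base_sets: tuple[frozenset[str], ...]
    _fwd_re: re.Pattern = field(repr=False, compare=False)
    _rev_re: re.Pattern = field(repr=False, compare=False)

    @property
    def length(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True, order=True)
class MotifOccurrence:
    """A strand-aware occurrence of the pattern on a contig.

    ``matched_seq`` is always reported as read on the forward strand;
    for a ``-`` occurrence its reverse complement matches the pattern.
    """

    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive; end - start == pattern length
    strand: str  # '+' or '-'
    matched_seq: str = field(compare=False, default="")


class AlleleEffect(Enum):
    SITE_PRESERVED = "SITE_PRESERVED"
    SITE_DESTROYED = "SITE_DESTROYED"
    SITE_CREATED = "SITE_CREATED"
    NO_SITE = "NO_SITE"


@dataclass
class AlleleEffectCall:
    """Outcome of comparing a SNV's two alleles against the pattern."""

    variant: object
    effect: AlleleEffect
    occurrences_ref_allele: list[MotifOccurrence]
    occurrences_alt_allele: list[MotifOccurrence]


@dataclass(frozen=True)
class SnpContext:
    """Flanking sequence around a SNV, Table-style ``LEFT[REF/ALT]RIGHT``."""

    contig: str
    pos: int
    ref: str
    alt: str
    left: str
    right: str

    @property
    def context_string(self) -> str:
        return f"{self.left}[{self.ref}/{self.alt}]{self.right}"


def compile_pattern(consensus: str = NFKB_CONSENSUS) -> IupacPattern:
    """Compile a degenerate consensus into a scannable pattern.

    Raises
    ------
    ValueError
        If the consensus is empty or contains an unsupported symbol; the
        message names the offending symbol and its position.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    consensus = consensus.upper()
    sets = []
    for i, sym in enumerate(consensus):
        if sym not in _IUPAC_SETS:
            raise ValueError(
                f"unsupported symbol {sym!r} at position {i} in consensus {consensus!r}"
            )
        sets.append(_IUPAC_SETS[sym])

    def _regex(symbols: str) -> re.Pattern:
        parts = []
        for sym in symbols:
            bases = sorted(_IUPAC_SETS[sym])
            if sym == "N":
                # pattern N also accepts an ambiguous reference N
                parts.append("[ACGTN]")
            elif len(bases) == 1:
                parts.append(bases[0])
            else:
                parts.append("[" + "".join(bases) + "]")
        # lookahead so overlapping occurrences are all reported
        return re.compile("(?=(" + "".join(parts) + "))")

    rc = reverse_complement(consensus)
    return IupacPattern(
        symbols=consensus,
        base_sets=tuple(sets),
        _fwd_re=_regex(consensus),
        _rev_re=_regex(rc),
    )


def scan(
    sequence: str,
    pattern: IupacPattern,
    *,
    contig: str = "",
    both_strands: bool = True,
) -> list[MotifOccurrence]:
    """Find all pattern occurrences in ``sequence``.

    A ``+`` occurrence is an offset where the forward substring matches the
    pattern; a ``-`` occurrence is one where the reverse complement of the
    substring matches (equivalently the substring matches the
    reverse-complemented pattern).  Overlapping matches are all reported and
    a palindromic hit yields one record per strand.  Output is sorted by
    (start, strand).
    """
    seq = sequence.upper()
    out: list[MotifOccurrence] = []
    L = pattern.length
    for m in pattern._fwd_re.finditer(seq):
        s = m.start()
        out.append(MotifOccurrence(contig, s, s + L, "+", m.group(1)))
    if both_strands:
        for m in pattern._rev_re.finditer(seq):
            s = m.start()
            out.append(MotifOccurrence(contig, s, s + L, "-", m.group(1)))
    out.sort(key=lambda o: (o.start, o.strand))
    return out


def scan_genome(
    genome: Mapping[str, str],
    pattern: IupacPattern,
    *,
    both_strands: bool = True,
) -> list[MotifOccurrence]:
    """Scan every contig of a genome mapping {contig: sequence}."""
    out: list[MotifOccurrence] = []
    for contig in genome:
        out.extend(
            scan(str(genome[contig]), pattern, contig=contig, both_strands=both_strands)
        )
    return out


def _covering(occs: Iterable[MotifOccurrence], pos: int) -> list[MotifOccurrence]:
    return [o for o in occs if o.start <= pos < o.end]


def classify_allele_effect(
    variant,
    genome: Mapping[str, str],
    pattern: IupacPattern,
    *,
    both_strands: bool = True,
) -> AlleleEffectCall:
    """Classify what swapping ref→alt at a SNV does to covering sites.

    The window ``[pos-(L-1), pos+L)`` (clipped to the contig) is scanned twice,
    once per allele, and only occurrences that cover the variant position are
    compared.  ``SITE_PRESERVED`` means both alleles retain at least one
    covering occurrence; ``SITE_DESTROYED``/``SITE_CREATED`` mean exactly one
    allele does; ``NO_SITE`` means neither.  The classification is
    antisymmetric in (ref, alt).

    Raises
    ------
    ValueError
        For indels (multi-base ref or alt) — only SNVs are supported.
    """
    ref, alt = variant.ref, variant.alts[0] if hasattr(variant, "alts") else variant.alt
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"classify_allele_effect supports SNVs only, got {ref}>{alt}")
    seq = str(genome[variant.contig]).upper()
    pos = variant.pos0
    if not 0 <= pos < len(seq):
        raise ValueError(f"variant position {pos} outside contig {variant.contig}")
    L = pattern.length
    lo = max(0, pos - (L - 1))
    hi = min(len(seq), pos + L)
    window = seq[lo:hi]
    rel = pos - lo

    def _occs(allele: str) -> list[MotifOccurrence]:
        w = window[:rel] + allele.upper() + window[rel + 1 :]
        occs = scan(w, pattern, contig=variant.contig, both_strands=both_strands)
        # shift to genome coordinates, keep only those covering the variant
        shifted = [
            MotifOccurrence(o.contig, o.start + lo, o.end + lo, o.strand, o.matched_seq)
            for o in occs
        ]
        return _covering(shifted, pos)

    ref_occs = _occs(ref)
    alt_occs = _occs(alt)
    if ref_occs and alt_occs:
        effect = AlleleEffect.SITE_PRESERVED
    elif ref_occs:
        effect = AlleleEffect.SITE_DESTROYED
    elif alt_occs:
        effect = AlleleEffect.SITE_CREATED
    else:
        effect = AlleleEffect.NO_SITE
    return AlleleEffectCall(variant, effect, ref_occs, alt_occs)


def snps_near_occurrences(
    variants: Sequence,
    occurrences: Sequence[MotifOccurrence],
    window: int = 500_000,
) -> list[tuple[object, int]]:
    """Variants within ``window`` bases of any occurrence interval.

    Distance to an interval is 0 inside it.  Returns (variant, nearest
    distance) pairs in input order.  Mirrors the ±500 kb proximity step of
    the screening funnel.
    """
    by_contig: dict[str, list[MotifOccurrence]] = {}
    for o in occurrences:
        by_contig.setdefault(o.contig, []).append(o)
    out = []
    for v in variants:
        best = None
        for o in by_contig.get(v.contig, ()):
            if o.start <= v.pos0 < o.end:
                d = 0
            elif v.pos0 < o.start:
                d = o.start - v.pos0
            else:
                d = v.pos0 - (o.end - 1)
            if best is None or d < best:
                best = d
        if best is not None and best <= window:
            out.append((v, best))
    return out


def snps_in_occurrences(
    variants: Sequence,
    occurrences: Sequence[MotifOccurrence],
) -> list[object]:
    """Variants whose position is covered by ≥1 occurrence (either strand).

    Containment is half-open: start ≤ pos < end.
    """
    by_contig: dict[str, list[MotifOccurrence]] = {}
    for o in occurrences:
        by_contig.setdefault(o.contig, []).append(o)
    return [
        v
        for v in variants
        if any(o.start <= v.pos0 < o.end for o in by_contig.get(v.contig, ()))
    ]


def context_string(variant, genome: Mapping[str, str], flank: int = 9) -> SnpContext:
    """Flanking context ``LEFT[REF/ALT]RIGHT`` around a SNV.

    Flanks are ``flank`` bases each side, clipped at contig edges.
    Substituting REF back into the brackets reproduces the reference window.
    """
    seq = str(genome[variant.contig]).upper()
    pos = variant.pos0
    if not 0 <= pos < len(seq):
        raise ValueError(
            f"position {pos} out of bounds for contig {variant.contig} "
            f"(length {len(seq)})"
        )
    left = seq[max(0, pos - flank) : pos]
    right = seq[pos + 1 : pos + 1 + flank]
    return SnpContext(
        contig=variant.contig,
        pos=pos,
        ref=variant.ref,
        alt=variant.alts[0],
        left=left,
        right=right,
    )
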