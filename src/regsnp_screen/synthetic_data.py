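"""Synthetic inputs for the screening funnel, association and qPCR stages.

Real inputs to this pipeline — a population-scale variant call set, a
reference genome and a ChIP-seq peak track, plus an ESRD case-control cohort
and a ChIP-qPCR plate — are not redistributable, so every stage is exercised
on generated data with the statistical structure the analysis assumes:

* a genome of iid-uniform bases with a known number of planted, non-
  overlapping NF-κB consensus occurrences (random strand, random concrete
  instantiation of the degenerate positions);
* SNVs and indels with heterogeneous call rates (truncated Beta) and MAFs
  (uniform), a configurable subset placed inside planted motifs at
  consensus-critical or degenerate offsets, the rest verified site-neutral;
* peak intervals covering a chosen fraction of planted motifs, plus decoy
  peaks overlapping no planted site;
* a case-control cohort with a recessive-model effect planted at one SNP
  (retrospective reweighting of the control genotype distribution) and
  group-specific covariates;
* a qPCR plate whose per-sample percent-input values are drawn on the
  percent scale and inverted exactly into IP/input Ct pairs, so the
  quantification stage has analytically known truth.

Every generator is driven by one seed; identical configurations produce
byte-identical output files.  Ground-truth labels (planted coordinates,
inside_motif, destroys_site, peak support, expected candidacy) are recorded
in a JSON sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import GenotypeCounts
from .motif_scan import NFKB_CONSENSUS, _IUPAC_SETS, reverse_complement
from .variant_qc import VariantRecord

__all__ = [
    "SimulationConfig",
    "PlantedMotif",
    "SyntheticDataset",
    "gen_reference",
    "gen_variants",
    "gen_peaks",
    "gen_cohort",
    "gen_qpcr",
    "simulate_genotype_counts",
    "generate_dataset",
    "write_fasta",
]

_BASES = "ACGT"

# Cohort covariate structure: group-specific means/rates for an end-stage
# renal disease case-control study (cases on hemodialysis, eGFR <= 15;
# screened healthy controls, eGFR >= 60).
_DEFAULT_COVARIATES: dict[str, dict[str, object]] = {
    "control": {
        "male_frac": 0.446,
        "age": (73.50, 7.21),
        "bmi": (24.22, 3.37),
        "htn_frac": 0.427,
        "dm_frac": 0.125,
        "egfr": (93.81, 23.76),
        "egfr_bounds": (60.0, 200.0),
    },
    "case": {
        "male_frac": 0.508,
        "age": (71.84, 12.93),
        "bmi": (24.66, 4.80),
        "htn_frac": 0.813,
        "dm_frac": 0.803,
        "egfr": (5.73, 2.45),
        "egfr_bounds": (1.0, 15.0),
    },
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults set to the study
    conditions the pipeline is meant to emulate.

    ``n_variants`` counts every emitted record; ``n_motif_variants`` of them
    are placed inside planted motifs (one per motif, cycling), the rest are
    verified not to touch any binding site under either allele.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_contigs: int = 2
    consensus: str = NFKB_CONSENSUS
    n_planted_motifs: int = 20
    n_variants: int = 200
    n_motif_variants: int = 20
    motif_destroy_fraction: float = 0.5
    indel_fraction: float = 0.194  # structural fraction of the emulated call set
    callrate_beta_params: tuple[float, float] = (30.0, 2.0)
    callrate_fixed: float | None = None  # overrides the Beta law when set
    maf_range: tuple[float, float] = (0.01, 0.5)
    peak_coverage: float = 0.75
    n_decoy_peaks: int = 10
    n_cases: int = 847
    n_controls: int = 846
    planted_snp_control_genotype_freqs: tuple[float, float, float] = (0.181, 0.495, 0.324)
    planted_or: float = 1.31
    planted_snp_call_rate: float = 0.999
    covariate_means_by_group: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in _DEFAULT_COVARIATES.items()}
    )

    def __post_init__(self) -> None:
        f = self.planted_snp_control_genotype_freqs
        if abs(sum(f) - 1.0) > 1e-9 or min(f) < 0:
            raise ValueError("planted genotype frequencies must sum to 1 and be >= 0")
        if self.planted_or <= 0:
            raise ValueError("planted_or must be positive")
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must be in [0, 1]")
        if not 0 <= self.peak_coverage <= 1:
            raise ValueError("peak_coverage must be in [0, 1]")
        if min(self.genome_length, self.n_contigs, self.n_variants) < 0:
            raise ValueError("counts must be non-negative")
        if self.genome_length < 10 * len(self.consensus):
            raise ValueError("genome_length must be at least 10 consensus lengths")


@dataclass(frozen=True)
class PlantedMotif:
    """Ground-truth coordinates of one planted consensus occurrence."""

    contig: str
    start: int
    end: int
    strand: str
    seq: str  # forward-strand sequence as planted


# --- naive matcher used only to certify ground truth -------------------------
# Kept deliberately separate from motif_scan.scan: planted labels must not
# depend on the code path they are meant to test.


def _base_sets(consensus: str) -> list[frozenset[str]]:
    return [_IUPAC_SETS[s] for s in consensus]


def _naive_covering_match(seq: str, pos: int, consensus: str) -> bool:
    """True if any offset covering ``pos`` matches the consensus on either strand."""
    for symbols in (consensus, reverse_complement(consensus)):
        sets = _base_sets(symbols)
        L = len(sets)
        for start in range(max(0, pos - L + 1), min(len(seq) - L, pos) + 1):
            if all(seq[start + i] in sets[i] for i in range(L)):
                return True
    return False


def _forward_allowed_sets(consensus: str, strand: str) -> list[frozenset[str]]:
    """Per-position allowed bases on the forward strand for a planted motif."""
    sets = _base_sets(consensus)
    if strand == "+":
        return sets
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return [frozenset(comp[b] for b in s) for s in reversed(sets)]


# --- generators ---------------------------------------------------------------


def gen_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[PlantedMotif]]:
    """Random genome with exactly ``n_planted_motifs`` non-overlapping
    consensus occurrences planted at recorded coordinates.

    Each planted instance is a random concrete realisation of the degenerate
    consensus on a random strand.  Chance occurrences elsewhere are possible
    (density ~1/8192 per offset per strand for the NF-κB consensus) and are
    not suppressed; ground truth records only what was planted.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = len(config.consensus)
    lengths = _contig_lengths(config)
    if config.n_planted_motifs * 2 * L > sum(lengths):
        raise ValueError(
            f"genome of {sum(lengths)} bp too short to place "
            f"{config.n_planted_motifs} non-overlapping {L}-mers"
        )
    genome: dict[str, list[str]] = {}
    names = [f"chr{i + 1}" for i in range(config.n_contigs)]
    for name, n in zip(names, lengths):
        genome[name] = list(rng.choice(list(_BASES), size=n))

    sets = _base_sets(config.consensus)
    planted: list[PlantedMotif] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    attempts = 0
    while len(planted) < config.n_planted_motifs:
        attempts += 1
        if attempts > 1000 * max(1, config.n_planted_motifs):
            raise ValueError("could not place requested motifs without overlap")
        ci = int(rng.integers(0, config.n_contigs))
        name = names[ci]
        if lengths[ci] < L:
            continue
        start = int(rng.integers(0, lengths[ci] - L + 1))
        if any(start < e and s < start + L for s, e in occupied[name]):
            continue
        instance = "".join(str(rng.choice(sorted(s))) for s in sets)
        strand = "+" if rng.random() < 0.5 else "-"
        fwd = instance if strand == "+" else reverse_complement(instance)
        genome[name][start : start + L] = list(fwd)
        occupied[name].append((start, start + L))
        planted.append(PlantedMotif(name, start, start + L, strand, fwd))
    planted.sort(key=lambda m: (m.contig, m.start))
    return {n: "".join(genome[n]) for n in names}, planted


def _contig_lengths(config: SimulationConfig) -> list[int]:
    base = config.genome_length // config.n_contigs
    lengths = [base] * config.n_contigs
    lengths[-1] += config.genome_length - base * config.n_contigs
    return lengths


def _draw_call_rate(config: SimulationConfig, rng: np.random.Generator) -> float:
    if config.callrate_fixed is not None:
        return float(config.callrate_fixed)
    a, b = config.callrate_beta_params
    while True:  # truncated to [0.5, 1]
        x = float(rng.beta(a, b))
        if x >= 0.5:
            return x


def gen_variants(
    config: SimulationConfig,
    genome: Mapping[str, str],
    planted: Sequence[PlantedMotif],
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantRecord], dict[str, dict]]:
    """Variant set with ground-truth site labels.

    Returns (records, truth) where truth maps variant id to
    ``{inside_motif, destroys_site, motif_index}``.  Motif variants get call
    rates and MAFs that survive the QC and MAF filters, so candidacy is
    decided purely by peak support; background variants draw call rate from
    the configured law and MAF uniformly, and are resampled until neither
    allele touches any binding site (planted or chance).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    if config.n_motif_variants > config.n_variants:
        raise ValueError("n_motif_variants cannot exceed n_variants")
    contigs = list(genome)
    lengths = {c: len(genome[c]) for c in contigs}
    records: list[VariantRecord] = []
    truth: dict[str, dict] = {}
    used_pos: set[tuple[str, int]] = set()

    # variants inside planted motifs, one per motif (cycling)
    for i in range(config.n_motif_variants):
        motif = planted[i % len(planted)]
        seq = genome[motif.contig]
        allowed = _forward_allowed_sets(config.consensus, motif.strand)
        destroy = rng.random() < config.motif_destroy_fraction
        offsets = list(range(len(allowed)))
        rng.shuffle(offsets)
        placed = False
        for off in offsets:
            pos = motif.start + off
            if (motif.contig, pos) in used_pos:
                continue
            ref = seq[pos]
            allowed_here = allowed[off]
            if destroy:
                choices = sorted(set(_BASES) - allowed_here)
            else:
                choices = sorted(allowed_here - {ref})
            if not choices:
                continue
            alt = str(choices[int(rng.integers(0, len(choices)))])
            # certify the label with the naive matcher, independent of scan()
            ref_hit = _naive_covering_match(seq, pos, config.consensus)
            alt_seq = seq[:pos] + alt + seq[pos + 1 :]
            alt_hit = _naive_covering_match(alt_seq, pos, config.consensus)
            if not ref_hit:  # planted motif must cover its own variant
                continue
            vid = f"snv_m{i:03d}"
            records.append(
                VariantRecord(
                    contig=motif.contig,
                    pos0=pos,
                    id=vid,
                    ref=ref,
                    alts=(alt,),
                    call_rate=float(0.95 + 0.05 * rng.random()),
                    maf=float(rng.uniform(0.06, 0.5)),
                )
            )
            truth[vid] = {
                "inside_motif": True,
                "destroys_site": bool(ref_hit and not alt_hit),
                "motif_index": i % len(planted),
            }
            used_pos.add((motif.contig, pos))
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place a variant in motif {i % len(planted)}")

    # background variants: indels and site-neutral SNVs
    n_background = config.n_variants - config.n_motif_variants
    n_indels = int(round(config.indel_fraction * n_background))
    motif_intervals = {
        c: [(m.start, m.end) for m in planted if m.contig == c] for c in contigs
    }
    for j in range(n_background):
        is_indel = j < n_indels
        for _ in range(10_000):
            c = contigs[int(rng.integers(0, len(contigs)))]
            pos = int(rng.integers(0, lengths[c] - 2))
            if (c, pos) in used_pos:
                continue
            if any(s - 1 <= pos < e for s, e in motif_intervals[c]):
                continue
            seq = genome[c]
            ref_base = seq[pos]
            if is_indel:
                if rng.random() < 0.5:  # insertion
                    ref, alt = ref_base, ref_base + str(rng.choice(list(_BASES)))
                else:  # deletion
                    ref, alt = seq[pos : pos + 2], ref_base
                break
            choices = sorted(set(_BASES) - {ref_base})
            alt = str(choices[int(rng.integers(0, 3))])
            if _naive_covering_match(seq, pos, config.consensus):
                continue
            if _naive_covering_match(seq[:pos] + alt + seq[pos + 1 :], pos, config.consensus):
                continue
            ref = ref_base
            break
        else:
            raise ValueError("could not place background variant")
        vid = ("indel_b" if is_indel else "snv_b") + f"{j:03d}"
        records.append(
            VariantRecord(
                contig=c,
                pos0=pos,
                id=vid,
                ref=ref,
                alts=(alt,),
                call_rate=_draw_call_rate(config, rng),
                maf=float(rng.uniform(*config.maf_range)),
            )
        )
        truth[vid] = {"inside_motif": False, "destroys_site": False, "motif_index": None}
        used_pos.add((c, pos))

    records.sort(key=lambda v: (v.contig, v.pos0))
    return records, truth


def gen_peaks(
    config: SimulationConfig,
    planted: Sequence[PlantedMotif],
    genome: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[list, list[int]]:
    """Peak intervals covering ``peak_coverage`` of planted motifs, plus decoys.

    Returns (peaks, covered_motif_indices).  The first
    ``round(peak_coverage * n_planted)`` motifs (in planted order) are each
    covered by one padded peak; decoy peaks keep a 3-consensus-length margin
    from every planted motif so they can never support a planted site.
    """
    from .peak_intersect import Peak

    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    L = len(config.consensus)
    n_cov = int(round(config.peak_coverage * len(planted)))
    covered = list(range(n_cov))
    peaks: list[Peak] = []
    for k in covered:
        m = planted[k]
        pad_l = int(rng.integers(20, 200))
        pad_r = int(rng.integers(20, 200))
        start = max(0, m.start - pad_l)
        end = min(len(genome[m.contig]), m.end + pad_r)
        # clip the padding so the peak keeps a consensus-length margin from
        # every other planted motif (never clipping into its own motif)
        for idx, other in enumerate(planted):
            if idx == k or other.contig != m.contig:
                continue
            if other.end <= m.start:
                start = max(start, min(other.end + L, m.start))
            elif other.start >= m.end:
                end = min(end, max(other.start - L, m.end))
        peaks.append(Peak(m.contig, start, end, f"peak_m{k:03d}"))
    contigs = list(genome)
    margin = 3 * L
    for j in range(config.n_decoy_peaks):
        for _ in range(10_000):
            c = contigs[int(rng.integers(0, len(contigs)))]
            width = int(rng.integers(100, 400))
            if len(genome[c]) <= width:
                continue
            start = int(rng.integers(0, len(genome[c]) - width))
            end = start + width
            clash = any(
                m.contig == c and start - margin < m.end and m.start < end + margin
                for m in planted
            )
            if not clash:
                peaks.append(Peak(c, start, end, f"peak_decoy{j:03d}"))
                break
        else:
            raise ValueError("could not place decoy peak")
    peaks.sort(key=lambda p: (p.contig, p.start))
    return peaks, covered


def case_genotype_freqs(
    control_freqs: Sequence[float], odds_ratio: float
) -> tuple[float, float, float]:
    """Case genotype distribution implied by a recessive odds ratio.

    Retrospective-sampling construction: the risk-homozygote class gets its
    control probability multiplied by the OR on the odds scale against the
    pooled carrier classes, then the vector is renormalised.  The induced
    case/control recessive OR equals ``odds_ratio`` exactly.
    """
    p0, p1, p2 = control_freqs
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    w = (p0, p1, odds_ratio * p2)
    z = sum(w)
    q = tuple(x / z for x in w)
    if not all(0 <= x <= 1 for x in q):
        raise ValueError("odds ratio drives a genotype frequency out of [0, 1]")
    return q  # type: ignore[return-value]


def gen_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Subject table: id, group (0 control / 1 case), planted-SNP risk-allele
    dosage (NaN = missing at rate 1 − call rate), sex, age, bmi, htn, dm, egfr.

    Controls draw genotypes from the configured frequencies; cases from the
    recessive reweighting at ``planted_or``.  eGFR respects the group
    definitions (cases ≤ 15, controls ≥ 60 mL/min/1.73 m²).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    ctrl = np.asarray(config.planted_snp_control_genotype_freqs)
    case = np.asarray(case_genotype_freqs(tuple(ctrl), config.planted_or))
    rows = []
    for group, n, freqs in ((0, config.n_controls, ctrl), (1, config.n_cases, case)):
        params = config.covariate_means_by_group["control" if group == 0 else "case"]
        geno = rng.choice([0, 1, 2], size=n, p=freqs).astype(float)
        missing = rng.random(n) >= config.planted_snp_call_rate
        geno[missing] = np.nan
        age_m, age_s = params["age"]
        bmi_m, bmi_s = params["bmi"]
        eg_m, eg_s = params["egfr"]
        lo, hi = params["egfr_bounds"]
        egfr = _truncated_normal(rng, eg_m, eg_s, lo, hi, n)
        for i in range(n):
            rows.append(
                {
                    "id": f"{'ctrl' if group == 0 else 'case'}_{i:04d}",
                    "group": group,
                    "genotype": geno[i],
                    "sex": int(rng.random() < params["male_frac"]),
                    "age": round(float(rng.normal(age_m, age_s)), 2),
                    "bmi": round(float(rng.normal(bmi_m, bmi_s)), 2),
                    "htn": int(rng.random() < params["htn_frac"]),
                    "dm": int(rng.random() < params["dm_frac"]),
                    "egfr": round(float(egfr[i]), 2),
                }
            )
    return pd.DataFrame(rows)


def _truncated_normal(rng, mean, sd, lo, hi, n) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def simulate_genotype_counts(
    n_controls: int,
    n_cases: int,
    control_freqs: Sequence[float],
    odds_ratio: float,
    rng: np.random.Generator,
    snp_id: str = "planted",
) -> GenotypeCounts:
    """Fast counts-level cohort draw for replicate studies (no covariates)."""
    case_freqs = case_genotype_freqs(tuple(control_freqs), odds_ratio)
    ctrl = rng.multinomial(n_controls, control_freqs)
    case = rng.multinomial(n_cases, case_freqs)
    return GenotypeCounts(snp_id=snp_id, control=tuple(ctrl), case=tuple(case))


def gen_qpcr(
    group_means: Mapping[str, float],
    group_sem: Mapping[str, float],
    n_per_group: int = 3,
    input_fraction: float = 0.01,
    rng: np.random.Generator | int | None = None,
    ct_input: float = 30.0,
):
    """qPCR plate whose percent-input truth is drawn then inverted to Ct pairs.

    Per-sample percent input ~ Normal(mean, SEM·√n) per group (redrawn if
    ≤ 0), then ``ct_ip`` is solved from the percent-input formula so the
    quantification stage recovers the drawn values exactly (≤1e-9 relative).
    """
    from .quantification import QpcrMeasurement

    if isinstance(rng, int) or rng is None:
        rng = np.random.default_rng(rng or 0)
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    measurements: list[QpcrMeasurement] = []
    adj = ct_input - math.log2(1.0 / input_fraction)
    for g in group_means:
        mean, sem = float(group_means[g]), float(group_sem[g])
        if mean <= 0:
            raise ValueError(f"group {g}: mean percent input must be positive")
        sd = sem * math.sqrt(n_per_group)
        for i in range(n_per_group):
            while True:
                pct = float(rng.normal(mean, sd)) if sd > 0 else mean
                if pct > 0:
                    break
            ct_ip = adj - math.log2(pct / 100.0)
            measurements.append(
                QpcrMeasurement(
                    sample=f"{g}_{i + 1}",
                    genotype=g,
                    ct_ip=ct_ip,
                    ct_input=ct_input,
                    input_fraction=input_fraction,
                )
            )
    return measurements


# --- file emission ------------------------------------------------------------


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = str(genome[name])
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class SyntheticDataset:
    """One fully generated study, in memory plus optional on-disk mirror."""

    config: SimulationConfig
    genome: dict[str, str]
    planted: list[PlantedMotif]
    variants: list[VariantRecord]
    peaks: list
    covered_motifs: list[int]
    variant_truth: dict[str, dict]
    subjects: pd.DataFrame

    @property
    def expected_candidates(self) -> list[str]:
        """Variant ids that must survive the whole screening funnel."""
        covered = set(self.covered_motifs)
        return sorted(
            vid
            for vid, t in self.variant_truth.items()
            if t["inside_motif"] and t["motif_index"] in covered
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .peak_intersect import write_peaks
        from .variant_qc import write_vcf

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "reference.fa",
            "vcf": outdir / "variants.vcf",
            "bed": outdir / "peaks.bed",
            "subjects": outdir / "subjects.tsv",
            "truth": outdir / "ground_truth.json",
        }
        write_fasta(self.genome, paths["fasta"])
        write_vcf(
            self.variants, paths["vcf"],
            contig_lengths={c: len(s) for c, s in self.genome.items()},
        )
        write_peaks(self.peaks, paths["bed"])
        self.subjects.to_csv(paths["subjects"], sep="\t", index=False, na_rep="NA")
        truth = {
            "planted_motifs": [asdict(m) for m in self.planted],
            "covered_motifs": self.covered_motifs,
            "variants": self.variant_truth,
            "expected_candidates": self.expected_candidates,
        }
        paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
        return paths


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate every pipeline input from one config (one seed)."""
    root = np.random.SeedSequence(config.seed)
    r_ref, r_var, r_peak, r_cohort = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    genome, planted = gen_reference(config, r_ref)
    variants, truth = gen_variants(config, genome, planted, r_var)
    peaks, covered = gen_peaks(config, planted, genome, r_peak)
    subjects = gen_cohort(config, r_cohort)
    return SyntheticDataset(
        config=config,
        genome=genome,
        planted=planted,
        variants=variants,
        peaks=peaks,
        covered_motifs=covered,
        variant_truth=truth,
        subjects=subjects,
    )
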