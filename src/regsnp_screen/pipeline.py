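"""Pipeline orchestration: the screening funnel, association battery, and
qPCR quantification, each as one callable with file inputs and tabular
outputs plus a per-stage count report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import pyfaidx

from . import association as assoc
from . import motif_scan as ms
from . import peak_intersect as pi
from . import quantification as qt
from . import variant_qc as vq

__all__ = ["PipelineConfig", "FunnelReport", "run_screen", "run_assoc", "run_chip"]

log = logging.getLogger("regsnp_screen")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    fasta: str | Path | None = None
    vcf: str | Path | None = None
    bed: str | Path | None = None
    subjects: str | Path | None = None
    qpcr: str | Path | None = None
    consensus: str = ms.NFKB_CONSENSUS
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    window: int = 500_000
    both_strands: bool = True
    snp_overlap: bool = False
    input_fraction: float = 0.01
    covariates: tuple[str, ...] = ("sex", "age", "bmi", "htn", "dm")
    outdir: str | Path | None = None

    def require(self, *names: str) -> None:
        for n in names:
            p = getattr(self, n)
            if p is None:
                raise ValueError(f"pipeline input '{n}' is not configured")
            if not Path(p).exists():
                raise FileNotFoundError(f"pipeline input '{n}' missing: {p}")


@dataclass
class FunnelReport:
    """Per-stage input/output counts of the screening funnel.

    Counts are non-increasing from QC onward; ``peak_stage_skipped`` is set
    when no peak file was supplied.
    """

    n_input_variants: int = 0
    n_structural_removed: int = 0
    n_low_call_rate_removed: int = 0
    n_after_qc: int = 0
    n_after_maf: int = 0
    n_occurrences: int = 0
    n_near_occurrences: int = 0
    n_in_occurrences: int = 0
    n_site_affecting: int = 0
    n_peaks: int = 0
    n_candidates: int = 0
    peak_stage_skipped: bool = False
    stages: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d.pop("stages")
        return d


def _load_genome(path: str | Path) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def run_screen(config: PipelineConfig) -> tuple[FunnelReport, pd.DataFrame]:
    """Execute the screening funnel: QC → MAF → motif scan → peak confirmation.

    Returns the funnel report and a candidate table shaped like a published
    screening endpoint: chromosome:location (1-based), SNP id, call rate,
    MAF, flanking context with the motif call, effect class and supporting
    peak.  Deterministic given inputs.
    """
    config.require("fasta", "vcf")
    genome = _load_genome(config.fasta)
    variants = vq.read_vcf(config.vcf)

    report = FunnelReport(n_input_variants=len(variants))
    ledger = vq.FilterLedger()
    after_qc = vq.apply_qc(variants, config.call_rate_min, ledger)
    report.n_structural_removed = ledger.n_structural_removed
    report.n_low_call_rate_removed = ledger.n_low_call_rate_removed
    report.n_after_qc = len(after_qc)

    after_maf = vq.maf_filter(after_qc, config.maf_min)
    report.n_after_maf = len(after_maf)

    pattern = ms.compile_pattern(config.consensus)
    occurrences = ms.scan_genome(genome, pattern, both_strands=config.both_strands)
    report.n_occurrences = len(occurrences)

    near = ms.snps_near_occurrences(after_maf, occurrences, config.window)
    report.n_near_occurrences = len(near)
    contained = ms.snps_in_occurrences(after_maf, occurrences)
    report.n_in_occurrences = len(contained)

    calls = [
        ms.classify_allele_effect(v, genome, pattern, both_strands=config.both_strands)
        for v in contained
    ]
    site_calls = [c for c in calls if c.effect is not ms.AlleleEffect.NO_SITE]
    report.n_site_affecting = len(site_calls)

    if config.bed is None:
        report.peak_stage_skipped = True
        candidates = [
            pi.CandidateSnp(c.variant, c, (c.occurrences_ref_allele or c.occurrences_alt_allele)[0], [])
            for c in site_calls
        ]
    else:
        config.require("bed")
        peaks = pi.read_peaks(config.bed)
        report.n_peaks = len(peaks)
        candidates = pi.confirm_candidates(site_calls, peaks, snp_overlap=config.snp_overlap)
    report.n_candidates = len(candidates)

    rows = []
    for cand in candidates:
        v = cand.variant
        ctx = ms.context_string(v, genome)
        rows.append(
            {
                "location": f"{v.contig}:{v.pos1}",
                "snp": v.id,
                "call_rate": v.call_rate,
                "maf": v.maf,
                "context": ctx.context_string,
                "effect": cand.effect_call.effect.value,
                "occurrence": f"{cand.occurrence.start}-{cand.occurrence.end}({cand.occurrence.strand})",
                "peaks": ";".join(p.source for p in cand.peaks) or ".",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["location", "snp", "call_rate", "maf", "context", "effect", "occurrence", "peaks"],
    )
    for stage, n_in, n_out in (
        ("variant_qc", report.n_input_variants, report.n_after_qc),
        ("maf_filter", report.n_after_qc, report.n_after_maf),
        ("motif_containment", report.n_after_maf, report.n_in_occurrences),
        ("peak_confirmation", report.n_site_affecting, report.n_candidates),
    ):
        report.stages.append({"stage": stage, "in": n_in, "out": n_out})
        log.info("%s: %d -> %d", stage, n_in, n_out)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        (outdir / "funnel.json").write_text(json.dumps(report.as_dict(), indent=1))
    return report, table


def run_assoc(
    config: PipelineConfig,
    snp_cols: Sequence[str] = ("genotype",),
) -> pd.DataFrame:
    """Per-SNP association battery on a subject table.

    For each dosage column: genotype-level χ², HWE in controls, and crude +
    covariate-adjusted ORs for the allele/dominant/recessive dichotomies.
    """
    config.require("subjects")
    subjects = pd.read_csv(config.subjects, sep="\t", na_values=["NA"])
    rows = []
    for col in snp_cols:
        counts = assoc.genotype_counts_from_subjects(subjects, col)
        hwe_chi2, hwe_p = assoc.hwe_test(counts.control)
        geno_p = assoc.genotype_chisq(counts)
        tables = assoc.build_model_tables(counts)
        for model, t in tables.items():
            crude = assoc.odds_ratio(t, snp_id=col, model=model)
            adj = assoc.adjusted_logistic(
                subjects, col, model=model, covariates=config.covariates
            )
            rows.append(
                {
                    "snp": col,
                    "model": model.value,
                    "control_counts": "/".join(map(str, counts.control)),
                    "case_counts": "/".join(map(str, counts.case)),
                    "genotype_p": geno_p,
                    "hwe_p": hwe_p,
                    "crude_or": round(crude.or_estimate, 2),
                    "crude_ci_lo": round(crude.ci95[0], 2),
                    "crude_ci_hi": round(crude.ci95[1], 2),
                    "crude_p": round(crude.p_value, 3),
                    "adj_or": round(adj.or_estimate, 2),
                    "adj_ci_lo": round(adj.ci95[0], 2),
                    "adj_ci_hi": round(adj.ci95[1], 2),
                    "adj_p": round(adj.p_value, 3),
                }
            )
    table = pd.DataFrame(rows)
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "association.tsv", sep="\t", index=False)
    return table


def run_chip(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a ChIP-qPCR Ct table: per-sample percent input, per-genotype
    mean ± SEM, one-way ANOVA across genotypes, and the top-vs-bottom group
    enrichment (both ratio and difference of means)."""
    config.require("qpcr")
    measurements = qt.read_ct_table(config.qpcr)
    per_sample = qt.quantify(measurements)
    summaries = qt.group_summary(measurements)
    groups = {g: per_sample.loc[per_sample.genotype == g, "percent_input"].to_list()
              for g in summaries}
    f, p = qt.anova_oneway(groups)
    ordered = sorted(summaries.values(), key=lambda s: s.mean)
    ratio, diff = qt.enrichment_ratio(ordered[-1].mean, ordered[0].mean)
    summary = pd.DataFrame(
        [
            {
                "genotype": s.genotype,
                "n": s.n,
                "mean_percent_input": s.mean,
                "sem": s.sem,
                "anova_f": f,
                "anova_p": p,
                "enrichment_ratio_top_vs_bottom": ratio,
                "enrichment_diff_top_vs_bottom": diff,
            }
            for s in summaries.values()
        ]
    )
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_sample.to_csv(outdir / "percent_input.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "chip_summary.tsv", sep="\t", index=False)
    return per_sample, summary
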