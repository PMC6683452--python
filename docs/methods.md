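# Methods

## Scope and model

The package implements a regulatory-variant screen for the NF-κB (p50–p65)
binding consensus and the statistics of the downstream case-control and
ChIP-qPCR follow-up. The screen is a literal degenerate-motif match, not a
position-weight-matrix scan: the binding model is the single IUPAC consensus
5′-GGGRNNYYCC-3′, matched exactly (R = {A,G}, Y = {C,T}, N = {A,C,G,T}), on
both strands. Both-strand scanning is deliberate: the consensus is not its
own reverse complement (its reverse complement reads GGRRNNYCCC), so the two
strand searches are genuinely distinct. An ambiguous reference base N is
matched only by the pattern symbol N, never by a constrained symbol.

Coordinates are 0-based half-open everywhere internally; VCF positions are
converted once on read, BED is written natively, and 1-based positions
appear only in display output.

## Allele-effect classification

For an SNV at position p and pattern length L, the window
[p − (L − 1), p + L) clipped to the contig is scanned twice, once per
allele, and only occurrences *covering* p are compared:

* both alleles retain ≥ 1 covering occurrence → `SITE_PRESERVED`;
* only the reference allele does → `SITE_DESTROYED`;
* only the alternate does → `SITE_CREATED`;
* neither → `NO_SITE`.

Giving `SITE_PRESERVED` precedence whenever both alleles retain a covering
occurrence (rather than comparing occurrence *counts*) keeps the
classification antisymmetric under swapping ref and alt, which is tested as
a property. Screening candidacy accepts any of the three site-involving
labels, so gain-of-site alleles are not lost.

## Filter semantics

The QC stage removes all non-SNV records (insertions and deletions alike —
the genotyping platform the screen feeds cannot type them) and sites with
call rate strictly below 0.90; a call rate of exactly 0.90 is kept. The MAF
filter keeps sites with MAF strictly above 0.05; exactly 0.05 is dropped.
Both choices implement the stated inequalities ("less than 90%" removed,
"> 5%" kept) and are frozen in tests because the boundary cases are easy to
flip silently. Filters are order-independent and idempotent (property
tested). Peak confirmation requires ≥ 1 bp overlap between the *occurrence*
and a peak; a point-in-peak mode (`--snp-overlap`) exists because either
reading of "the variant's position is bound" is defensible.

## Association statistics

All χ² tests are Pearson without Yates continuity correction, and all CIs
are Wald on the log-odds scale with z = 1.96. These two conventions were
chosen because they reproduce the published two-decimal tables exactly from
the printed genotype counts (recessive OR 1.31, CI 1.07–1.60, p = 0.008;
genotype p = 0.031; and the genotype-level rows 1.22, 0.82, 0.49, 2.00 with
their CIs). Zero cells get no Haldane–Anscombe correction: a zero
case-exposed cell reports OR = 0 with CI (0, ∞) — matching the published
"0.00 (0.00 – inf)" convention — and a zero denominator cell reports ∞.
HWE is tested in controls only (standard practice; the whole-sample variant
is a one-line change on the counts). Statistics use non-missing genotypes
only, which is why per-SNP totals (e.g. 841 cases) can fall below the
cohort size (847).

Four published allele/genotype rows are *not* reproducible from their own
printed counts (the allele-model OR printed as 1.31 where the cross-product
of the printed allele counts gives 1.18 is the clearest case; three
heterozygote rows differ in the second decimal). These appear to be
transcription inconsistencies in the source tables; the package computes
the count-consistent values and the inconsistent rows are excluded from the
reproduction surface.

Adjusted odds ratios come from a maximum-likelihood logistic fit
(IRLS, relative log-likelihood tolerance 1e-10, 100 iterations max) with
Wald inference; perfect separation is flagged on the result rather than
raised. With no covariates the fit is saturated on the 2×2 and reproduces
the cross-product OR to 1e-6 relative, which is tested.

Power uses the noncentral-χ² approximation: under the alternative (control
exposure frequency from the genotype model, case frequency from applying
the target OR on the odds scale), the noncentrality is N times the χ²
discrepancy between the alternative's joint cell probabilities and the
independence table with the same margins. A 2000-replicate simulation
cross-checks it in the tests.

## Percent-input quantification

percent_input = 100 × 2^((Ct_input − log₂(1/f)) − Ct_IP), with input
fraction f defaulting to 0.01 (1% input) and configurable. The published
per-genotype summaries (1.71–3.20 with SEMs ≤ 0.2) are treated as
percent-input values; the "1.49-fold TT vs GG" enrichment statement matches
the *difference* of those means (3.20 − 1.71 = 1.49) and not their ratio
(1.87), so the tool reports both and asserts neither as canonical. The
ANOVA is classical one-way fixed-effects; its published single-plate
p = 0.027 depends on raw Ct values that are not published, so it is checked
only as a property (plates generated at the published parameters reject at
5% in the large majority of replicates).

## Synthetic-study generator

The generator's defaults are the study conditions the pipeline emulates:

* **Genome** — 100 kb over 2 contigs of iid-uniform bases with 20 planted,
  non-overlapping consensus instances (random strand, random concrete
  bases at degenerate positions). Chance matches are left in; their density
  is (1/4)³·(1/2)·1·1·(1/2)²·(1/4)² = 1/8192 per offset per strand, and a
  Monte-Carlo test on 10⁶ bases checks the scanner against that constant.
  100 kb keeps every test and the acceptance run fast while holding ~24
  chance occurrences, enough to exercise the decoy paths.
* **Variants** — 200 records; 19.4% indels (the structural fraction of the
  emulated call set); call rates Beta(30, 2) truncated to [0.5, 1] (median
  ≈ 0.95, a realistic left tail below the 0.90 cutoff; only the cutoff
  itself is prescribed, the law is ours), optionally a point mass for
  boundary tests; MAFs uniform on [0.01, 0.5]. One SNV per planted motif
  (half site-destroying, half site-preserving, certified by a brute-force
  rescan that is independent of the scanner under test); background SNVs
  are resampled until neither allele touches any site, so the funnel
  endpoint is exactly the planted, peak-covered motif SNPs — zero false
  positives and negatives by construction.
* **Peaks** — cover 75% of planted motifs (15 of 20) with 20–200 bp random
  padding, clipped to keep a consensus-length margin from every other
  planted motif; 10 decoy peaks keep a 3-consensus margin from all planted
  sites. The 15/20 split makes the funnel endpoint 15, the size of the
  candidate list the screen is meant to produce, with the 5 uncovered
  motif-SNPs acting as peak-stage decoys.
* **Cohort** — 846 controls / 847 cases; control genotypes at the index SNP
  drawn from (18.1%, 49.5%, 32.4%); case genotypes from the retrospective
  reweighting q ∝ (p₀, p₁, OR·p₂) with OR = 1.31, which makes the induced
  recessive odds ratio exactly the planted value (no generative disease
  model is implied by a case-control design, so reweighting is the natural
  construction). Genotypes go missing at rate 1 − call rate (0.999).
  Covariates (sex, age, BMI, hypertension, diabetes, eGFR) are drawn per
  group from the published demographic means/rates, with eGFR truncated to
  the group definitions (≤ 15 cases, ≥ 60 controls). Covariates are drawn
  independently within group, so they are *not* confounders of the planted
  genotype effect; adjustment machinery is exercised on a separate
  deliberately confounded simulation in the tests.
* **qPCR** — per-sample percent input ~ Normal(mean, SEM·√n) per genotype
  group (redrawn if ≤ 0), then inverted exactly through the percent-input
  formula into (Ct_IP, Ct_input) pairs at fixed Ct_input = 30 and f = 0.01,
  so quantification tests have analytically known truth.

Everything is driven by one seed through spawned substreams; identical
configurations give byte-identical FASTA/VCF/BED/TSV/JSON outputs (tested).

What the generator does **not** emulate: linkage disequilibrium and
population structure, chromosome-scale genomes, read-level sequencing
error, batch effects in genotyping, PWM-strength binding variation, and
qPCR efficiency ≠ 2. Passing tests therefore demonstrate correctness of the
computations and calibration of the statistics under the assumed sampling
models, not robustness to those real-data complications.

## Problem sizes

Test and acceptance runs use the sizes above (100 kb genome, 200 variants,
~1700 subjects, 500-replicate recovery, 2000-replicate power, 200-plate
qPCR averaging); they were chosen as the smallest sizes at which the
Monte-Carlo tolerances in use (3–4 standard errors) are informative. The
genome-scale counts of the original funnel (tens of millions of variants)
depend on a non-redistributable call set and are out of reach by design;
only the funnel's *shape* and its fixture-scale exactness are claimed.

## Known limitations

* Exact consensus matching cannot rank partial or flanking-dependent
  binding changes; `SITE_PRESERVED` may still alter affinity.
* The ±500 kb proximity step is implemented and reported but feeds nothing
  downstream (containment does); it exists for funnel parity.
* The published per-genotype odds-ratio column of the qPCR table (n = 3 per
  group) has no stated model and is not reproduced.
* Multi-allelic sites are kept as single records with MAF of the least
  frequent allele; only the first alternate allele is classified.
* No multiple-testing correction by default, mirroring the emulated study's
  explicit choice; a Bonferroni flag would be a trivial addition but is not
  claimed by the reproduction surface.
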