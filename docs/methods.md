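# Methods

`tillmap` re-implements, at desk scale, the computational core of a haploid-
mutagenesis trait-mapping workflow for allotetraploid *Brassica napus*: EMS
variant quality control and spectrum analysis, phenotype-ranked pseudo-bulk
(MutMap-style) ΔSNP-index mapping, gene-coverage-ratio detection and
zygosity typing of homoeologous non-reciprocal translocations (HNRTs), and
multi-environment trait statistics. A synthetic-cohort generator supplies
every input with the statistical structure the analyses assume, so the whole
pipeline is testable without sequencing data.

## The synthetic cohort

### Toy genome

Four chromosomes (A1, A2, C1, C2; 500 kb each; A1/C1 and A2/C2 declared
homoeologous) carry 220 non-overlapping genes per chromosome. Each gene has
1–3 CDS exons (60–200 codons total, ATG start, single stop, introns
60–240 bp, either strand); coordinates are 1-based inclusive, GFF3-native.
The genome is a downscaled stand-in: gene count and chromosome number are
two orders of magnitude below a real *B. napus* assembly, but every
structural property the downstream methods rely on (gene packing, exon
structure, homoeologous pairing) is present. All generation flows from one
seeded `numpy` generator; a fixed seed reproduces every output file
byte-identically.

### EMS variants

Per-line SNP loads are Poisson around a dose-specific mean density. The four
EMS dose groups (0.1–0.4%) receive lines in the source population's
proportions (669:231:324:34), and per-dose mean densities scale linearly
with dose, normalised so the line-weighted mean equals the configured
155 SNPs/Mb. The published per-dose loads are ranges only, so the linear
dose–response is a modelling choice, configurable via
`SimConfig.ems_dose_labels`. Indels (1–3 bp) are drawn at the published
indel:SNP rate ratio (60:155).

Substitutions are drawn from the six strand-pooled classes at the published
pooled frequencies (44.48, 22.02, 12.07, 8.67, 7.63, 5.14%; renormalised
to sum to one) and respect the reference base: a C/G→T/A event placed on a C
emits C→T, on a G emits G→A. Read depths are negative binomial (mean 30),
and QUAL scores are normal (mean 60, sd 18) so that about 5% of true
variants fall below the SNP quality threshold — the filters must have
something to do. A configurable number of *shared artifacts* (identical
variants injected into ≥ 5 random lines) exercises the shared-variant
filter; the generator's ledger distinguishes `true` from `artifact` records
so tests can verify zero false removals of line-private variants.

### F2 genotypes and phenotypes

Each of the 184 F2 individuals draws a deletion state (`d_copies`) and a
duplication state (`p_copies`) independently, each Binomial(2, ½), i.e.
1:2:1. The two A1 deletion segments D1 and D2 (60 genes each, separated by
a 50-gene retained segment) share the single deletion indicator, so they
co-segregate exactly; the C1 duplication P1 (60 genes) segregates
independently. The retained segment must exceed the detection method's
resolution (window unions overhang the true boundary by up to w−6 genes, so
events closer than ~2(w−6) genes merge); 50 genes leaves a margin at the
default window of 20.

Phenotypes follow
`y = baseline + g + location + (g×location) + residual` with
`g = locus effect + polygenic`, over 2 locations × 2 reps. The locus effect
is additive in deletion copies (`del_effect_hom` is the homozygote shift,
optional dominance), plus an interaction term
`dup_modulation · (d/2) · (p/2)` so the duplication modulates deletion
carriers only. Given a target entry-mean heritability `H²`, the generator
computes the locus variance analytically over the 1:2:1 ⊗ 1:2:1 joint
distribution, adds the polygenic variance, and solves
`N = V_G (1/H² − 1)` for the non-genetic entry-mean variance, splitting it
30:70 between G×L and residual. Expected entry-mean H² therefore equals the
target exactly, which is what makes the heritability recovery loop a clean
calibration check.

Default trait models: meal ADF carries the causal signal
(baseline 18.1, homozygous-deletion effect −1.8 — the published parent
difference — interaction −0.4, H² 0.85); meal protein a weaker effect
(+0.9, H² 0.35); seed oil and seed protein are polygenic-only (H² 0.16 and
0.31). The causal-trait H² of 0.85 deserves a note: the field-trial
estimate for meal ADF is 0.55, but under a Gaussian single-major-locus
model an entry-mean H² of 0.55 leaves enough non-genetic spread that the
extreme 25-line bulks are genotypically contaminated and the ΔSNP-index
cannot exceed 0.9 anywhere. The observed SNP-index clusters above 0.9 in
the real experiment imply nearly pure bulks, i.e. a higher effective
signal-to-noise at the causal locus than the genome-wide H² summary
suggests (real ADF distributions are bimodal at a major locus; a Gaussian
polygenic model is not). The generator's default encodes that purity; the
heritability recovery tests simulate at 0.10/0.44/0.55 explicitly.

### Coverage and bulk pileups

Per-gene read counts are negative binomial with mean
`depth × length / read_length` (8× depth, 150 bp reads) scaled by the
copy-ratio multiplier 0, 0.5, 1, 1.5 or 2, with dispersion (size) 10 —
deliberately overdispersed relative to Poisson shot noise. The two parents
are included as samples (`WT_PARENT` copy-normal everywhere; `MUT_PARENT`
homozygous for every segment, as a doubled-haploid parent is), matching the
study design in which both parents were sequenced.

Bulk pileups place 150 loci per chromosome uniformly. Loci inside the
causal interval (the D1-start to D2-end span on A1) have alt dosage equal
to `d_copies` — perfect linkage; all other loci draw an independent 1:2:1
genotype per individual (no linkage map is simulated; that is a stated
non-goal). Reads per individual and locus are Binomial(Poisson(8),
dosage/2). A `sampling_noise=False` switch yields exact expected counts for
limit tests.

## Variant QC

SNPs are kept iff QUAL ≥ 30 and 5 ≤ DP ≤ 250; indels iff QUAL ≥ 50 and
10 ≤ DP ≤ 250 (the 250× cap applies to all variants before the stricter
indel pass). Variants present in ≥ 5 distinct lines — identity is
(chrom, pos, ref, alt), since independent EMS recurrence of the *same*
substitution is implausible — are removed entirely. Quality/depth filtering
runs before shared-line counting; the result is order-dependent near the
5-line boundary, and this order is fixed.

The substitution classifier pools each point substitution with its
complement into the six classes. Genic context uses the precedence
exon > intron > upstream 2 kb > downstream 2 kb > intergenic, flanks
strand-aware. The coding-effect classifier translates the affected codon
before and after the substitution (standard genetic code, via Biopython):
start_lost / stop_gained / stop_lost / missense / synonymous, with impacts
high/high/high/moderate/low; intronic SNPs within 8 bp of an exon boundary
are splice_region (low), a SnpEff-like convention since no published
definition exists. CDS indels are frameshift (length change not divisible
by 3 → high) or inframe_indel (moderate). Tests verify the codon-local path
against an independent full-CDS re-translation oracle on 1000 random
exonic variants.

## MutMap pseudo-bulk mapping

Entry means (per-line means over locations and reps) rank the cohort; the
25 most extreme lines in the mutant direction (low for meal ADF, high for
the protein traits) form the mutant bulk and the opposite 25 the reference
bulk, ties broken by line id for determinism. Bulks are formed by summing
simulated per-individual allele counts — the count-level equivalent of
pooling reads before alignment. Per locus, SNP index = alt/total within a
bulk; loci with bulk depth < 10 are excluded (the same depth-10 floor the
study applied to bulk SNPs). Δ = mutant index − reference index, smoothed
by a right-aligned 5-locus rolling mean per chromosome (right alignment is
a choice — the published figure does not state alignment — made so a run
boundary never reflects loci downstream of it). Candidate regions are
maximal runs of ≥ 3 consecutive loci with smoothed Δ > 0.9; the 3-locus
floor guards single-locus noise (no published run-length rule exists). The
threshold is applied to the smoothed ΔSNP-index; a flag can instead
threshold a single bulk's raw index, since the study's text describes the
single-bulk variant while its figure thresholds Δ.

## LSV detection and typing

The chain is: per-sample TPM normalisation of the genes × samples count
matrix → per-gene copy ratio → window-20/step-5 smoothing over gene rank →
per-sample segment calling → cohort-level consensus loci → calibrated
zygosity states.

**Ratios.** The default denominator is the per-gene median across samples
(the reference-free mode); `reference_sample` switches it to one sample's
TPM. Genes with zero denominator are masked, not pseudocounted — ratios
should not be manufactured from absent data (column TPM sums are not
re-normalised after masking). Because TPM is compositional, a sample
carrying a sizeable deletion redistributes the missing mass over all other
genes and its entire ratio track shifts off 1; each sample's track is
therefore recentred on its own genome-wide median ratio (valid while most
genes are copy-normal).

**Segments.** Windows of 20 genes at step 5 (gene rank, not physical
distance — the smoothing operates on a gene-count matrix); a chromosome
yields `floor((n−w)/s)+1` windows. Maximal runs of ≥ 3 windows below 0.75
(deletion) or above 1.25 (duplication) become segments; bounds are the
member-window union. Zygosity per segment comes from the **median** of the
member genes' raw ratios: the union overhangs the true copy-number boundary
by up to a window per side, so the mean is biased toward 1 there (a
homozygous deletion's union mean lands in the hemizygous band), while the
median is robust; runs whose member median falls in the normal band
(0.75–1.25) are discarded as smoothing artifacts. Thresholds and zygosity
bands (midpoints of the expected copy ratios 0, 0.5, 1, 1.5, 2) are
equidistant decision boundaries, all overridable.

**Recurrent loci.** Per gene, the number of distinct carrier samples whose
segments cover it is counted; maximal gene runs with support ≥ 5% of the
cohort become loci, with reported bounds trimmed to ≥ half the run's peak
support. Consensus support — rather than merging segment intervals — keeps
sporadic per-sample noise runs from chaining into pseudo-loci or widening
real ones. Each locus also carries a *core*: its bounds shaved by w−s
genes per side (capped at a third of the span), clear of the systematic
window overhang.

**Calibrated states.** Each sample's locus level is the mean ratio over
core genes. At a locus where the variant is frequent enough that the
cohort median is itself a carrier class — exactly the situation in a 1:2:1
F2, where the per-gene median is the hemizygous class — reference-free
levels are relabelled (wild type ≈ 2, hemizygous ≈ 1, homozygous-deleted
= 0 at a deletion) and absolute zygosity typing needs an anchor.
`calibrate_sample` names a known copy-normal sample (the wild-type parent);
its level seeds a grid fit of the copy scale against the whole cohort
(minimising distance of every level to the nearest multiple of
{0, 0.5, 1, 1.5, 2}, grid ±40% around the seed, then one least-squares
pass under the implied assignment). The refit matters: a single 8× sample's
locus level carries ~6% sampling error, which scales to ±12% at copy
level 2 and crosses a zygosity band. Calibrated copy ratios are banded at
0.25/0.75/1.25/1.75 into homozygous/hemizygous deletion, wild type, and
hemizygous/homozygous duplication; locus kinds are re-derived as the
majority variant type among non-wild-type calls. Without a calibration
sample the cohort median is assumed copy-normal — correct for variants
carried by fewer than half the cohort, and documented as miscalibrated
otherwise.

**Co-segregation and association.** Pairwise locus concordance is the
fraction of samples with identical state, plus a chi-square independence
test on the state contingency table. Genotype–phenotype association groups
entry means by state; the statistic is the mean difference between the
most-severe present class and wild type, with a two-sided permutation
p-value (10,000 label permutations, add-one estimator, so the smallest
attainable p is 1/10,001).

## Trait statistics

Entry means are plain per-line means over locations and reps — the upstream
BLUEs came from a spatial mixed model (AR1×AR1 residuals, row/column
effects) that is out of scope here, so BLUE parity is explicitly not
claimed; only arithmetic derivatives of the printed tables (mid-parent
values, range spans) are reproduced exactly. Mid-parent is the parent
average; reported values are rounded half-away-from-zero to one decimal,
matching table precision. CV% = 100 × SD/mean of entry means.

Variance components come from the balanced two-way method-of-moments:
`V_E = MS_E`, `V_GL = (MS_GL − MS_E)/R`, `V_G = (MS_G − MS_GL)/(LR)`,
negatives truncated at zero with a warning. Near-balanced tables are
balanced by cell-mean imputation (missing cells fall back to line means)
so the closed form applies; a single location or single rep is an error,
not a guess. Entry-mean broad-sense heritability is
`H² = V_G / (V_G + V_GL/L + V_E/(LR))` — the standard multi-environment
form, adopted because no formula is printed in the source tables — and
`SED = sqrt(2 V_E/(LR))`. The entry-mean basis (line means across
locations) is this package's documented choice, not an assertion about how
the published Table values were computed.

## Numerical and degenerate-input conventions

- All randomness flows from explicit `numpy.random.Generator` objects;
  library functions never draw from global state.
- Spectrum frequencies sum to 1 within 1e-9; TPM columns to 1e6 within
  1e-6 relative.
- Zero-depth loci are flagged missing and excluded from index tracks, not
  imputed. Empty variant sets produce all-zero summaries, not errors.
- Bulk ties, window boundaries and region bounds are deterministic
  (stable sorts, fixed alignment).
- Chromosomes with fewer loci than the smoothing window, or fewer genes
  than the coverage window, are skipped with a warning.

## Problem sizes

Defaults are chosen so a full cohort simulates in ~3 s and the complete
test suite runs in about a minute: 60 DH lines on a 2 Mb genome (the
published population is 1240 lines on ~1 Gb; per-line densities and
spectra are scale-free, absolute genome-wide counts are not reproduced),
184 F2 individuals (the published mapping population size), 600 bulk loci,
880 genes. Recovery loops use 20 seeds (MutMap), 100 seeds per
heritability target, and 200 seeds for permutation-null calibration.

## Known limitations

- The generator has no linkage map: loci are either perfectly linked to
  the causal deletion or fully independent. ΔSNP-index decay with genetic
  distance, and hence region-boundary sharpness, is not modelled.
- Gaussian polygenic and residual terms cannot reproduce the bimodal trait
  distributions a real major locus produces; see the H² discussion above
  for what that means for bulk purity.
- Reference-free zygosity typing is miscalibrated whenever a variant's
  carrier class occupies the cohort median; the calibration-sample path is
  the supported answer, and matches the study design (parents sequenced
  alongside the cohort).
- Coverage bias (GC, mappability) is a single dispersion knob, not a
  structured model; segment-boundary precision is reported at gene, not
  base-pair, resolution.
- Passing tests demonstrate internal consistency and recovery under the
  generator's assumptions — clean 1:2:1 segregation, unstructured noise,
  no population substructure — not performance on real sequencing data.
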