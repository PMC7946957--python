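# Methods

## The inference problem

A gene's contribution to disease under a recessive model is carried by
samples with **two** dysfunctional copies: homozygotes, and compound
heterozygotes whose two variants lie on opposite parental haplotypes
(*trans*). Short-read genotypes do not carry phase, so a double
heterozygote is only a *candidate* biallelic sample. The pipeline's job
is (1) to decide which variants qualify as deleterious, (2) to resolve
cis/trans for candidate pairs where the data allow, (3) to audit every
exclusion, and (4) to estimate risk under the standard genetic-model
codings.

## Variant qualification

* **pLoF**: consequence ∈ {stop_gain, start_loss, stop_loss,
  splice_donor, splice_acceptor, frameshift}. A pure function of the
  annotated consequence; annotations are consumed, never computed.
* **pdNS**: missense with deleterious votes from all five predictors
  (SIFT, LRT, MutationTaster, PolyPhen2 HumDiv, PolyPhen2 HumVar).
  The conjunction is configurable (`k_of_five`); a missing vote counts
  as benign — conservative, since it can only shrink the qualifying set.
* **Frequency**: "rare" is MAF < 2% (strict), "low-frequency" MAF ≤ 5%
  (inclusive); the burden ceiling defaults to ≤ 5% and both the ceiling
  and the comparison are configurable. The effective MAF is the
  variant's external reference frequency when annotated, else the
  cohort frequency computed over founders only when a pedigree is
  present (so transmitted alleles are not double-counted).

## Phasing

**Pedigree rule.** For a child heterozygous at two variants A and B:
if exactly one parent carries A and exactly one carries B and they are
different parents, the pair is TRANS; if one parent carries both and
the other neither, CIS. Missing parents or genotypes, both parents
carrying both variants, or a Mendelian inconsistency (child allele with
no carrier parent; logged) leave the pair UNRESOLVED. Verdicts are
symmetric in (A, B).

**Population rule.** Two-locus haplotype frequencies
(p_AB, p_Ab, p_aB, p_ab) are estimated by EM over nominally unrelated
samples (founders and singletons). Only the double-het genotype is
ambiguous; the E step splits it between cis (AB/ab) and trans (Ab/aB)
in proportion to 2·p_AB·p_ab vs 2·p_Ab·p_aB. The observed-data
log-likelihood is asserted non-decreasing at every step; convergence at
max|Δp| < 1e-10 (cap 1000 iterations). A double-het's posterior
probability of trans is p_Ab·p_aB / (p_Ab·p_aB + p_AB·p_ab); the
verdict requires clearing a symmetric threshold (default 0.95 — a
declared choice, since no numeric criterion is standard).

An important structural fact: under linkage equilibrium the posterior
is exactly ½ for any allele frequencies, so an isolated variant pair
can only be population-phased when the two loci are in strong LD (the
repulsion limit p_AB → 0 gives posterior → 1, the known-cis limit gives
posterior → 0). This is why long-range statistical phasers use many
flanking markers, and why double-hets in singletons generally remain
**putative** here. Putative compound hets are therefore a mixture —
roughly half cis under equilibrium — and any estimate that counts them
as biallelic is attenuated toward the null. The package exposes
`include_putative` (default true, matching how putative carriers are
usually reported) and the test suite demonstrates the attenuation.

**Priority and blacklist.** Pedigree evidence overrides population
evidence. Pairs on the cis blacklist (defaults: {L1007fs, M863V},
{S431L, V793M} — pairs known to travel on one haplotype) are removed
from compound-het candidacy before phasing; the sample remains a
CARRIER of that haplotype. With ≥ 3 qualifying hets the decisive pair
is chosen by evidence strength, then ascending position.

**Genotype QC.** Homozygous-alternate calls with depth < 10 or alt
allele balance < 0.85 are the signature of heterozygotes miscalled
homozygous; the default policy sets them missing (demotion to het is
available). Thresholds are declared defaults, not derived constants.

**Cascade.** Candidates (any dosage-2 qualifying call, or ≥ 2
qualifying hets) are partitioned into {qc_removed, blacklist_excluded,
cis_excluded, retained}; the partition identity is asserted on every
run, making the exclusion narrative machine-checkable.

## Association statistics

Per-variant and pooled exposures are summarized as case/control ×
{ref, het, biallelic} counts. Point estimate: unconditional
cross-product OR. CI: Woolf log-normal, SE = √(Σ 1/cell). p-values:
two-sided Fisher exact (scipy's exact enumeration), with the
uncorrected Pearson chi-square reported alongside as `p_chi2` —
published grids of this kind often print the chi-square value under a
"Fisher" heading, and carrying both makes either convention checkable.
A zero cell marks the estimate undefined; a Haldane–Anscombe (+0.5) OR
is reported alongside, never silently substituted.

The gene burden fit maximizes the Jeffreys-penalized log-likelihood
ℓ(β) + ½·log det I(β) (intercept + one covariate) by Newton iteration
on the hat-adjusted score with strict-ascent step-halving; convergence
when max|U*| < 1e-8 or the accepted step < 1e-10, or when no halved
step improves the penalized likelihood (a float64 plateau — the
maximizer to machine precision), capped at 50 iterations. Wald CI and
p from the penalized information. Identical covariate rows are
aggregated first, so cohort-scale fits cost the same as their 2×3
table. Useful exact property: on a saturated 2×2 design the penalty
separates per exposure group into p̂ = (y+½)/(n+1), i.e. the Firth fit
equals the +0.5-cell estimator — the independent oracle used in tests.
(A corollary: Firth does **not** always shrink the OR toward 1; with a
small exposed-case cell it can exceed the crude OR.)

Onset ages are compared by the pooled-variance two-sample t test
(Welch optional).

## Known discrepancies with the published grid

Three published numbers cannot be recovered from the published counts,
and the package deliberately reproduces the *counts'* implications:

1. The composite additive OR prints 1.64, but allele-counting the
   printed composite counts gives ≈ 1.75; the pooled-exposure additive
   construction behind 1.64 is not recoverable. Implemented as standard
   allele counting; the discrepancy is asserted in the test suite.
2. The burden recessive ORs print 20.74 (pLoF) and 13.15 (pLoF+pdNS),
   but any covariate-free logistic fit of the printed breakdowns gives
   21.3–22.0 and 13.8–14.1 (crude, conditional-ML, and Firth bracket
   the range; the Firth values are 22.00 and 14.06 by the closed form
   above). The printed CIs are geometrically centred on the printed
   ORs with exactly the crude Woolf SE, consistent with fits that
   included covariates (e.g. ancestry components) not represented in
   the printed counts. The corresponding assertions are left failing
   by design rather than loosened.
3. The per-variant genotypic het/hom p-values sit between chi-square
   variants and match no standard 2×2 test exactly; they are not
   asserted.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes:
a single-gene panel with the three common risk alleles at their
clinical-cohort frequencies (0.050 / 0.017 / 0.029) plus rarer
deleterious alleles and one non-deleterious decoy; founder haplotypes
drawn per variant at panel frequency (founders in Hardy–Weinberg
proportions), with cis groups nested by frequency so the rarer member
always rides with the commoner (cis_linkage = 1 by default — no
simulated individual is true-trans for a blacklisted pair);
trio/quartet/singleton families with uniform gamete transmission and
no recombination within the gene; disease odds κ0/(1−κ0) × ψ_het
(carriers, including cis double-carriers) or ψ_rec (biallelic), so the
simulated ψ_rec equals the recessive OR asymptotically *for the
truth-coded exposure*; onset ages normal with the biallelic mean
younger by 8.1 years (defaults 43.4 vs 51.5, sd 12); ≥ 2 IBD encounter
codes on distinct days per affected sample, an anemia code preceding
the first IBD code by ≈ 2.26 years in a configurable fraction,
occasional UC codes to exercise conflict flagging, and Poisson
background codes for everyone. Defaults: κ0 = 0.02 (the adult IBD
prevalence scale), ψ_het = 1.5, ψ_rec = 8, het→hom miscall rate 0.02,
chosen once as realistic study conditions; all draws flow from a
single integer seed and identical seeds give byte-identical outputs.

What the generator does **not** model: recombination within the gene,
population structure/relatedness beyond declared families, genotyping
error beyond the two QC channels, EHR truncation (records predating
system adoption), and code-assignment noise. Passing tests therefore
validate the pipeline's logic and statistics under idealized sampling,
not robustness to those real-data artifacts.

## Problem sizes used in tests

The suite exercises 500-trio phasing oracles, 20-sample EM grid
fixtures, and 20 seeded replicates of the ψ_rec = 10 recovery at
n = 60,000 singletons (truth-coded exposure, Woolf CI coverage ≥ 18/20)
plus 20 null replicates; these sizes make the whole suite run in well
under a minute while keeping Monte-Carlo tolerances meaningful (each
stochastic assertion states its own 3-SE band).
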