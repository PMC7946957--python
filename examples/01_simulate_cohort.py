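"""Generate a synthetic single-gene cohort and inspect its structure.

Builds trios, quartets and singletons with founder genotypes in
Hardy-Weinberg proportions, Mendelian transmission, genotype-dependent
disease penetrance, and longitudinal diagnosis-code streams.
"""

import recburden as rb

config = rb.SimCohortConfig(n_trios=300, n_quartets=15, n_singletons=300, seed=1)
cohort = rb.simulate_cohort(config)

print(f"samples: {cohort.matrix.n_samples}, panel variants: {cohort.matrix.n_variants}")
print("\nTrue diplotype categories (from the generative haplotypes):")
print(cohort.truth.true_category.value_counts().to_string())

n_cases = sum(1 for s in cohort.phenotypes.samples if cohort.phenotypes[s].affection == "CD")
print(f"\naffected (CD) samples: {n_cases}")
print(
    "\nHOM = homozygous for a deleterious allele, CHET_TRANS = two alleles on\n"
    "opposite haplotypes (true biallelic loss), CHET_CIS = two alleles on one\n"
    "haplotype (a single functional copy remains - not recessive)."
)
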