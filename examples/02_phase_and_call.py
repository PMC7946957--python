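"""Classify variants, phase candidate compound heterozygotes, and call
per-sample diplotype categories with the exclusion-cascade audit.

Phasing combines pedigree segregation (decisive when each parental
carrier pattern is unambiguous) with two-locus haplotype frequencies
estimated by EM (decisive only for pairs in strong linkage
disequilibrium, e.g. known cis haplotypes).
"""

from collections import Counter

import recburden as rb

cohort = rb.simulate_cohort(
    rb.SimCohortConfig(n_trios=300, n_quartets=15, n_singletons=300, seed=1)
)

mask = rb.build_class_mask(cohort.matrix, pedigree=cohort.pedigree)
print("Variant classification (pLoF / predicted-deleterious missense, MAF tiers):")
print(mask.frame[["label", "consequence", "is_plof", "is_pdns", "maf", "tier"]].to_string(index=False))

qualifying = rb.select_burden_variants(mask, cohort.matrix, class_set="plof_plus_pdns")
calls, cascade, _ = rb.call_diplotypes(
    "NOD2", qualifying, cohort.matrix, pedigree=cohort.pedigree
)

print("\nDiplotype categories:", dict(Counter(c.category for c in calls.values())))
print("Exclusion cascade:", cascade.counts())
print(
    "\nretained + qc_removed + blacklist_excluded + cis_excluded equals the\n"
    "initial putative-recessive candidates: the audit is a partition, so no\n"
    "candidate is dropped silently or counted twice."
)
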