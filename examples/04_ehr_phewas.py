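"""EHR case definitions, onset ages, anemia lead time, and a phenome-wide
scan of the biallelic-carrier indicator.

A sample is an IBD case when its record holds a problem-list entry or
encounter diagnoses on two separate calendar days for ICD-9 555*/556*
or ICD-10 K50*/K51*.
"""

import recburden as rb

cohort = rb.simulate_cohort(
    rb.SimCohortConfig(
        n_trios=0, n_quartets=0, n_singletons=6000, seed=2,
        penetrance=rb.PenetranceModel(baseline_risk=0.02, psi_het=1.0, psi_rec=25.0),
    )
)

cases = rb.define_cases(cohort.phenotypes)
print(f"IBD cases under the two-encounter rule: {sum(cases.values())} / {len(cases)}")

ages = []
pediatric = 0
for s in cohort.phenotypes.samples:
    rec = cohort.phenotypes[s]
    age, flags = rb.first_diagnosis_age(rec.events, rec.birth_date)
    if age is not None:
        ages.append(age)
        pediatric += flags["pediatric"]
print(f"first-diagnosis ages: n={len(ages)}, mean={sum(ages)/len(ages):.1f} y, pediatric (<18 y): {pediatric}")

conflicts = rb.flag_conflicting_diagnoses(cohort.phenotypes)
print(f"samples with both CD-family and UC-family codes (manual review): {len(conflicts)}")

lead = rb.diagnosis_lead_time(cohort.phenotypes)
print(
    f"anemia lead time: {len(lead.per_sample)} samples with both codes, "
    f"{100 * lead.proportion_prior:.0f}% anemia-first, "
    f"mean lead {lead.mean_positive_lead:.2f} y"
)

exposure = dict(
    zip(cohort.truth["sample"], cohort.truth.true_category.isin(("HOM", "CHET_TRANS")))
)
phewas = rb.run_phewas(exposure, cohort.phenotypes)
print("\nPheWAS (top 3 grouped codes):")
print(phewas.head(3)[["code", "odds_ratio", "p_value", "p_adjusted", "significant"]].to_string(index=False))
print(
    "\nThe disease code attached to the simulated recessive genotype (K50)\n"
    "tops the scan and survives Bonferroni; background codes do not."
)
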