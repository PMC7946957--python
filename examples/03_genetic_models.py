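"""Genetic-model odds ratios and the Firth burden regression on the
published genotype counts for the three low-frequency CD risk alleles.

The per-variant grid uses cross-product odds ratios with Woolf 95%
confidence intervals; the gene burden uses Firth-penalized logistic
regression on 0/1/2 diplotype codes (recessive coding: biallelic class
exposed).
"""

import recburden as rb

r702w = rb.GenotypeCounts(cases=(857, 116, 11), controls=(45433, 4727, 145), label="p.R702W")

add = rb.or_additive(r702w)
het, hom = rb.or_genotypic(r702w)
rec = rb.or_recessive(r702w)
print("p.R702W (cases N=984, controls N=50,305):")
for name, r in (("additive", add), ("genotypic het", het), ("genotypic hom", hom), ("recessive", rec)):
    print(f"  {name:14s} OR = {r.odds_ratio:5.2f}  [{r.ci_low:.2f}-{r.ci_high:.2f}]  chi2 p = {r.p_chi2:.3g}")
print(
    "  -> heterozygous carriers have a modest risk (OR ~1.3) while biallelic\n"
    "     carriers are at ~4x odds: the signature of recessive inheritance.\n"
)

plof = rb.GenotypeCounts(cases=(529, 73, 11), controls=(51501, 3254, 47), label="plof_only")
for model in ("additive", "recessive"):
    res = rb.firth_from_counts(plof, model=model)
    print(
        f"pLoF burden, {model:9s} Firth OR = {res.odds_ratio:5.2f} "
        f"[{res.ci_low:.2f}-{res.ci_high:.2f}]  p = {res.p_value:.3g}"
    )
print(
    "  -> aggregating predicted loss-of-function alleles, the recessive-coded\n"
    "     burden odds ratio is an order of magnitude above the additive one."
)
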