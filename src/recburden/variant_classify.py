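"""Functional tiers and frequency filters for the single-gene variant panel.

Two variant classes drive the burden analysis:

* **pLoF** — predicted loss of function: premature stop, start/stop loss,
  canonical splice donor/acceptor disruption, or frameshift.
* **pdNS** — missense predicted deleterious by all five predictors
  (SIFT, LRT, MutationTaster, PolyPhen2 HumDiv, PolyPhen2 HumVar);
  a missing vote counts as benign, and the conjunction is configurable
  down to k-of-five.

Frequency filters follow the analysis convention: "rare" means MAF
strictly below 2%, "low-frequency" means MAF at or below 5%.  MAF is
computed on the analysis cohort itself (founders only when a pedigree is
supplied, so transmitted alleles are not double-counted); an external
reference frequency on the variant, when present, takes precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, Pedigree, Variant

PLOF_CONSEQUENCES = frozenset(
    {"stop_gain", "start_loss", "stop_loss", "splice_donor", "splice_acceptor", "frameshift"}
)

#: the three low-frequency risk alleles treated as "common" in this gene
DEFAULT_COMMON_RISK = ("p.R702W", "p.G908R", "p.L1007fs")

RARE_CEILING = 0.02  # strict: MAF < 2%
LOWFREQ_CEILING = 0.05  # inclusive: MAF <= 5%


def classify_plof(variant: Variant) -> bool:
    """Predicted loss of function, a pure function of the consequence class."""
    return variant.consequence in PLOF_CONSEQUENCES


def classify_pdns(variant: Variant, rule: str = "all_five", k: int = 5) -> bool:
    """Predicted-deleterious missense under the five-predictor panel.

    ``rule="all_five"`` (default) requires all five votes; ``rule="k_of_five"``
    requires at least ``k``.  Non-missense variants are never pdNS.
    """
    if variant.consequence != "missense":
        return False
    votes = sum(bool(v) for v in variant.deleterious_votes)
    if rule == "all_five":
        return votes == 5
    if rule == "k_of_five":
        return votes >= k
    raise ValueError(f"unknown pdNS rule {rule!r}")


def compute_maf(
    matrix: GenotypeMatrix,
    variant: Variant | int | str,
    founders_only: bool = False,
    pedigree: Pedigree | None = None,
) -> float:
    """Alt-allele frequency over non-missing genotypes in scope.

    With ``founders_only`` the scope is restricted to pedigree founders,
    so alleles transmitted to offspring are counted once.  Returns the
    alt-allele frequency; callers fold to the minor allele if needed.
    """
    if isinstance(variant, Variant):
        j = matrix.variants.index(variant)
    elif isinstance(variant, str):
        j = matrix.variant_index(variant)
    else:
        j = int(variant)
    col = matrix.calls[:, j]
    if founders_only:
        if pedigree is None:
            raise ValueError("founders_only requires a pedigree")
        founders = set(pedigree.founders)
        in_scope = np.array([s in founders for s in matrix.samples])
        col = col[in_scope]
    genotyped = col != MISSING
    n = int(genotyped.sum())
    if n == 0:
        raise ValueError(f"no genotyped individuals in scope for variant index {j}")
    return float(col[genotyped].sum()) / (2 * n)


@dataclass
class VariantClassMask:
    """Per-variant classification table.

    ``frame`` columns: label, pos, consequence, is_plof, is_pdns,
    maf_cohort, maf (effective, external override applied), passes_rare,
    passes_lowfreq, tier.
    """

    frame: pd.DataFrame
    common_risk: tuple[str, ...] = DEFAULT_COMMON_RISK

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def build_class_mask(
    matrix: GenotypeMatrix,
    pedigree: Pedigree | None = None,
    common_risk: tuple[str, ...] = DEFAULT_COMMON_RISK,
    pdns_rule: str = "all_five",
    pdns_k: int = 5,
    lowfreq_ceiling: float = LOWFREQ_CEILING,
    lowfreq_inclusive: bool = True,
) -> VariantClassMask:
    """Classify every panel variant and apply the frequency filters.

    The effective MAF is the external reference frequency when the
    variant carries one, else the cohort frequency (founders-only when a
    pedigree is available).
    """
    rows = []
    founders_only = pedigree is not None
    for j, v in enumerate(matrix.variants):
        maf_cohort = compute_maf(matrix, j, founders_only=founders_only, pedigree=pedigree)
        maf_cohort = min(maf_cohort, 1.0 - maf_cohort)  # fold to minor
        maf = v.maf_external if v.maf_external is not None else maf_cohort
        is_plof = classify_plof(v)
        is_pdns = classify_pdns(v, rule=pdns_rule, k=pdns_k)
        passes_lowfreq = (maf <= lowfreq_ceiling) if lowfreq_inclusive else (maf < lowfreq_ceiling)
        if v.label in common_risk:
            tier = "common_risk"
        elif passes_lowfreq:
            tier = "rare"
        else:
            tier = "excluded"
        rows.append(
            dict(
                label=v.label,
                pos=v.pos,
                consequence=v.consequence,
                is_plof=is_plof,
                is_pdns=is_pdns,
                maf_cohort=maf_cohort,
                maf=maf,
                passes_rare=maf < RARE_CEILING,
                passes_lowfreq=passes_lowfreq,
                tier=tier,
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "label",
            "pos",
            "consequence",
            "is_plof",
            "is_pdns",
            "maf_cohort",
            "maf",
            "passes_rare",
            "passes_lowfreq",
            "tier",
        ],
    )
    return VariantClassMask(frame=frame, common_risk=tuple(common_risk))


def select_burden_variants(
    mask: VariantClassMask,
    matrix: GenotypeMatrix,
    class_set: str = "plof_plus_pdns",
    maf_ceiling: float = LOWFREQ_CEILING,
    maf_inclusive: bool = True,
) -> list[int]:
    """Indices of variants qualifying for the gene burden, ordered by position.

    ``class_set`` is ``"plof_only"`` or ``"plof_plus_pdns"``.
    """
    if class_set not in ("plof_only", "plof_plus_pdns"):
        raise ValueError(f"unknown class set {class_set!r}")
    chosen = []
    for j, row in mask.frame.iterrows():
        in_class = bool(row.is_plof) or (class_set == "plof_plus_pdns" and bool(row.is_pdns))
        in_freq = (row.maf <= maf_ceiling) if maf_inclusive else (row.maf < maf_ceiling)
        if in_class and in_freq:
            chosen.append(int(j))
    chosen.sort(key=lambda j: (matrix.variants[j].chrom, matrix.variants[j].pos))
    return chosen
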