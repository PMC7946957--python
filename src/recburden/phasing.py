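"""Cis/trans resolution for candidate compound heterozygotes and per-sample
diplotype calls.

Only *trans* pairs (one variant on each parental haplotype) constitute
biallelic loss, so every double-heterozygote must be phased.  Two
evidence sources are combined, pedigree first:

* **pedigree** — if each variant is carried by exactly one parent and the
  parents differ, the pair is trans; if one parent carries both and the
  other neither, cis.  Anything else (missing parents or genotypes,
  both parents carrying both variants, Mendelian inconsistency) is
  unresolved.
* **population** — two-locus haplotype frequencies estimated by EM over
  the double-heterozygote ambiguity give the posterior probability that
  a double-het is trans, P(trans) = p_Ab·p_aB / (p_Ab·p_aB + p_AB·p_ab);
  the verdict requires the posterior to clear a symmetric threshold
  (default 0.95).

Known cis haplotypes (variant pairs that travel together in the
population) are excluded from compound-het candidacy by a label
blacklist before any phasing; the sample remains a carrier of that
haplotype.  A genotype-QC pass demotes homozygous calls with low depth
or skewed allelic balance, the signature of heterozygotes miscalled as
homozygous.

The per-sample diplotype call collapses everything to one category —
REF, CARRIER, HOM, CHET_CONFIRMED, CHET_PUTATIVE, or CIS_EXCLUDED — and
the 0/1/2 burden code used by the association module.  An exclusion
cascade records how many candidates each filter removed; retained plus
excluded always equals the initial candidate count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GenotypeMatrix, Pedigree, Variant

logger = logging.getLogger(__name__)

#: variant pairs known to travel in cis on one haplotype
DEFAULT_CIS_BLACKLIST = (
    frozenset({"p.L1007fs", "p.M863V"}),
    frozenset({"p.S431L", "p.V793M"}),
)

CATEGORIES = ("REF", "CARRIER", "HOM", "CHET_CONFIRMED", "CHET_PUTATIVE", "CIS_EXCLUDED")


@dataclass(frozen=True)
class PhaseCall:
    sample: str
    pair: tuple[str, str]  # variant labels
    verdict: str  # TRANS | CIS | UNRESOLVED
    evidence: str  # pedigree | population | blacklist | none
    posterior_trans: float | None = None

    def __post_init__(self) -> None:
        if self.verdict in ("TRANS", "CIS") and self.evidence == "none":
            raise ValueError("a decided verdict requires evidence")
        if (self.evidence == "population") != (self.posterior_trans is not None):
            raise ValueError("posterior_trans present iff evidence is population")


@dataclass(frozen=True)
class DiplotypeCall:
    sample: str
    gene: str
    category: str
    variants: tuple[str, ...] = ()
    evidence: str = "none"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    def burden_code(self, include_putative: bool = True) -> int:
        if self.category == "REF":
            return 0
        if self.category in ("CARRIER", "CIS_EXCLUDED"):
            return 1
        if self.category == "CHET_PUTATIVE" and not include_putative:
            return 1
        return 2  # HOM, CHET_CONFIRMED, CHET_PUTATIVE (included)


@dataclass
class PhasingConfig:
    min_depth: float = 10.0
    hom_ab_min: float = 0.85
    qc_policy: str = "set_missing"  # or "demote_hom_to_het" / "keep"
    trans_threshold: float = 0.95
    blacklist: tuple[frozenset, ...] = DEFAULT_CIS_BLACKLIST
    include_putative: bool = True
    use_population: bool = True
    em_tol: float = 1e-10
    em_max_iter: int = 1000


# ---------------------------------------------------------------------------
# genotype QC


def qc_genotype(
    dosage: int,
    depth: float | None,
    allele_balance: float | None,
    min_depth: float = 10.0,
    hom_ab_min: float = 0.85,
    policy: str = "set_missing",
) -> str:
    """Decide the fate of one genotype call: 'keep', 'demote_hom_to_het'
    or 'set_missing'.

    Only homozygous-alternate calls are at risk: low depth or an allelic
    balance below ``hom_ab_min`` marks a likely miscalled heterozygote.
    Calls without QC fields are kept.
    """
    if dosage != 2:
        return "keep"
    bad_depth = depth is not None and not np.isnan(depth) and depth < min_depth
    bad_ab = (
        allele_balance is not None
        and not np.isnan(allele_balance)
        and allele_balance < hom_ab_min
    )
    if bad_depth or bad_ab:
        return policy if policy in ("demote_hom_to_het", "set_missing") else "keep"
    return "keep"


def apply_genotype_qc(
    matrix: GenotypeMatrix, config: PhasingConfig
) -> tuple[GenotypeMatrix, list[tuple[str, str, str]]]:
    """Apply :func:`qc_genotype` across the matrix; returns the cleaned
    matrix and a log of (sample, variant label, action)."""
    calls = matrix.calls.copy()
    log: list[tuple[str, str, str]] = []
    if matrix.depth is None and matrix.allele_balance is None:
        return matrix, log
    hom_idx = np.argwhere(calls == 2)
    for i, j in hom_idx:
        depth = None if matrix.depth is None else matrix.depth[i, j]
        ab = None if matrix.allele_balance is None else matrix.allele_balance[i, j]
        action = qc_genotype(
            2, depth, ab, min_depth=config.min_depth, hom_ab_min=config.hom_ab_min,
            policy=config.qc_policy,
        )
        if action == "demote_hom_to_het":
            calls[i, j] = 1
        elif action == "set_missing":
            calls[i, j] = MISSING
        if action != "keep":
            log.append((matrix.samples[i], matrix.variants[j].label, action))
    return (
        GenotypeMatrix(
            samples=list(matrix.samples), variants=list(matrix.variants), calls=calls,
            depth=matrix.depth, allele_balance=matrix.allele_balance,
        ),
        log,
    )


# ---------------------------------------------------------------------------
# pedigree phasing


def phase_pair_by_pedigree(
    sample: str,
    var_a: str,
    var_b: str,
    pedigree: Pedigree,
    matrix: GenotypeMatrix,
) -> PhaseCall:
    """Phase a double-heterozygote from parental genotypes.

    TRANS when the two alt alleles must have come from different parents;
    CIS when one parent carries both variants and the other neither.
    Missing parents or genotypes, both parents carrying both variants, or
    Mendelian-inconsistent genotypes give UNRESOLVED.
    """
    if sample not in pedigree.individuals:
        raise KeyError(f"sample {sample!r} not in pedigree")
    ja, jb = matrix.variant_index(var_a), matrix.variant_index(var_b)
    si = matrix.sample_index(sample)
    if matrix.calls[si, ja] != 1 or matrix.calls[si, jb] != 1:
        raise ValueError(f"{sample!r} is not heterozygous at both {var_a} and {var_b}")

    father, mother = pedigree.parents(sample)
    unresolved = PhaseCall(sample, (var_a, var_b), "UNRESOLVED", "none")
    if father is None or mother is None:
        return unresolved
    try:
        fi, mi = matrix.sample_index(father), matrix.sample_index(mother)
    except KeyError:
        return unresolved
    geno = {
        "fa": int(matrix.calls[fi, ja]), "fb": int(matrix.calls[fi, jb]),
        "ma": int(matrix.calls[mi, ja]), "mb": int(matrix.calls[mi, jb]),
    }
    if any(g == MISSING for g in geno.values()):
        return unresolved

    father_carries = (geno["fa"] > 0, geno["fb"] > 0)
    mother_carries = (geno["ma"] > 0, geno["mb"] > 0)

    # Mendelian consistency: each child alt allele needs a possible source
    if not (father_carries[0] or mother_carries[0]) or not (
        father_carries[1] or mother_carries[1]
    ):
        logger.warning(
            "Mendelian inconsistency for %s at (%s, %s): child het without a carrier parent",
            sample, var_a, var_b,
        )
        return unresolved

    sole_a = father_carries[0] != mother_carries[0]  # exactly one parent carries A
    sole_b = father_carries[1] != mother_carries[1]
    if sole_a and sole_b:
        a_from_father = father_carries[0]
        b_from_father = father_carries[1]
        if a_from_father != b_from_father:
            return PhaseCall(sample, (var_a, var_b), "TRANS", "pedigree")
        return PhaseCall(sample, (var_a, var_b), "CIS", "pedigree")
    return unresolved


# ---------------------------------------------------------------------------
# population phasing (two-locus haplotype-frequency EM)


def estimate_haplotype_freqs_em(
    matrix: GenotypeMatrix,
    var_a: str,
    var_b: str,
    samples: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[float, float, float, float]:
    """Maximum-likelihood two-locus haplotype frequencies
    (p_AB, p_Ab, p_aB, p_ab) by EM over the double-heterozygote ambiguity.

    Under random mating every genotype pair except the double-het has a
    determined haplotype decomposition; the E step splits double-hets
    between cis (AB/ab) and trans (Ab/aB) in proportion to
    2·p_AB·p_ab vs 2·p_Ab·p_aB.  The observed log-likelihood is asserted
    non-decreasing at every step.
    """
    ja, jb = matrix.variant_index(var_a), matrix.variant_index(var_b)
    if samples is None:
        rows = np.arange(matrix.n_samples)
    else:
        rows = np.array([matrix.sample_index(s) for s in samples])
    ga = matrix.calls[rows, ja]
    gb = matrix.calls[rows, jb]
    ok = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[ok].astype(int), gb[ok].astype(int)
    n = len(ga)
    if n < 2:
        raise ValueError("need >= 2 samples with non-missing genotypes at both loci")

    counts = np.zeros((3, 3))
    for i, j in zip(ga, gb):
        counts[i, j] += 1

    # haplotype order: AB, Ab, aB, ab  (A/B = alt alleles)
    p = np.full(4, 0.25)

    def genotype_probs(p):
        pAB, pAb, paB, pab = p
        g = np.empty((3, 3))
        g[2, 2] = pAB ** 2
        g[2, 1] = 2 * pAB * pAb
        g[2, 0] = pAb ** 2
        g[1, 2] = 2 * pAB * paB
        g[1, 0] = 2 * pAb * pab
        g[0, 2] = paB ** 2
        g[0, 1] = 2 * paB * pab
        g[0, 0] = pab ** 2
        g[1, 1] = 2 * pAB * pab + 2 * pAb * paB
        return g

    def loglik(p):
        g = np.clip(genotype_probs(p), 1e-300, None)
        return float((counts * np.log(g)).sum())

    last_ll = loglik(p)
    n_dh = counts[1, 1]
    for it in range(1, max_iter + 1):
        pAB, pAb, paB, pab = p
        cis = pAB * pab
        trans = pAb * paB
        denom = cis + trans
        w_cis = 0.5 if denom == 0 else cis / denom
        # expected haplotype counts
        hap = np.zeros(4)
        hap[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + n_dh * w_cis
        hap[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + n_dh * (1 - w_cis)
        hap[2] = 2 * counts[0, 2] + counts[1, 2] + counts[0, 1] + n_dh * (1 - w_cis)
        hap[3] = 2 * counts[0, 0] + counts[1, 0] + counts[0, 1] + n_dh * w_cis
        new = hap / (2 * n)
        ll = loglik(new)
        if ll < last_ll - 1e-9:
            raise AssertionError(f"EM log-likelihood decreased: {last_ll} -> {ll}")
        delta = float(np.max(np.abs(new - p)))
        p, last_ll = new, ll
        if delta < tol:
            return tuple(float(x) for x in p)
    raise RuntimeError(f"EM did not converge in {max_iter} iterations; last delta {delta:.3g}")


def phase_pair_by_population(
    sample: str,
    var_a: str,
    var_b: str,
    hap_freqs: tuple[float, float, float, float],
    trans_threshold: float = 0.95,
) -> PhaseCall:
    """Posterior phase for a double-het given haplotype frequencies.

    P(trans) = p_Ab·p_aB / (p_Ab·p_aB + p_AB·p_ab); TRANS at or above the
    threshold, CIS at or below its complement, otherwise UNRESOLVED.
    """
    pAB, pAb, paB, pab = hap_freqs
    trans = pAb * paB
    cis = pAB * pab
    denom = trans + cis
    if denom == 0:
        return PhaseCall(sample, (var_a, var_b), "UNRESOLVED", "none")
    post = trans / denom
    if post >= trans_threshold:
        verdict = "TRANS"
    elif post <= 1 - trans_threshold:
        verdict = "CIS"
    else:
        verdict = "UNRESOLVED"
    return PhaseCall(sample, (var_a, var_b), verdict, "population", posterior_trans=post)


# ---------------------------------------------------------------------------
# blacklist


def apply_cis_blacklist(
    pairs: list[tuple[str, str]],
    blacklist: tuple[frozenset, ...] = DEFAULT_CIS_BLACKLIST,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Split candidate pairs into (retained, excluded-as-known-cis)."""
    bl = {frozenset(p) for p in blacklist}
    kept, excluded = [], []
    for pair in pairs:
        (excluded if frozenset(pair) in bl else kept).append(pair)
    return kept, excluded


# ---------------------------------------------------------------------------
# diplotype calling


@dataclass
class CascadeLog:
    """Ordered exclusion audit: each initial candidate lands in exactly one bin."""

    initial: set = field(default_factory=set)
    qc_removed: set = field(default_factory=set)
    blacklist_excluded: set = field(default_factory=set)
    cis_excluded: set = field(default_factory=set)
    retained: set = field(default_factory=set)

    def counts(self) -> dict[str, int]:
        return {
            "initial_candidates": len(self.initial),
            "qc_removed": len(self.qc_removed),
            "blacklist_excluded": len(self.blacklist_excluded),
            "cis_excluded": len(self.cis_excluded),
            "retained": len(self.retained),
        }

    def check_partition(self) -> bool:
        bins = [self.qc_removed, self.blacklist_excluded, self.cis_excluded, self.retained]
        union: set = set()
        total = 0
        for b in bins:
            union |= b
            total += len(b)
        return union == self.initial and total == len(self.initial)


def _candidate_samples(matrix: GenotypeMatrix, qual_idx: list[int]) -> set[str]:
    """Samples with a putative recessive signal: any dosage-2 qualifying
    call or >= 2 qualifying heterozygous calls."""
    sub = matrix.calls[:, qual_idx]
    hom_any = (sub == 2).any(axis=1)
    n_het = (sub == 1).sum(axis=1)
    mask = hom_any | (n_het >= 2)
    return {matrix.samples[i] for i in np.nonzero(mask)[0]}


def call_diplotypes(
    gene: str,
    qualifying: list[int],
    matrix: GenotypeMatrix,
    pedigree: Pedigree | None = None,
    config: PhasingConfig | None = None,
    phase_calls: dict | None = None,
    unrelated: list[str] | None = None,
) -> tuple[dict[str, DiplotypeCall], CascadeLog, list[PhaseCall]]:
    """Assign every sample exactly one recessive-status category.

    Order of operations: genotype QC → per-sample candidate pairs →
    cis blacklist → pedigree phasing → population phasing (EM haplotype
    frequencies over the unrelated set) → category.  HOM wins outright;
    any trans pair makes a confirmed compound het; pairs that stay
    undecided leave the sample a putative compound het; a sample whose
    pairs are all cis (or blacklisted) remains a carrier of one
    haplotype, logged CIS_EXCLUDED.

    Returns (calls keyed by sample, exclusion cascade, phase-call log).
    """
    config = config or PhasingConfig()
    pre_candidates = _candidate_samples(matrix, qualifying)
    clean, qc_log = apply_genotype_qc(matrix, config)
    post_candidates = _candidate_samples(clean, qualifying)

    cascade = CascadeLog(initial=set(pre_candidates))
    cascade.qc_removed = pre_candidates - post_candidates

    sub = clean.calls[:, qualifying]
    labels = [clean.variants[j].label for j in qualifying]
    pos = {clean.variants[j].label: clean.variants[j].pos for j in qualifying}

    # population haplotype frequencies per needed pair, lazily estimated
    if unrelated is None:
        unrelated = pedigree.unrelated_set() if pedigree is not None else None
    freq_cache: dict[frozenset, tuple | None] = {}

    def pair_freqs(a: str, b: str):
        key = frozenset((a, b))
        if key not in freq_cache:
            try:
                freq_cache[key] = estimate_haplotype_freqs_em(
                    clean, a, b, samples=unrelated, tol=config.em_tol,
                    max_iter=config.em_max_iter,
                )
            except (ValueError, RuntimeError):
                freq_cache[key] = None
        return freq_cache[key]

    calls: dict[str, DiplotypeCall] = {}
    phase_log: list[PhaseCall] = []
    has_parents: set[str] = set()
    if pedigree is not None:
        for iid, ind in pedigree.individuals.items():
            if ind.father is not None or ind.mother is not None:
                has_parents.add(iid)

    for i, sample in enumerate(clean.samples):
        row = sub[i]
        hom_j = np.nonzero(row == 2)[0]
        het_j = np.nonzero(row == 1)[0]
        if len(hom_j) > 0:
            calls[sample] = DiplotypeCall(sample, gene, "HOM", (labels[hom_j[0]],))
            if sample in cascade.initial:
                cascade.retained.add(sample)
            continue
        if len(het_j) == 0:
            calls[sample] = DiplotypeCall(sample, gene, "REF")
            continue
        if len(het_j) == 1:
            calls[sample] = DiplotypeCall(sample, gene, "CARRIER", (labels[het_j[0]],))
            continue

        het_labels = sorted((labels[j] for j in het_j), key=lambda l: pos[l])
        all_pairs = list(itertools.combinations(het_labels, 2))
        pairs, black = apply_cis_blacklist(all_pairs, config.blacklist)
        if not pairs:
            calls[sample] = DiplotypeCall(
                sample, gene, "CIS_EXCLUDED", tuple(het_labels), evidence="blacklist"
            )
            if sample in cascade.initial:
                cascade.blacklist_excluded.add(sample)
            continue

        verdicts: list[PhaseCall] = []
        for a, b in pairs:
            pc = None
            if phase_calls is not None:
                pc = phase_calls.get((sample, frozenset((a, b))))
            if pc is None and pedigree is not None and sample in has_parents:
                pc = phase_pair_by_pedigree(sample, a, b, pedigree, clean)
            if (pc is None or pc.verdict == "UNRESOLVED") and config.use_population:
                freqs = pair_freqs(a, b)
                if freqs is not None:
                    pop = phase_pair_by_population(
                        sample, a, b, freqs, trans_threshold=config.trans_threshold
                    )
                    # pedigree overrides population; population fills unresolved
                    if pc is None or (pc.verdict == "UNRESOLVED" and pop.verdict != "UNRESOLVED"):
                        pc = pop
            if pc is None:
                pc = PhaseCall(sample, (a, b), "UNRESOLVED", "none")
            verdicts.append(pc)
            phase_log.append(pc)

        trans = [pc for pc in verdicts if pc.verdict == "TRANS"]
        unresolved = [pc for pc in verdicts if pc.verdict == "UNRESOLVED"]
        if trans:
            # best-evidence pair: pedigree before population, then position
            trans.sort(
                key=lambda pc: (
                    0 if pc.evidence == "pedigree" else 1,
                    pos[pc.pair[0]], pos[pc.pair[1]],
                )
            )
            best = trans[0]
            calls[sample] = DiplotypeCall(
                sample, gene, "CHET_CONFIRMED", best.pair, evidence=best.evidence
            )
            if sample in cascade.initial:
                cascade.retained.add(sample)
        elif unresolved:
            calls[sample] = DiplotypeCall(
                sample, gene, "CHET_PUTATIVE", tuple(het_labels), evidence="none"
            )
            if sample in cascade.initial:
                cascade.retained.add(sample)
        else:
            ev = verdicts[0].evidence if verdicts else "none"
            calls[sample] = DiplotypeCall(
                sample, gene, "CIS_EXCLUDED", tuple(het_labels), evidence=ev
            )
            if sample in cascade.initial:
                cascade.cis_excluded.add(sample)

    assert cascade.check_partition(), "exclusion cascade failed to partition candidates"
    return calls, cascade, phase_log
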