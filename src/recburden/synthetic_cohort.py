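"""Synthetic single-gene cohort generator.

The study data this pipeline targets (protected exome sequencing linked
to de-identified health records) cannot be redistributed, so every
downstream stage is exercised on simulated cohorts with the same
statistical structure:

* a single-gene variant panel containing the three "common" low-frequency
  risk alleles at their clinical-cohort frequencies (0.050 / 0.017 /
  0.029) plus rarer deleterious alleles;
* founder haplotypes drawn independently per variant at the panel
  frequencies — founder genotypes therefore sit in Hardy–Weinberg
  proportions — except designated cis groups, whose members travel on
  the same haplotype (nested by frequency, so the rarer member of a cis
  pair always rides with the commoner one);
* trio / quartet / singleton family structure with Mendelian gamete
  transmission (one uniformly chosen haplotype per parent, no
  recombination within the gene);
* disease risk multiplicative on the odds scale — baseline odds
  κ0/(1−κ0) times ψ_het for carriers and ψ_rec for biallelic
  (homozygous or true-trans compound-het) samples — so the simulated ψ
  equals the odds ratio the association module estimates asymptotically;
* longitudinal diagnosis-code streams: affected samples receive at
  least two IBD encounter diagnoses on distinct calendar days, an
  optional earlier anemia code (the planted comorbidity lead time), and
  everyone receives background codes;
* two observation-noise channels: a true heterozygote miscalled
  homozygous with low depth and skewed allelic balance, and a random
  low-depth flag — the artifacts the genotype-QC stage is built to catch.

A truth table records each individual's haplotypes and true diplotype
category so oracle tests can compare pipeline output against the
generative state.  All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .io_formats import (
    DiagnosisEvent,
    GenotypeMatrix,
    Individual,
    Pedigree,
    PhenotypeTable,
    SampleRecord,
    Variant,
)
from .variant_classify import classify_pdns, classify_plof

ALL_FIVE = (True,) * 5


@dataclass(frozen=True)
class SimVariantSpec:
    """One panel variant: label, functional class, predictor votes,
    population allele frequency, and optional cis-haplotype group tag."""

    label: str
    consequence: str
    frequency: float
    deleterious_votes: tuple[bool, ...] = ALL_FIVE
    cis_group: str | None = None
    chrom: str = "16"
    pos: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.frequency < 0.5):
            raise ValueError(f"frequency must be in (0, 0.5): {self.frequency}")


def default_panel() -> list[SimVariantSpec]:
    """NOD2-like panel: the three common risk alleles at their clinical
    cohort frequencies, the two known cis pairs, and rarer deleterious
    alleles.  Positions are ordered by codon."""
    base = 50_744_000
    return [
        SimVariantSpec("p.S431L", "missense", 0.006, ALL_FIVE, cis_group="S431L+V793M", pos=base + 431 * 3),
        SimVariantSpec("p.S506Vfs", "frameshift", 0.001, (False,) * 5, pos=base + 506 * 3),
        SimVariantSpec("p.R702W", "missense", 0.050, ALL_FIVE, pos=base + 702 * 3),
        SimVariantSpec("p.V793M", "missense", 0.006, ALL_FIVE, cis_group="S431L+V793M", pos=base + 793 * 3),
        SimVariantSpec("p.N852S", "missense", 0.004, ALL_FIVE, pos=base + 852 * 3),
        SimVariantSpec("p.M863V", "missense", 0.010, ALL_FIVE, cis_group="L1007fs+M863V", pos=base + 863 * 3),
        SimVariantSpec("p.G908R", "missense", 0.017, ALL_FIVE, pos=base + 908 * 3),
        SimVariantSpec("p.L1007fs", "frameshift", 0.029, (False,) * 5, cis_group="L1007fs+M863V", pos=base + 1007 * 3),
        # a non-deleterious missense decoy the classifier must drop
        SimVariantSpec("p.A612T", "missense", 0.020, (True, True, True, False, False), pos=base + 612 * 3),
    ]


@dataclass
class PenetranceModel:
    """Multiplicative odds model: κ0 baseline risk, ψ multipliers."""

    baseline_risk: float = 0.02
    psi_het: float = 1.5
    psi_rec: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_risk < 1.0):
            raise ValueError("baseline_risk must be in (0, 1)")
        if self.psi_rec < self.psi_het or self.psi_het < 1.0:
            raise ValueError("need psi_rec >= psi_het >= 1")


@dataclass
class DiagnosisModel:
    onset_mean: float = 51.5  # mean age at first IBD diagnosis, years
    onset_sd: float = 12.0
    recessive_onset_gap: float = 8.1  # biallelic carriers present younger
    extra_encounters_mean: float = 2.0  # IBD encounters beyond the required two
    cd_codes: tuple[str, ...] = ("K50.0", "K50.1", "K50.9")
    uc_codes: tuple[str, ...] = ("K51.0", "K51.9")
    conflict_prob: float = 0.05  # affected sample also receives a UC code
    background_codes: tuple[str, ...] = ("I10", "E11.9", "J06.9", "M54.5", "R51.9")
    background_rate: float = 2.0  # Poisson mean of non-IBD codes per sample
    anemia_code: str = "D50.9"
    anemia_prob: float = 0.75
    anemia_prior_frac: float = 0.58  # fraction of anemia diagnoses preceding IBD
    anemia_lead_mean: float = 2.26  # years before first IBD diagnosis
    anemia_lead_sd: float = 1.0


@dataclass
class QcNoise:
    p_het_to_hom: float = 0.02  # true het miscalled hom (low depth, skewed balance)
    p_lowdepth: float = 0.0  # random low-depth flag on an otherwise good call


@dataclass
class SimCohortConfig:
    n_trios: int = 400
    n_quartets: int = 20
    n_singletons: int = 400
    panel: list[SimVariantSpec] = field(default_factory=default_panel)
    penetrance: PenetranceModel = field(default_factory=PenetranceModel)
    diagnosis: DiagnosisModel = field(default_factory=DiagnosisModel)
    qc_noise: QcNoise = field(default_factory=QcNoise)
    cis_linkage: float = 1.0
    gene: str = "NOD2"
    seed: int = 0


TRUTH_CATEGORIES = ("REF", "CARRIER", "HOM", "CHET_TRANS", "CHET_CIS")


def panel_variants(panel: list[SimVariantSpec], gene: str = "NOD2") -> list[Variant]:
    """Materialize panel specs as annotated :class:`Variant` objects."""
    out = []
    for i, spec in enumerate(panel):
        pos = spec.pos or (50_744_000 + i * 100)
        ref, alt = ("A", "T") if spec.consequence != "frameshift" else ("AT", "A")
        out.append(
            Variant(
                chrom=spec.chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                label=spec.label,
                gene=gene,
                consequence=spec.consequence,
                deleterious_votes=spec.deleterious_votes,
                maf_external=spec.frequency,  # the generating frequency doubles
                # as the reference-database MAF the classifier prefers
            )
        )
    return out


def qualifying_labels(panel: list[SimVariantSpec], maf_ceiling: float = 0.05) -> list[str]:
    """Panel members that would qualify for the burden (pLoF or pdNS,
    frequency at or below the ceiling) — the truth-side filter."""
    out = []
    for v in panel_variants(panel):
        spec = next(s for s in panel if s.label == v.label)
        if (classify_plof(v) or classify_pdns(v)) and spec.frequency <= maf_ceiling:
            out.append(spec.label)
    return out


def simulate_founder_haplotypes(
    config: SimCohortConfig, n: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw 2n founder haplotypes as a boolean (2n × panel) array.

    Variants are placed independently at their frequencies; members of a
    cis group are nested by frequency (a haplotype carrying the rarer
    member always carries the commoner ones), so with cis_linkage = 1 no
    haplotype splits a cis group.
    """
    rng = rng or np.random.default_rng(config.seed)
    m = len(config.panel)
    haps = np.zeros((2 * n, m), dtype=bool)
    groups: dict[str | None, list[int]] = {}
    for j, spec in enumerate(config.panel):
        groups.setdefault(spec.cis_group, []).append(j)
    for tag, members in groups.items():
        if tag is None:
            for j in members:
                haps[:, j] = rng.random(2 * n) < config.panel[j].frequency
        else:
            u = rng.random(2 * n)
            linked = rng.random(2 * n) < config.cis_linkage
            for j in members:
                nested = u < config.panel[j].frequency
                independent = rng.random(2 * n) < config.panel[j].frequency
                haps[:, j] = np.where(linked, nested, independent)
    return haps


def _true_category(h1: np.ndarray, h2: np.ndarray, qual_mask: np.ndarray) -> str:
    q1, q2 = h1 & qual_mask, h2 & qual_mask
    if bool((q1 & q2).any()):
        return "HOM"
    n1, n2 = int(q1.sum()), int(q2.sum())
    if n1 >= 1 and n2 >= 1:
        return "CHET_TRANS"
    if n1 + n2 >= 2:
        return "CHET_CIS"
    if n1 + n2 == 1:
        return "CARRIER"
    return "REF"


def simulate_pedigree_genotypes(
    config: SimCohortConfig, rng: np.random.Generator | None = None
) -> tuple[Pedigree, GenotypeMatrix, pd.DataFrame]:
    """Build pedigree, observed genotype matrix, and truth table.

    Founders draw haplotype pairs from the Hardy–Weinberg pool; each
    offspring receives one uniformly chosen haplotype per parent.  The
    truth table records both haplotypes and the true diplotype category
    per sample; QC noise corrupts only the observed matrix.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_founders = 2 * (config.n_trios + config.n_quartets) + config.n_singletons
    pool = simulate_founder_haplotypes(config, n_founders, rng)

    variants = panel_variants(config.panel, config.gene)
    qual = set(qualifying_labels(config.panel))
    qual_mask = np.array([v.label in qual for v in variants])

    individuals: dict[str, Individual] = {}
    hap1: list[np.ndarray] = []
    hap2: list[np.ndarray] = []
    samples: list[str] = []
    meta: list[tuple[str, str]] = []  # (family, role)
    next_founder = 0

    def add(sample, fid, father, mother, sex, h1, h2, role):
        individuals[sample] = Individual(sample, fid, father, mother, sex)
        samples.append(sample)
        hap1.append(h1)
        hap2.append(h2)
        meta.append((fid, role))

    fam = 0
    for n_children, n_fams in ((1, config.n_trios), (2, config.n_quartets)):
        for _ in range(n_fams):
            fam += 1
            fid = f"F{fam:05d}"
            fa, mo = f"{fid}_FA", f"{fid}_MO"
            fh = (pool[2 * next_founder], pool[2 * next_founder + 1]); next_founder += 1
            mh = (pool[2 * next_founder], pool[2 * next_founder + 1]); next_founder += 1
            add(fa, fid, None, None, 1, fh[0], fh[1], "founder")
            add(mo, fid, None, None, 2, mh[0], mh[1], "founder")
            for c in range(n_children):
                pick = rng.integers(0, 2, size=2)
                add(
                    f"{fid}_C{c + 1}", fid, fa, mo, int(rng.integers(1, 3)),
                    fh[pick[0]], mh[pick[1]], "child",
                )
    for k in range(config.n_singletons):
        fid = f"S{k + 1:05d}"
        h = (pool[2 * next_founder], pool[2 * next_founder + 1]); next_founder += 1
        add(fid, fid, None, None, int(rng.integers(1, 3)), h[0], h[1], "singleton")

    pedigree = Pedigree(individuals=individuals)
    H1 = np.vstack(hap1)
    H2 = np.vstack(hap2)
    true_dosage = H1.astype(np.int8) + H2.astype(np.int8)

    # observed matrix with QC noise on qualifying calls
    calls = true_dosage.copy()
    n, m = calls.shape
    depth = rng.poisson(40.0, size=(n, m)).astype(float)
    depth = np.maximum(depth, 12.0)
    ab = np.zeros((n, m))
    ab[calls == 1] = np.clip(rng.normal(0.5, 0.05, size=int((calls == 1).sum())), 0.2, 0.8)
    ab[calls == 2] = rng.uniform(0.92, 1.0, size=int((calls == 2).sum()))

    noise = config.qc_noise
    if noise.p_het_to_hom > 0:
        het_cells = np.argwhere((calls == 1) & qual_mask[None, :])
        flip = rng.random(len(het_cells)) < noise.p_het_to_hom
        for (i, j), f in zip(het_cells, flip):
            if f:
                calls[i, j] = 2
                depth[i, j] = float(rng.integers(3, 9))
                ab[i, j] = rng.uniform(0.55, 0.80)
    if noise.p_lowdepth > 0:
        cells = rng.random((n, m)) < noise.p_lowdepth
        depth[cells] = rng.integers(3, 9, size=int(cells.sum())).astype(float)

    matrix = GenotypeMatrix(
        samples=samples, variants=variants, calls=calls, depth=depth, allele_balance=ab
    )

    labels = [v.label for v in variants]

    def hap_str(h):
        return ";".join(l for l, b in zip(labels, h) if b)

    truth = pd.DataFrame(
        {
            "sample": samples,
            "family": [f for f, _ in meta],
            "role": [r for _, r in meta],
            "hap1": [hap_str(h) for h in H1],
            "hap2": [hap_str(h) for h in H2],
            "true_category": [
                _true_category(H1[i], H2[i], qual_mask) for i in range(n)
            ],
            "n_qual_alt": (true_dosage[:, qual_mask].sum(axis=1)).astype(int),
        }
    )
    return pedigree, matrix, truth


def truth_pair_is_trans(row, var_a: str, var_b: str) -> bool | None:
    """Whether a double-het row carries var_a and var_b on opposite
    haplotypes; None when the sample is not het-het for the pair."""
    h1 = set(row.hap1.split(";")) if row.hap1 else set()
    h2 = set(row.hap2.split(";")) if row.hap2 else set()
    in1 = (var_a in h1, var_b in h1)
    in2 = (var_a in h2, var_b in h2)
    het_a = (var_a in h1) != (var_a in h2)
    het_b = (var_b in h1) != (var_b in h2)
    if not (het_a and het_b):
        return None
    same = (in1[0] and in1[1]) or (in2[0] and in2[1])
    return not same


def simulate_disease_status(
    truth: pd.DataFrame, config: SimCohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the disease indicator and onset age per sample.

    Disease odds are κ0/(1−κ0) multiplied by ψ_het for carriers (including
    cis double-carriers) and ψ_rec for biallelic samples.  Affected
    biallelic samples draw onset from a younger mean.
    """
    pen = config.penetrance
    diag = config.diagnosis
    base_odds = pen.baseline_risk / (1 - pen.baseline_risk)
    mult = np.ones(len(truth))
    cat = truth["true_category"].to_numpy()
    mult[np.isin(cat, ("CARRIER", "CHET_CIS"))] = pen.psi_het
    mult[np.isin(cat, ("HOM", "CHET_TRANS"))] = pen.psi_rec
    odds = base_odds * mult
    p = odds / (1 + odds)
    disease = rng.random(len(truth)) < p
    mean = np.where(
        np.isin(cat, ("HOM", "CHET_TRANS")),
        diag.onset_mean - diag.recessive_onset_gap,
        diag.onset_mean,
    )
    onset = np.clip(rng.normal(mean, diag.onset_sd), 2.0, 85.0)
    out = truth[["sample", "true_category"]].copy()
    out["disease"] = disease
    out["onset_age"] = np.where(disease, onset, np.nan)
    return out


def simulate_phenotypes(
    pedigree: Pedigree,
    truth: pd.DataFrame,
    config: SimCohortConfig,
    rng: np.random.Generator | None = None,
    status: pd.DataFrame | None = None,
) -> PhenotypeTable:
    """Generate the longitudinal diagnosis-code stream per sample."""
    rng = rng or np.random.default_rng(config.seed + 1)
    diag = config.diagnosis
    if status is None:
        status = simulate_disease_status(truth, config, rng)
    records: dict[str, SampleRecord] = {}
    for row in status.itertuples(index=False):
        sample = row.sample
        birth = date(1940, 1, 1) + timedelta(days=int(rng.integers(0, 40 * 365)))
        events: list[DiagnosisEvent] = []
        affection = "unaffected"
        if row.disease:
            affection = "CD"
            first_dx = birth + timedelta(days=int(row.onset_age * 365.25))
            n_enc = 2 + int(rng.poisson(diag.extra_encounters_mean))
            day = first_dx
            for _ in range(n_enc):
                code = diag.cd_codes[int(rng.integers(0, len(diag.cd_codes)))]
                events.append(DiagnosisEvent(sample, code, "ICD10", day, "encounter"))
                day = day + timedelta(days=int(rng.integers(30, 700)))
            if rng.random() < diag.conflict_prob:
                code = diag.uc_codes[int(rng.integers(0, len(diag.uc_codes)))]
                events.append(
                    DiagnosisEvent(sample, code, "ICD10", day + timedelta(days=14), "encounter")
                )
            if rng.random() < diag.anemia_prob:
                if rng.random() < diag.anemia_prior_frac:
                    lead = max(0.0, rng.normal(diag.anemia_lead_mean, diag.anemia_lead_sd))
                    when = first_dx - timedelta(days=int(lead * 365.25))
                else:
                    when = first_dx + timedelta(days=int(rng.uniform(0.5, 4.0) * 365.25))
                if when > birth:
                    events.append(DiagnosisEvent(sample, diag.anemia_code, "ICD10", when, "encounter"))
        n_bg = int(rng.poisson(diag.background_rate))
        for _ in range(n_bg):
            code = diag.background_codes[int(rng.integers(0, len(diag.background_codes)))]
            when = birth + timedelta(days=int(rng.integers(18 * 365, 70 * 365)))
            events.append(DiagnosisEvent(sample, code, "ICD10", when, "encounter"))
        events.sort(key=lambda e: e.date)
        records[sample] = SampleRecord(
            sample=sample, birth_date=birth, sex=pedigree.individuals[sample].sex,
            affection=affection, events=events,
        )
    return PhenotypeTable(records=records)


@dataclass
class SimulatedCohort:
    pedigree: Pedigree
    matrix: GenotypeMatrix
    truth: pd.DataFrame
    phenotypes: PhenotypeTable
    status: pd.DataFrame
    config: SimCohortConfig


def simulate_cohort(config: SimCohortConfig) -> SimulatedCohort:
    """One-call generator: pedigree + genotypes + truth + phenotypes,
    all driven by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    pedigree, matrix, truth = simulate_pedigree_genotypes(config, rng)
    status = simulate_disease_status(truth, config, rng)
    phenotypes = simulate_phenotypes(pedigree, truth, config, rng, status=status)
    return SimulatedCohort(pedigree, matrix, truth, phenotypes, status, config)
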