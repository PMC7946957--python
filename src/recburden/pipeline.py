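"""End-to-end orchestration: simulate (or load) → classify → phase →
call diplotypes → genetic-model association → burden regression →
optional PheWAS, with an exclusion-cascade audit and a reproducible run
manifest.

The pipeline is deterministic given its seed: two runs with the same
config produce byte-identical TSV outputs and the same manifest hash
(the manifest deliberately contains no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    AssocResult,
    GenotypeCounts,
    build_genotype_counts,
    burden_test,
    or_additive,
    or_genotypic,
    or_recessive,
)
from .ehr_phewas import CaseDefinition, define_cases, run_phewas
from .io_formats import (
    DiagnosisEvent,
    GenotypeMatrix,
    Pedigree,
    PhenotypeTable,
    SampleRecord,
    Variant,
    read_pedigree,
    read_phenotypes,
    read_vcf,
    write_pedigree,
    write_phenotypes,
    write_vcf,
)
from .phasing import DEFAULT_CIS_BLACKLIST, PhasingConfig, call_diplotypes
from .synthetic_cohort import SimCohortConfig, simulate_cohort
from .variant_classify import (
    DEFAULT_COMMON_RISK,
    LOWFREQ_CEILING,
    build_class_mask,
    select_burden_variants,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Everything a run needs; YAML-serializable with full defaulting."""

    # inputs: either paths, or a simulation config
    vcf: str | None = None
    pedigree: str | None = None
    phenotypes: str | None = None
    simulate: SimCohortConfig | None = None

    gene: str = "NOD2"
    common_risk: tuple[str, ...] = DEFAULT_COMMON_RISK
    maf_ceiling: float = LOWFREQ_CEILING
    maf_inclusive: bool = True
    class_sets: tuple[str, ...] = ("plof_only", "plof_plus_pdns")
    phasing: PhasingConfig = field(default_factory=PhasingConfig)
    case_definition: CaseDefinition = field(default_factory=CaseDefinition)
    models: tuple[str, ...] = ("additive", "genotypic", "recessive")
    run_phewas: bool = False
    phewas_prefix_length: int = 3
    out_dir: str = "recburden_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if kwargs.get("simulate") is not None and not isinstance(
            kwargs["simulate"], SimCohortConfig
        ):
            sim = dict(kwargs["simulate"])
            for key, sub in (
                ("penetrance", "PenetranceModel"),
                ("diagnosis", "DiagnosisModel"),
                ("qc_noise", "QcNoise"),
            ):
                if key in sim and isinstance(sim[key], dict):
                    from . import synthetic_cohort as sc

                    sim[key] = getattr(sc, sub)(**sim[key])
            if "panel" in sim and sim["panel"] and isinstance(sim["panel"][0], dict):
                from .synthetic_cohort import SimVariantSpec

                sim["panel"] = [SimVariantSpec(**v) for v in sim["panel"]]
            kwargs["simulate"] = SimCohortConfig(**sim)
        if isinstance(kwargs.get("phasing"), dict):
            ph = dict(kwargs["phasing"])
            if "blacklist" in ph:
                ph["blacklist"] = tuple(frozenset(p) for p in ph["blacklist"])
            kwargs["phasing"] = PhasingConfig(**ph)
        if isinstance(kwargs.get("case_definition"), dict):
            cd = dict(kwargs["case_definition"])
            if "prefixes" in cd:
                cd["prefixes"] = tuple(tuple(p) for p in cd["prefixes"])
            kwargs["case_definition"] = CaseDefinition(**cd)
        for key in ("common_risk", "class_sets", "models"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def canonical_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, frozenset):
                return sorted(obj)
            if isinstance(obj, (list, tuple)):
                return [enc(x) for x in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunBundle:
    diplotypes: dict
    cascade: "object"
    association: pd.DataFrame
    burden: pd.DataFrame
    phewas: pd.DataFrame | None
    manifest: dict
    out_dir: Path


def _assoc_row(label: str, model: str, res: AssocResult, counts: GenotypeCounts) -> dict:
    return dict(
        exposure=label,
        model=model,
        case_ref=counts.cases[0], case_het=counts.cases[1], case_rec=counts.cases[2],
        ctrl_ref=counts.controls[0], ctrl_het=counts.controls[1], ctrl_rec=counts.controls[2],
        odds_ratio=res.odds_ratio, ci_low=res.ci_low, ci_high=res.ci_high,
        p_value=res.p_value, undefined=res.undefined, haldane_or=res.haldane_or,
        method=res.method,
    )


def association_grid(
    matrix: GenotypeMatrix,
    diplotypes: dict,
    case_flags: dict[str, bool],
    common_risk: tuple[str, ...] = DEFAULT_COMMON_RISK,
    include_putative: bool = True,
    models: tuple[str, ...] = ("additive", "genotypic", "recessive"),
) -> pd.DataFrame:
    """Per-variant, compound-het, and composite genetic-model odds ratios.

    One row per (exposure, model): each common-risk variant under the
    additive / genotypic het / genotypic hom / recessive codings, the
    compound-het-only exposure under the recessive coding, and the
    composite exposure pooling the common-risk alleles.
    """
    rows: list[dict] = []

    def run_models(counts: GenotypeCounts):
        if "additive" in models:
            rows.append(_assoc_row(counts.label, "additive", or_additive(counts), counts))
        if "genotypic" in models:
            het, hom = or_genotypic(counts)
            rows.append(_assoc_row(counts.label, "genotypic_het", het, counts))
            rows.append(_assoc_row(counts.label, "genotypic_hom", hom, counts))
        if "recessive" in models:
            rows.append(_assoc_row(counts.label, "recessive", or_recessive(counts), counts))

    present = {v.label for v in matrix.variants}
    for lab in common_risk:
        if lab not in present:
            continue
        counts = build_genotype_counts(
            case_flags, matrix=matrix, variant=lab, mode="variant", label=lab
        )
        run_models(counts)

    chet = build_genotype_counts(
        case_flags, diplotypes=diplotypes, mode="chet",
        include_putative=include_putative, label="compound_het",
    )
    rows.append(_assoc_row("compound_het", "recessive", or_recessive(chet), chet))

    composite = composite_counts(matrix, diplotypes, case_flags, common_risk, include_putative)
    run_models(composite)
    return pd.DataFrame(rows)


def composite_counts(
    matrix: GenotypeMatrix,
    diplotypes: dict,
    case_flags: dict[str, bool],
    common_risk: tuple[str, ...] = DEFAULT_COMMON_RISK,
    include_putative: bool = True,
) -> GenotypeCounts:
    """Pool the common-risk alleles into one exposure: biallelic = hom for
    any pooled allele or compound-het for any combination; het = carriers
    of exactly one pooled allele."""
    idx = [matrix.variant_index(l) for l in common_risk if l in {v.label for v in matrix.variants}]
    tall = {True: [0, 0, 0], False: [0, 0, 0]}
    for i, s in enumerate(matrix.samples):
        if s not in case_flags:
            continue
        doses = [int(matrix.calls[i, j]) for j in idx]
        doses = [d for d in doses if d >= 0]
        n_alt = sum(doses)
        call = diplotypes.get(s)
        chet_cats = {"CHET_CONFIRMED"} | ({"CHET_PUTATIVE"} if include_putative else set())
        is_chet_of_pool = (
            call is not None
            and call.category in chet_cats
            and sum(1 for l in call.variants if l in common_risk) >= 2
        )
        if any(d == 2 for d in doses) or is_chet_of_pool:
            code = 2
        elif n_alt >= 1:
            code = 1
        else:
            code = 0
        tall[case_flags[s]][code] += 1
    return GenotypeCounts(
        cases=tuple(tall[True]), controls=tuple(tall[False]), label="composite"
    )


def run_pipeline(config: PipelineConfig) -> RunBundle:
    """Execute the full analysis and write the report bundle to
    ``config.out_dir`` (diplotypes, association, burden, optional PheWAS,
    exclusion cascade, manifest)."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs
    try:
        if config.simulate is not None:
            cohort = simulate_cohort(config.simulate)
            pedigree, matrix, phenotypes = cohort.pedigree, cohort.matrix, cohort.phenotypes
            cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            write_vcf(matrix, out / "cohort.vcf")
            write_pedigree(pedigree, out / "cohort.fam")
            write_phenotypes(phenotypes, out / "cohort_phenotypes.tsv")
        else:
            if not (config.vcf and config.phenotypes):
                raise ValueError("need vcf+phenotypes paths or a simulate block")
            matrix = read_vcf(config.vcf)
            pedigree = read_pedigree(config.pedigree) if config.pedigree else None
            phenotypes = read_phenotypes(config.phenotypes)
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    # --- classify
    try:
        mask = build_class_mask(
            matrix, pedigree=pedigree, common_risk=config.common_risk,
            lowfreq_ceiling=config.maf_ceiling, lowfreq_inclusive=config.maf_inclusive,
        )
        mask.to_tsv(out / "variant_classes.tsv")
        qualifying = {
            cs: select_burden_variants(
                mask, matrix, class_set=cs, maf_ceiling=config.maf_ceiling,
                maf_inclusive=config.maf_inclusive,
            )
            for cs in config.class_sets
        }
    except Exception as exc:
        raise StageError("classify", exc) from exc

    # --- phase + call (on the widest class set)
    try:
        widest = (
            "plof_plus_pdns" if "plof_plus_pdns" in qualifying else config.class_sets[0]
        )
        diplotypes, cascade, phase_log = call_diplotypes(
            config.gene, qualifying[widest], matrix, pedigree=pedigree,
            config=config.phasing,
        )
        dip_rows = [
            dict(
                sample=s, gene=c.gene, category=c.category,
                variants=";".join(c.variants), evidence=c.evidence,
                burden_code=c.burden_code(include_putative=config.phasing.include_putative),
            )
            for s, c in diplotypes.items()
        ]
        pd.DataFrame(dip_rows).to_csv(out / "diplotypes.tsv", sep="\t", index=False)
        cascade_counts = cascade.counts()
        for step, n in cascade_counts.items():
            logger.info("cascade %s: %d", step, n)
        with open(out / "cascade.json", "w") as fh:
            json.dump(cascade_counts, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise StageError("phase", exc) from exc

    # --- case definitions
    try:
        case_flags = define_cases(phenotypes, config.case_definition)
        case_flags = {s: case_flags[s] for s in matrix.samples if s in case_flags}
    except Exception as exc:
        raise StageError("cases", exc) from exc

    # --- association grid + burden
    try:
        assoc = association_grid(
            matrix, diplotypes, case_flags, common_risk=config.common_risk,
            include_putative=config.phasing.include_putative, models=config.models,
        )
        assoc.to_csv(out / "association.tsv", sep="\t", index=False)
        burden_rows = []
        for cs, idx in qualifying.items():
            calls_cs, _, _ = call_diplotypes(
                config.gene, idx, matrix, pedigree=pedigree, config=config.phasing
            )
            for model in ("additive", "recessive"):
                try:
                    res = burden_test(
                        calls_cs, case_flags, class_set=cs, model=model,
                        include_putative=config.phasing.include_putative,
                    )
                except ValueError as err:
                    logger.warning("burden %s/%s skipped: %s", cs, model, err)
                    continue
                burden_rows.append(
                    dict(
                        class_set=cs, model=model, beta=res.beta, se=res.se,
                        odds_ratio=res.odds_ratio, ci_low=res.ci_low,
                        ci_high=res.ci_high, p_value=res.p_value,
                        case_ref=res.counts.cases[0], case_het=res.counts.cases[1],
                        case_rec=res.counts.cases[2],
                        ctrl_ref=res.counts.controls[0], ctrl_het=res.counts.controls[1],
                        ctrl_rec=res.counts.controls[2],
                        n_iter=res.n_iter,
                    )
                )
        burden = pd.DataFrame(burden_rows)
        burden.to_csv(out / "burden.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("association", exc) from exc

    # --- PheWAS
    phewas_frame = None
    if config.run_phewas:
        try:
            exposure = {
                s: diplotypes[s].burden_code(config.phasing.include_putative) == 2
                for s in diplotypes
                if s in phenotypes
            }
            phewas_frame = run_phewas(
                exposure,
                PhenotypeTable(records={s: phenotypes[s] for s in exposure}),
                prefix_length=config.phewas_prefix_length,
            )
            phewas_frame.to_csv(out / "phewas.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError("phewas", exc) from exc

    manifest = dict(
        package="recburden",
        version=__version__,
        seed=config.seed,
        config_hash=config.config_hash(),
        config=config.canonical_dict(),
        cascade=cascade.counts(),
        n_samples=matrix.n_samples,
        n_variants=matrix.n_variants,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunBundle(
        diplotypes=diplotypes, cascade=cascade, association=assoc, burden=burden,
        phewas=phewas_frame, manifest=manifest, out_dir=out,
    )


# ---------------------------------------------------------------------------
# deterministic fixtures from printed count tables


def make_fixture_cohort(
    counts: GenotypeCounts,
    variant: Variant | None = None,
) -> tuple[GenotypeMatrix, PhenotypeTable, dict[str, bool]]:
    """Expand a case/control × {ref, het, hom} count table into a minimal
    deterministic cohort whose per-variant breakdown equals the table.

    Case samples receive two qualifying IBD encounter diagnoses so the
    standard case definition recovers exactly the declared case arm.
    Returns (matrix, phenotypes, case_flags).
    """
    if variant is None:
        variant = Variant(
            chrom="16", pos=50_744_000, ref_allele="A", alt_allele="T",
            label="fixture_variant", gene="NOD2", consequence="missense",
            deleterious_votes=(True,) * 5,
        )
    samples: list[str] = []
    dosages: list[int] = []
    case_flags: dict[str, bool] = {}
    records: dict[str, SampleRecord] = {}
    k = 0
    for arm, is_case in ((counts.controls, False), (counts.cases, True)):
        for dose, n in enumerate(arm):
            for _ in range(n):
                k += 1
                s = f"X{k:07d}"
                samples.append(s)
                dosages.append(dose)
                case_flags[s] = is_case
                events = []
                if is_case:
                    events = [
                        DiagnosisEvent(s, "K50.9", "ICD10", date(2010, 1, 6), "encounter"),
                        DiagnosisEvent(s, "K50.9", "ICD10", date(2010, 3, 2), "encounter"),
                    ]
                records[s] = SampleRecord(
                    sample=s, birth_date=date(1970, 1, 1), sex=0,
                    affection="CD" if is_case else "unaffected", events=events,
                )
    calls = np.array(dosages, dtype=np.int8).reshape(-1, 1)
    matrix = GenotypeMatrix(samples=samples, variants=[variant], calls=calls)
    return matrix, PhenotypeTable(records=records), case_flags
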