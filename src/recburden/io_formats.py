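"""Data model and file formats for the recessive-burden pipeline.

The pipeline works on a single-gene variant panel, so the in-memory
containers are deliberately small: a :class:`Variant` carries the
functional annotation the analysis consumes (consequence class, the five
deleteriousness-predictor votes, an optional external allele frequency);
a :class:`GenotypeMatrix` holds unphased allele dosages (0/1/2/missing)
for samples × variants together with optional per-call depth and allele
balance; :class:`Pedigree` and :class:`PhenotypeTable` hold family
structure and longitudinal diagnosis-code streams.

Files are the standard plain-text formats: VCF v4.2 (read with cyvcf2,
written directly), 6-column PED/FAM, and a long-format phenotype TSV.
Phase is *never* read from ``|`` separators: the phasing module derives
it from pedigrees and population haplotype frequencies.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1  # dosage code for a missing genotype

CONSEQUENCES = {
    "missense",
    "stop_gain",
    "start_loss",
    "stop_loss",
    "splice_donor",
    "splice_acceptor",
    "frameshift",
    "inframe_indel",
    "synonymous",
    "other",
}

PREDICTOR_NAMES = ("SIFT", "LRT", "MutationTaster", "PolyPhen2_HumDiv", "PolyPhen2_HumVar")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class Variant:
    """One annotated alternate allele at a site."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    label: str
    gene: str = ""
    consequence: str = "other"
    deleterious_votes: tuple[bool, ...] = (False,) * 5
    maf_external: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if len(self.deleterious_votes) != 5:
            raise ValueError("deleterious_votes must have exactly 5 entries")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.maf_external is not None and not (0.0 <= self.maf_external <= 0.5):
            raise ValueError(f"maf_external out of [0, 0.5]: {self.maf_external}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class GenotypeMatrix:
    """Unphased allele-dosage matrix (samples × variants).

    ``calls`` uses 0/1/2 for allele dosage and -1 for missing.  ``depth``
    and ``allele_balance`` (alt-read fraction) are optional per-call QC
    arrays with NaN where unavailable.
    """

    samples: list[str]
    variants: list[Variant]
    calls: np.ndarray
    depth: np.ndarray | None = None
    allele_balance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        expect = (len(self.samples), len(self.variants))
        if self.calls.shape != expect:
            raise ValueError(f"calls shape {self.calls.shape} != samples×variants {expect}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosage codes outside {{0,1,2,missing}}: {np.unique(self.calls[bad])}")
        for name in ("depth", "allele_balance"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != expect:
                    raise ValueError(f"{name} shape {arr.shape} != {expect}")
                setattr(self, name, arr)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample: str) -> int:
        lut = self.__dict__.get("_sample_lut")
        if lut is None or len(lut) != len(self.samples):
            lut = {s: i for i, s in enumerate(self.samples)}
            self.__dict__["_sample_lut"] = lut
        try:
            return lut[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def variant_index(self, label: str) -> int:
        lut = self.__dict__.get("_variant_lut")
        if lut is None or len(lut) != len(self.variants):
            lut = {v.label: i for i, v in enumerate(self.variants)}
            self.__dict__["_variant_lut"] = lut
        try:
            return lut[label]
        except KeyError:
            raise KeyError(f"variant {label!r} not in matrix") from None

    def dosage(self, sample: str, label: str) -> int:
        return int(self.calls[self.sample_index(sample), self.variant_index(label)])

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            depth=None if self.depth is None else self.depth[:, idx].copy(),
            allele_balance=None
            if self.allele_balance is None
            else self.allele_balance[:, idx].copy(),
        )


@dataclass(frozen=True)
class Individual:
    iid: str
    fid: str
    father: str | None
    mother: str | None
    sex: int  # 1 male, 2 female, 0 unknown

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """Family structure; founder = both parents absent."""

    individuals: dict[str, Individual]

    def __post_init__(self) -> None:
        for ind in self.individuals.values():
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self.individuals:
                    raise FormatError(
                        f"individual {ind.iid!r} references absent parent {parent!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in self.individuals:
            if start in state:
                continue
            stack = [(start, iter(self._parent_ids(start)))]
            state[start] = 0
            while stack:
                iid, parents = stack[-1]
                advanced = False
                for p in parents:
                    if state.get(p) == 0:
                        raise FormatError(f"cyclic parentage involving {p!r}")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(self._parent_ids(p))))
                        advanced = True
                        break
                if not advanced:
                    state[iid] = 1
                    stack.pop()

    def _parent_ids(self, iid: str) -> list[str]:
        ind = self.individuals[iid]
        return [p for p in (ind.father, ind.mother) if p is not None]

    @property
    def founders(self) -> list[str]:
        return [iid for iid, ind in self.individuals.items() if ind.is_founder]

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        ind = self.individuals[iid]
        return ind.father, ind.mother

    def unrelated_set(self) -> list[str]:
        """Founders plus singletons: one generation of nominally unrelated samples."""
        return self.founders

    def complete_trios(self) -> list[tuple[str, str, str]]:
        """(child, father, mother) for every individual with both parents present."""
        return [
            (ind.iid, ind.father, ind.mother)
            for ind in self.individuals.values()
            if ind.father is not None and ind.mother is not None
        ]


@dataclass(frozen=True)
class DiagnosisEvent:
    sample: str
    code: str
    system: str  # "ICD9" | "ICD10"
    date: date
    source: str = "encounter"  # "problem_list" | "encounter"

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("empty diagnosis code")
        if self.source not in ("problem_list", "encounter"):
            raise ValueError(f"unknown source {self.source!r}")


AFFECTION_LABELS = ("CD", "UC", "IBDU", "unaffected", "unknown")


@dataclass
class SampleRecord:
    sample: str
    birth_date: date
    sex: int = 0
    affection: str = "unknown"
    events: list[DiagnosisEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.affection not in AFFECTION_LABELS:
            raise ValueError(f"unknown affection label {self.affection!r}")


@dataclass
class PhenotypeTable:
    records: dict[str, SampleRecord]

    def __post_init__(self) -> None:
        for rec in self.records.values():
            for ev in rec.events:
                if ev.sample != rec.sample:
                    raise ValueError(
                        f"event sample {ev.sample!r} filed under record {rec.sample!r}"
                    )

    @property
    def samples(self) -> list[str]:
        return list(self.records)

    def __contains__(self, sample: str) -> bool:
        return sample in self.records

    def __getitem__(self, sample: str) -> SampleRecord:
        return self.records[sample]

    def case_flags(self, case_samples: Iterable[str]) -> dict[str, bool]:
        flagged = set(case_samples)
        return {s: (s in flagged) for s in self.records}


# ---------------------------------------------------------------------------
# VCF


@dataclass(frozen=True)
class AnnotationKeys:
    """INFO keys carrying the functional annotation (per alt allele, Number=A)."""

    gene: str = "GENE"
    label: str = "AA"
    consequence: str = "CSQ"
    votes: str = "PRED"  # five characters, D = deleterious (e.g. "DDDTT")
    maf_external: str = "EXTMAF"


def _parse_votes(text: str | None) -> tuple[bool, ...]:
    if not text or text == ".":
        return (False,) * 5
    text = text.strip()
    if len(text) != 5:
        logger.warning("predictor vote string %r does not have 5 entries; missing -> benign", text)
        text = (text + "TTTTT")[:5]
    return tuple(ch == "D" for ch in text)


def _per_alt(value, n_alt: int, j: int):
    """Pick the j-th entry of a Number=A INFO value (scalar when n_alt == 1)."""
    if value is None:
        return None
    if isinstance(value, (tuple, list, np.ndarray)):
        return value[j] if j < len(value) else None
    if isinstance(value, str) and n_alt > 1:
        parts = value.split(",")
        return parts[j] if j < len(parts) else None
    return value if (n_alt == 1 or j == 0) else None


def read_vcf(
    path: str | os.PathLike,
    annotation_keys: AnnotationKeys = AnnotationKeys(),
    annotations: Mapping[tuple[str, int, str, str], Mapping] | None = None,
) -> GenotypeMatrix:
    """Read a VCF v4.x into a :class:`GenotypeMatrix`.

    Multi-allelic records are split into one :class:`Variant` per alt
    allele; the per-sample dosage for alt *j* is the number of GT alleles
    equal to *j*.  Phased and unphased separators are treated alike.  A
    genotype with any missing allele maps to missing.  ``annotations``
    optionally supplies a side table keyed by (chrom, pos, ref, alt) that
    overrides INFO-derived annotation.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(os.fspath(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    variants: list[Variant] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    ab_cols: list[np.ndarray] = []
    any_depth = False
    any_ab = False

    for rec in vcf:
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        try:
            ab = rec.format("AB")
        except KeyError:
            ab = None
        alts = rec.ALT or []
        for j, alt in enumerate(alts):
            side = annotations.get((rec.CHROM, rec.POS, rec.REF, alt)) if annotations else None

            def anno(field_name: str, info_key: str):
                if side is not None and field_name in side:
                    return side[field_name]
                return _per_alt(rec.INFO.get(info_key), len(alts), j)

            csq = anno("consequence", annotation_keys.consequence)
            csq = str(csq) if csq is not None else "other"
            if csq not in CONSEQUENCES:
                logger.warning("unknown consequence %r at %s:%s mapped to 'other'", csq, rec.CHROM, rec.POS)
                csq = "other"
            votes = anno("deleterious_votes", annotation_keys.votes)
            if not isinstance(votes, tuple):
                votes = _parse_votes(votes if votes is None else str(votes))
            maf = anno("maf_external", annotation_keys.maf_external)
            maf = None if maf in (None, ".") else float(maf)
            label = anno("label", annotation_keys.label)
            gene = anno("gene", annotation_keys.gene)
            variants.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref_allele=rec.REF,
                    alt_allele=alt,
                    label=str(label) if label is not None else f"{rec.CHROM}:{rec.POS}:{rec.REF}>{alt}",
                    gene=str(gene) if gene is not None else "",
                    consequence=csq,
                    deleterious_votes=votes,
                    maf_external=maf,
                )
            )
            col = np.empty(len(samples), dtype=np.int8)
            for i, gt in enumerate(gts):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    col[i] = MISSING
                else:
                    col[i] = sum(1 for a in alleles if a == j + 1)
            dosage_cols.append(col)
            if dp is not None:
                any_depth = True
                depth_cols.append(np.asarray(dp, dtype=float).reshape(-1))
            else:
                depth_cols.append(np.full(len(samples), np.nan))
            if ab is not None:
                any_ab = True
                ab_cols.append(np.asarray(ab, dtype=float).reshape(-1))
            else:
                ab_cols.append(np.full(len(samples), np.nan))

    calls = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        calls=calls,
        depth=np.column_stack(depth_cols) if (dosage_cols and any_depth) else None,
        allele_balance=np.column_stack(ab_cols) if (dosage_cols and any_ab) else None,
    )


def _chrom_sort_key(chrom: str):
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


_GT_FOR_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | os.PathLike,
    annotation_keys: AnnotationKeys = AnnotationKeys(),
) -> None:
    """Write a VCF v4.2 with GT (+DP/AB when present) and annotation INFO keys.

    Records are sorted by (chrom, pos); chromosome labels must not mix
    'chr'-prefixed and bare names.
    """
    prefixed = {v.chrom for v in matrix.variants if v.chrom.lower().startswith("chr")}
    bare = {v.chrom for v in matrix.variants if not v.chrom.lower().startswith("chr")}
    if prefixed and bare:
        raise FormatError(
            f"unsortable chromosome mix: {sorted(prefixed)} vs {sorted(bare)}"
        )
    order = sorted(range(matrix.n_variants), key=lambda i: (_chrom_sort_key(matrix.variants[i].chrom), matrix.variants[i].pos))

    ak = annotation_keys
    has_depth = matrix.depth is not None
    has_ab = matrix.allele_balance is not None
    fmt = "GT" + (":DP" if has_depth else "") + (":AB" if has_ab else "")
    lines = [
        "##fileformat=VCFv4.2",
        f'##INFO=<ID={ak.gene},Number=A,Type=String,Description="Gene symbol">',
        f'##INFO=<ID={ak.label},Number=A,Type=String,Description="Protein notation">',
        f'##INFO=<ID={ak.consequence},Number=A,Type=String,Description="Functional consequence">',
        f'##INFO=<ID={ak.votes},Number=A,Type=String,Description="Five deleteriousness predictor votes (D/T): '
        + ",".join(PREDICTOR_NAMES)
        + '">',
        f'##INFO=<ID={ak.maf_external},Number=A,Type=Float,Description="External reference MAF">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if has_depth:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    if has_ab:
        lines.append('##FORMAT=<ID=AB,Number=1,Type=Float,Description="Alt allele balance">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + "\t".join(["FORMAT"] + matrix.samples)
                 if matrix.samples
                 else "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    for i in order:
        v = matrix.variants[i]
        info = ";".join(
            [
                f"{ak.gene}={v.gene or '.'}",
                f"{ak.label}={v.label}",
                f"{ak.consequence}={v.consequence}",
                f"{ak.votes}={''.join('D' if d else 'T' for d in v.deleterious_votes)}",
            ]
            + ([f"{ak.maf_external}={v.maf_external:.6g}"] if v.maf_external is not None else [])
        )
        cols = [v.chrom, str(v.pos), v.label, v.ref_allele, v.alt_allele, ".", "PASS", info]
        if matrix.samples:
            cols.append(fmt)
            for s in range(matrix.n_samples):
                parts = [_GT_FOR_DOSAGE[int(matrix.calls[s, i])]]
                if has_depth:
                    d = matrix.depth[s, i]
                    parts.append("." if np.isnan(d) else str(int(d)))
                if has_ab:
                    b = matrix.allele_balance[s, i]
                    parts.append("." if np.isnan(b) else f"{b:.4g}")
                cols.append(":".join(parts))
        lines.append("\t".join(cols))

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED / FAM


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read a 6-column PED/FAM file; '0' denotes an absent parent.

    The phenotype column is ignored — affection status comes from the
    phenotype table, not the pedigree.
    """
    individuals: dict[str, Individual] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            fid, iid, father, mother, sex, _pheno = fields[:6]
            if iid in individuals:
                raise FormatError(f"{path}:{lineno}: duplicated individual id {iid!r}")
            individuals[iid] = Individual(
                iid=iid,
                fid=fid,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                sex=int(sex) if sex in ("0", "1", "2") else 0,
            )
    return Pedigree(individuals=individuals)


def write_pedigree(pedigree: Pedigree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for ind in pedigree.individuals.values():
            fh.write(
                f"{ind.fid}\t{ind.iid}\t{ind.father or 0}\t{ind.mother or 0}\t{ind.sex}\t-9\n"
            )


# ---------------------------------------------------------------------------
# Phenotype TSV (long format)

_PHENO_COLUMNS = ["sample", "birth_date", "sex", "code_system", "code", "event_date", "source"]


def _parse_date(text: str, path, lineno: int) -> date:
    try:
        return datetime.strptime(text, "%Y-%m-%d").date()
    except ValueError:
        raise FormatError(f"{path}:{lineno}: unparseable date {text!r} (expected YYYY-MM-DD)") from None


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    """Read the long-format phenotype TSV.

    Columns: sample, birth_date, sex, code_system, code, event_date,
    source, and optionally affection.  A sample row with an empty code
    declares the sample without any diagnosis event.
    """
    records: dict[str, SampleRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing_cols = [c for c in _PHENO_COLUMNS if c not in header]
        if missing_cols:
            raise FormatError(f"{path}: missing columns {missing_cols}")
        col = {name: header.index(name) for name in header}
        has_affection = "affection" in col
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            sample = fields[col["sample"]]
            if sample not in records:
                records[sample] = SampleRecord(
                    sample=sample,
                    birth_date=_parse_date(fields[col["birth_date"]], path, lineno),
                    sex=int(fields[col["sex"]] or 0),
                    affection=(fields[col["affection"]] or "unknown") if has_affection else "unknown",
                )
            code = fields[col["code"]]
            if code:
                records[sample].events.append(
                    DiagnosisEvent(
                        sample=sample,
                        code=code,
                        system=fields[col["code_system"]],
                        date=_parse_date(fields[col["event_date"]], path, lineno),
                        source=fields[col["source"]],
                    )
                )
    return PhenotypeTable(records=records)


def write_phenotypes(table: PhenotypeTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PHENO_COLUMNS + ["affection"]) + "\n")
        for rec in table.records.values():
            base = [rec.sample, rec.birth_date.isoformat(), str(rec.sex)]
            if not rec.events:
                fh.write("\t".join(base + ["", "", "", "", rec.affection]) + "\n")
            for ev in rec.events:
                fh.write(
                    "\t".join(base + [ev.system, ev.code, ev.date.isoformat(), ev.source, rec.affection])
                    + "\n"
                )
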