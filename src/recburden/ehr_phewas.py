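"""ICD-code case definitions, onset ages, diagnosis-conflict and lead-time
summaries, and a phenome-wide association scan.

The IBD case definition mirrors clinical-cohort practice: a sample is a
case when its record contains a problem-list entry for a qualifying
code, or encounter diagnoses for qualifying codes on at least two
separate calendar days.  Qualifying codes are prefix families per code
system (ICD-9 555*/556*, ICD-10 K50*/K51* by default); the two systems
are matched independently, with no cross-walk.

The PheWAS groups every recorded code at a configurable prefix length
(3 characters by default), applies the same two-encounter rule per
grouped code, and tests each against a biallelic-carrier indicator by
Fisher's exact test with Bonferroni (or Benjamini–Hochberg) correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .association import fisher_exact_p
from .io_formats import DiagnosisEvent, PhenotypeTable

DAYS_PER_YEAR = 365.25

CD_PREFIXES = (("ICD9", "555"), ("ICD10", "K50"))
UC_PREFIXES = (("ICD9", "556"), ("ICD10", "K51"))
IBD_PREFIXES = CD_PREFIXES + UC_PREFIXES


@dataclass(frozen=True)
class CaseDefinition:
    """Prefix families + the two-separate-calendar-days encounter rule."""

    prefixes: tuple[tuple[str, str], ...] = IBD_PREFIXES  # (system, prefix)
    min_distinct_days: int = 2
    sources: tuple[str, ...] = ("problem_list", "encounter")

    def __post_init__(self) -> None:
        if not self.prefixes:
            raise ValueError("need at least one code prefix")
        if self.min_distinct_days < 1:
            raise ValueError("min_distinct_days must be >= 1")

    def matches(self, event: DiagnosisEvent) -> bool:
        return any(
            event.system == system and event.code.startswith(prefix)
            for system, prefix in self.prefixes
        )


def _matching_events(events: list[DiagnosisEvent], definition: CaseDefinition):
    return [e for e in events if e.source in definition.sources and definition.matches(e)]


def is_case(events: list[DiagnosisEvent], definition: CaseDefinition) -> bool:
    matching = _matching_events(events, definition)
    if any(e.source == "problem_list" for e in matching):
        return True
    days = {e.date for e in matching if e.source == "encounter"}
    return len(days) >= definition.min_distinct_days


def define_cases(
    phenotypes: PhenotypeTable, definition: CaseDefinition = CaseDefinition()
) -> dict[str, bool]:
    """Case flag per sample under the prefix/two-encounter definition."""
    return {s: is_case(rec.events, definition) for s, rec in phenotypes.records.items()}


def first_diagnosis_age(
    events: list[DiagnosisEvent],
    birth_date: date,
    prefixes: tuple[tuple[str, str], ...] = IBD_PREFIXES,
) -> tuple[float | None, dict]:
    """Age in years (365.25-day years) at the earliest matching event.

    Returns (age, flags) where flags marks pediatric (< 18) and early
    (< 30) onset; (None, {"reason": ...}) when no code matches.
    """
    definition = CaseDefinition(prefixes=prefixes, min_distinct_days=1)
    matching = [e for e in events if definition.matches(e)]
    if not matching:
        return None, {"reason": "no matching diagnosis codes"}
    first = min(e.date for e in matching)
    if first < birth_date:
        raise ValueError(f"diagnosis event {first} predates birth {birth_date}")
    age = (first - birth_date).days / DAYS_PER_YEAR
    return age, {"pediatric": age < 18.0, "early": age < 30.0}


def flag_conflicting_diagnoses(phenotypes: PhenotypeTable) -> list[str]:
    """Samples carrying both CD-family and UC-family codes.

    Resolution is not attempted — conflicting charts go to manual review.
    """
    cd = CaseDefinition(prefixes=CD_PREFIXES, min_distinct_days=1)
    uc = CaseDefinition(prefixes=UC_PREFIXES, min_distinct_days=1)
    out = []
    for s, rec in phenotypes.records.items():
        if any(cd.matches(e) for e in rec.events) and any(uc.matches(e) for e in rec.events):
            out.append(s)
    return out


@dataclass
class LeadTimeSummary:
    per_sample: pd.DataFrame  # sample, lead_years (positive = comorbidity earlier)
    proportion_prior: float | None  # comorbidity on/before the index diagnosis
    mean_positive_lead: float | None  # mean lead among strictly positive leads


def diagnosis_lead_time(
    phenotypes: PhenotypeTable,
    index_prefixes: tuple[tuple[str, str], ...] = IBD_PREFIXES,
    comorbidity_prefixes: tuple[tuple[str, str], ...] = (("ICD10", "D50"),),
) -> LeadTimeSummary:
    """Lead time of a comorbidity relative to the index diagnosis.

    lead = (first index date − first comorbidity date) in years; positive
    means the comorbidity came first.  Samples lacking either code family
    are omitted.
    """
    index_def = CaseDefinition(prefixes=index_prefixes, min_distinct_days=1)
    com_def = CaseDefinition(prefixes=comorbidity_prefixes, min_distinct_days=1)
    rows = []
    for s, rec in phenotypes.records.items():
        idx_dates = [e.date for e in rec.events if index_def.matches(e)]
        com_dates = [e.date for e in rec.events if com_def.matches(e)]
        if not idx_dates or not com_dates:
            continue
        lead = (min(idx_dates) - min(com_dates)).days / DAYS_PER_YEAR
        rows.append((s, lead))
    frame = pd.DataFrame(rows, columns=["sample", "lead_years"])
    if frame.empty:
        return LeadTimeSummary(frame, None, None)
    prior = float((frame.lead_years >= 0).mean())
    pos = frame.lead_years[frame.lead_years > 0]
    return LeadTimeSummary(frame, prior, float(pos.mean()) if len(pos) else None)


@dataclass(frozen=True)
class PhewasRow:
    code: str
    system: str
    n_exposed_cases: int
    n_exposed_noncases: int
    n_unexposed_cases: int
    n_unexposed_noncases: int
    odds_ratio: float | None
    p_value: float
    p_adjusted: float
    significant: bool


def run_phewas(
    exposure: dict[str, bool],
    phenotypes: PhenotypeTable,
    prefix_length: int = 3,
    correction: str = "bonferroni",
    alpha: float = 0.05,
    min_distinct_days: int = 2,
) -> pd.DataFrame:
    """Scan every grouped diagnosis code against a genotype indicator.

    ``exposure`` maps sample → biallelic-carrier flag (must cover every
    phenotyped sample).  Per grouped code the same two-encounter case
    rule defines code-cases, then a 2×2 Fisher exact test against the
    indicator.  Codes with no code-cases are skipped.  Rows sorted by p.
    """
    samples = [s for s in phenotypes.records if s in exposure]
    missing = [s for s in phenotypes.records if s not in exposure]
    if missing:
        raise ValueError(f"exposure undefined for {len(missing)} samples, e.g. {missing[:3]}")

    groups: set[tuple[str, str]] = set()
    for s in samples:
        for e in phenotypes[s].events:
            groups.add((e.system, e.code[:prefix_length]))

    rows = []
    exp_arr = np.array([exposure[s] for s in samples], dtype=bool)
    for system, prefix in sorted(groups):
        definition = CaseDefinition(
            prefixes=((system, prefix),), min_distinct_days=min_distinct_days
        )
        flags = np.array([is_case(phenotypes[s].events, definition) for s in samples])
        if not flags.any():
            continue
        a = int((exp_arr & flags).sum())
        b = int((exp_arr & ~flags).sum())
        c = int((~exp_arr & flags).sum())
        d = int((~exp_arr & ~flags).sum())
        p = fisher_exact_p([[a, b], [c, d]])
        odds = (a * d) / (b * c) if min(a, b, c, d) > 0 else None
        rows.append(dict(code=prefix, system=system, n_exposed_cases=a,
                         n_exposed_noncases=b, n_unexposed_cases=c,
                         n_unexposed_noncases=d, odds_ratio=odds, p_value=p))
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
    reject, p_adj, _, _ = multipletests(frame.p_value, alpha=alpha, method=method)
    frame["p_adjusted"] = p_adj
    frame["significant"] = reject
    return frame.sort_values("p_value", kind="stable").reset_index(drop=True)


def phewas_manhattan(frame: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Optional Manhattan-style plot of the PheWAS (-log10 p per code)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.2))
    x = np.arange(len(frame))
    ax.scatter(x, -np.log10(frame.p_value), s=12)
    n = max(len(frame), 1)
    ax.axhline(-np.log10(alpha / n), color="red", ls="--", lw=0.8)
    ax.set_xticks(x)
    ax.set_xticklabels(frame.code, rotation=90, fontsize=6)
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
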