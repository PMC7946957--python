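"""Genetic-model contingency statistics and Firth-penalized burden regression.

Per-variant (and compound-heterozygote, and composite) disease risk is
estimated from case/control genotype counts under four codings:

* additive — allele-level 2×2 (each individual contributes two alleles);
* genotypic heterozygous — het vs homozygous-reference individuals;
* genotypic homozygous — biallelic (hom or compound-het) vs reference;
* recessive — biallelic vs everyone else.

Every contingency estimate is the unconditional cross-product odds
ratio with a Woolf (log-normal) 95% CI and a two-sided Fisher exact
p-value; this triplet reproduces the published per-variant grids at
two-decimal precision.  Tables with a zero cell are flagged undefined
and a Haldane–Anscombe (+0.5) estimate is reported alongside, never
silently substituted.

The gene-burden test regresses case status on the 0/1/2 diplotype code
(additive) or on the biallelic indicator (recessive) by Firth-penalized
logistic regression — maximizing ℓ(β) + ½·log det I(β) — which keeps
estimates finite under separation and reduces small-sample bias.  On a
2×2 design the Firth maximizer coincides with the +0.5-cell estimator;
that closed form serves as an independent oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class GenotypeCounts:
    """Case/control × {ref, het, biallelic} contingency counts."""

    cases: tuple[int, int, int]  # (n_ref, n_het, n_rec)
    controls: tuple[int, int, int]
    label: str = ""

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.cases + self.controls):
            raise ValueError("negative genotype count")

    @property
    def n_cases(self) -> int:
        return sum(self.cases)

    @property
    def n_controls(self) -> int:
        return sum(self.controls)


@dataclass(frozen=True)
class AssocResult:
    model: str  # additive | genotypic_het | genotypic_hom | recessive | carrier
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    method: str = "fisher_exact"
    table: tuple[int, int, int, int] | None = None  # (case_exposed, case_base, ctrl_exposed, ctrl_base)
    undefined: bool = False
    haldane_or: float | None = None
    label: str = ""
    #: companion uncorrected Pearson chi-square p.  Published per-variant
    #: grids of this kind are often labelled "Fisher" while actually
    #: printing the uncorrected chi-square p; both are reported so either
    #: convention can be checked.
    p_chi2: float | None = None


@dataclass(frozen=True)
class BurdenResult:
    class_set: str
    model: str  # additive | recessive
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    counts: GenotypeCounts
    method: str = "firth"
    n_iter: int = 0
    converged: bool = True


# ---------------------------------------------------------------------------
# 2x2 machinery


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    all tables with fixed margins no more probable than the observed one."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def chi2_p(table) -> float | None:
    """Uncorrected Pearson chi-square p for a 2×2 table (None when a
    margin is zero)."""
    t = np.asarray(table)
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return None
    return float(stats.chi2_contingency(t, correction=False)[1])


def _or_2x2(a: int, b: int, c: int, d: int, model: str, label: str = "") -> AssocResult:
    """Cross-product OR + Woolf CI + Fisher p for the table [[a, b], [c, d]].

    a = exposed cases, b = baseline cases, c = exposed controls,
    d = baseline controls.
    """
    p = fisher_exact_p([[a, b], [c, d]])
    pc = chi2_p([[a, b], [c, d]])
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    if min(a, b, c, d) == 0:
        return AssocResult(
            model=model, odds_ratio=None, ci_low=None, ci_high=None, p_value=p,
            table=(a, b, c, d), undefined=True, haldane_or=haldane, label=label,
            p_chi2=pc,
        )
    odds_ratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(odds_ratio) - Z95 * se)
    hi = math.exp(math.log(odds_ratio) + Z95 * se)
    return AssocResult(
        model=model, odds_ratio=odds_ratio, ci_low=lo, ci_high=hi, p_value=p,
        table=(a, b, c, d), haldane_or=haldane, label=label, p_chi2=pc,
    )


def or_additive(counts: GenotypeCounts) -> AssocResult:
    """Allele-level 2×2: alt alleles = n_het + 2·n_rec per arm."""
    ca_alt = counts.cases[1] + 2 * counts.cases[2]
    ca_ref = 2 * counts.n_cases - ca_alt
    co_alt = counts.controls[1] + 2 * counts.controls[2]
    co_ref = 2 * counts.n_controls - co_alt
    return _or_2x2(ca_alt, ca_ref, co_alt, co_ref, "additive", counts.label)


def or_genotypic(counts: GenotypeCounts) -> tuple[AssocResult, AssocResult]:
    """(het vs ref, biallelic vs ref) against the homozygous-reference baseline."""
    het = _or_2x2(
        counts.cases[1], counts.cases[0], counts.controls[1], counts.controls[0],
        "genotypic_het", counts.label,
    )
    hom = _or_2x2(
        counts.cases[2], counts.cases[0], counts.controls[2], counts.controls[0],
        "genotypic_hom", counts.label,
    )
    return het, hom


def or_recessive(counts: GenotypeCounts) -> AssocResult:
    """Biallelic carriers vs everyone else (ref + het) per arm."""
    return _or_2x2(
        counts.cases[2], counts.cases[0] + counts.cases[1],
        counts.controls[2], counts.controls[0] + counts.controls[1],
        "recessive", counts.label,
    )


def or_carrier(counts: GenotypeCounts) -> AssocResult:
    """Any-carrier (het or biallelic) vs reference."""
    return _or_2x2(
        counts.cases[1] + counts.cases[2], counts.cases[0],
        counts.controls[1] + counts.controls[2], counts.controls[0],
        "carrier", counts.label,
    )


# ---------------------------------------------------------------------------
# genotype-count construction


def build_genotype_counts(
    case_flags: dict[str, bool],
    *,
    diplotypes=None,
    matrix=None,
    variant: str | None = None,
    mode: str = "burden",
    include_putative: bool = True,
    label: str = "",
) -> GenotypeCounts:
    """Assemble case/control genotype counts for one exposure definition.

    ``mode`` selects the exposure:

    * ``"variant"`` — dosage of ``variant`` in ``matrix`` (0/1/2; missing
      genotypes are dropped from both arms);
    * ``"burden"`` — the 0/1/2 diplotype burden codes from ``diplotypes``
      (a mapping sample → DiplotypeCall);
    * ``"chet"`` — compound-heterozygous samples as the biallelic class,
      all other samples as reference (no het class).
    """
    if mode == "variant":
        if matrix is None or variant is None:
            raise ValueError("variant mode needs matrix and variant")
        j = matrix.variant_index(variant)
        tall = {True: [0, 0, 0], False: [0, 0, 0]}
        for i, s in enumerate(matrix.samples):
            if s not in case_flags:
                continue
            d = int(matrix.calls[i, j])
            if d < 0:
                continue
            tall[case_flags[s]][d] += 1
    elif mode in ("burden", "chet"):
        if diplotypes is None:
            raise ValueError(f"{mode} mode needs diplotypes")
        tall = {True: [0, 0, 0], False: [0, 0, 0]}
        seen: set[str] = set()
        for s, call in diplotypes.items():
            if s not in case_flags:
                continue
            if s in seen:
                raise ValueError(f"sample {s!r} counted twice in exposure")
            seen.add(s)
            if mode == "burden":
                code = call.burden_code(include_putative=include_putative)
            else:
                is_chet = call.category in ("CHET_CONFIRMED",) or (
                    include_putative and call.category == "CHET_PUTATIVE"
                )
                code = 2 if is_chet else 0
            tall[case_flags[s]][code] += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GenotypeCounts(cases=tuple(tall[True]), controls=tuple(tall[False]), label=label or (variant or mode))


# ---------------------------------------------------------------------------
# Firth logistic regression


class FirthNonConvergence(RuntimeError):
    def __init__(self, trace):
        self.trace = trace
        super().__init__(f"Firth Newton iteration did not converge; last deltas {trace[-3:]}")


def firth_fit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    step_tol: float = 1e-10,
):
    """Maximize the Jeffreys-penalized logistic log-likelihood.

    ℓ*(β) = Σ w_i [y_i log p_i + (1−y_i) log(1−p_i)] + ½ log det X'WX,
    solved by Newton iteration on the hat-adjusted score
    U*(β) = Σ w_i (y_i − p_i + h_i(½ − p_i)) x_i with step-halving to keep
    the penalized likelihood non-decreasing.  Returns
    (beta, cov, n_iter, penalized log-likelihood).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)

    def pll(beta):
        eta = X @ beta
        # log-likelihood via logaddexp for numerical safety
        ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
        p = 1.0 / (1.0 + np.exp(-eta))
        W = w * p * (1 - p)
        sign, logdet = np.linalg.slogdet(X.T @ (X * W[:, None]))
        return ll + 0.5 * logdet

    beta = np.zeros(X.shape[1])
    trace = []
    current = pll(beta)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = w * p * (1 - p)
        info = X.T @ (X * W[:, None])
        info_inv = np.linalg.inv(info)
        h = W * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (w * (y - p) + h * (0.5 - p))
        step = info_inv @ score
        # step-halving: require a strict increase of the penalized target.
        # When no halved step improves it, the maximum is attained to
        # machine precision and the iteration stops there.
        scale = 1.0
        improved = False
        new = current
        for _ in range(25):
            cand = beta + scale * step
            new = pll(cand)
            if new > current:
                improved = True
                break
            scale /= 2.0
        if improved:
            beta = beta + scale * step
            current = new
        delta = float(np.max(np.abs(scale * step))) if improved else 0.0
        trace.append((it, delta, float(np.max(np.abs(score)))))
        if (not improved) or np.max(np.abs(score)) < score_tol or (0 < delta < step_tol):
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            W = w * p * (1 - p)
            cov = np.linalg.inv(X.T @ (X * W[:, None]))
            return beta, cov, it, current
    raise FirthNonConvergence(trace)


def firth_logistic(
    codes,
    case_labels,
    model: str = "recessive",
    class_set: str = "",
) -> BurdenResult:
    """Firth-penalized logistic burden fit: case status ~ genotype code.

    ``codes`` are per-sample 0/1/2 diplotype codes; the additive model
    uses them as-is, the recessive model collapses to the biallelic
    indicator (code == 2).  Duplicate covariate patterns are aggregated
    before fitting, so cohort-scale inputs cost the same as their 2×3
    count table.  Wald 95% CI and p from the penalized information.
    """
    codes = np.asarray(codes)
    y = np.asarray(case_labels).astype(int)
    if codes.shape != y.shape:
        raise ValueError("codes and labels differ in length")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    if model == "recessive":
        x = (codes == 2).astype(float)
    elif model == "additive":
        x = codes.astype(float)
    else:
        raise ValueError(f"unknown model {model!r}")
    if np.all(x == x[0]):
        raise ValueError("degenerate covariate: genotype code is constant")

    # aggregate identical (x, y) rows
    pairs, counts = np.unique(np.column_stack([x, y]), axis=0, return_counts=True)
    X = np.column_stack([np.ones(len(pairs)), pairs[:, 0]])
    beta, cov, n_iter, _ = firth_fit(X, pairs[:, 1], weights=counts.astype(float))

    b = float(beta[1])
    se = float(math.sqrt(cov[1, 1]))
    wald = (b / se) ** 2
    p = float(stats.chi2.sf(wald, df=1))

    tall = {0: [0, 0, 0], 1: [0, 0, 0]}
    for code, yy in zip(codes, y):
        tall[int(yy)][int(code)] += 1
    gc = GenotypeCounts(cases=tuple(tall[1]), controls=tuple(tall[0]), label=class_set)
    return BurdenResult(
        class_set=class_set,
        model=model,
        beta=b,
        se=se,
        odds_ratio=math.exp(b),
        ci_low=math.exp(b - Z95 * se),
        ci_high=math.exp(b + Z95 * se),
        p_value=p,
        counts=gc,
        n_iter=n_iter,
    )


def firth_from_counts(counts: GenotypeCounts, model: str = "recessive") -> BurdenResult:
    """Expand a printed ref/het/rec count breakdown into per-observation
    genotype codes and run the Firth burden fit on them."""
    codes = []
    labels = []
    for arm, is_case in ((counts.controls, 0), (counts.cases, 1)):
        for code, n in enumerate(arm):
            codes.extend([code] * n)
            labels.extend([is_case] * n)
    return firth_logistic(np.array(codes), np.array(labels), model=model, class_set=counts.label)


def burden_test(
    diplotypes,
    case_flags: dict[str, bool],
    class_set: str = "plof_plus_pdns",
    model: str = "recessive",
    include_putative: bool = True,
) -> BurdenResult:
    """Gene-burden Firth regression from diplotype calls and case labels."""
    samples = [s for s in diplotypes if s in case_flags]
    codes = np.array(
        [diplotypes[s].burden_code(include_putative=include_putative) for s in samples]
    )
    y = np.array([case_flags[s] for s in samples], dtype=int)
    return firth_logistic(codes, y, model=model, class_set=class_set)


# ---------------------------------------------------------------------------
# onset-age comparison


def compare_onset_age(ages_a, ages_b, welch: bool = False) -> tuple[float, float]:
    """Unpaired two-sample t test on onset ages (pooled-variance Student
    form by default; Welch optional).  Returns (t, two-sided p)."""
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
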