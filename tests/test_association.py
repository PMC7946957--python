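"""Contingency statistics, Fisher exactness, and the Firth burden engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

import recburden as rb
from recburden.association import Z95, firth_fit


def _enumerate_fisher(a, b, c, d):
    """Independent oracle: full hypergeometric enumeration over tables
    with the observed margins."""
    from math import comb

    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)
    probs = []
    for k in range(max(0, col1 - row2), min(row1, col1) + 1):
        probs.append(comb(row1, k) * comb(row2, col1 - k) / denom)
    obs = comb(row1, a) * comb(row2, c) / denom
    return sum(p for p in probs if p <= obs * (1 + 1e-12))


class TestFisherExact:
    def test_identical_rows_give_p_one(self):
        assert rb.fisher_exact_p([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_small_table_matches_full_enumeration(self):
        # (3,1;1,3): two-sided p = 34/70
        assert rb.fisher_exact_p([[3, 1], [1, 3]]) == pytest.approx(34 / 70, rel=1e-7)
        assert _enumerate_fisher(3, 1, 1, 3) == pytest.approx(34 / 70, rel=1e-12)

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 12, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            assert rb.fisher_exact_p([[a, b], [c, d]]) == pytest.approx(
                _enumerate_fisher(a, b, c, d), rel=1e-7
            )

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_symmetry_property(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        p = rb.fisher_exact_p([[a, b], [c, d]])
        assert 0 < p <= 1
        assert rb.fisher_exact_p([[d, c], [b, a]]) == pytest.approx(p, rel=1e-9)

    def test_invariant_under_transpose_and_swaps(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.integers(0, 30, (2, 2)) + 1
            p = rb.fisher_exact_p(t)
            assert rb.fisher_exact_p(t.T) == pytest.approx(p, rel=1e-10)
            assert rb.fisher_exact_p(t[::-1]) == pytest.approx(p, rel=1e-10)
            assert rb.fisher_exact_p(t[:, ::-1]) == pytest.approx(p, rel=1e-10)


class TestOddsRatioFormulas:
    def test_cross_product_and_woolf_match_textbook_arithmetic(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            counts = rb.GenotypeCounts(
                cases=tuple(int(x) for x in rng.integers(1, 40, 3)),
                controls=tuple(int(x) for x in rng.integers(1, 40, 3)),
            )
            res = rb.or_recessive(counts)
            a = counts.cases[2]
            b = counts.cases[0] + counts.cases[1]
            c = counts.controls[2]
            d = counts.controls[0] + counts.controls[1]
            assert res.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-12)
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert math.log(res.ci_high / res.odds_ratio) == pytest.approx(Z95 * se, rel=1e-12)
            assert math.log(res.odds_ratio / res.ci_low) == pytest.approx(Z95 * se, rel=1e-12)

    def test_balanced_table_gives_or_one_p_one(self):
        counts = rb.GenotypeCounts(cases=(10, 5, 5), controls=(10, 5, 5))
        res = rb.or_additive(counts)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_recessive_equals_genotypic_hom_without_hets(self):
        counts = rb.GenotypeCounts(cases=(30, 0, 4), controls=(90, 0, 2))
        _, hom = rb.or_genotypic(counts)
        rec = rb.or_recessive(counts)
        assert rec.odds_ratio == pytest.approx(hom.odds_ratio)
        assert rec.p_value == pytest.approx(hom.p_value)

    def test_zero_cell_flags_undefined_with_haldane_alongside(self):
        counts = rb.GenotypeCounts(cases=(30, 5, 0), controls=(90, 10, 2))
        res = rb.or_recessive(counts)
        assert res.undefined
        assert res.odds_ratio is None
        assert res.haldane_or == pytest.approx((0.5 * 100.5) / (35.5 * 2.5))

    def test_proportional_het_counts_give_het_or_one(self):
        counts = rb.GenotypeCounts(cases=(100, 20, 3), controls=(500, 100, 7))
        het, _ = rb.or_genotypic(counts)
        assert het.odds_ratio == pytest.approx(1.0)


class TestFirth:
    def test_matches_half_cell_closed_form_on_two_by_two_designs(self):
        """On a saturated 2x2 design the Jeffreys penalty separates per
        exposure group into p=(y+1/2)/(n+1), i.e. the +0.5-cell estimator —
        an independently derivable closed form."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 50, 4))
            counts = rb.GenotypeCounts(cases=(b, 0, a), controls=(d, 0, c))
            res = rb.firth_from_counts(counts, model="recessive")
            expected = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            # the Newton iteration stops on a float64 likelihood plateau,
            # which bounds the attainable precision near 1e-7 in the OR
            assert res.odds_ratio == pytest.approx(expected, rel=1e-5)

    def test_finite_estimate_under_complete_separation(self):
        codes = np.array([0, 0, 0, 0, 2, 2, 2, 2])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = rb.firth_logistic(codes, y, model="recessive")
        assert np.isfinite(res.beta) and np.isfinite(res.se)
        # +0.5-cell closed form for the separated table
        assert res.odds_ratio == pytest.approx((4.5 * 4.5) / (0.5 * 0.5), rel=1e-6)

    def test_symmetric_design_gives_zero_beta(self):
        codes = np.array([0, 0, 2, 2] * 4)
        y = np.array([0, 1, 0, 1] * 4)
        res = rb.firth_logistic(codes, y, model="recessive")
        assert res.beta == pytest.approx(0.0, abs=1e-10)

    def test_tiny_dataset_matches_penalized_likelihood_grid(self):
        """Two-stage grid search (coarse then 1e-4 refinement) over the
        slope with the intercept profiled out numerically."""
        codes = np.array([0, 0, 0, 1, 1, 2, 2, 2])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        res = rb.firth_logistic(codes, y, model="additive")

        x = codes.astype(float)

        def pll_profile(b1):
            def neg(b0):
                eta = b0 + b1 * x
                ll = np.sum(y * eta - np.logaddexp(0, eta))
                p = 1 / (1 + np.exp(-eta))
                X = np.column_stack([np.ones_like(x), x])
                W = p * (1 - p)
                sign, logdet = np.linalg.slogdet(X.T @ (X * W[:, None]))
                return -(ll + 0.5 * logdet)

            return -optimize.minimize_scalar(neg, bounds=(-8, 8), method="bounded").fun

        coarse = np.arange(-3, 3, 0.01)
        best = coarse[np.argmax([pll_profile(b) for b in coarse])]
        fine = np.arange(best - 0.02, best + 0.02, 1e-4)
        best = fine[np.argmax([pll_profile(b) for b in fine])]
        assert res.beta == pytest.approx(best, abs=2e-4)

    def test_aggregation_invariance(self):
        """Fitting expanded per-observation rows equals fitting weighted
        unique patterns (internal aggregation)."""
        counts = rb.GenotypeCounts(cases=(20, 6, 3), controls=(200, 30, 4))
        res = rb.firth_from_counts(counts, model="additive")
        X = np.column_stack([np.ones(6), [0, 1, 2, 0, 1, 2]])
        yy = np.array([0, 0, 0, 1, 1, 1])
        w = np.array([200, 30, 4, 20, 6, 3], dtype=float)
        beta, cov, _, _ = firth_fit(X, yy, weights=w)
        assert res.beta == pytest.approx(float(beta[1]), rel=1e-8)

    def test_degenerate_covariate_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            rb.firth_logistic(np.zeros(10, dtype=int), np.r_[np.ones(5), np.zeros(5)], model="recessive")

    def test_all_case_or_all_control_is_an_error(self):
        with pytest.raises(ValueError, match="case and one control"):
            rb.firth_logistic(np.array([0, 1, 2]), np.array([1, 1, 1]))


class TestBurdenFromDiplotypes:
    def test_counts_breakdown_matches_input_coding(self, called_clean_trios):
        cfg, pedigree, matrix, truth, calls, cascade, _ = called_clean_trios
        rng = np.random.default_rng(9)
        case_flags = {s: bool(rng.random() < 0.3) for s in calls}
        res = rb.burden_test(calls, case_flags, model="recessive")
        codes = [c.burden_code() for c in calls.values()]
        flags = [case_flags[s] for s in calls]
        for arm, want in ((res.counts.cases, True), (res.counts.controls, False)):
            for code in (0, 1, 2):
                assert arm[code] == sum(
                    1 for cd, f in zip(codes, flags) if cd == code and f is want
                )
        assert res.odds_ratio == pytest.approx(math.exp(res.beta))

    def test_truth_coded_and_pipeline_coded_counts_agree_without_noise(
        self, called_clean_trios
    ):
        """With complete trios and no observation noise, counting biallelic
        samples from the pipeline's calls equals counting from the
        generative truth, excluding pairs only phase-ambiguity can hide."""
        cfg, pedigree, matrix, truth, calls, cascade, _ = called_clean_trios
        truth_cat = dict(zip(truth["sample"], truth.true_category))
        for s, call in calls.items():
            if call.category in ("HOM",):
                assert truth_cat[s] == "HOM"
            if call.category == "CHET_CONFIRMED":
                assert truth_cat[s] == "CHET_TRANS"
            if call.category == "CIS_EXCLUDED":
                assert truth_cat[s] == "CHET_CIS"


class TestOnsetAge:
    def test_identical_groups(self):
        t, p = rb.compare_onset_age([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(40, 10, 25), rng.normal(50, 12, 35)
        t, p = rb.compare_onset_age(a, b)
        sp = math.sqrt(
            ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
            / (len(a) + len(b) - 2)
        )
        expect = (np.mean(a) - np.mean(b)) / (sp * math.sqrt(1 / len(a) + 1 / len(b)))
        assert t == pytest.approx(expect, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(expect), len(a) + len(b) - 2), rel=1e-12)

    def test_groups_too_small_rejected(self):
        with pytest.raises(ValueError):
            rb.compare_onset_age([1.0], [2.0, 3.0])
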