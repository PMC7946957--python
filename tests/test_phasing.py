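"""Cis/trans phasing, genotype QC, and diplotype calling."""

import itertools

import numpy as np
import pytest

import recburden as rb
from recburden.io_formats import MISSING
from recburden.phasing import CascadeLog
from recburden.synthetic_cohort import truth_pair_is_trans


def _matrix(samples, dosage_rows, labels=("p.A", "p.B")):
    variants = [
        rb.Variant(chrom="16", pos=100 + 50 * j, ref_allele="A", alt_allele="T",
                   label=lab, consequence="missense", deleterious_votes=(True,) * 5)
        for j, lab in enumerate(labels)
    ]
    return rb.GenotypeMatrix(
        samples=list(samples), variants=variants,
        calls=np.array(dosage_rows, dtype=np.int8),
    )


def _trio_ped():
    return rb.Pedigree(
        individuals={
            "FA": rb.io_formats.Individual("FA", "F1", None, None, 1),
            "MO": rb.io_formats.Individual("MO", "F1", None, None, 2),
            "C1": rb.io_formats.Individual("C1", "F1", "FA", "MO", 1),
        }
    )


class TestQcGenotype:
    def test_clean_hom_is_kept(self):
        assert rb.qc_genotype(2, 40, 0.98) == "keep"

    def test_low_depth_hom_removed_under_default_policy(self):
        assert rb.qc_genotype(2, 6, 0.98) == "set_missing"

    def test_skewed_balance_hom_removed(self):
        assert rb.qc_genotype(2, 40, 0.60) == "set_missing"

    def test_het_never_touched(self):
        assert rb.qc_genotype(1, 3, 0.2) == "keep"

    def test_missing_qc_fields_keep_the_call(self):
        assert rb.qc_genotype(2, None, None) == "keep"

    def test_qc_reduces_false_hom_diplotypes_on_noisy_cohort(self):
        cfg = rb.SimCohortConfig(
            n_trios=0, n_quartets=0, n_singletons=4000, seed=13,
            qc_noise=rb.QcNoise(p_het_to_hom=0.05),
        )
        cohort = rb.simulate_cohort(cfg)
        mask = rb.build_class_mask(cohort.matrix)
        qual = rb.select_burden_variants(mask, cohort.matrix)
        truth_cat = dict(zip(cohort.truth["sample"], cohort.truth.true_category))

        def false_homs(config):
            calls, _, _ = rb.call_diplotypes("NOD2", qual, cohort.matrix, config=config)
            return sum(
                1 for s, c in calls.items()
                if c.category == "HOM" and truth_cat[s] != "HOM"
            )

        with_qc = false_homs(rb.PhasingConfig())
        without_qc = false_homs(rb.PhasingConfig(min_depth=0, hom_ab_min=0))
        assert without_qc > 0
        assert with_qc < without_qc


class TestPedigreePhasing:
    def test_alleles_from_different_parents_is_trans(self):
        m = _matrix(["FA", "MO", "C1"], [[1, 0], [0, 1], [1, 1]])
        pc = rb.phase_pair_by_pedigree("C1", "p.A", "p.B", _trio_ped(), m)
        assert (pc.verdict, pc.evidence) == ("TRANS", "pedigree")

    def test_both_alleles_from_one_parent_is_cis(self):
        m = _matrix(["FA", "MO", "C1"], [[0, 0], [1, 1], [1, 1]])
        pc = rb.phase_pair_by_pedigree("C1", "p.A", "p.B", _trio_ped(), m)
        assert (pc.verdict, pc.evidence) == ("CIS", "pedigree")

    def test_missing_parent_genotypes_unresolved(self):
        m = _matrix(["FA", "MO", "C1"], [[MISSING, 0], [0, 1], [1, 1]])
        assert rb.phase_pair_by_pedigree("C1", "p.A", "p.B", _trio_ped(), m).verdict == "UNRESOLVED"

    def test_both_parents_double_carriers_unresolved(self):
        m = _matrix(["FA", "MO", "C1"], [[1, 1], [1, 1], [1, 1]])
        assert rb.phase_pair_by_pedigree("C1", "p.A", "p.B", _trio_ped(), m).verdict == "UNRESOLVED"

    def test_mendelian_inconsistency_unresolved(self):
        m = _matrix(["FA", "MO", "C1"], [[0, 1], [0, 1], [1, 1]])
        assert rb.phase_pair_by_pedigree("C1", "p.A", "p.B", _trio_ped(), m).verdict == "UNRESOLVED"

    def test_sample_not_in_pedigree_is_an_error(self):
        m = _matrix(["FA", "MO", "C1"], [[1, 0], [0, 1], [1, 1]])
        with pytest.raises(KeyError):
            rb.phase_pair_by_pedigree("ZZ", "p.A", "p.B", _trio_ped(), m)

    def test_verdict_invariant_under_pair_swap(self, clean_trios):
        _, pedigree, matrix, _ = clean_trios
        labels = [v.label for v in matrix.variants]
        checked = 0
        for child, _, _ in pedigree.complete_trios():
            i = matrix.sample_index(child)
            hets = [l for l in labels if matrix.calls[i, matrix.variant_index(l)] == 1]
            for a, b in itertools.combinations(hets, 2):
                v1 = rb.phase_pair_by_pedigree(child, a, b, pedigree, matrix).verdict
                v2 = rb.phase_pair_by_pedigree(child, b, a, pedigree, matrix).verdict
                assert v1 == v2
                checked += 1
        assert checked > 0

    def test_never_contradicts_simulated_truth(self, clean_trios):
        _, pedigree, matrix, truth = clean_trios
        truth_by = {r.sample: r for r in truth.itertuples(index=False)}
        labels = [v.label for v in matrix.variants]
        decided = 0
        for child, _, _ in pedigree.complete_trios():
            i = matrix.sample_index(child)
            hets = [l for l in labels if matrix.calls[i, matrix.variant_index(l)] == 1]
            for a, b in itertools.combinations(hets, 2):
                pc = rb.phase_pair_by_pedigree(child, a, b, pedigree, matrix)
                if pc.verdict == "UNRESOLVED":
                    continue
                decided += 1
                assert (pc.verdict == "TRANS") == truth_pair_is_trans(truth_by[child], a, b)
        assert decided > 0


class TestHaplotypeEm:
    def _sim_pair(self, n, pA, pB, pAB, seed):
        """Draw genotypes from explicit haplotype frequencies."""
        rng = np.random.default_rng(seed)
        freqs = np.array([pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB])
        haps = rng.choice(4, size=(n, 2), p=freqs)
        ga = (haps <= 1).sum(axis=1)  # haplotypes 0,1 carry A
        gb = ((haps == 0) | (haps == 2)).sum(axis=1)  # 0,2 carry B
        return _matrix(
            [f"S{i}" for i in range(n)], np.column_stack([ga, gb]),
        )

    def test_linkage_equilibrium_recovers_product_frequency(self):
        pA, pB, n = 0.3, 0.2, 10_000
        m = self._sim_pair(n, pA, pB, pA * pB, seed=21)
        pAB, pAb, paB, pab = rb.estimate_haplotype_freqs_em(m, "p.A", "p.B")
        se = np.sqrt(pA * pB * (1 - pA * pB) / (2 * n))
        assert abs(pAB - pA * pB) < 3 * se
        assert pAB + pAb + paB + pab == pytest.approx(1.0)

    def test_complete_repulsion_drives_pab_to_zero(self):
        m = self._sim_pair(2000, 0.3, 0.2, 0.0, seed=22)
        pAB, _, _, _ = rb.estimate_haplotype_freqs_em(m, "p.A", "p.B")
        assert pAB == pytest.approx(0.0, abs=1e-6)

    def test_matches_exhaustive_grid_on_small_fixtures(self):
        """The ML solution preserves the observed allele frequencies, so an
        exhaustive 1e-3 grid over the feasible p_AB interval is the full
        likelihood surface."""
        for seed in (23, 24, 25):
            m = self._sim_pair(20, 0.35, 0.25, 0.15, seed=seed)
            est = rb.estimate_haplotype_freqs_em(m, "p.A", "p.B")
            ga = m.calls[:, 0].astype(int)
            gb = m.calls[:, 1].astype(int)
            pA = ga.sum() / (2 * len(ga))
            pB = gb.sum() / (2 * len(gb))

            def loglik(pAB):
                p = np.array([pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB])
                if (p < -1e-12).any():
                    return -np.inf
                p = np.clip(p, 1e-12, None)
                ll = 0.0
                for a, b in zip(ga, gb):
                    if (a, b) == (1, 1):
                        g = 2 * p[0] * p[3] + 2 * p[1] * p[2]
                    else:
                        # genotype probability from haplotype pair products
                        g = {
                            (0, 0): p[3] ** 2, (0, 1): 2 * p[2] * p[3], (0, 2): p[2] ** 2,
                            (1, 0): 2 * p[1] * p[3], (1, 2): 2 * p[0] * p[2],
                            (2, 0): p[1] ** 2, (2, 1): 2 * p[0] * p[1], (2, 2): p[0] ** 2,
                        }[(a, b)]
                    ll += np.log(max(g, 1e-300))
                return ll

            lo = max(0.0, pA + pB - 1)
            hi = min(pA, pB)
            grid = np.arange(lo, hi + 1e-9, 1e-3)
            best = grid[np.argmax([loglik(x) for x in grid])]
            assert est[0] == pytest.approx(best, abs=2e-3)

    def test_loglik_monotone_is_enforced_internally(self):
        # the EM asserts monotonicity per step; a normal run must not trip it
        m = self._sim_pair(500, 0.3, 0.2, 0.1, seed=26)
        rb.estimate_haplotype_freqs_em(m, "p.A", "p.B")

    def test_too_few_samples_rejected(self):
        m = _matrix(["S0"], [[1, 1]])
        with pytest.raises(ValueError):
            rb.estimate_haplotype_freqs_em(m, "p.A", "p.B")


class TestPopulationPhasing:
    def test_no_cis_haplotype_forces_trans(self):
        pc = rb.phase_pair_by_population("S", "p.A", "p.B", (0.0, 0.3, 0.2, 0.5))
        assert (pc.verdict, pc.posterior_trans) == ("TRANS", 1.0)

    def test_symmetric_frequencies_stay_unresolved(self):
        pc = rb.phase_pair_by_population("S", "p.A", "p.B", (0.25, 0.25, 0.25, 0.25))
        assert pc.verdict == "UNRESOLVED"
        assert pc.posterior_trans == pytest.approx(0.5)

    def test_degenerate_frequencies_unresolved(self):
        pc = rb.phase_pair_by_population("S", "p.A", "p.B", (0.0, 0.5, 0.5, 0.0))
        assert pc.verdict == "TRANS"  # denominator positive: pure repulsion
        pc2 = rb.phase_pair_by_population("S", "p.A", "p.B", (0.0, 1.0, 0.0, 0.0))
        assert (pc2.verdict, pc2.evidence) == ("UNRESOLVED", "none")

    def test_decided_population_verdicts_match_truth_in_ld_cohort(self):
        """With a strong-LD (repulsion) pair, population phasing decides and
        must agree with the generative truth for nearly all decided pairs."""
        cfg = rb.SimCohortConfig(n_trios=0, n_quartets=0, n_singletons=8000, seed=27)
        rng = np.random.default_rng(cfg.seed)
        from recburden.synthetic_cohort import simulate_pedigree_genotypes

        _, matrix, truth = simulate_pedigree_genotypes(cfg, rng)
        truth_by = {r.sample: r for r in truth.itertuples(index=False)}
        # the designated cis pair is in complete LD: every double-het is cis
        freqs = rb.estimate_haplotype_freqs_em(matrix, "p.L1007fs", "p.M863V")
        decided = agree = 0
        for i, s in enumerate(matrix.samples):
            da = matrix.calls[i, matrix.variant_index("p.L1007fs")]
            db = matrix.calls[i, matrix.variant_index("p.M863V")]
            if da == 1 and db == 1:
                tt = truth_pair_is_trans(truth_by[s], "p.L1007fs", "p.M863V")
                if tt is None:
                    continue
                pc = rb.phase_pair_by_population(s, "p.L1007fs", "p.M863V", freqs)
                if pc.verdict == "UNRESOLVED":
                    continue
                decided += 1
                agree += (pc.verdict == "TRANS") == tt
        assert decided > 10
        assert agree / decided >= 0.95


class TestBlacklist:
    def test_known_cis_pair_excluded(self):
        kept, excl = rb.apply_cis_blacklist([("p.L1007fs", "p.M863V")])
        assert kept == [] and excl == [("p.L1007fs", "p.M863V")]

    def test_other_pairs_retained(self):
        kept, excl = rb.apply_cis_blacklist([("p.R702W", "p.G908R")])
        assert kept == [("p.R702W", "p.G908R")] and excl == []

    def test_empty_blacklist_is_identity(self):
        pairs = [("p.L1007fs", "p.M863V"), ("p.R702W", "p.G908R")]
        kept, excl = rb.apply_cis_blacklist(pairs, blacklist=())
        assert kept == pairs and excl == []


class TestCallDiplotypes:
    def test_hom_at_any_qualifying_variant(self):
        m = _matrix(["S1"], [[2, 0]])
        calls, _, _ = rb.call_diplotypes("NOD2", [0, 1], m, config=rb.PhasingConfig(use_population=False))
        assert calls["S1"].category == "HOM"
        assert calls["S1"].burden_code() == 2

    def test_trans_pair_by_pedigree_is_confirmed_chet(self):
        m = _matrix(["FA", "MO", "C1"], [[1, 0], [0, 1], [1, 1]])
        calls, _, _ = rb.call_diplotypes(
            "NOD2", [0, 1], m, pedigree=_trio_ped(),
            config=rb.PhasingConfig(use_population=False),
        )
        assert calls["C1"].category == "CHET_CONFIRMED"
        assert calls["C1"].evidence == "pedigree"

    def test_singleton_double_het_is_putative(self):
        m = _matrix(["S1", "S2"], [[1, 1], [0, 0]])
        calls, _, _ = rb.call_diplotypes("NOD2", [0, 1], m, config=rb.PhasingConfig(use_population=False))
        assert calls["S1"].category == "CHET_PUTATIVE"
        assert calls["S1"].burden_code(include_putative=True) == 2
        assert calls["S1"].burden_code(include_putative=False) == 1

    def test_blacklisted_pair_never_called_chet(self):
        m = _matrix(["S1"], [[1, 1]], labels=("p.L1007fs", "p.M863V"))
        calls, cascade, _ = rb.call_diplotypes("NOD2", [0, 1], m)
        assert calls["S1"].category == "CIS_EXCLUDED"
        assert calls["S1"].burden_code() == 1
        assert cascade.counts()["blacklist_excluded"] == 1

    def test_every_sample_gets_exactly_one_category(self, called_clean_trios):
        _, _, matrix, _, calls, _, _ = called_clean_trios
        assert set(calls) == set(matrix.samples)

    def test_categories_match_truth_on_clean_trios(self, called_clean_trios):
        """Zero noise + complete trios: agreement with the generative truth
        for every sample outside the putative class."""
        _, _, _, truth, calls, _, _ = called_clean_trios
        mapping = {
            "HOM": "HOM", "CHET_TRANS": "CHET_CONFIRMED",
            "CHET_CIS": "CIS_EXCLUDED", "CARRIER": "CARRIER", "REF": "REF",
        }
        truth_cat = dict(zip(truth["sample"], truth.true_category))
        for s, call in calls.items():
            if call.category == "CHET_PUTATIVE":
                continue
            assert call.category == mapping[truth_cat[s]], s

    def test_cascade_partitions_candidates(self, small_cohort):
        mask = rb.build_class_mask(small_cohort.matrix, pedigree=small_cohort.pedigree)
        qual = rb.select_burden_variants(mask, small_cohort.matrix)
        _, cascade, _ = rb.call_diplotypes(
            "NOD2", qual, small_cohort.matrix, pedigree=small_cohort.pedigree
        )
        assert cascade.check_partition()
        c = cascade.counts()
        assert (
            c["qc_removed"] + c["blacklist_excluded"] + c["cis_excluded"] + c["retained"]
            == c["initial_candidates"]
        )
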