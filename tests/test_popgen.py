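"""Single-locus genetics: HWE departure f, association, OR, power."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cgstats.cohort import Locus, SubjectRecord
from cgstats.popgen import (
    GenotypeCounts,
    additive_or,
    genotype_assoc,
    genotype_assoc_chi2,
    hwe_chi2,
    hwe_f,
    hwe_test,
    power_case_control,
    stratified_assoc,
    tally,
    trend_test,
)
from cgstats.stats_core import EstimationError
from cgstats.synthetic import SimulationParams, simulate_cohort, simulate_genotypes_hwe


def counts_from(n_CC, n_Cc, n_cc):
    return GenotypeCounts("rs_test", "C", "c", n_CC, n_Cc, n_cc)


class TestTally:
    def test_counts_three_genotypes(self, small_cohort, locus_ga):
        groups = tally(small_cohort, locus_ga)
        for grp in ("case", "control"):
            assert groups[grp].as_array().tolist() == [1, 1, 1]

    def test_missing_genotype_excluded(self, small_cohort, locus_ga):
        assert tally(small_cohort, locus_ga)["case"].n == 3  # ca_na dropped

    def test_order_invariant(self, small_cohort, locus_ga):
        fwd = tally(small_cohort, locus_ga)
        rev = tally(list(reversed(small_cohort)), locus_ga)
        for grp in ("case", "control"):
            assert fwd[grp] == rev[grp]


class TestHWEDeparture:
    @pytest.mark.parametrize("cts, expected", [
        ((25, 50, 25), 0.0),       # exact HW proportions
        ((0, 10, 0), -1.0),        # all heterozygotes
        ((30, 30, 40), 0.3939),    # p_C=0.45, p_CC=0.30
    ])
    def test_f_formula(self, cts, expected):
        assert hwe_f(counts_from(*cts)) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("cts", [(10, 0, 0), (0, 0, 7)])
    def test_monomorphic_undefined(self, cts):
        with pytest.raises(EstimationError):
            hwe_f(counts_from(*cts))

    def test_zero_departure_gives_null_test(self):
        res = hwe_test(counts_from(25, 50, 25), M=500, B=0, seed=0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_asymptotic == pytest.approx(1.0)

    @given(st.integers(0, 200), st.integers(1, 200), st.integers(0, 200))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_chi2_equals_n_f_squared(self, a, b, c):
        cts = counts_from(a, b, c)
        res = hwe_test(cts, M=0, B=0)
        assert res.chi2 == pytest.approx(cts.n * res.f**2, abs=1e-9)

    def test_study_sized_heterozygote_excess(self):
        # the n f^2 identity at the study's patient-group size: f = -0.1352
        # on 336 subjects gives the printed chi-square 6.14
        assert round(hwe_chi2(-0.1352, 336), 2) == 6.14

    def test_f_sign_convention(self):
        assert hwe_f(counts_from(5, 90, 5)) < 0      # heterozygote excess
        assert hwe_f(counts_from(45, 10, 45)) > 0    # heterozygote deficiency

    def test_empirical_p_matches_asymptotic_at_large_n(self):
        doses = simulate_genotypes_hwe(p=0.3, n=10_000, f=0.0, seed=5)
        cts = counts_from(int((doses == 2).sum()), int((doses == 1).sum()),
                          int((doses == 0).sum()))
        res = hwe_test(cts, M=5_000, B=0, seed=6)
        assert res.p_empirical == pytest.approx(res.p_asymptotic, abs=0.02)

    def test_bootstrap_ci_covers_true_f(self):
        # subject-level percentile bootstrap at the study's case-group size
        rng = np.random.default_rng(99)
        f_true, p = 0.1, 0.4
        covered = 0
        for _ in range(100):
            doses = simulate_genotypes_hwe(p, 336, f_true, rng=rng)
            cts = counts_from(int((doses == 2).sum()), int((doses == 1).sum()),
                              int((doses == 0).sum()))
            res = hwe_test(cts, M=0, B=300, seed=int(rng.integers(2**31)))
            lo, hi = res.f_ci
            covered += lo <= f_true <= hi
        assert covered >= 90


class TestGenotypeAssociation:
    def test_identical_distributions_null(self):
        c = counts_from(30, 40, 30)
        chi2, df, p, _ = genotype_assoc_chi2(c, c, M=0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 2 and p == pytest.approx(1.0)

    def test_matches_pearson_oracle(self):
        case, ctrl = counts_from(30, 40, 30), counts_from(40, 40, 20)
        chi2, df, p, _ = genotype_assoc_chi2(case, ctrl, M=0)
        oracle = sps.chi2_contingency(
            np.vstack([case.as_array(), ctrl.as_array()]), correction=False)
        assert chi2 == pytest.approx(oracle.statistic, abs=1e-10)
        assert df == oracle.dof
        assert p == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_empty_class_reduces_df(self):
        chi2, df, _, _ = genotype_assoc_chi2(counts_from(30, 40, 0),
                                             counts_from(40, 40, 0), M=0)
        assert df == 1

    def test_empirical_close_to_asymptotic_at_n_1000(self):
        case, ctrl = counts_from(310, 480, 210), counts_from(290, 500, 210)
        chi2, df, p_asym, p_emp = genotype_assoc_chi2(case, ctrl, M=4_000, seed=8)
        assert p_emp == pytest.approx(p_asym, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            genotype_assoc_chi2(counts_from(0, 0, 0), counts_from(1, 1, 1))


class TestAdditiveOR:
    def test_no_association(self):
        or_, ci, _ = additive_or(counts_from(10, 20, 10), counts_from(20, 40, 20))
        assert or_ == pytest.approx(1.0)
        assert ci[0] < 1.0 < ci[1]

    def test_cross_product_and_woolf_ci(self):
        # allele tables: cases 40 C / 60 c, controls 20 C / 80 c
        case = counts_from(10, 20, 20)     # 40 C, 60 c alleles
        ctrl = counts_from(5, 10, 35)      # 20 C, 80 c alleles
        or_, ci, corrected = additive_or(case, ctrl)
        assert not corrected
        assert or_ == pytest.approx(8 / 3, abs=5e-4)
        # hand Woolf: exp(ln(8/3) +/- 1.96 sqrt(1/40+1/60+1/20+1/80))
        assert ci[0] == pytest.approx(1.417, abs=5e-4)
        assert ci[1] == pytest.approx(5.020, abs=5e-4)

    def test_group_swap_inverts_or(self):
        case, ctrl = counts_from(12, 30, 18), counts_from(9, 22, 40)
        or_fwd, _, _ = additive_or(case, ctrl)
        or_rev, _, _ = additive_or(ctrl, case)
        assert or_fwd == pytest.approx(1.0 / or_rev)

    def test_zero_cell_triggers_continuity_correction(self):
        or_, ci, corrected = additive_or(counts_from(0, 0, 50), counts_from(5, 10, 35))
        assert corrected
        assert np.isfinite(or_) and or_ > 0 and ci[0] > 0

    def test_trend_test_null_on_balanced_data(self):
        chi2, p = trend_test(counts_from(10, 20, 10), counts_from(20, 40, 20))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)


class TestStratifiedAssociation:
    def test_strata_consistent_when_hla_independent(self):
        params = SimulationParams(n_cases=2000, n_controls=2000, seed=31,
                                  per_allele_or={"rs1132200": 1.6, "rs17281647": 1.0})
        table = simulate_cohort(params)
        locus = table.loci[0]
        pooled = genotype_assoc(*[tally(table.records, locus)[g]
                                  for g in ("case", "control")], M=0)
        strata = stratified_assoc(table.records, locus, M=0)
        for res in strata.values():
            assert res is not None
            assert pooled.or_ci[0] * 0.8 < res.or_per_allele < pooled.or_ci[1] * 1.2

    def test_single_stratum_when_no_carriers(self, locus_ga):
        recs = [SubjectRecord(f"s{i}", "case" if i % 2 else "control",
                              hla1501_dose=0,
                              genotypes={locus_ga.name: ("A", "G") if i % 3 else ("G", "G")})
                for i in range(40)]
        strata = stratified_assoc(recs, locus_ga, M=0)
        assert strata["carrier"] is None
        assert strata["non-carrier"] is not None


class TestPower:
    def test_null_or_gives_alpha(self):
        for alpha in (0.01, 0.05, 0.2):
            assert power_case_control(1.0, 0.3, 300, 300, alpha) == pytest.approx(
                alpha, abs=1e-9)

    def test_monotone_in_n_and_effect(self):
        ns = [100, 200, 400, 800]
        powers = [power_case_control(1.5, 0.3, n, n) for n in ns]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        ors = [1.1, 1.3, 1.6, 2.0]
        powers = [power_case_control(o, 0.3, 300, 300) for o in ors]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        # protective effects mirror risk effects through |log OR|
        assert power_case_control(0.5, 0.3, 300, 300) == pytest.approx(
            power_case_control(2.0, 0.3, 300, 300), abs=0.02)

    def test_matches_monte_carlo_oracle(self):
        # brute-force oracle: draw allele counts, run the 2x2 Pearson test
        or_, maf, n, alpha, reps = 1.5, 0.3, 500, 0.05, 10_000
        p0 = maf
        p1 = or_ * p0 / (1 - p0 + or_ * p0)
        rng = np.random.default_rng(17)
        a = rng.binomial(2 * n, p1, size=reps)   # case C alleles
        c = rng.binomial(2 * n, p0, size=reps)   # control C alleles
        b, d = 2 * n - a, 2 * n - c
        tot = 4.0 * n
        # Pearson chi2 on [[a,b],[c,d]] computed directly
        exp_a = 2 * n * (a + c) / tot
        exp_b = 2 * n * (b + d) / tot
        chi2 = ((a - exp_a) ** 2 / exp_a + (b - exp_b) ** 2 / exp_b
                + (c - exp_a) ** 2 / exp_a + (d - exp_b) ** 2 / exp_b)
        mc_power = np.mean(chi2 > sps.chi2.ppf(1 - alpha, 1))
        assert power_case_control(or_, maf, n, n, alpha) == pytest.approx(
            mc_power, abs=0.02)

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            power_case_control(1.5, 0.3, 100, 100, alpha=1.2)
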