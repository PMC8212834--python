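import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from apmstrata import (
    SnpDef,
    StratifiedGenotypeCounts,
    Stratum,
    additive_prediction,
    builtin_table2_counts,
    gene_global_test,
    genotype_or,
    get_counts,
    hwe,
    mantel_haenszel,
    mantel_haenszel_from_counts,
    or_ci,
    pstar,
    run_association_scan,
    score_test_1df,
)

SNP = SnpDef("rsX", "G", ("A", "B"))


def make_counts(case, ctrl, stratum=Stratum.SMOKERS):
    return StratifiedGenotypeCounts(SNP, stratum, tuple(case), tuple(ctrl))


class TestGenotypeOR:
    @pytest.mark.parametrize(
        "snp,stratum,comparison,expected",
        [
            ("rs26653", Stratum.SMOKERS, "het_vs_ref", 1.01),
            ("rs26653", Stratum.SMOKERS, "hom_vs_ref", 2.56),
            ("rs26653", Stratum.NEVER_SMOKERS, "het_vs_ref", 0.51),
            ("rs26653", Stratum.NEVER_SMOKERS, "hom_vs_ref", 0.42),
            ("rs30187", Stratum.NEVER_SMOKERS, "het_vs_ref", 0.57),
            ("rs30187", Stratum.NEVER_SMOKERS, "hom_vs_ref", 0.32),
            ("rs27044", Stratum.NEVER_SMOKERS, "hom_vs_ref", 0.26),
            ("rs2287987", Stratum.NEVER_SMOKERS, "hom_vs_ref", 2.94),
        ],
    )
    def test_published_corrected_ors(self, snp, stratum, comparison, expected):
        res = genotype_or(get_counts(snp, stratum), comparison)
        assert round(res.or_value, 2) == expected

    def test_uncorrected_rs26653(self):
        res = genotype_or(get_counts("rs26653", Stratum.SMOKERS), "hom_vs_ref",
                          correction=False)
        assert round(res.or_value, 2) == 2.81  # (24*96)/(4*205)

    def test_symmetric_table_gives_unity(self):
        # a = b and c = d for the het-vs-ref slice
        c = make_counts((5, 10, 10), (7, 20, 20))
        for corr in (True, False):
            assert genotype_or(c, "het_vs_ref", correction=corr).or_value == pytest.approx(1.0)

    def test_zero_cell_requires_correction(self):
        c = make_counts((0, 5, 10), (2, 5, 10))
        with pytest.raises(ZeroDivisionError, match="correction"):
            genotype_or(c, "hom_vs_ref", correction=False)
        assert genotype_or(c, "hom_vs_ref").or_value > 0

    @given(st.tuples(*[st.integers(0, 500)] * 6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_cross_product(self, cells):
        a, h, b, c, k, d = cells
        counts = make_counts((a, h, b + 1), (c, k, d + 1))
        res = genotype_or(counts, "hom_vs_ref")
        oracle = ((a + 0.5) * (d + 1.5)) / ((b + 1.5) * (c + 0.5))
        assert res.or_value == pytest.approx(oracle, rel=1e-12)
        assert 0 < res.or_value < math.inf
        assert res.log_or == pytest.approx(math.log(res.or_value))


class TestConfidenceIntervals:
    def test_woolf_symmetric_about_unity(self):
        c = make_counts((50, 0, 50), (50, 0, 50))
        res = or_ci(genotype_or(c, "hom_vs_ref"), c, method="woolf")
        assert res.ci_low * res.ci_high == pytest.approx(1.0, rel=1e-9)

    def test_woolf_rs26653_smokers_hom(self):
        c = get_counts("rs26653", Stratum.SMOKERS)
        res = or_ci(genotype_or(c, "hom_vs_ref"), c, method="woolf")
        # closed-form Woolf with delta=0.5; differs from the printed
        # bootstrap interval (1.07; 10.1)
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (0.91, 7.19)

    def test_bootstrap_seeded_determinism(self):
        c = get_counts("rs26653", Stratum.SMOKERS)
        r1 = or_ci(genotype_or(c, "hom_vs_ref"), c, method="bootstrap", reps=10_000, seed=5)
        r2 = or_ci(genotype_or(c, "hom_vs_ref"), c, method="bootstrap", reps=10_000, seed=5)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        with pytest.raises(ValueError):
            or_ci(genotype_or(c, "hom_vs_ref"), c, method="bootstrap", reps=100)


@pytest.mark.parametrize("het_or,expected", [(0.51, 0.2601), (1.0, 1.0), (2.0, 4.0)])
def test_additive_prediction(het_or, expected):
    assert additive_prediction(het_or) == pytest.approx(expected)


class TestHWE:
    def test_rs26653_smoker_controls(self):
        res = hwe(get_counts("rs26653", Stratum.SMOKERS).control_counts)
        assert round(res.f, 2) == -0.18

    def test_exact_hwe_proportions_give_zero(self):
        res = hwe((25, 50, 25))
        assert res.f == pytest.approx(0.0, abs=1e-15)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_chi2_against_pearson_oracle(self):
        # observed vs n*(p^2, 2pq, q^2) Pearson chi-square
        counts = get_counts("rs26653", Stratum.SMOKERS).control_counts  # (4, 73, 96)
        res = hwe(counts)
        n = sum(counts)
        p = res.p_c
        expected = n * np.array([p ** 2, 2 * p * (1 - p), (1 - p) ** 2])
        pearson = (((np.array(counts) - expected) ** 2) / expected).sum()
        assert res.chi2 == pytest.approx(pearson, rel=1e-9)
        assert round(res.chi2, 2) == 5.40
        assert res.p_value == pytest.approx(0.020, abs=5e-4)

    def test_exact_method_close_to_chi2_here(self):
        counts = get_counts("rs26653", Stratum.SMOKERS).control_counts
        res = hwe(counts, method="exact")
        assert 0.01 < res.p_value < 0.03

    def test_sign_convention_heterozygote_excess_negative(self):
        assert hwe((0, 60, 40)).f < 0  # no homozygotes for the minor allele
        assert hwe((30, 10, 60)).f > 0  # heterozygote deficiency

    def test_monomorphic_flagged(self):
        res = hwe((0, 0, 50))
        assert res.flag == "monomorphic"
        assert math.isnan(res.f)

    @given(st.integers(1, 99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_f_zero_iff_exact_hwe_counts(self, k):
        # counts exactly proportional to (p^2, 2pq, q^2) with p = k/100
        n = 100
        counts = (k * k, 2 * k * (n - k), (n - k) * (n - k))
        res = hwe(counts)
        assert res.f == pytest.approx(0.0, abs=1e-12)


class TestScoreAndPstar:
    def test_null_identity(self):
        c = make_counts((10, 20, 30), (10, 20, 30))
        stat, p = score_test_1df(c)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_rs2248374_never_smokers_matches_brute_force(self):
        from apmstrata import CaseStatus

        c = get_counts("rs2248374", Stratum.NEVER_SMOKERS)
        stat, _ = score_test_1df(c)
        # independent oracle: N * r^2 over expanded individual dosage/status
        dos, status = [], []
        case = c.dosage_counts(CaseStatus.CASE)
        ctrl = c.dosage_counts(CaseStatus.CONTROL)
        for d, (nc, nk) in enumerate(zip(case, ctrl)):
            dos += [d] * int(nc + nk)
            status += [1] * int(nc) + [0] * int(nk)
        r = stats.pearsonr(dos, status).statistic
        assert stat == pytest.approx(len(dos) * r ** 2, rel=1e-9)
        assert stat == pytest.approx(0.29, abs=0.005)

    def test_invariant_to_dosage_reversal(self):
        c = make_counts((5, 21, 31), (31, 68, 57))
        flipped = make_counts((31, 21, 5), (57, 68, 31))
        assert score_test_1df(c)[0] == pytest.approx(score_test_1df(flipped)[0], rel=1e-12)

    def test_pstar_null_is_one(self):
        c1 = make_counts((10, 20, 30), (10, 20, 30), Stratum.SMOKERS)
        c2 = make_counts((5, 10, 15), (5, 10, 15), Stratum.NEVER_SMOKERS)
        assert pstar(c1, c2).pstar_p == pytest.approx(1.0)

    def test_pstar_rs2248374_reproduces_printed_value(self):
        res = pstar(get_counts("rs2248374", Stratum.SMOKERS),
                    get_counts("rs2248374", Stratum.NEVER_SMOKERS))
        assert res.pstar_p == pytest.approx(0.861, abs=0.005)
        assert res.pstar_stat == pytest.approx(sum(res.per_stratum_chi2))

    def test_pstar_monotone_in_effect_size(self):
        # stronger genotype effect -> smaller P*, on expected-count tables
        pvals = []
        for or_hom in (1.0, 1.5, 2.0, 3.0):
            n = 400
            p0 = np.array([0.09, 0.42, 0.49])  # control genotype distribution
            w = p0 * np.array([or_hom, math.sqrt(or_hom), 1.0])
            p1 = w / w.sum()
            c1 = make_counts(tuple((p1 * n).astype(int)), tuple((p0 * n).astype(int)),
                             Stratum.SMOKERS)
            c2 = make_counts(tuple((p1 * n).astype(int)), tuple((p0 * n).astype(int)),
                             Stratum.NEVER_SMOKERS)
            pvals.append(pstar(c1, c2).pstar_p)
        assert all(a > b for a, b in zip(pvals, pvals[1:]))


class TestGeneGlobal:
    def test_published_erap1_combination(self):
        res = gene_global_test([0.011, 0.182, 0.036, 0.017, 0.069], gene="ERAP1")
        assert round(res.stat, 1) == 32.6
        assert res.df == 10

    def test_identity_and_single_term(self):
        assert gene_global_test([1.0, 1.0]).stat == pytest.approx(0.0)
        assert gene_global_test([1.0, 1.0]).p_value == pytest.approx(1.0)
        single = gene_global_test([0.04])
        assert single.stat == pytest.approx(-2 * math.log(0.04))
        assert single.df == 2
        assert single.p_value == pytest.approx(stats.chi2.sf(-2 * math.log(0.04), 2))

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            gene_global_test([0.0, 0.5])

    def test_uniform_inputs_give_uniform_pvalues(self, rng):
        # KS audit on 5000 replicates of L=5 independent uniforms
        u = rng.uniform(size=(5000, 5))
        ps = stats.chi2.sf(-2 * np.log(u).sum(axis=1), df=10)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMantelHaenszel:
    def test_single_stratum_collapses_to_raw_or(self):
        res = mantel_haenszel([np.array([[20, 30], [10, 40]])])
        assert res.or_mh == pytest.approx((20 * 40) / (30 * 10))
        assert res.breslow_stat == 0.0

    def test_identical_strata_homogeneous(self):
        t = np.array([[20, 30], [10, 40]])
        res = mantel_haenszel([t, t])
        assert res.or_mh == pytest.approx((20 * 40) / (30 * 10))
        assert res.breslow_stat == pytest.approx(0.0, abs=1e-9)
        assert res.p_mh == pytest.approx(1.0)

    def test_rs26653_het_reproduces_printed_ormh(self):
        strata = [get_counts("rs26653", s) for s in (Stratum.SMOKERS, Stratum.NEVER_SMOKERS)]
        res = mantel_haenszel_from_counts(strata, "het_vs_ref")
        # direct formula: (158*96/532 + 17*73/194) / (205*73/532 + 37*67/194)
        oracle = (158 * 96 / 532 + 17 * 73 / 194) / (205 * 73 / 532 + 37 * 67 / 194)
        assert res.or_mh == pytest.approx(oracle, rel=1e-9)
        assert round(res.or_mh, 2) == 0.85  # as printed
        assert round(res.ci[0], 2) == 0.62 and round(res.ci[1], 2) == 1.17

    def test_stratum_permutation_invariance(self):
        t1, t2 = np.array([[20, 30], [10, 40]]), np.array([[5, 15], [25, 35]])
        assert mantel_haenszel([t1, t2]).or_mh == pytest.approx(
            mantel_haenszel([t2, t1]).or_mh)

    def test_empty_margin_dropped_with_warning(self):
        good = np.array([[20, 30], [10, 40]])
        bad = np.array([[0, 0], [10, 40]])
        with pytest.warns(UserWarning, match="margin"):
            res = mantel_haenszel([good, bad])
        assert res.n_strata == 1

    def test_ormh_between_stratum_ors(self):
        strata = [get_counts("rs2248374", s) for s in (Stratum.SMOKERS, Stratum.NEVER_SMOKERS)]
        res = mantel_haenszel_from_counts(strata, "het_vs_ref")
        raw = []
        for c in strata:
            a, b = c.case_counts[1], c.case_counts[2]
            cc, d = c.control_counts[1], c.control_counts[2]
            raw.append((a * d) / (b * cc))
        assert min(raw) <= res.or_mh <= max(raw)


class TestScan:
    def test_table2_scan_shape_and_gene_df(self):
        scan = run_association_scan(builtin_table2_counts())
        snp_tab, gene_tab = scan["snp_table"], scan["gene_table"]
        assert len(snp_tab) == 6
        assert (snp_tab["error"] == "").all()
        erap1 = gene_tab[gene_tab["gene"] == "ERAP1"].iloc[0]
        assert erap1["L"] == 5 and erap1["df"] == 10
        # ordering: gene then snp
        assert list(snp_tab["gene"]) == sorted(snp_tab["gene"])

    def test_empty_input(self):
        scan = run_association_scan([])
        assert scan["snp_table"].empty and scan["gene_table"].empty

    def test_scan_deterministic(self):
        a = run_association_scan(builtin_table2_counts(), seed=7)["snp_table"]
        b = run_association_scan(builtin_table2_counts(), seed=7)["snp_table"]
        assert a.equals(b)
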