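import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apmstrata import (
    CohortTable,
    aad_contrast_anova,
    cox_ph,
    kaplan_meier,
    or_contrast_weights,
    ordinal_response_model,
    sn_estimator,
    stage_mahalanobis_mc,
    survival_at,
)

from conftest import make_cohort


class TestSn:
    def test_constant_vector_zero(self):
        assert sn_estimator([5.0] * 10).value == 0.0

    def test_one_two_three(self):
        assert sn_estimator([1, 2, 3]).value == 1.0

    def test_matches_exhaustive_double_median(self, rng):
        for n in (2, 3, 7, 20, 55):
            x = rng.normal(size=n) * 10
            inner = [np.median([abs(xi - xj) for xj in x]) for xi in x]
            assert sn_estimator(x).value == pytest.approx(np.median(inner), abs=1e-12)

    @given(st.floats(-50, 50), st.floats(0.1, 20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_location_invariant_scale_equivariant(self, c, k):
        x = np.array([1.4, -2.2, 0.7, 9.1, 3.3, -0.5])
        base = sn_estimator(x).value
        assert sn_estimator(x + c).value == pytest.approx(base, abs=1e-9)
        assert sn_estimator(k * x).value == pytest.approx(k * base, rel=1e-9)

    def test_rejects_short_input(self):
        with pytest.raises(ValueError):
            sn_estimator([1.0])


def _aad_cohort(rng, shift=0.0, n_per_cell=200):
    """Cohort with genotype x stratum AAD cells; optional shift in smoker g2."""
    rows = []
    for g in (0, 1, 2):
        for stratum in ("smokers", "never_smokers"):
            mu = 64.0 + (shift if (g == 2 and stratum == "smokers") else 0.0)
            for i in range(n_per_cell):
                rows.append({
                    "id": f"{g}{stratum}{i}",
                    "status": "case",
                    "stratum": stratum,
                    "sex": "male" if rng.random() < 0.7 else "female",
                    "age_at_diagnosis": rng.normal(mu, 9.0),
                    "rs1": float(g),
                })
    return CohortTable(pd.DataFrame(rows), ["rs1"])


class TestContrastAnova:
    def test_weights_centered_log_ors(self):
        w = or_contrast_weights({0: 1.0, 1: 1.0, 2: 4.0})
        assert sum(w.values()) == pytest.approx(0.0, abs=1e-12)
        assert w[2] == pytest.approx(2 * math.log(4.0) / 3)
        with pytest.raises(ValueError):
            or_contrast_weights({0: 1.0, 1: 1.0})

    def test_identical_cells_give_zero_f(self):
        # every genotype x stratum cell holds the same outcome values
        rows = []
        for g in (0, 1, 2):
            for stratum in ("smokers", "never_smokers"):
                for i, age in enumerate([58.0, 62.0, 66.0, 70.0]):
                    rows.append({"id": f"{g}{stratum}{i}", "status": "case",
                                 "stratum": stratum, "age_at_diagnosis": age,
                                 "rs1": float(g)})
        cohort = CohortTable(pd.DataFrame(rows), ["rs1"])
        fit = aad_contrast_anova(cohort, "rs1", {0: -1.0, 1: 0.0, 2: 1.0})
        assert fit.f_stat == pytest.approx(0.0, abs=1e-18)
        assert fit.p_value == pytest.approx(1.0)

    def test_recovers_injected_shift(self, rng):
        cohort = _aad_cohort(rng, shift=-3.0, n_per_cell=2000)
        fit = aad_contrast_anova(cohort, "rs1", {(2, "smokers"): 1.0, (0, "smokers"): -1.0})
        cm = fit.cell_means.set_index(["genotype", "stratum"])["expected_outcome"]
        diff = cm.loc[(2, "smokers")] - cm.loc[(0, "smokers")]
        assert diff == pytest.approx(-3.0, abs=0.5)
        assert fit.p_value < 0.01

    def test_r_squared_matches_brute_force(self, rng):
        cohort = _aad_cohort(rng, shift=-5.0, n_per_cell=5)  # 30 rows
        fit = aad_contrast_anova(cohort, "rs1", {0: -1.0, 1: 0.0, 2: 1.0})
        df = cohort.df
        # brute force: SSE from cell+sex model predictions vs SST about mean
        y = df["age_at_diagnosis"].to_numpy()
        sst = ((y - y.mean()) ** 2).sum()
        import statsmodels.formula.api as smf

        ols = smf.ols("age_at_diagnosis ~ C(rs1):C(stratum) + sex", data=df).fit()
        assert fit.r_squared == pytest.approx(1 - ols.ssr / sst, abs=1e-6)

    def test_nonzero_sum_weights_rejected(self, rng):
        cohort = _aad_cohort(rng, n_per_cell=10)
        with pytest.raises(ValueError, match="zero"):
            aad_contrast_anova(cohort, "rs1", {0: 1.0, 2: 1.0})


class TestMahalanobisMC:
    def test_null_small_d2(self, rng):
        stage = rng.integers(1, 5, 400).astype(float)
        groups = rng.integers(0, 2, 400)
        res = stage_mahalanobis_mc(stage, groups, n_mc=999, seed=3)
        assert res.p_mc > 0.01
        assert res.p_mc * (res.n_mc + 1) == pytest.approx(round(res.p_mc * (res.n_mc + 1)))

    def test_separated_groups_detected(self, rng):
        a = rng.normal(2.0, 1.0, 100)
        b = rng.normal(3.0, 1.0, 100)
        res = stage_mahalanobis_mc(np.r_[a, b], np.r_[np.zeros(100), np.ones(100)],
                                   n_mc=9999, seed=4)
        assert res.p_mc < 0.01

    def test_within_stratum_permutation_null(self, rng):
        stage = rng.integers(1, 5, 300).astype(float)
        groups = rng.integers(0, 2, 300)
        strata = rng.integers(0, 2, 300)
        res = stage_mahalanobis_mc(stage, groups, n_mc=999, seed=8, strata=strata)
        assert 0 < res.p_mc <= 1

    def test_seeded_determinism(self, rng):
        stage = rng.integers(1, 5, 120).astype(float)
        groups = rng.integers(0, 3, 120)
        r1 = stage_mahalanobis_mc(stage, groups, n_mc=999, seed=9)
        r2 = stage_mahalanobis_mc(stage, groups, n_mc=999, seed=9)
        assert (r1.d2, r1.p_mc) == (r2.d2, r2.p_mc)


class TestSurvival:
    def test_km_closed_form(self):
        km = kaplan_meier([1, 2, 3], [True, True, True])
        s = survival_at(km, [1, 2, 3])
        assert list(np.round(s, 6)) == [round(2 / 3, 6), round(1 / 3, 6), 0.0]

    def test_all_censored_flat(self):
        km = kaplan_meier([5, 8, 12], [False, False, False])
        assert (km.survival_function_["KM_estimate"] == 1.0).all()

    def test_ten_subject_mixed_vs_hand_product_limit(self):
        times = [2, 3, 3, 5, 6, 7, 9, 10, 12, 15]
        events = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0]
        km = kaplan_meier(times, events)
        # hand product-limit: at each event time t, factor (1 - d/n_at_risk)
        s, at_risk = 1.0, 10
        expected = {}
        for t, d, c in [(2, 1, 0), (3, 1, 1), (5, 1, 0), (6, 0, 1), (7, 1, 0),
                        (9, 1, 0), (10, 0, 1), (12, 1, 0), (15, 0, 1)]:
            if d:
                s *= 1 - d / at_risk
            expected[t] = s
            at_risk -= d + c
        for t, v in expected.items():
            got = float(np.asarray(survival_at(km, [t])).ravel()[0])
            assert got == pytest.approx(v, abs=1e-9)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 50) + 0.01
        km = kaplan_meier(t, np.ones(50, dtype=bool))
        grid = np.quantile(t, [0.2, 0.5, 0.8])
        emp = [(t > g).mean() for g in grid]
        assert np.allclose(survival_at(km, grid), emp, atol=1e-9)

    def test_cox_null_and_recovery(self, rng):
        n = 1000
        x = rng.integers(0, 2, n).astype(float)
        t_null = rng.exponential(10, n)
        df = pd.DataFrame({"survival_time": t_null, "event": True, "x": x})
        fit = cox_ph(df, ["x"])
        assert abs(fit.cox.loc["x", "coef"]) < 0.15

        t_eff = rng.exponential(10, n) / np.exp(math.log(2.0) * x)
        cens = rng.uniform(0, 25, n)
        df2 = pd.DataFrame({
            "survival_time": np.minimum(t_eff, cens),
            "event": t_eff <= cens,
            "x": x,
        })
        fit2 = cox_ph(df2, ["x"])
        assert 1.8 < fit2.cox.loc["x", "hr"] < 2.2

    def test_cox_requires_event(self):
        df = pd.DataFrame({"survival_time": [1.0, 2.0], "event": [False, False],
                           "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="event"):
            cox_ph(df, ["x"])


class TestOrdinalModel:
    def test_binary_case_matches_two_by_two(self, rng):
        # binary response + binary predictor: OR is the cross-product ratio
        a, b, c, d = 40, 60, 25, 75  # (x=1,y=1),(x=1,y=0),(x=0,y=1),(x=0,y=0)
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        df = pd.DataFrame({"response": y.astype(int), "x": x})
        fit = ordinal_response_model(df, "response", ["x"], reps=0)
        assert fit.or_table["or"].iloc[0] == pytest.approx((a * d) / (b * c), rel=1e-3)

    def test_null_predictor_beta_near_zero(self, rng):
        n = 2000
        df = pd.DataFrame({
            "response": rng.integers(1, 5, n),
            "x": rng.normal(size=n),
        })
        fit = ordinal_response_model(df, "response", ["x"], reps=0)
        assert abs(fit.beta["x"]) < 0.1

    def test_thresholds_increasing_and_bootstrap_seeded(self, rng):
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        latent = 0.6 * x + rng.logistic(size=n)
        resp = np.digitize(latent, [-1.0, 0.2, 1.4]) + 1
        df = pd.DataFrame({"response": resp, "x": x})
        f1 = ordinal_response_model(df, "response", ["x"], reps=1000, seed=21)
        f2 = ordinal_response_model(df, "response", ["x"], reps=1000, seed=21)
        assert np.all(np.diff(f1.alpha) > 0)
        assert f1.or_table.equals(f2.or_table)
        assert f1.or_table["ci_low"].iloc[0] < f1.or_table["or"].iloc[0] < f1.or_table["ci_high"].iloc[0]
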