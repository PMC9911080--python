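"""Dysgenesis cross statistics and the qPCR expression analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import oracle_fisher
from pirnahd import (CrossDesign, boxcox_lambda, classify_extremes,
                     dysgenic_proportion, fisher_exact_2x2, line_effect_glm,
                     line_resistance, reciprocal_fisher, relative_expression,
                     replicate_concordance, screen_correlation,
                     simulate_cross_counts, splicing_anova)


class TestProportions:
    @pytest.mark.parametrize("d,n,expected", [
        (20, 80, 0.20), (93, 7, 0.93), (0, 50, 0.0)])
    def test_examples(self, d, n, expected):
        assert dysgenic_proportion(d, n) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            dysgenic_proportion(0, 0)

    def test_line_resistance_is_one_minus_mean_proportion(self):
        table = pd.DataFrame([
            {"line": "A", "direction": "dysgenic", "n_dysgenic": 20,
             "n_normal": 80},
            {"line": "A", "direction": "dysgenic", "n_dysgenic": 40,
             "n_normal": 60},
            {"line": "A", "direction": "reciprocal", "n_dysgenic": 0,
             "n_normal": 100},
        ])
        assert line_resistance(table)["A"] == pytest.approx(1 - 0.3)


class TestFisher:
    def test_enumerated_examples(self):
        # margins (4,4,4,4): five tables, p = 34/70
        assert fisher_exact_2x2(3, 1, 1, 3) == pytest.approx(34 / 70,
                                                             rel=1e-9)
        # diagonal table: 2 of the 252 equiprobable arrangements
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252,
                                                             rel=1e-9)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_all_zero_table(self):
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_matches_exact_enumeration_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            got = fisher_exact_2x2(a, b, c, d)
            want = oracle_fisher(a, b, c, d)
            assert got == pytest.approx(want, rel=1e-7, abs=1e-12)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            want = sps.fisher_exact([[a, b], [c, d]])[1]
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(want,
                                                                 rel=1e-6)

    def test_reciprocal_fisher_flags_dysgenic_lines(self):
        table = pd.DataFrame([
            {"line": "hot", "tester_subline": "T1", "direction": "dysgenic",
             "n_dysgenic": 80, "n_normal": 20},
            {"line": "hot", "tester_subline": "T1", "direction": "reciprocal",
             "n_dysgenic": 2, "n_normal": 98},
            {"line": "cold", "tester_subline": "T1", "direction": "dysgenic",
             "n_dysgenic": 3, "n_normal": 97},
            {"line": "cold", "tester_subline": "T1",
             "direction": "reciprocal", "n_dysgenic": 2, "n_normal": 98},
        ])
        res = reciprocal_fisher(table)
        assert res.loc["hot", "fisher_p"] < 0.05 < res.loc["cold", "fisher_p"]


class TestLineEffectGlm:
    def _two_line_table(self, d1, d2, n=100):
        return pd.DataFrame([
            {"line": "A", "tester_subline": "T1", "direction": "dysgenic",
             "n_dysgenic": d1, "n_normal": n - d1},
            {"line": "B", "tester_subline": "T1", "direction": "dysgenic",
             "n_dysgenic": d2, "n_normal": n - d2},
        ])

    def test_saturated_closed_form_log_odds(self):
        res = line_effect_glm(self._two_line_table(30, 70))
        expected = math.log((70 / 30) / (30 / 70))  # ~ 1.6946
        assert res.coefficients["line[B]"] == pytest.approx(expected,
                                                            abs=1e-4)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm
        table = pd.DataFrame([
            {"line": ln, "tester_subline": sub, "direction": "dysgenic",
             "n_dysgenic": d, "n_normal": 120 - d}
            for (ln, sub, d) in [("A", "T1", 25), ("A", "T2", 31),
                                 ("B", "T1", 60), ("B", "T2", 70),
                                 ("C", "T1", 44), ("C", "T2", 50)]])
        res = line_effect_glm(table)
        X = pd.get_dummies(table[["line", "tester_subline"]],
                           drop_first=True, dtype=float)
        X.insert(0, "const", 1.0)
        y = table[["n_dysgenic", "n_normal"]].to_numpy()
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(res.coefficients.to_numpy(), fit.params.to_numpy(),
                           atol=1e-6)
        assert res.deviance == pytest.approx(fit.deviance, abs=1e-6)

    def test_identical_lines_give_null_lrt(self):
        res = line_effect_glm(self._two_line_table(50, 50))
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_deviance_trace_non_increasing(self):
        res = line_effect_glm(self._two_line_table(20, 85))
        trace = res.deviance_trace
        assert all(b <= a + 1e-6 for a, b in zip(trace, trace[1:]))

    def test_power_on_separated_line_logits(self):
        hits = 0
        n_sim = 40
        for i in range(n_sim):
            design = CrossDesign(lines={"A": -1.0, "B": 1.0},
                                 tester_sublines={"T1": 0.0, "T2": 0.2},
                                 n_f1_per_cross=200,
                                 directions=("dysgenic",), seed=500 + i)
            res = line_effect_glm(simulate_cross_counts(design))
            if res.p_value < 0.05:
                hits += 1
        assert hits >= int(0.95 * n_sim)

    def test_separation_flagged(self):
        res = line_effect_glm(self._two_line_table(0, 100))
        assert res.separation


class TestScreenCorrelation:
    def test_perfect_linear_relations(self):
        x = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        r, _ = screen_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r2, _ = screen_correlation(x, -x)
        assert r2 == pytest.approx(-1.0)

    def test_t_transform_p_value(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=12)
        y = 0.8 * x + rng.normal(scale=0.5, size=12)
        r, p = screen_correlation(x, y)
        t = r * math.sqrt((12 - 2) / (1 - r * r))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 10), rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            screen_correlation([1, 1, 1], [1, 2, 3])

    def test_replicate_concordance_paired_t(self):
        x = [0.2, 0.4, 0.6, 0.8]
        y = [0.25, 0.42, 0.62, 0.83]
        t, p = replicate_concordance(x, y)
        t_ref, p_ref = sps.ttest_rel(x, y)
        assert (t, p) == (pytest.approx(float(t_ref)),
                          pytest.approx(float(p_ref)))


class TestClassifyExtremes:
    def test_simple_split(self):
        res = classify_extremes({"A": 0.1, "B": 0.5, "C": 0.9}, k=1)
        assert res.resistant == ["A"] and res.susceptible == ["C"]
        assert not res.tied

    def test_disjoint_sets_of_size_k(self, rng):
        means = {f"L{i}": float(rng.random()) for i in range(12)}
        res = classify_extremes(means, k=3)
        assert len(res.resistant) == len(res.susceptible) == 3
        assert not set(res.resistant) & set(res.susceptible)

    def test_boundary_tie_flagged_lexicographic(self):
        res = classify_extremes({"A": 0.2, "B": 0.2, "C": 0.8, "D": 0.9},
                                k=1)
        assert res.resistant == ["A"] and res.tied

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            classify_extremes({"A": 0.1, "B": 0.9}, k=2)


def _qpcr_frame(rows):
    return pd.DataFrame(rows)


class TestRelativeExpression:
    def _rows(self, ct_spliced, ct_total, ct_ref):
        base = {"line": "A", "direction": "dysgenic", "temperature": 29,
                "replicate": 1}
        return _qpcr_frame([
            dict(base, target="spliced", ct=ct_spliced),
            dict(base, target="total", ct=ct_total),
            dict(base, target="reference", ct=ct_ref),
        ])

    def test_delta_ct_identities(self):
        expr = relative_expression(self._rows(20, 20, 20))
        assert expr["spliced_expr"].iloc[0] == pytest.approx(1.0)
        expr2 = relative_expression(self._rows(18, 19, 20))
        assert expr2["spliced_expr"].iloc[0] == pytest.approx(4.0)
        assert expr2["total_expr"].iloc[0] == pytest.approx(2.0)
        assert expr2["splicing_efficiency"].iloc[0] == pytest.approx(2.0)

    def test_efficiency_ratio(self):
        expr = relative_expression(self._rows(19, 18, 20))
        # spliced 2, total 4 -> efficiency 0.5
        assert expr["splicing_efficiency"].iloc[0] == pytest.approx(0.5)

    def test_invariant_to_constant_ct_shift(self):
        a = relative_expression(self._rows(18, 19, 20))
        b = relative_expression(self._rows(21, 22, 23))
        for col in ("spliced_expr", "total_expr", "splicing_efficiency"):
            assert a[col].iloc[0] == pytest.approx(b[col].iloc[0])

    def test_missing_reference_rejected(self):
        df = self._rows(18, 19, 20)
        with pytest.raises(ValueError):
            relative_expression(df[df["target"] != "reference"])


class TestBoxCox:
    def test_lambda_one_transform_is_x_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, y = boxcox_lambda(x, grid=(1.0, 1.0, 0.01))
        assert np.allclose(y, x - 1.0)

    def test_normal_data_recovers_lambda_near_one(self):
        rng = np.random.default_rng(11)
        x = rng.normal(10, 2, size=500)
        lam, _ = boxcox_lambda(x)
        assert abs(lam - 1.0) < 0.5

    def test_lognormal_data_recovers_lambda_near_zero(self):
        rng = np.random.default_rng(12)
        x = np.exp(rng.normal(0, 1, size=500))
        lam, _ = boxcox_lambda(x)
        assert abs(lam) < 0.2

    def test_agrees_with_scipy_profile_mle(self):
        rng = np.random.default_rng(13)
        x = rng.gamma(2.0, 3.0, size=400)
        lam, _ = boxcox_lambda(x)
        lam_scipy = sps.boxcox_normmax(x, method="mle")
        assert abs(lam - float(lam_scipy)) <= 0.02

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            boxcox_lambda([1.0, -2.0, 3.0, 4.0, 5.0])


class TestSplicingAnova:
    def _design(self, rng, direction_effect=0.0, line_effect=0.0):
        rows = []
        for line in ("A", "B", "C"):
            for direction in ("dysgenic", "reciprocal"):
                for temp in (25, 29):
                    for rep in range(3):
                        y = (rng.normal(0, 1)
                             + direction_effect * (direction == "dysgenic")
                             + line_effect * (line == "B"))
                        rows.append({"line": line, "direction": direction,
                                     "temperature": temp, "y": y})
        return pd.DataFrame(rows)

    def test_constant_response_has_zero_factor_sums_of_squares(self):
        rng = np.random.default_rng(14)
        df = self._design(rng)
        df["y"] = 3.14
        table = splicing_anova(df, "y")
        assert table.loc[["direction", "temperature", "line"],
                         "sum_sq"].max() < 1e-20

    def test_planted_direction_effect_dominates(self):
        rng = np.random.default_rng(15)
        df = self._design(rng, direction_effect=3.0)
        table = splicing_anova(df, "y")
        f = table["F"].dropna()
        assert f.idxmax() == "direction"

    def test_f_equals_t_squared_on_two_level_factor(self):
        rng = np.random.default_rng(16)
        df = self._design(rng, direction_effect=1.0)
        table = splicing_anova(df, "y", factors=("direction",))
        a = df[df["direction"] == "dysgenic"]["y"]
        b = df[df["direction"] == "reciprocal"]["y"]
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert table.loc["direction", "F"] == pytest.approx(float(t) ** 2,
                                                            rel=1e-9)

    def test_null_line_effect_calibration(self):
        rng = np.random.default_rng(17)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            df = self._design(rng, direction_effect=1.0, line_effect=0.0)
            table = splicing_anova(df, "y")
            if table.loc["line", "PR(>F)"] < 0.05:
                hits += 1
        assert hits <= 0.10 * n_sim  # line p > 0.05 in >= 90% of null sims
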