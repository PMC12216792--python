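"""Inferential layer: assumption checks, t/ANOVA/ANCOVA/RM-ANOVA/Tukey/Pearson."""
import numpy as np
import pandas as pd
import pytest

from boldmaze.errors import (
    DegenerateDataError,
    DesignError,
    InsufficientDataError,
)
from boldmaze.stats import (
    ancova,
    assumption_checks,
    pearson_matrix,
    rm_anova,
    tukey_hsd,
    two_sample_t,
    two_way_anova,
)


class TestAssumptionChecks:
    def test_identical_samples_homogeneous(self, rng):
        # two identical large normal samples: Bartlett statistic 0, p = 1
        a = rng.normal(0, 1, 500)
        normality, bartlett_p = assumption_checks({"a": a, "b": a.copy()})
        assert bartlett_p > 0.99
        assert all(p > 0.01 for p in normality.values())

    def test_tenfold_variance_detected(self, rng):
        a, b = rng.normal(0, 1, 50), rng.normal(0, np.sqrt(10), 50)
        _, bartlett_p = assumption_checks({"a": a, "b": b})
        assert bartlett_p < 0.05

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateDataError):
            assumption_checks({"a": np.ones(5), "b": np.arange(5.0)})

    def test_small_group_insufficient(self):
        with pytest.raises(InsufficientDataError):
            assumption_checks({"a": np.array([1.0, 2.0])})


class TestTwoSampleT:
    def test_identical_samples(self):
        t, df, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_pooled_formula(self):
        # pooled SD = 1, SE = sqrt(2/3), t = -3 / 0.8165 = -3.674
        t, df, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4

    def test_cohort_degrees_of_freedom(self, rng):
        t, df, p = two_sample_t(rng.normal(size=23), rng.normal(size=23))
        assert df == 44

    def test_zero_pooled_variance(self):
        with pytest.raises(DegenerateDataError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])


class TestTwoWayAnova:
    @staticmethod
    def _table(values):
        rows = []
        for (a, b), ys in values.items():
            rows += [{"A": a, "B": b, "y": y} for y in ys]
        return pd.DataFrame(rows)

    def test_hand_computed_balanced_design(self):
        # cells (1,2),(3,4),(5,6),(7,8): SS_A=32, SS_B=8, SS_AB=0, MS_err=0.5
        table = self._table({("a1", "b1"): [1, 2], ("a1", "b2"): [3, 4],
                             ("a2", "b1"): [5, 6], ("a2", "b2"): [7, 8]})
        res = two_way_anova(table, "y", ("A", "B"))
        assert res.effect("A")["F"] == pytest.approx(64.0)
        assert res.effect("B")["F"] == pytest.approx(16.0)
        assert res.effect("A:B")["F"] == pytest.approx(0.0, abs=1e-10)
        assert res.effect("A")["df_num"] == 1
        assert res.effect("A")["df_den"] == 4

    def test_pure_main_effect(self, rng):
        table = self._table({
            ("a1", "b1"): rng.normal(0, 0.01, 6), ("a1", "b2"): rng.normal(0, 0.01, 6),
            ("a2", "b1"): rng.normal(1, 0.01, 6), ("a2", "b2"): rng.normal(1, 0.01, 6)})
        res = two_way_anova(table, "y", ("A", "B"))
        assert res.effect("A")["F"] > 100 * max(res.effect("B")["F"],
                                                res.effect("A:B")["F"])

    def test_constant_response_degenerate(self):
        table = self._table({("a1", "b1"): [1, 1], ("a1", "b2"): [1, 1],
                             ("a2", "b1"): [1, 1], ("a2", "b2"): [1, 1]})
        res = two_way_anova(table, "y", ("A", "B"))
        assert np.isnan(res.effect("A")["F"])
        assert res.notes  # degeneracy reported

    def test_empty_cell_named(self):
        table = self._table({("a1", "b1"): [1, 2], ("a1", "b2"): [3, 4],
                             ("a2", "b1"): [5, 6]})
        with pytest.raises(DesignError, match="a2"):
            two_way_anova(table, "y", ("A", "B"))


class TestAncova:
    @staticmethod
    def _table(rng, n=12, cov_effect=0.0, a_effect=0.0):
        rows = []
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                cov = rng.normal(10, 2, n)
                y = (cov_effect * cov + a_effect * (a == "a2")
                     + rng.normal(0, 1, n))
                rows += [{"A": a, "B": b, "cov": c, "y": v}
                         for c, v in zip(cov, y)]
        return pd.DataFrame(rows)

    def test_independent_covariate_matches_plain_anova(self, rng):
        table = self._table(rng, n=50, a_effect=1.0)
        plain = two_way_anova(table, "y", ("A", "B"))
        adj = ancova(table, "y", ("A", "B"), "cov")
        assert adj.effect("A")["F"] == pytest.approx(plain.effect("A")["F"], rel=0.10)

    def test_pure_covariate_response(self, rng):
        table = self._table(rng, cov_effect=2.0)
        table["y"] = 2.0 * table["cov"]  # exact linear relation, no factor effect
        res = ancova(table, "y", ("A", "B"), "cov")
        assert res.effect("cov")["F"] > 1e6 or np.isnan(res.effect("cov")["F"])
        p_a = res.effect("A")["p"]
        assert np.isnan(p_a) or p_a > 0.5

    def test_constant_covariate_reduces_to_anova(self, rng):
        table = self._table(rng)
        table["cov"] = 5.0
        res = ancova(table, "y", ("A", "B"), "cov")
        plain = two_way_anova(table, "y", ("A", "B"))
        assert res.effect("A")["F"] == pytest.approx(plain.effect("A")["F"])
        assert any("constant" in n for n in res.notes)


class TestRmAnova:
    @staticmethod
    def _long(values_by_group):
        rows = []
        for g, matrix in values_by_group.items():
            for s, vec in enumerate(matrix):
                for b, v in enumerate(vec, start=1):
                    rows.append({"subject_id": f"{g}{s}", "group": g,
                                 "bin": b, "y": v})
        return pd.DataFrame(rows)

    def test_built_in_interaction_detected(self, rng):
        groups = {}
        for gi, g in enumerate(["g1", "g2", "g3", "g4"]):
            base = rng.normal(0, 1, (12, 6))
            if g == "g4":
                base[:, 3:] += 2.0  # one group shifts at bin 4
            groups[g] = base
        res = rm_anova(self._long(groups), "y")
        assert res.effect("group:bin")["p"] < 0.05
        assert res.effect("bin")["df_num"] == 5
        assert res.effect("group")["df_num"] == 3

    def test_two_bins_time_f_equals_adjusted_paired_t2(self, rng):
        # classical identity: with 2 within levels the time F equals the
        # paired t^2 up to the error-df ratio (N-2)/(N-1) once the second
        # group's difference scores are a permutation of the first's
        n = 20
        d = rng.normal(0.4, 1.0, n)
        g1 = np.column_stack([rng.normal(0, 1, n), np.zeros(n)])
        g1[:, 1] = g1[:, 0] + d
        g2 = np.column_stack([rng.normal(5, 1, n), np.zeros(n)])
        g2[:, 1] = g2[:, 0] + rng.permutation(d)
        res = rm_anova(self._long({"g1": g1, "g2": g2}), "y")
        diffs = np.concatenate([d, d])
        t2 = (len(diffs) * diffs.mean() ** 2) / diffs.var(ddof=1)
        expected = t2 * (2 * n - 2) / (2 * n - 1)
        assert res.effect("bin")["F"] == pytest.approx(expected, rel=1e-6)

    def test_incomplete_subjects_dropped_and_logged(self, rng):
        df = self._long({"g1": rng.normal(size=(5, 6)), "g2": rng.normal(size=(5, 6))})
        df = df[~((df.subject_id == "g10") & (df.bin > 3))]  # fish with 3 bins
        res = rm_anova(df, "y")
        assert any("g10" in n for n in res.notes)

    def test_too_few_per_group(self, rng):
        df = self._long({"g1": rng.normal(size=(1, 6)), "g2": rng.normal(size=(5, 6))})
        with pytest.raises(InsufficientDataError):
            rm_anova(df, "y")


class TestTukey:
    def test_two_groups_matches_t_test(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        values = np.concatenate([a, b])
        groups = ["a"] * 15 + ["b"] * 15
        tk = tukey_hsd(values, groups)
        _, _, p_t = two_sample_t(a, b)
        assert tk["p_adj"].iloc[0] == pytest.approx(p_t, abs=1e-3)

    def test_identical_means(self):
        values = np.tile([1.0, 2.0, 3.0], 3)
        groups = np.repeat(["a", "b", "c"], 3)
        tk = tukey_hsd(values, groups)
        assert (tk["p_adj"] > 0.9).all()

    def test_single_shifted_group(self, rng):
        base = rng.normal(0, 1, (2, 12))
        shifted = rng.normal(5, 1, 12)  # 5 SD shift
        values = np.concatenate([base[0], base[1], shifted])
        groups = np.repeat(["a", "b", "c"], 12)
        tk = tukey_hsd(values, groups).set_index(["group1", "group2"])
        assert tk.loc[("a", "c"), "p_adj"] < 0.001
        assert tk.loc[("b", "c"), "p_adj"] < 0.001
        assert tk.loc[("a", "b"), "p_adj"] > 0.5

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            tukey_hsd([1.0, 2.0], ["a", "a"])


class TestPearsonMatrix:
    @staticmethod
    def _table(x, y, treatment="CTRL"):
        return pd.DataFrame({"x": x, "y": y, "treatment": treatment})

    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        mats = pearson_matrix(self._table(x, 2 * x + 1), ["x", "y"])
        assert mats["CTRL"].loc["x", "y"] == pytest.approx(1.0)
        mats = pearson_matrix(self._table(x, -x), ["x", "y"])
        assert mats["CTRL"].loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        mats = pearson_matrix(self._table([1, 2, 3, 4], [2, 1, 4, 3]), ["x", "y"])
        assert mats["CTRL"].loc["x", "y"] == pytest.approx(0.6)

    def test_symmetry_unit_diagonal_by_group(self, rng):
        df = pd.DataFrame({
            "x": rng.normal(size=40), "y": rng.normal(size=40),
            "z": rng.normal(size=40),
            "treatment": np.repeat(["CTRL", "CAS"], 20)})
        mats = pearson_matrix(df, ["x", "y", "z"])
        assert set(mats) == {"CTRL", "CAS"}
        for mat in mats.values():
            np.testing.assert_allclose(mat.values, mat.values.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(mat.values), 1.0)

    def test_constant_variable_undefined_not_zero(self):
        df = self._table([1.0, 2.0, 3.0, 4.0], [1.0, 1.0, 1.0, 1.0])
        mats = pearson_matrix(df, ["x", "y"])
        assert np.isnan(mats["CTRL"].loc["x", "y"])
        assert np.isnan(mats["CTRL"].loc["y", "y"])

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            pearson_matrix(self._table([1.0, 2.0], [1.0, 2.0]), ["x", "y"])
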