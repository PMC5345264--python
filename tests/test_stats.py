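"""Association statistics against independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from shoremeth import stats as ss
from shoremeth.config import SimulationConfig
from shoremeth.errors import DegenerateTableError
from shoremeth.simulate import generate_cohort


# ---------------------------------------------------------------------------
# oracles (direct formula evaluation, independent of the implementation path)


def chi_square_oracle(table):
    table = np.asarray(table, dtype=float)
    n = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / n
            stat += (table[i, j] - e) ** 2 / e
    return stat


def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return t, df


def anova_oracle(groups):
    groups = [np.asarray(g, float) for g in groups]
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


# ---------------------------------------------------------------------------
# summaries


class TestSummarizeCohort:
    def test_percentages_one_decimal(self):
        subjects = ss.subjects_from_counts({
            "GG": {"n": 211}, "GA": {"n": 119}, "AA": {"n": 19}})
        out = ss.summarize_cohort(subjects)
        cases = out[out["feature"] == "cases"].iloc[0]
        assert cases["GG_n"] == 211 and cases["GG_pct"] == 60.5
        assert cases["GA_pct"] == 34.1 and cases["AA_pct"] == 5.4

    def test_msi_fraction_within_genotype(self):
        subjects = ss.subjects_from_counts({
            "GG": {"n": 211, "msi_high": 30},
            "GA": {"n": 119, "msi_high": 24},
            "AA": {"n": 19, "msi_high": 8}})
        out = ss.summarize_cohort(subjects)
        msih = out[(out["feature"] == "msi") & (out["level"] == "MSI-H")].iloc[0]
        assert msih["AA_n"] == 8 and msih["AA_pct"] == 42.1
        assert msih["All_n"] == 62 and msih["All_pct"] == 17.8

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            ss.summarize_cohort(pd.DataFrame())


def test_pooled_mean_weighted():
    """Genotype-stratified means pool to the printed overall means."""
    assert round(ss.pooled_mean([30.1, 28.3, 22.6], [211, 119, 19]), 1) == 29.1
    assert round(ss.pooled_mean([33.3, 32.8, 37.0], [211, 119, 19]), 1) == 33.3


# ---------------------------------------------------------------------------
# elementary tests vs oracles


class TestPearsonChiSquare:
    def test_uniform_table(self):
        r = ss.pearson_chi_square([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)
        assert r.df == 1

    def test_msi_by_genotype_table(self):
        """Counts from the cohort summary agree with the hand oracle."""
        table = [[181, 95, 11], [30, 24, 8]]
        r = ss.pearson_chi_square(table)
        assert r.statistic == pytest.approx(chi_square_oracle(table), abs=1e-10)
        assert r.df == 2
        assert r.p_value < 0.01  # MSI-H enrichment in AA carriers

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateTableError):
            ss.pearson_chi_square([[0, 0], [5, 5]])

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    def test_random_2x2_vs_oracle(self, cells):
        table = np.array(cells, float).reshape(2, 2)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return
        r = ss.pearson_chi_square(table)
        assert r.statistic == pytest.approx(chi_square_oracle(table), abs=1e-10)


class TestTTest:
    def test_identical_groups(self):
        r = ss.independent_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_location_shift_significant(self, rng):
        a = rng.normal(0, 1, 500)
        r = ss.independent_t_test(a, a + 1.0)
        assert r.p_value < 1e-10

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_welch_vs_oracle(self, seed):
        g = np.random.default_rng(seed)
        a = g.normal(0, 1, g.integers(3, 20))
        b = g.normal(0.5, 2, g.integers(3, 20))
        r = ss.independent_t_test(a, b)
        t, df = welch_oracle(a, b)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.df == pytest.approx(df, abs=1e-8)
        assert r.p_value == pytest.approx(
            2 * sps.t.sf(abs(t), df), abs=1e-10)

    def test_stage_comparison_monte_carlo(self):
        """Stage I-III vs IV at printed parameters is decisively significant."""
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            a = g.normal(34.1, 7.3, 328)
            b = g.normal(20.8, 3.6, 21)
            if ss.independent_t_test(a, b).p_value < 1e-4:
                hits += 1
        assert hits == 20


class TestAnova:
    def test_identical_values_f_zero(self):
        r = ss.one_way_anova([[5.0, 5, 5], [5.0, 5, 5]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 9)
        f = ss.one_way_anova([a, b])
        t = ss.independent_t_test(a, b, equal_var=True)
        assert f.statistic == pytest.approx(t.statistic ** 2, abs=1e-9)
        assert f.p_value == pytest.approx(t.p_value, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_f_vs_oracle(self, seed):
        g = np.random.default_rng(seed)
        groups = [g.normal(g.normal(), 1, g.integers(3, 15)) for _ in range(3)]
        r = ss.one_way_anova(groups)
        assert r.statistic == pytest.approx(anova_oracle(groups), abs=1e-10)
        assert r.df == (2, sum(len(x) for x in groups) - 3)


# ---------------------------------------------------------------------------
# regression


class TestRegression:
    def test_exact_linear_relation(self):
        df = pd.DataFrame({"pmr": [2.0, 4, 6, 8, 10],
                           "age": [1.0, 2, 3, 4, 5]})
        r = ss.multiple_linear_regression(df, predictors=["age"])
        assert r.params["age"] == pytest.approx(2.0, abs=1e-10)
        assert r.marginal.loc["age", "r"] == pytest.approx(1.0, abs=1e-10)

    def test_independent_predictor_near_zero_r(self, rng):
        df = pd.DataFrame({"pmr": rng.normal(30, 5, 2000),
                           "age": rng.normal(60, 9, 2000)})
        r = ss.multiple_linear_regression(df, predictors=["age"])
        assert abs(r.marginal.loc["age", "r"]) < 0.05
        assert r.marginal.loc["age", "r"] == pytest.approx(
            pearson_oracle(df["age"], df["pmr"]), abs=1e-10)

    def test_singular_design_names_columns(self):
        df = pd.DataFrame({"pmr": [1.0, 2, 3, 4, 5, 6],
                           "age": [1.0, 2, 3, 4, 5, 6],
                           "age2": [2.0, 4, 6, 8, 10, 12]})
        with pytest.raises(ValueError, match="collinear.*age"):
            ss.multiple_linear_regression(df, predictors=["age", "age2"])

    def test_genotype_effect_recovered(self):
        """Additive genotype effect of -3 per A allele is inside its 95% CI."""
        cfg = SimulationConfig(seed=31)
        cfg.tissue_genotype_params = dict(cfg.tissue_genotype_params)
        for g, m in (("GG", 30.0), ("GA", 27.0), ("AA", 24.0)):
            cfg.tissue_genotype_params[("PBMC", g)] = (m, 4.5)
        cohort = generate_cohort(cfg)
        df = pd.DataFrame({
            "pmr": [s.true_shore_methylation["PBMC"] for s in cohort],
            "genotype": [s.genotype for s in cohort]})
        r = ss.multiple_linear_regression(df, predictors=["genotype_additive"])
        lo, hi = r.conf_int.loc["genotype_additive"]
        assert lo <= -3.0 <= hi
        assert r.params["genotype_additive"] == pytest.approx(-3.0, abs=1.0)


# ---------------------------------------------------------------------------
# matched-tissue mixed model


def _long(y, subjects, tissues):
    return pd.DataFrame({"subject_id": subjects, "tissue": tissues, "pmr": y})


class TestMixedModel:
    def test_pure_subject_effects_give_null_contrasts(self):
        """Equal tissues within each subject: tissue contrasts are 0, p = 1."""
        n = 30
        rng = np.random.default_rng(1)
        base = rng.normal(30, 5, n)
        rows = []
        for i in range(n):
            for t in ("PBMC", "normal_colon", "tumour"):
                rows.append({"subject_id": f"s{i}", "tissue": t, "pmr": base[i]})
        res = ss.matched_tissue_mixed_model(pd.DataFrame(rows))
        for _, row in res.contrasts.iterrows():
            assert row["estimate"] == pytest.approx(0.0, abs=1e-6)
            assert row["p"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_between_subject_variance_matches_anova(self):
        """With no subject effect, contrasts equal group-mean differences."""
        rng = np.random.default_rng(2)
        n = 80
        rows = []
        means = {"PBMC": 29.0, "normal_colon": 30.5, "tumour": 33.3}
        for i in range(n):
            for t, m in means.items():
                rows.append({"subject_id": f"s{i}", "tissue": t,
                             "pmr": rng.normal(m, 5.0)})
        df = pd.DataFrame(rows)
        res = ss.matched_tissue_mixed_model(df)
        grp = df.groupby("tissue")["pmr"].mean()
        assert res.contrasts.loc["tumour - PBMC", "estimate"] == pytest.approx(
            grp["tumour"] - grp["PBMC"], abs=1e-6)
        assert res.contrasts.loc["normal_colon - PBMC", "estimate"] == pytest.approx(
            grp["normal_colon"] - grp["PBMC"], abs=1e-6)
        # fitted subject variance collapses toward zero
        assert res.subject_variance < 1.0

    def test_balanced_estimates_match_closed_form(self):
        """Balanced complete data: fixed effects equal tissue means."""
        rng = np.random.default_rng(3)
        n = 40
        rows = []
        subj_eff = rng.normal(0, 3, n)
        means = {"PBMC": 29.0, "tumour": 34.0}
        for i in range(n):
            for t, m in means.items():
                rows.append({"subject_id": f"s{i}", "tissue": t,
                             "pmr": m + subj_eff[i] + rng.normal(0, 2)})
        df = pd.DataFrame(rows)
        res = ss.matched_tissue_mixed_model(df)
        grp = df.groupby("tissue")["pmr"].mean()
        assert res.contrasts.loc["tumour - PBMC", "estimate"] == pytest.approx(
            grp["tumour"] - grp["PBMC"], abs=1e-6)
        assert res.subject_variance > 1.0  # real between-subject variance found

    def test_no_within_subject_information_errors(self):
        df = _long([1.0, 2.0], ["a", "b"], ["PBMC", "tumour"])
        with pytest.raises(ValueError, match="within-subject"):
            ss.matched_tissue_mixed_model(df)

    def test_tumour_hypermethylation_detected_at_study_parameters(self):
        """Tumour vs normal and tumour vs PBMC contrasts: positive, p < 0.05."""
        cfg = SimulationConfig(seed=17)
        cohort = generate_cohort(cfg)
        rows = []
        for s in cohort:
            for t, v in s.true_shore_methylation.items():
                rows.append({"subject_id": s.subject_id, "tissue": t, "pmr": v})
        res = ss.matched_tissue_mixed_model(pd.DataFrame(rows))
        tn = res.contrasts.loc["tumour - normal_colon"]
        tp = res.contrasts.loc["tumour - PBMC"]
        assert tn["estimate"] > 0 and tn["p"] < 0.05
        assert tp["estimate"] > 0 and tp["p"] < 0.05
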