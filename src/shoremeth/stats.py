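"""Association statistics for genotype/tissue/stage methylation analyses.

Implements the statistical layer of the shore-methylation analysis:
Table-1-style cohort summaries, Pearson chi-square contingency tests,
Welch/pooled t-tests, one-way ANOVA, multiple linear regression of PMR
on covariates (with marginal Pearson correlations reported alongside OLS
coefficients), and a random-intercept linear mixed model comparing
matched tissues from the same subject.  All p-values are two-sided and
no multiple-testing adjustment is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import DegenerateTableError

GENOTYPE_ADDITIVE = {"GG": 0, "GA": 1, "AA": 2}  # A-allele dose
COHORT_COLUMNS = ("subject_id", "tissue", "pmr", "genotype", "age", "sex",
                  "stage_binary", "msi_binary", "island_methylated")


@dataclass
class TestResult:
    name: str
    statistic: float
    df: object  # float or (df1, df2)
    p_value: float
    group_summaries: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _summary(name, values) -> dict:
    v = np.asarray(values, dtype=float)
    return {"group": name, "n": int(v.size), "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0}


# ---------------------------------------------------------------------------
# cohort table construction and summaries


def make_cohort_table(subjects: pd.DataFrame, pmr: pd.DataFrame) -> pd.DataFrame:
    """Long-format subjects x tissues table feeding the association layer.

    ``subjects`` has one row per subject (subject_id, genotype, age, sex,
    stage, msi_class, island_methylated); ``pmr`` has one row per
    (sample_id, tissue) with a ``pmr`` column.  Stage is binarized I-III
    vs IV ("unavailable" becomes missing); MSI is binarized MSS/MSI-L vs
    MSI-H.
    """
    df = pmr.rename(columns={"sample_id": "subject_id"}).merge(
        subjects, on="subject_id", how="inner", validate="many_to_one")
    if df.duplicated(["subject_id", "tissue"]).any():
        raise ValueError("more than one PMR record per (subject, tissue)")
    if (df["pmr"].dropna() < 0).any():
        raise ValueError("negative PMR in cohort table")
    stage = df["stage"].astype(object)
    df["stage_binary"] = [
        np.nan if s in ("unavailable", None) or pd.isna(s)
        else ("IV" if int(s) == 4 else "I-III")
        for s in stage
    ]
    df["msi_binary"] = df["msi_class"]
    return df[[c for c in df.columns]].copy()


def summarize_cohort(subjects: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style counts and one-decimal percentages by genotype.

    Rows cover case counts, mean age (SD), sex, TNM stage, binarized MSI
    status, CpG-island methylation and MMR germline mutation (when the
    corresponding columns are present); columns are All/GG/GA/AA.
    Percentages are of the genotype-column total, rounded to one decimal.
    """
    if subjects.empty:
        raise ValueError("empty cohort")
    cols = ["All", "GG", "GA", "AA"]
    groups = {"All": subjects}
    for g in ("GG", "GA", "AA"):
        groups[g] = subjects[subjects["genotype"] == g]
    rows = []

    def add(feature, level, fn):
        row = {"feature": feature, "level": level}
        for c in cols:
            sub = groups[c]
            row[f"{c}_n"], row[f"{c}_pct"] = fn(sub)
        rows.append(row)

    add("cases", "", lambda s: (len(s), round(100.0 * len(s) / len(subjects), 1)))

    if "age" in subjects:
        row = {"feature": "age", "level": "mean (SD)"}
        for c in cols:
            a = groups[c]["age"].astype(float)
            row[f"{c}_n"] = round(float(a.mean()), 1) if len(a) else np.nan
            row[f"{c}_pct"] = round(float(a.std(ddof=1)), 1) if len(a) > 1 else np.nan
        rows.append(row)

    def count_pct(colname, value):
        def fn(s):
            n = int((s[colname] == value).sum())
            return n, round(100.0 * n / len(s), 1) if len(s) else np.nan
        return fn

    if "sex" in subjects:
        for level in ("female", "male"):
            add("sex", level, count_pct("sex", level))
    if "stage" in subjects:
        for level in (1, 2, 3, 4, "unavailable"):
            add("stage", str(level), count_pct("stage", level))
    if "msi_class" in subjects:
        for level in ("MSS/MSI-L", "MSI-H"):
            add("msi", level, count_pct("msi_class", level))
    if "island_methylated" in subjects:
        col = subjects["island_methylated"]
        for label, match in (("unmethylated", False), ("methylated", True)):
            add("island", label,
                lambda s, m=match: (
                    int(s["island_methylated"].eq(m).fillna(False).sum()),
                    round(100.0 * int(s["island_methylated"].eq(m)
                                      .fillna(False).sum()) / len(s), 1)))
        if col.isna().any():
            add("island", "unavailable",
                lambda s: (int(s["island_methylated"].isna().sum()),
                           round(100.0 * int(s["island_methylated"].isna().sum())
                                 / len(s), 1)))
    if "mmr_mutation" in subjects:
        for label, match in (("no", False), ("yes", True)):
            add("mmr_mutation", label, count_pct("mmr_mutation", match))
    return pd.DataFrame(rows)


def subjects_from_counts(counts: dict) -> pd.DataFrame:
    """Expand published per-genotype count margins into a subject table.

    ``counts`` maps genotype -> {"n", "female", "stage": {level: n},
    "msi_high", "island_methylated", "island_unavailable", "mmr_mutation",
    "age_mean"}; any key other than "n" may be omitted.  Attributes are
    assigned jointly in a fixed order, which reproduces every marginal
    count exactly (the summaries only consume margins).
    """
    rows = []
    for g, c in counts.items():
        n = c["n"]
        stages: list = []
        for level, k in c.get("stage", {}).items():
            stages.extend([level] * k)
        stages.extend(["unavailable"] * (n - len(stages)))
        n_f = c.get("female", 0)
        n_msi = c.get("msi_high", 0)
        n_isl = c.get("island_methylated", 0)
        n_isl_na = c.get("island_unavailable", 0)
        n_mmr = c.get("mmr_mutation", 0)
        for i in range(n):
            rows.append({
                "subject_id": f"{g}{i + 1:04d}",
                "genotype": g,
                "age": float(c.get("age_mean", 60.0)),
                "sex": "female" if i < n_f else "male",
                "stage": stages[i],
                "msi_class": "MSI-H" if i < n_msi else "MSS/MSI-L",
                "island_methylated": (True if i < n_isl
                                      else (pd.NA if i >= n - n_isl_na
                                            else False)),
                "mmr_mutation": i < n_mmr,
            })
    return pd.DataFrame(rows)


def pooled_mean(means: Sequence[float], weights: Sequence[float]) -> float:
    """Count-weighted pooled mean of stratified group means."""
    means = np.asarray(means, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(means * weights) / np.sum(weights))


# ---------------------------------------------------------------------------
# elementary tests


def pearson_chi_square(table) -> TestResult:
    """Pearson chi-square for an r x c count table (no continuity correction)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("negative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero margin in contingency table")
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return TestResult("pearson_chi_square", float(stat), int(df), float(p))


def independent_t_test(group_a, group_b, equal_var: bool = False) -> TestResult:
    """Two-sided independent-samples t-test (Welch by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return TestResult("t_test", 0.0, float(a.size + b.size - 2), 1.0,
                              [_summary("a", a), _summary("b", b)])
        raise ValueError("degenerate groups with zero variance")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    name = "t_test_pooled" if equal_var else "t_test_welch"
    return TestResult(name, float(res.statistic), float(res.df),
                      float(res.pvalue), [_summary("a", a), _summary("b", b)])


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA across k groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df = (k - 1, n_total - k)
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return TestResult("one_way_anova", 0.0, df, 1.0,
                          [_summary(i, a) for i, a in enumerate(arrays)])
    res = sps.f_oneway(*arrays)
    return TestResult("one_way_anova", float(res.statistic), df,
                      float(res.pvalue), [_summary(i, a) for i, a in enumerate(arrays)])


# ---------------------------------------------------------------------------
# regression


@dataclass
class RegressionReport:
    """OLS fit plus per-predictor marginal Pearson correlations.

    ``params``/``bse``/``p_values``/``conf_int`` come from the OLS fit
    (including the intercept); ``marginal`` maps each predictor to its
    unadjusted Pearson r and two-sided p against the outcome, the way
    per-variable correlations are reported alongside a multivariable
    model.
    """

    outcome: str
    n: int
    params: pd.Series
    bse: pd.Series
    p_values: pd.Series
    conf_int: pd.DataFrame
    r_squared: float
    marginal: pd.DataFrame  # index: predictor; columns: r, p


def _design_matrix(table: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=table.index)
    for pred in predictors:
        if pred == "tissue":
            for t in ("normal_colon", "tumour"):  # PBMC is reference level
                X[f"tissue_{t}"] = (table["tissue"] == t).astype(float)
        elif pred == "genotype_additive":
            X["genotype_additive"] = table["genotype"].map(GENOTYPE_ADDITIVE).astype(float)
        elif pred == "sex":
            X["sex_male"] = (table["sex"] == "male").astype(float)
        elif pred == "stage_binary":
            X["stage_IV"] = (table["stage_binary"] == "IV").astype(float)
        elif pred == "msi_binary":
            X["msi_high"] = (table["msi_binary"] == "MSI-H").astype(float)
        elif pred == "island_methylated":
            X["island_methylated"] = table["island_methylated"].astype(float)
        else:
            X[pred] = table[pred].astype(float)
    return X


def multiple_linear_regression(
        table: pd.DataFrame, outcome: str = "pmr",
        predictors: Sequence[str] = ("tissue", "genotype_additive", "age", "sex",
                                     "stage_binary", "msi_binary",
                                     "island_methylated")) -> RegressionReport:
    """OLS of the outcome on the predictor set, with marginal correlations.

    Rows with a missing outcome or predictor are dropped.  Genotype is
    coded additively by A-allele dose (GG=0, GA=1, AA=2); tissue enters
    as treatment-coded dummies with PBMC as reference.  A singular
    design raises, naming the collinear columns.
    """
    src_cols = set([outcome])
    for pred in predictors:
        src_cols.add({"genotype_additive": "genotype"}.get(pred, pred))
    sub = table.dropna(subset=[c for c in src_cols if c in table.columns]).copy()
    y = sub[outcome].astype(float)
    X = _design_matrix(sub, predictors)
    if len(sub) <= X.shape[1] + 1:
        raise ValueError("not enough observations for the predictor set")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        bad = []
        base = Xc.to_numpy()
        for j, col in enumerate(Xc.columns):
            reduced = np.delete(base, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(col)
        raise ValueError(f"singular design; collinear columns: {bad}")
    fit = sm.OLS(y, Xc).fit()
    marg_rows = []
    for col in X.columns:
        x = X[col].to_numpy()
        if np.std(x) == 0:
            marg_rows.append({"predictor": col, "r": np.nan, "p": np.nan})
            continue
        r, p = sps.pearsonr(x, y.to_numpy())
        marg_rows.append({"predictor": col, "r": float(r), "p": float(p)})
    marginal = pd.DataFrame(marg_rows).set_index("predictor")
    return RegressionReport(outcome, int(len(sub)), fit.params, fit.bse,
                            fit.pvalues, fit.conf_int(), float(fit.rsquared),
                            marginal)


# ---------------------------------------------------------------------------
# matched-tissue mixed model


@dataclass
class MixedModelResult:
    """Random-intercept model of PMR across matched tissues.

    Fixed effects are tissue levels (treatment-coded, PBMC reference);
    each subject contributes a random intercept, inducing compound
    symmetry among that subject's tissues.  Fit by maximum likelihood.
    """

    n_obs: int
    n_subjects: int
    fixed_effects: pd.Series
    subject_variance: float
    residual_variance: float
    contrasts: pd.DataFrame  # index: contrast; columns: estimate, se, z, p
    converged: bool


def matched_tissue_mixed_model(table: pd.DataFrame,
                               outcome: str = "pmr") -> MixedModelResult:
    """Compare tissues within subjects via a random-intercept mixed model."""
    sub = table.dropna(subset=[outcome]).copy()
    tissues = sorted(sub["tissue"].unique(),
                     key=lambda t: ["PBMC", "normal_colon", "tumour"].index(t)
                     if t in ("PBMC", "normal_colon", "tumour") else 99)
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues")
    counts = sub.groupby("subject_id")["tissue"].nunique()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects with >= 2 tissues "
                         "(no within-subject information)")
    y = sub[outcome].astype(float).to_numpy()
    X = pd.DataFrame({"const": 1.0}, index=sub.index)
    for t in tissues[1:]:
        X[f"tissue_{t}"] = (sub["tissue"] == t).astype(float)
    model = sm.MixedLM(y, X.to_numpy(), groups=sub["subject_id"].to_numpy())
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False)
    k_fe = X.shape[1]
    params = pd.Series(fit.fe_params, index=X.columns)
    cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]
    subject_var = float(np.asarray(fit.cov_re)[0, 0])
    resid_var = float(fit.scale)

    def contrast(name, vec):
        est = float(vec @ params.to_numpy())
        se = float(np.sqrt(vec @ cov @ vec))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = est / se
            p = 2.0 * sps.norm.sf(abs(z))
        return {"contrast": name, "estimate": est, "se": se, "z": z, "p": p}

    rows = []
    ref = tissues[0]
    cols = list(X.columns)
    for t in tissues[1:]:
        vec = np.zeros(k_fe)
        vec[cols.index(f"tissue_{t}")] = 1.0
        rows.append(contrast(f"{t} - {ref}", vec))
    for i in range(1, len(tissues)):
        for j in range(i + 1, len(tissues)):
            vec = np.zeros(k_fe)
            vec[cols.index(f"tissue_{tissues[j]}")] = 1.0
            vec[cols.index(f"tissue_{tissues[i]}")] = -1.0
            rows.append(contrast(f"{tissues[j]} - {tissues[i]}", vec))
    contrasts = pd.DataFrame(rows).set_index("contrast")
    return MixedModelResult(
        n_obs=int(len(sub)),
        n_subjects=int(sub["subject_id"].nunique()),
        fixed_effects=params,
        subject_variance=subject_var,
        residual_variance=resid_var,
        contrasts=contrasts,
        converged=bool(getattr(fit, "converged", True)),
    )
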