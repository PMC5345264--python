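"""Statsmodels-style front door for the shore-methylation association analysis.

``ShoreAssociationModel`` wraps a long-format cohort table (one row per
subject x tissue with PMR and covariates); ``fit()`` runs the full
statistical layer — matched-tissue mixed model, per-tissue genotype
ANOVA with pairwise t-tests, stage/MSI/island comparisons in tumour DNA,
and the multivariable regression with marginal correlations — and
returns a results object with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as ss
from .config import GENOTYPES, TISSUES


class ShoreAssociationModel:
    """Association model for CpG-shore PMR across tissues and genotypes.

    Parameters
    ----------
    cohort : DataFrame
        Long format with columns subject_id, tissue, pmr, genotype, age,
        sex, stage_binary, msi_binary, island_methylated (see
        ``stats.make_cohort_table``).
    """

    def __init__(self, cohort: pd.DataFrame):
        missing = [c for c in ("subject_id", "tissue", "pmr", "genotype")
                   if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort table missing columns {missing}")
        self.cohort = cohort.copy()

    @classmethod
    def from_dataframe(cls, subjects: pd.DataFrame,
                       pmr: pd.DataFrame) -> "ShoreAssociationModel":
        """Build from a subject sheet plus a per-(sample, tissue) PMR table."""
        return cls(ss.make_cohort_table(subjects, pmr))

    def fit(self, equal_var: bool = False) -> "ShoreAssociationResults":
        df = self.cohort
        tissues = [t for t in TISSUES if t in set(df["tissue"])]

        tissue_mixed = None
        if len(tissues) >= 2:
            tissue_mixed = ss.matched_tissue_mixed_model(df)

        genotype_anova: dict[str, ss.TestResult] = {}
        pairwise_t: dict[str, dict[tuple[str, str], ss.TestResult]] = {}
        tissue_genotype_means: dict[str, list[dict]] = {}
        for tissue in tissues:
            sub = df[df["tissue"] == tissue]
            groups = [sub.loc[sub["genotype"] == g, "pmr"].dropna().to_numpy()
                      for g in GENOTYPES]
            groups = [g for g in groups if g.size >= 2]
            if len(groups) >= 2:
                genotype_anova[tissue] = ss.one_way_anova(groups)
            tissue_genotype_means[tissue] = [
                ss._summary(g, sub.loc[sub["genotype"] == g, "pmr"].dropna())
                for g in GENOTYPES if (sub["genotype"] == g).sum() > 0]
            pw = {}
            for i in range(len(GENOTYPES)):
                for j in range(i + 1, len(GENOTYPES)):
                    a = sub.loc[sub["genotype"] == GENOTYPES[i], "pmr"].dropna()
                    b = sub.loc[sub["genotype"] == GENOTYPES[j], "pmr"].dropna()
                    if len(a) >= 2 and len(b) >= 2:
                        pw[(GENOTYPES[i], GENOTYPES[j])] = ss.independent_t_test(
                            a, b, equal_var=equal_var)
            pairwise_t[tissue] = pw

        tum = df[df["tissue"] == "tumour"]
        stage_t = msi_t = island_t = None
        if "stage_binary" in tum:
            a = tum.loc[tum["stage_binary"] == "I-III", "pmr"].dropna()
            b = tum.loc[tum["stage_binary"] == "IV", "pmr"].dropna()
            if len(a) >= 2 and len(b) >= 2:
                stage_t = ss.independent_t_test(a, b, equal_var=equal_var)
        if "msi_binary" in tum:
            a = tum.loc[tum["msi_binary"] == "MSS/MSI-L", "pmr"].dropna()
            b = tum.loc[tum["msi_binary"] == "MSI-H", "pmr"].dropna()
            if len(a) >= 2 and len(b) >= 2:
                msi_t = ss.independent_t_test(a, b, equal_var=equal_var)
        if "island_methylated" in tum:
            a = tum.loc[tum["island_methylated"] == False, "pmr"].dropna()  # noqa: E712
            b = tum.loc[tum["island_methylated"] == True, "pmr"].dropna()  # noqa: E712
            if len(a) >= 2 and len(b) >= 2:
                island_t = ss.independent_t_test(a, b, equal_var=equal_var)

        preds_all = ["genotype_additive", "age", "sex", "stage_binary",
                     "msi_binary", "island_methylated"]
        if len(tissues) >= 2:
            preds_all = ["tissue"] + preds_all
        preds_all = [p for p in preds_all
                     if p in ("tissue", "genotype_additive")
                     or {"sex": "sex", "age": "age", "stage_binary": "stage_binary",
                         "msi_binary": "msi_binary",
                         "island_methylated": "island_methylated"}[p] in df.columns]
        regression_all = None
        regression_by_tissue: dict[str, ss.RegressionReport] = {}
        try:
            regression_all = ss.multiple_linear_regression(df, predictors=preds_all)
        except (ValueError, KeyError):
            pass
        per_tissue_preds = [p for p in preds_all if p != "tissue"]
        for tissue in tissues:
            try:
                regression_by_tissue[tissue] = ss.multiple_linear_regression(
                    df[df["tissue"] == tissue], predictors=per_tissue_preds)
            except (ValueError, KeyError):
                pass

        return ShoreAssociationResults(
            model=self, tissues=tissues, tissue_mixed=tissue_mixed,
            genotype_anova=genotype_anova, pairwise_t=pairwise_t,
            tissue_genotype_means=tissue_genotype_means,
            stage_t=stage_t, msi_t=msi_t, island_t=island_t,
            regression_all=regression_all,
            regression_by_tissue=regression_by_tissue)


@dataclass
class ShoreAssociationResults:
    """Fitted association results; ``summary()`` renders a report table."""

    model: ShoreAssociationModel
    tissues: list[str]
    tissue_mixed: Optional[ss.MixedModelResult]
    genotype_anova: dict[str, ss.TestResult]
    pairwise_t: dict[str, dict[tuple[str, str], ss.TestResult]]
    tissue_genotype_means: dict[str, list[dict]] = field(default_factory=dict)
    stage_t: Optional[ss.TestResult] = None
    msi_t: Optional[ss.TestResult] = None
    island_t: Optional[ss.TestResult] = None
    regression_all: Optional[ss.RegressionReport] = None
    regression_by_tissue: dict[str, ss.RegressionReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serializable report of every fitted test."""
        def tr(t: Optional[ss.TestResult]):
            if t is None:
                return None
            return {"name": t.name, "statistic": t.statistic,
                    "df": list(t.df) if isinstance(t.df, tuple) else t.df,
                    "p_value": t.p_value, "groups": t.group_summaries}

        out: dict = {"tissues": self.tissues}
        if self.tissue_mixed is not None:
            mm = self.tissue_mixed
            out["tissue_mixed_model"] = {
                "n_obs": mm.n_obs, "n_subjects": mm.n_subjects,
                "fixed_effects": {k: float(v)
                                  for k, v in mm.fixed_effects.items()},
                "subject_variance": mm.subject_variance,
                "residual_variance": mm.residual_variance,
                "contrasts": {idx: {k: float(v) for k, v in row.items()}
                              for idx, row in mm.contrasts.iterrows()},
                "converged": mm.converged,
            }
        out["genotype_anova"] = {t: tr(r) for t, r in self.genotype_anova.items()}
        out["pairwise_t"] = {
            t: {f"{a}_vs_{b}": tr(r) for (a, b), r in pw.items()}
            for t, pw in self.pairwise_t.items()}
        out["tissue_genotype_means"] = self.tissue_genotype_means
        out["stage_t"] = tr(self.stage_t)
        out["msi_t"] = tr(self.msi_t)
        out["island_t"] = tr(self.island_t)

        def reg(r: Optional[ss.RegressionReport]):
            if r is None:
                return None
            return {
                "n": r.n, "r_squared": r.r_squared,
                "coefficients": {k: {"estimate": float(r.params[k]),
                                     "se": float(r.bse[k]),
                                     "p": float(r.p_values[k]),
                                     "ci_low": float(r.conf_int.loc[k, 0]),
                                     "ci_high": float(r.conf_int.loc[k, 1])}
                                 for k in r.params.index},
                "marginal": {k: {"r": (None if np.isnan(row["r"])
                                       else float(row["r"])),
                                 "p": (None if np.isnan(row["p"])
                                       else float(row["p"]))}
                             for k, row in r.marginal.iterrows()},
            }

        out["regression_all"] = reg(self.regression_all)
        out["regression_by_tissue"] = {t: reg(r)
                                       for t, r in self.regression_by_tissue.items()}
        return out

    def summary(self) -> str:
        """Human-readable multi-section report."""
        lines = ["Shore methylation association results",
                 "=" * 46]
        if self.tissue_mixed is not None:
            mm = self.tissue_mixed
            lines.append(f"Matched-tissue mixed model (n={mm.n_obs} obs, "
                         f"{mm.n_subjects} subjects; ML, random intercept)")
            lines.append(f"  subject var {mm.subject_variance:.3f}, "
                         f"residual var {mm.residual_variance:.3f}")
            for idx, row in mm.contrasts.iterrows():
                lines.append(f"  {idx:28s} est {row['estimate']:+7.2f} "
                             f"se {row['se']:.2f}  p {row['p']:.3g}")
        for tissue in self.tissues:
            means = self.tissue_genotype_means.get(tissue, [])
            desc = ", ".join(f"{m['group']} {m['mean']:.1f} ({m['sd']:.1f})"
                             for m in means)
            lines.append(f"{tissue}: mean PMR (SD) by genotype: {desc}")
            if tissue in self.genotype_anova:
                a = self.genotype_anova[tissue]
                lines.append(f"  ANOVA F={a.statistic:.2f} "
                             f"df={a.df} p={a.p_value:.3g}")
            for (g1, g2), t in self.pairwise_t.get(tissue, {}).items():
                lines.append(f"  {g1} vs {g2}: t={t.statistic:+.2f} "
                             f"p={t.p_value:.3g}")
        for label, t in (("Stage I-III vs IV (tumour)", self.stage_t),
                         ("MSS/MSI-L vs MSI-H (tumour)", self.msi_t),
                         ("Island unmeth vs meth (tumour)", self.island_t)):
            if t is not None:
                lines.append(f"{label}: t={t.statistic:+.2f} df={t.df:.1f} "
                             f"p={t.p_value:.3g}")
        if self.regression_all is not None:
            r = self.regression_all
            lines.append(f"Multiple linear regression (n={r.n}, "
                         f"R^2={r.r_squared:.3f})")
            for k in r.params.index:
                marg = ""
                if k in r.marginal.index and not np.isnan(r.marginal.loc[k, "r"]):
                    marg = (f"  marginal r={r.marginal.loc[k, 'r']:+.3f} "
                            f"p={r.marginal.loc[k, 'p']:.3g}")
                lines.append(f"  {k:20s} b={r.params[k]:+8.3f} "
                             f"p={r.p_values[k]:.3g}{marg}")
        return "\n".join(lines)
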