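"""Inferential layer over the cohort table.

Thin, schema-stable wrappers around scipy, statsmodels and pingouin covering
the analysis plan of the boldness / Y-maze study design:

* Kolmogorov-Smirnov normality and Bartlett variance-homogeneity checks
  (reported, not gating);
* pooled-variance Student's t for bold-vs-shy NTT endpoints;
* two-way factorial ANOVA (Type-II SS) — phenotype x stress for total turns,
  tetragram-pattern (16 levels) x phenotype for choice frequencies;
* two-way ANCOVA with total turns as covariate for alternation/repetition
  percentages (homogeneity-of-slopes form: no factor x covariate terms);
* mixed (repeated-measures) ANOVA with time bin within and 4-level group
  between, Greenhouse-Geisser corrected when Mauchly's test rejects;
* Tukey HSD post hoc comparisons;
* per-treatment Pearson correlation matrices.

Significance is read at alpha = 0.05 throughout; no multiple-testing
correction beyond Tukey is applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats as ss
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import (
    DegenerateDataError,
    DesignError,
    InsufficientDataError,
)

__all__ = [
    "AnovaResult",
    "assumption_checks",
    "two_sample_t",
    "two_way_anova",
    "ancova",
    "rm_anova",
    "tukey_hsd",
    "pearson_matrix",
]


@dataclass
class AnovaResult:
    """An ANOVA-family fit: one row per effect plus a model descriptor.

    ``table`` columns: ``effect, df_num, df_den, F, p``. ``notes`` records
    degeneracies (zero residual variance, dropped covariate, applied
    sphericity correction).
    """

    model: str
    table: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def effect(self, name: str) -> pd.Series:
        match = self.table[self.table["effect"] == name]
        if match.empty:
            raise KeyError(f"no effect {name!r} in {self.model}; "
                           f"have {self.table['effect'].tolist()}")
        return match.iloc[0]


def assumption_checks(groups: dict[str, np.ndarray]) -> tuple[dict[str, float], float]:
    """Normality (KS) per group and variance homogeneity (Bartlett) across groups.

    Each group's KS test compares against a normal with that group's mean and
    SD. Results are meant to be logged alongside the main analysis, not to
    gate it. Raises for groups smaller than 3 or with zero variance.
    """
    normality: dict[str, float] = {}
    samples = []
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 3:
            raise InsufficientDataError(f"group {name!r}: need >= 3 values")
        sd = values.std(ddof=1)
        if sd == 0:
            raise DegenerateDataError(f"group {name!r}: constant sample")
        normality[name] = float(
            ss.kstest(values, "norm", args=(values.mean(), sd)).pvalue)
        samples.append(values)
    bartlett_p = float(ss.bartlett(*samples).pvalue) if len(samples) >= 2 else np.nan
    return normality, bartlett_p


def two_sample_t(a, b) -> tuple[float, int, float]:
    """Pooled-variance Student's t-test; returns ``(t, df, two-sided p)``.

    ``df = n_a + n_b - 2``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("both samples need >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, len(a) + len(b) - 2, 1.0
        raise DegenerateDataError("zero pooled variance with unequal means")
    res = ss.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), len(a) + len(b) - 2, float(res.pvalue)


def _check_cells(table: pd.DataFrame, factors: tuple[str, str]) -> None:
    a, b = factors
    counts = table.groupby([a, b], observed=True).size()
    full = pd.MultiIndex.from_product(
        [table[a].unique(), table[b].unique()], names=[a, b])
    missing = full.difference(counts.index)
    if len(missing):
        raise DesignError(f"empty design cell(s): {list(missing)}")


def _anova_from_lm(model_desc: str, fitted, effects: list[str],
                   labels: list[str]) -> AnovaResult:
    aov = sm.stats.anova_lm(fitted, typ=2)
    df_den = int(aov.loc["Residual", "df"])
    resid_ms = aov.loc["Residual", "sum_sq"] / max(df_den, 1)
    # residual variance at roundoff scale relative to the response means the
    # F ratios are 0/0 noise: report the fit as degenerate, not significant
    endog_var = float(np.var(fitted.model.endog))
    degenerate = endog_var == 0 or resid_ms <= 1e-10 * endog_var
    notes = []
    rows = []
    for term, label in zip(effects, labels):
        row = aov.loc[term]
        F, p = row["F"], row["PR(>F)"]
        if degenerate or not np.isfinite(F):
            F, p = np.nan, np.nan
            notes.append(f"{label}: degenerate (zero residual variance)")
        rows.append({"effect": label, "df_num": int(row["df"]),
                     "df_den": df_den, "F": F, "p": p})
    return AnovaResult(model=model_desc, table=pd.DataFrame(rows), notes=notes)


def two_way_anova(
    table: pd.DataFrame, response: str, factors: tuple[str, str]
) -> AnovaResult:
    """Two-way factorial ANOVA with interaction, Type-II sums of squares.

    Works for any pair of categorical factors, including the 16-level
    tetragram-pattern factor used for choice-frequency analysis.
    """
    a, b = factors
    data = table[[response, a, b]].dropna()
    _check_cells(data, factors)
    df = data.rename(columns={response: "_y", a: "_A", b: "_B"})
    fitted = ols("_y ~ C(_A) * C(_B)", data=df).fit()
    return _anova_from_lm(
        f"{response} ~ {a} * {b} (Type II)",
        fitted,
        ["C(_A)", "C(_B)", "C(_A):C(_B)"],
        [a, b, f"{a}:{b}"],
    )


def ancova(
    table: pd.DataFrame,
    response: str,
    factors: tuple[str, str],
    covariate: str,
) -> AnovaResult:
    """Two-way ANCOVA: factor effects adjusted for a numeric covariate.

    Homogeneity-of-slopes form — the covariate enters additively with no
    factor x covariate interaction. A constant covariate is dropped and the
    model falls back to the plain two-way ANOVA (noted in ``notes``).
    """
    a, b = factors
    data = table[[response, a, b, covariate]].dropna()
    _check_cells(data, factors)
    if data[covariate].nunique() <= 1:
        res = two_way_anova(data, response, factors)
        res.model = f"{response} ~ {a} * {b} (covariate {covariate} constant, dropped)"
        res.notes.append(f"covariate {covariate!r} constant; reduced to two-way ANOVA")
        return res
    df = data.rename(columns={response: "_y", a: "_A", b: "_B", covariate: "_cov"})
    fitted = ols("_y ~ C(_A) * C(_B) + _cov", data=df).fit()
    if fitted.df_resid <= 0:
        raise DesignError("covariate collinear with design: zero residual df")
    return _anova_from_lm(
        f"{response} ~ {a} * {b} + {covariate} (Type II)",
        fitted,
        ["C(_A)", "C(_B)", "_cov", "C(_A):C(_B)"],
        [a, b, covariate, f"{a}:{b}"],
    )


def rm_anova(
    binned: pd.DataFrame,
    dv: str,
    within: str = "bin",
    subject: str = "subject_id",
    between: str = "group",
) -> AnovaResult:
    """Mixed repeated-measures ANOVA: time bin within, group between.

    Subjects with incomplete bin vectors are dropped (listwise) and recorded
    in ``notes``. Sphericity of the within factor is assessed by Mauchly's
    test and the Greenhouse-Geisser correction applied when it rejects
    (pingouin's ``correction='auto'``); the corrected p-value is reported.
    """
    data = binned[[subject, between, within, dv]].dropna()
    n_levels = data[within].nunique()
    complete = data.groupby(subject)[within].nunique() == n_levels
    kept = complete[complete].index
    dropped = sorted(set(data[subject]) - set(kept))
    data = data[data[subject].isin(kept)]
    if data.empty:
        raise InsufficientDataError("no subject has a complete bin vector")
    group_sizes = data.groupby(between)[subject].nunique()
    if (group_sizes < 2).any() or len(group_sizes) < 2:
        raise InsufficientDataError(
            f"need >= 2 subjects in >= 2 groups; have {group_sizes.to_dict()}")

    aov = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                         between=between, correction="auto")
    notes = [f"dropped incomplete subjects: {dropped}"] if dropped else []
    rows = []
    for _, row in aov.iterrows():
        label = {"Interaction": f"{between}:{within}"}.get(row["Source"], row["Source"])
        p = row["p_unc"]
        if "p_GG_corr" in aov.columns and np.isfinite(row.get("p_GG_corr", np.nan)):
            p = row["p_GG_corr"]
            notes.append(f"{label}: Greenhouse-Geisser corrected "
                         f"(eps={row['eps']:.3f})")
        rows.append({"effect": label, "df_num": int(row["DF1"]),
                     "df_den": int(row["DF2"]), "F": row["F"], "p": p})
    return AnovaResult(
        model=f"{dv} ~ {between} (between) x {within} (within)",
        table=pd.DataFrame(rows), notes=notes)


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise Tukey HSD comparisons on the studentized-range distribution.

    Returns columns ``group1, group2, meandiff, ci_lower, ci_upper, p_adj,
    reject``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise InsufficientDataError("Tukey HSD needs >= 2 groups")
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    ci = np.asarray(res.confint)
    return pd.DataFrame({
        "group1": [p[0] for p in res._results_table.data[1:]],
        "group2": [p[1] for p in res._results_table.data[1:]],
        "meandiff": res.meandiffs,
        "ci_lower": ci[:, 0],
        "ci_upper": ci[:, 1],
        "p_adj": res.pvalues,
        "reject": res.reject,
    })


def pearson_matrix(
    table: pd.DataFrame, variables: list[str], by: str = "treatment"
) -> dict[str, pd.DataFrame]:
    """Pearson correlation matrix among ``variables``, separately per group.

    Constant variables yield NaN rows/columns (undefined, not zero); the
    diagonal is 1 wherever the variable varies.
    """
    out: dict[str, pd.DataFrame] = {}
    for level, sub in table.groupby(by, observed=True):
        data = sub[variables].dropna()
        if len(data) < 3:
            raise InsufficientDataError(
                f"{by}={level}: need >= 3 complete rows, have {len(data)}")
        mat = data.corr(method="pearson")
        constant = data.nunique() <= 1
        mat.loc[constant, :] = np.nan
        mat.loc[:, constant] = np.nan
        out[str(level)] = mat
    return out
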