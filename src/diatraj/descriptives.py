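"""Baseline descriptive tables and group-difference tests.

Continuous variables are summarised as median [Q1, Q3] by default (the
biomarkers are right-skewed) or mean ± SD; categoricals as n (%).  Group
differences use: Student/Welch t or Mann–Whitney U for two samples,
chi-square (Fisher's exact for sparse 2×2) for categoricals,
Kruskal–Wallis with post-hoc Dunn tests across the diabetes subtypes, and
one-way ANOVA with Dunnett tests of each subtype against the controls.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError


def proportion(n: int, total: int) -> float:
    """Percent share ``100 * n / total`` rounded to one decimal."""
    if total <= 0:
        raise ConfigurationError("proportion denominator must be positive")
    if n < 0 or n > total:
        raise ConfigurationError("numerator must lie in [0, total]")
    return round(100.0 * n / total, 1)


def summarize_continuous(values, style: str = "median") -> str:
    """``median [Q1, Q3]`` or ``mean ± SD`` summary string."""
    v = pd.Series(values).dropna().astype(float)
    if v.empty:
        return ""
    if style == "median":
        q1, med, q3 = v.quantile([0.25, 0.5, 0.75])
        return f"{med:.3g} [{q1:.3g}, {q3:.3g}]"
    if style == "mean":
        return f"{v.mean():.3g} ± {v.std(ddof=1):.3g}"
    raise ConfigurationError(f"unknown summary style {style!r}")


def two_sample_test(a, b, kind: str = "mannwhitney") -> tuple[str, float]:
    """Two-sample location test; returns ``(test_name, p)``."""
    a = pd.Series(a).dropna().astype(float)
    b = pd.Series(b).dropna().astype(float)
    if len(a) < 2 or len(b) < 2:
        return kind, np.nan
    if kind == "student":
        return "student_t", float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    if kind == "welch":
        return "welch_t", float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if kind == "mannwhitney":
        return "mann_whitney_u", float(stats.mannwhitneyu(a, b).pvalue)
    raise ConfigurationError(f"unknown two-sample test {kind!r}")


def categorical_test(table: pd.DataFrame) -> tuple[str, float]:
    """Chi-square test of independence; Fisher's exact for sparse 2×2."""
    t = table.to_numpy(dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.size == 0 or min(t.shape) < 2:
        return "chi_square", np.nan
    if t.shape == (2, 2):
        expected = stats.contingency.expected_freq(t)
        if (expected < 5).any():
            return "fisher_exact", float(stats.fisher_exact(t).pvalue)
    return "chi_square", float(stats.chi2_contingency(t).pvalue)


def kruskal_wallis(groups: dict[str, pd.Series]) -> float:
    """Kruskal–Wallis H-test p-value across the given groups."""
    samples = [pd.Series(v).dropna().astype(float) for v in groups.values()]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 2:
        return np.nan
    return float(stats.kruskal(*samples).pvalue)


def dunn_posthoc(groups: dict[str, pd.Series], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based post-hoc comparisons after Kruskal–Wallis.

    Pooled ranks with tie correction; two-sided normal p-values, optionally
    Bonferroni-adjusted over the pair family.
    """
    clean = {k: pd.Series(v).dropna().astype(float) for k, v in groups.items()}
    clean = {k: v for k, v in clean.items() if len(v) > 0}
    names = list(clean)
    pooled = pd.concat(clean.values(), ignore_index=True)
    n = len(pooled)
    ranks = pooled.rank()
    offsets = np.cumsum([0] + [len(clean[k]) for k in names[:-1]])
    mean_ranks = {
        k: float(ranks.iloc[o: o + len(clean[k])].mean()) for k, o in zip(names, offsets)
    }
    ties = pooled.value_counts()
    tie_corr = float(((ties ** 3 - ties).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_corr
    rows = []
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / len(clean[a]) + 1.0 / len(clean[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else np.nan
        p = float(2 * stats.norm.sf(abs(z)))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p, "p_adjusted": p_adj})
    return pd.DataFrame(rows)


def anova_dunnett(groups: dict[str, pd.Series], control: str) -> tuple[float, pd.DataFrame]:
    """One-way ANOVA p plus Dunnett comparisons of each group vs ``control``."""
    clean = {k: pd.Series(v).dropna().astype(float).to_numpy() for k, v in groups.items()}
    clean = {k: v for k, v in clean.items() if len(v) > 1}
    if control not in clean or len(clean) < 2:
        return np.nan, pd.DataFrame()
    others = [k for k in clean if k != control]
    p_anova = float(stats.f_oneway(*clean.values()).pvalue)
    res = stats.dunnett(*[clean[k] for k in others], control=clean[control])
    table = pd.DataFrame(
        {"group": others, "statistic": res.statistic, "p_adjusted": res.pvalue}
    )
    return p_anova, table


def descriptive_table(
    data: pd.DataFrame,
    continuous: tuple[str, ...],
    categorical: tuple[str, ...],
    group_col: str = "group",
    control_label: str = "control",
    summary_style: str = "median",
    two_sample_kind: str = "mannwhitney",
) -> dict:
    """Baseline characteristics by group, with tests.

    Returns ``{"summary": DataFrame, "tests": DataFrame, "posthoc": dict}``.
    ``summary`` has one row per variable (or variable level) with one column
    per group; ``tests`` collects the case-vs-control two-sample or
    categorical test, the Kruskal–Wallis p across subtypes and the ANOVA p;
    ``posthoc`` maps each continuous variable to its Dunn and Dunnett tables.
    """
    groups = [g for g in data[group_col].dropna().unique()]
    subtype_names = [g for g in groups if g != control_label]
    case_mask = data[group_col] != control_label

    summary_rows, test_rows, posthoc = [], [], {}
    for var in continuous:
        if var not in data.columns:
            continue
        row = {"variable": var, "level": ""}
        for g in groups:
            row[g] = summarize_continuous(data.loc[data[group_col] == g, var], summary_style)
        row["cases_pooled"] = summarize_continuous(data.loc[case_mask, var], summary_style)
        summary_rows.append(row)

        by_subtype = {g: data.loc[data[group_col] == g, var] for g in subtype_names}
        by_all = {g: data.loc[data[group_col] == g, var] for g in groups}
        tname, p2 = two_sample_test(
            data.loc[case_mask, var], data.loc[~case_mask, var], two_sample_kind
        )
        p_kw = kruskal_wallis(by_subtype) if len(by_subtype) > 1 else np.nan
        p_anova, dunnett_tab = (
            anova_dunnett(by_all, control_label) if control_label in groups else (np.nan, pd.DataFrame())
        )
        test_rows.append(
            {
                "variable": var,
                "two_sample_test": tname,
                "p_two_sample": p2,
                "p_kruskal_wallis": p_kw,
                "p_anova": p_anova,
            }
        )
        posthoc[var] = {
            "dunn": dunn_posthoc(by_subtype) if len(by_subtype) > 1 else pd.DataFrame(),
            "dunnett": dunnett_tab,
        }

    for var in categorical:
        if var not in data.columns:
            continue
        nonmiss = data[data[var].notna() & (data[var].astype(str) != "")]
        table = pd.crosstab(nonmiss[var], nonmiss[group_col])
        for level in table.index:
            row = {"variable": var, "level": str(level)}
            for g in groups:
                n = int(table.at[level, g]) if g in table.columns else 0
                tot = int(table[g].sum()) if g in table.columns else 0
                row[g] = f"{n} ({proportion(n, tot)}%)" if tot else "0"
            summary_rows.append(row)
        cc = pd.crosstab(nonmiss[var], nonmiss[group_col] != control_label)
        tname, p = categorical_test(cc)
        test_rows.append(
            {
                "variable": var,
                "two_sample_test": tname,
                "p_two_sample": p,
                "p_kruskal_wallis": np.nan,
                "p_anova": np.nan,
            }
        )

    return {
        "summary": pd.DataFrame(summary_rows),
        "tests": pd.DataFrame(test_rows),
        "posthoc": posthoc,
    }
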