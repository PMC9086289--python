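"""Cohort-level statistical battery for mean-expression tables.

Repeated-measures ANOVA across datasources with structures as subjects,
per-structure post-hoc ANOVAs with Bonferroni correction, the Grubbs
single-outlier test, Kruskal-Wallis, nested linear-model comparison and
a Tukey post-hoc with a repeated-measures correction.

The input everywhere is a tidy "mean expression table": one row per
(structure[, stage], datasource[, replicate]) with a ``value`` column of
mean log2 expression.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TestReport",
    "DATASOURCES",
    "rm_two_way_anova",
    "posthoc_pairwise_anova",
    "grubbs_test",
    "kruskal_wallis",
    "nested_model_comparison",
    "tukey_posthoc",
]

#: Fixed datasource vocabulary for provenance labels.
DATASOURCES = ("control", "deserts", "deserts_sweeps")


@dataclass
class TestReport:
    """One statistical test (or one contrast of a multi-test family)."""

    name: str
    statistic: float
    p_value: float
    df: tuple[float, ...] = ()
    adj_p: float | None = None
    group: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")
        if self.adj_p is not None and self.adj_p < self.p_value - 1e-12:
            raise ValueError("adjusted p below raw p")


def _require_columns(t: pd.DataFrame, cols: set[str]) -> None:
    missing = cols - set(t.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")


def rm_two_way_anova(
    t: pd.DataFrame,
    subject: str = "structure",
    within: str = "datasource",
    value: str = "value",
) -> TestReport:
    """Repeated-measures ANOVA: ``within`` factor (datasource) varied
    within each ``subject`` (structure).

    Requires a complete design (every subject observed in every within
    level); replicate rows per cell are averaged first. Degenerate inputs
    with no variation return F = 0, p = 1.
    """
    _require_columns(t, {subject, within, value})
    cell = t.groupby([subject, within], sort=True)[value].mean().unstack(within)
    if cell.isna().any().any():
        missing = [
            (str(s), str(w))
            for s in cell.index
            for w in cell.columns
            if pd.isna(cell.loc[s, w])
        ]
        raise ValueError(f"unbalanced design; missing cells: {missing}")
    if cell.shape[1] < 2:
        raise ValueError("need >= 2 datasource levels")
    Y = cell.to_numpy(dtype=float)
    n, k = Y.shape  # subjects x within levels
    grand = Y.mean()
    ss_within_factor = n * np.sum((Y.mean(axis=0) - grand) ** 2)
    ss_subject = k * np.sum((Y.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_error = ss_total - ss_within_factor - ss_subject
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_factor = ss_within_factor / df1
    ms_error = ss_error / df2 if df2 > 0 else np.nan
    if not np.isfinite(ms_error) or ms_error <= 0:
        if ss_within_factor <= 1e-12:
            return TestReport(
                "rm_two_way_anova", 0.0, 1.0, df=(df1, df2),
                extra={"note": "no variation"},
            )
        raise ValueError("zero error variance with non-zero effect")
    F = ms_factor / ms_error
    p = float(stats.f.sf(F, df1, df2))
    return TestReport(
        "rm_two_way_anova", float(F), p, df=(df1, df2),
        extra={"ss_factor": ss_within_factor, "ss_subject": ss_subject,
               "ss_error": ss_error},
    )


def posthoc_pairwise_anova(
    t: pd.DataFrame,
    subject: str = "structure",
    within: str = "datasource",
    value: str = "value",
) -> list[TestReport]:
    """One one-way ANOVA per structure comparing datasources, Bonferroni
    corrected over the number of structures."""
    _require_columns(t, {subject, within, value})
    structures = sorted(t[subject].unique())
    m = len(structures)
    reports: list[TestReport] = []
    for s in structures:
        sub = t[t[subject] == s]
        groups = [g[value].to_numpy(dtype=float) for _, g in sub.groupby(within)]
        if len(groups) < 2:
            raise ValueError(f"structure {s}: fewer than 2 datasources")
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            F, p = 0.0, 1.0
        else:
            F, p = stats.f_oneway(*groups)
            if not np.isfinite(F):
                F, p = 0.0, 1.0
        reports.append(
            TestReport(
                "posthoc_pairwise_anova",
                float(F),
                float(p),
                adj_p=float(min(1.0, p * m)),
                group=str(s),
            )
        )
    return reports


def grubbs_test(values: np.ndarray | pd.Series) -> TestReport:
    """Two-sided Grubbs single-outlier test.

    ``G = max |x - mean| / sd``; the p-value comes from the t-distribution
    relation for the critical value. Both the max-side and min-side
    variants are reported in ``extra``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    mean = x.mean()

    def one_sided_p(g: float) -> float:
        denom = (n - 1) ** 2 - n * g**2
        if denom <= 0:
            return 0.0
        tval = np.sqrt(n * (n - 2) * g**2 / denom)
        return float(min(1.0, n * stats.t.sf(tval, n - 2)))

    g_max = (x.max() - mean) / sd
    g_min = (mean - x.min()) / sd
    G = max(g_max, g_min)
    p_max = one_sided_p(g_max)
    p_min = one_sided_p(g_min)
    p_two = min(1.0, 2.0 * min(p_max, p_min))
    return TestReport(
        "grubbs",
        float(G),
        p_two,
        df=(n - 2,),
        extra={
            "g_max": float(g_max), "p_max": p_max,
            "g_min": float(g_min), "p_min": p_min,
            "suspect_max": float(x.max()), "suspect_min": float(x.min()),
        },
    )


def kruskal_wallis(groups: dict[str, np.ndarray]) -> TestReport:
    """Tie-corrected Kruskal-Wallis H with a chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(a) < 1 for a in arrays):
        raise ValueError("every group needs >= 1 value")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestReport(
            "kruskal_wallis", 0.0, 1.0, df=(len(groups) - 1,),
            extra={"note": "all values identical"},
        )
    H, p = stats.kruskal(*arrays)
    return TestReport(
        "kruskal_wallis", float(H), float(p), df=(len(groups) - 1,),
        extra={"groups": sorted(groups)},
    )


def nested_model_comparison(
    t: pd.DataFrame,
    with_factor: str = "structure",
    selection: str = "datasource",
    value: str = "value",
) -> TestReport:
    """F-test between nested linear models with and without ``with_factor``.

    Full model: value ~ C(selection) + C(with_factor); reduced model drops
    the factor. Also reports the selection-status coefficient p-value from
    the full model in ``extra``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    _require_columns(t, {with_factor, selection, value})
    d = t.rename(columns={value: "_y"})
    if d[with_factor].nunique() < 2:
        # degenerate: reduced == full
        return TestReport(
            "nested_model_comparison", 0.0, 1.0, df=(0, np.nan),
            extra={"note": "factor has a single level; models identical"},
        )
    full = smf.ols(f"_y ~ C({selection}) + C({with_factor})", data=d).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError(
            f"rank-deficient design: C({selection}) and C({with_factor}) "
            "are collinear"
        )
    reduced = smf.ols(f"_y ~ C({selection})", data=d).fit()
    cmp_table = anova_lm(reduced, full)
    F = float(cmp_table["F"].iloc[1])
    p = float(cmp_table["Pr(>F)"].iloc[1])
    if not np.isfinite(F):
        F, p = 0.0, 1.0
    sel_terms = [n for n in full.params.index if n.startswith(f"C({selection})")]
    sel_p = {n: float(full.pvalues[n]) for n in sel_terms}
    return TestReport(
        "nested_model_comparison",
        F,
        p,
        df=(float(cmp_table["df_diff"].iloc[1]), float(full.df_resid)),
        extra={"selection_coef_p": sel_p},
    )


def tukey_posthoc(
    t: pd.DataFrame,
    factor: str = "stage",
    subject: str = "structure",
    value: str = "value",
) -> list[TestReport]:
    """All pairwise ``factor`` contrasts with studentized-range adjusted p.

    Repeated-measures correction: contrasts are computed on per-subject
    factor means, so each subject contributes one value per level. The raw
    pooled-variance pairwise t-test p accompanies each contrast.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    _require_columns(t, {factor, subject, value})
    per_subject = (
        t.groupby([subject, factor], sort=True)[value].mean().reset_index()
    )
    levels = sorted(per_subject[factor].unique())
    if len(levels) < 2:
        return []
    vals = per_subject[value].to_numpy(dtype=float)
    labs = per_subject[factor].to_numpy()
    if np.ptp(vals) == 0:
        return [
            TestReport("tukey", 0.0, 1.0, adj_p=1.0, group=f"{a} vs {b}")
            for a, b in itertools.combinations(levels, 2)
        ]
    res = pairwise_tukeyhsd(vals, labs, alpha=0.05)
    reports: list[TestReport] = []
    groups = {lv: vals[labs == lv] for lv in levels}
    # pooled within-group variance for the raw t-test
    dfe = sum(len(g) - 1 for g in groups.values())
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    mse = sse / dfe if dfe > 0 else 0.0
    for row, (a, b) in zip(res.summary().data[1:], itertools.combinations(levels, 2)):
        adj_p = float(row[3])
        ga, gb = groups[a], groups[b]
        if mse > 0:
            se = np.sqrt(mse * (1 / len(ga) + 1 / len(gb)))
            tstat = (gb.mean() - ga.mean()) / se
            raw_p = float(2 * stats.t.sf(abs(tstat), dfe))
        else:
            tstat, raw_p = 0.0, 1.0
        reports.append(
            TestReport(
                "tukey",
                float(tstat),
                raw_p,
                adj_p=max(adj_p, raw_p),
                group=f"{a} vs {b}",
                extra={"mean_diff": float(gb.mean() - ga.mean())},
            )
        )
    return reports
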