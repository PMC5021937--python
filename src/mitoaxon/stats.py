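"""Group statistics: percentage-change endpoints, two-way ANOVA with
Bonferroni post-hoc contrasts, and per-field infiltrate correlations.

Per-field summaries are the unit of analysis; stage is the primary
factor and mouse the blocking factor of the two-way ANOVA.  Normality
is checked with the D'Agostino-Pearson omnibus test.  Pairwise stage
contrasts are Welch t tests with Bonferroni adjustment
(``p_adj = min(1, m * p)`` over the m contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


def percent_change(stage_value: float, reference_value: float) -> float:
    """Signed percentage decrease of ``stage_value`` vs the reference.

    Positive for a decrease (e.g. ``(81, 100) -> 19.0``), negative for
    an increase, following the convention "decreased by X%".
    """
    if reference_value == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * (reference_value - stage_value) / reference_value


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """Two-way ANOVA (stage x mouse) plus Bonferroni pairwise contrasts."""

    metric: str
    level_means: pd.DataFrame       # mean, sem, n per stage
    anova_table: pd.DataFrame
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame          # level_a, level_b, t, p_raw, p_adj, stars
    normality: pd.DataFrame         # stage, statistic, p, normal flag


def compare_groups(field_summaries: pd.DataFrame, metric: str,
                   factors: tuple[str, str] = ("stage", "mouse_id")
                   ) -> GroupComparison:
    """Compare a per-field metric across stages.

    Requires at least two levels of the primary factor with at least
    two observations each; raises naming the deficient level otherwise.
    """
    primary, blocking = factors
    df = field_summaries[[primary, blocking, metric]].dropna().copy()
    counts = df.groupby(primary)[metric].count()
    if len(counts) < 2:
        raise ValueError("need at least two levels to compare")
    deficient = counts[counts < 2]
    if len(deficient):
        raise ValueError(
            f"level {deficient.index[0]!r} has fewer than two observations")

    df = df.rename(columns={metric: "value"})
    model = smf.ols(f"value ~ C({primary}) + C({blocking})", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    f_stat = float(anova.loc[f"C({primary})", "F"])
    p_value = float(anova.loc[f"C({primary})", "PR(>F)"])

    levels = sorted(df[primary].unique())
    means = df.groupby(primary)["value"].agg(
        mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")

    rows = []
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    for a, b in pairs:
        va = df.loc[df[primary] == a, "value"]
        vb = df.loc[df[primary] == b, "value"]
        if va.var(ddof=1) == 0 and vb.var(ddof=1) == 0:
            t, p = (0.0, 1.0) if va.mean() == vb.mean() else (np.inf, 0.0)
        else:
            t, p = sps.ttest_ind(va, vb, equal_var=False)
        p_adj = min(1.0, m * float(p))
        rows.append({"level_a": a, "level_b": b, "t": float(t),
                     "p_raw": float(p), "p_adj": p_adj,
                     "stars": significance_stars(p_adj)})
    pairwise = pd.DataFrame(rows)

    norm_rows = []
    for lv in levels:
        v = df.loc[df[primary] == lv, "value"]
        if len(v) >= 8:
            stat, p = sps.normaltest(v)
        else:  # omnibus test undefined for tiny n
            stat, p = np.nan, np.nan
        norm_rows.append({primary: lv, "statistic": float(stat),
                          "p": float(p),
                          "normal": bool(p > 0.05) if np.isfinite(p) else None})
    normality = pd.DataFrame(norm_rows)

    return GroupComparison(metric, means, anova, f_stat, p_value, pairwise,
                           normality)


@dataclass
class CorrelationResult:
    """OLS of a per-field metric on the infiltrating-cell count."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_fields: int


def infiltrate_correlation(field_summaries: pd.DataFrame, metric: str,
                           predictor: str = "infiltrate_count"
                           ) -> CorrelationResult:
    """Regress a per-field metric on the per-field infiltrate count.

    r-squared is the squared Pearson correlation of the OLS fit.
    Requires at least three fields and a non-constant predictor.
    """
    df = field_summaries[[predictor, metric]].dropna()
    if len(df) < 3:
        raise ValueError("need at least three fields for a correlation")
    x = df[predictor].to_numpy(dtype=float)
    y = df[metric].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("infiltrate count is constant across fields")
    res = sps.linregress(x, y)
    return CorrelationResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2), p_value=float(res.pvalue),
        n_fields=len(df))
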