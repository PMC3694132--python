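"""Summary-statistic inference for demographic tables and metric curves.

Implements the tests a cohort demographics table reports from printed means,
SDs and group sizes alone: pooled-variance two-sample t, one-way ANOVA, Tukey
HSD on the studentized range, and a chi-square test of count tables.  Also the
per-cost pooled t comparison of metric curves between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .metrics import METRIC_NAMES


@dataclass
class SummaryStat:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary statistics need n >= 2")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def pooled_t_from_summary(a: SummaryStat, b: SummaryStat) -> TTestResult:
    """Two-tailed pooled-variance two-sample t test from summary statistics."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    p = 2 * scipy.stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def oneway_anova_from_summary(groups: list[SummaryStat]) -> AnovaResult:
    """One-way ANOVA F from group means, SDs and sizes."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in groups])
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    big_n = ns.sum()
    k = len(groups)
    grand = (ns * means).sum() / big_n
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, int(big_n - k)
    f = (ssb / df_b) / (ssw / df_w)
    p = scipy.stats.f.sf(f, df_b, df_w)
    return AnovaResult(F=float(f), df_between=df_b, df_within=df_w, p=float(p))


def tukey_hsd_from_summary(
    groups: list[SummaryStat], names: list[str] | None = None
) -> pd.DataFrame:
    """Tukey HSD pairwise p-values from summary statistics.

    Uses the pooled mean square within and, for unequal group sizes, the
    harmonic mean of each pair's sizes in the studentized-range statistic.
    """
    if len(groups) < 3:
        raise ValueError("Tukey HSD needs at least 3 groups")
    if names is None:
        names = [f"group{i}" for i in range(len(groups))]
    ns = np.array([g.n for g in groups])
    k = len(groups)
    df_w = int(ns.sum() - k)
    msw = float(((ns - 1) * np.array([g.sd for g in groups]) ** 2).sum()) / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            nh = 2.0 / (1.0 / groups[i].n + 1.0 / groups[j].n)
            q = abs(groups[i].mean - groups[j].mean) / np.sqrt(msw / nh)
            p = scipy.stats.studentized_range.sf(q, k, df_w)
            rows.append((names[i], names[j], float(q), float(p)))
    return pd.DataFrame(rows, columns=["group1", "group2", "q", "p"])


def chi_square_counts(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of a contingency table (no continuity correction).

    Returns (chi2, df, p).  Suited to e.g. a 2 x k gender-by-group table.
    """
    chi2, p, df, _ = scipy.stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), int(df), float(p)


def compare_metric_curves(curves: pd.DataFrame, group_a: str, group_b: str) -> pd.DataFrame:
    """Pooled two-sample t test per cost per metric between two groups.

    ``curves`` is the tidy frame from :func:`rsfcnet.metrics.metric_curves`.
    P-values are two-tailed and uncorrected across costs.
    """
    metrics = [m for m in METRIC_NAMES + ["sigma"] if m in curves.columns]
    rows = []
    for cost, chunk in curves.groupby("cost"):
        va = chunk.loc[chunk["group"] == group_a]
        vb = chunk.loc[chunk["group"] == group_b]
        if va.empty or vb.empty:
            raise ValueError(f"missing group at cost {cost}")
        for m in metrics:
            x, y = va[m].to_numpy(), vb[m].to_numpy()
            t, p = scipy.stats.ttest_ind(x, y, equal_var=True)
            rows.append((cost, m, float(t), len(x) + len(y) - 2, float(p)))
    return pd.DataFrame(rows, columns=["cost", "metric", "t", "df", "p"])
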