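"""Group comparison and correlation with distribution-based test selection.

The comparison branch mirrors standard practice in experimental biology:
Shapiro–Wilk normality per group and (median-centered) Levene homogeneity
across groups, both at 0.05, decide between one-way ANOVA with Tukey's HSD
and Kruskal–Wallis with Dunn's post-hoc test.  Pairwise verdicts
('up'/'down'/'ns', reading as "second group relative to first") feed the
expression-change classifier.  Correlations likewise select Pearson when
both variables pass normality, Spearman otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "CorrelationResult",
    "compare_groups",
    "correlate",
    "tukey_pairwise",
    "dunn_pairwise",
]


@dataclass
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")


@dataclass
class ComparisonResult:
    test_used: str  # "anova_tukey" | "kruskal_dunn"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_adj, direction
    alpha: float = 0.05

    def verdict(self, group_a: str, group_b: str) -> str:
        """Direction of group_b relative to group_a: 'up', 'down' or 'ns'."""
        t = self.pairwise
        row = t[(t.group_a == group_a) & (t.group_b == group_b)]
        if row.empty:
            row = t[(t.group_a == group_b) & (t.group_b == group_a)]
            if row.empty:
                raise KeyError(f"no pair ({group_a}, {group_b})")
            d = row.direction.iloc[0]
            return {"up": "down", "down": "up"}.get(d, d)
        return row.direction.iloc[0]


def tukey_pairwise(samples: list[GroupSample]) -> pd.DataFrame:
    """Tukey–Kramer HSD adjusted p for every unordered pair.

    p = P(Q >= |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))) with Q the
    studentized range with k groups and N-k error degrees of freedom.
    """
    k = len(samples)
    ns = np.array([s.values.size for s in samples])
    means = np.array([s.values.mean() for s in samples])
    big_n = int(ns.sum())
    ssw = sum(((s.values - s.values.mean()) ** 2).sum() for s in samples)
    df_err = big_n - k
    msw = ssw / df_err
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = np.abs(means[i] - means[j]) / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
        rows.append(
            {
                "group_a": samples[i].label,
                "group_b": samples[j].label,
                "p_adj": min(p, 1.0),
                "effect": means[j] - means[i],
            }
        )
    return pd.DataFrame(rows)


def dunn_pairwise(samples: list[GroupSample], p_adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based post-hoc test after Kruskal–Wallis.

    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)) with
    the tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal
    p-values, optionally multiplicity-adjusted (holm / bonferroni / none).
    """
    pooled = np.concatenate([s.values for s in samples])
    ranks = sps.rankdata(pooled)
    big_n = pooled.size
    bounds = np.cumsum([0] + [s.values.size for s in samples])
    rbar = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(samples))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = np.sum(tie_counts**3 - tie_counts) / (12.0 * (big_n - 1))
    var_base = big_n * (big_n + 1) / 12.0 - tie_corr
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        ni, nj = samples[i].values.size, samples[j].values.size
        se = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
        z = (rbar[j] - rbar[i]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": samples[i].label,
                "group_b": samples[j].label,
                "p_raw": p,
                "effect": rbar[j] - rbar[i],
            }
        )
    df = pd.DataFrame(rows)
    if p_adjust == "none" or df.empty:
        df["p_adj"] = df.get("p_raw", [])
    else:
        df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method=p_adjust)[1]
    return df.drop(columns=["p_raw"])


def compare_groups(
    samples: list[GroupSample],
    alpha: float = 0.05,
    dunn_adjust: str = "holm",
) -> ComparisonResult:
    """Omnibus + post-hoc comparison with distribution-based branch selection.

    All groups normal (Shapiro–Wilk) and homoscedastic (Levene) at 0.05 →
    one-way ANOVA with Tukey's HSD; otherwise Kruskal–Wallis with Dunn's
    test.  Directions use adjusted p < alpha and the sign of the mean (or
    mean-rank) difference of group_b minus group_a.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for s in samples:
        if s.values.size < 3:
            raise ValueError(f"group {s.label!r} has n < 3")
    arrays = [s.values for s in samples]
    normal = all(
        s.values.std() > 0 and sps.shapiro(s.values).pvalue > 0.05 for s in samples
    )
    homosced = sps.levene(*arrays, center="median").pvalue > 0.05 if normal else False

    if normal and homosced:
        stat, p = sps.f_oneway(*arrays)
        table = tukey_pairwise(samples)
        test = "anova_tukey"
    else:
        stat, p = sps.kruskal(*arrays)
        table = dunn_pairwise(samples, p_adjust=dunn_adjust)
        test = "kruskal_dunn"
    table["direction"] = [
        ("up" if e > 0 else "down") if padj < alpha else "ns"
        for padj, e in zip(table["p_adj"], table["effect"])
    ]
    return ComparisonResult(
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
        pairwise=table,
        alpha=alpha,
    )


@dataclass
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    coefficient: float
    p_value: float


def correlate(x, y) -> CorrelationResult:
    """Pearson when both variables pass Shapiro–Wilk at 0.05, else Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance variable; correlation undefined")
    normal = sps.shapiro(x).pvalue > 0.05 and sps.shapiro(y).pvalue > 0.05
    if normal:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method=method, coefficient=float(r), p_value=float(p))
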