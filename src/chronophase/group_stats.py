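"""Group comparisons: two-way ANOVA, one-way ANOVA on phases, rank tests.

Two-way genotype x time ANOVA with interaction (classical fixed-effects
decomposition for balanced designs, Type II sums of squares otherwise);
one-way ANOVA on circular phases after unwrapping them to the branch
nearest the circular grand mean, with Bonferroni-adjusted pairwise
t-tests; Mann-Whitney U for onset comparisons.  All tests two-tailed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "RankTestResult",
    "two_way_anova",
    "one_way_anova",
    "mann_whitney",
    "bonferroni",
    "unwrap_phases",
]


@dataclass(frozen=True)
class AnovaResult:
    """ANOVA table plus optional Bonferroni pairwise comparisons."""

    table: pd.DataFrame = field(repr=False)  # index: term; cols: sum_sq, df, F, p
    design: str
    pairwise: pd.DataFrame | None = field(default=None, repr=False)

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


@dataclass(frozen=True)
class RankTestResult:
    u: float  # min(U1, U2)
    n1: int
    n2: int
    p: float  # two-tailed


def _balanced_two_way(df: pd.DataFrame, a: str, b: str, value: str) -> pd.DataFrame:
    """Classical SS decomposition for an equal-replication two-way design."""
    cell = df.groupby([a, b])[value].agg(["mean", "count"])
    n = int(cell["count"].iloc[0])
    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    la = df[a].nunique()
    lb = df[b].nunique()
    mean_a = df.groupby(a)[value].mean()
    mean_b = df.groupby(b)[value].mean()
    ss_a = n * lb * float(((mean_a - grand) ** 2).sum())
    ss_b = n * la * float(((mean_b - grand) ** 2).sum())
    cell_means = cell["mean"]
    ss_cells = n * float(((cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = float(((y - grand) ** 2).sum())
    ss_res = ss_tot - ss_cells
    df_a, df_b = la - 1, lb - 1
    df_ab = df_a * df_b
    df_res = la * lb * (n - 1)
    rows = {}
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    for name, ss, d in ((a, ss_a, df_a), (b, ss_b, df_b), (f"{a}:{b}", ss_ab, df_ab)):
        if ms_res and np.isfinite(ms_res) and ms_res > 0:
            f = (ss / d) / ms_res
            p = float(stats.f.sf(f, d, df_res))
        else:
            f, p = np.nan, np.nan
        rows[name] = {"sum_sq": ss, "df": d, "F": f, "p": p}
    rows["Residual"] = {"sum_sq": ss_res, "df": df_res, "F": np.nan, "p": np.nan}
    return pd.DataFrame(rows).T


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "zt_h",
) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction.

    Balanced designs use the classical closed-form decomposition; mildly
    unbalanced designs (e.g. n = 3 vs 4 per cell) fall back to Type II
    sums of squares via an OLS fit.  Empty cells are an error.
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    if data[factor_a].nunique() < 2 or data[factor_b].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")
    counts = data.groupby([factor_a, factor_b])[value].count()
    full = data[factor_a].nunique() * data[factor_b].nunique()
    if len(counts) < full or (counts == 0).any():
        raise ValueError("empty cell(s) in the genotype x time design")
    if counts.nunique() == 1:
        table = _balanced_two_way(data, factor_a, factor_b, value)
    else:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        d = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
        model = smf.ols("_y ~ C(_a) * C(_b)", data=d).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        aov = aov.rename(
            index={
                "C(_a)": factor_a,
                "C(_b)": factor_b,
                "C(_a):C(_b)": f"{factor_a}:{factor_b}",
            },
            columns={"PR(>F)": "p"},
        )
        table = aov[["sum_sq", "df", "F", "p"]]
    return AnovaResult(table=table, design=f"{factor_a}*{factor_b}")


def _circular_mean(phases: np.ndarray, period: float) -> float:
    theta = 2 * np.pi * phases / period
    mean_angle = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    return float((mean_angle * period / (2 * np.pi)) % period)


def unwrap_phases(phases, period: float = 24.0) -> np.ndarray:
    """Shift circular phases onto the linear branch nearest their circular mean.

    Each phase is moved by a multiple of the period so it lies within
    half a period of the circular grand mean, making linear statistics
    defensible for concentrated phase samples.
    """
    p = np.asarray(phases, dtype=float).reshape(-1)
    mu = _circular_mean(p, period)
    return mu + ((p - mu + period / 2) % period) - period / 2


def one_way_anova(
    groups: dict[str, np.ndarray],
    circular: bool = True,
    period: float = 24.0,
) -> AnovaResult:
    """One-way ANOVA across groups with Bonferroni pairwise t-tests.

    With ``circular=True`` (phases in hours) all values are jointly
    unwrapped to a common branch first.  Pairwise two-sample t-tests are
    Bonferroni-adjusted by the number of comparisons.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float).reshape(-1) for g in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    if circular:
        flat = unwrap_phases(np.concatenate(arrays), period)
        splits = np.cumsum([len(a) for a in arrays])[:-1]
        arrays = np.split(flat, splits)
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    table = pd.DataFrame(
        {
            "group": {"sum_sq": ss_between, "df": k - 1, "F": float(f), "p": float(p)},
            "Residual": {
                "sum_sq": ss_within,
                "df": n - k,
                "F": np.nan,
                "p": np.nan,
            },
        }
    ).T
    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        t = stats.ttest_ind(arrays[i], arrays[j])
        p_ij = t.pvalue
        if np.isnan(p_ij):  # zero pooled variance: decided by the means
            p_ij = 1.0 if arrays[i].mean() == arrays[j].mean() else 0.0
        raw.append(float(p_ij))
    adj = bonferroni(raw)
    pairwise = pd.DataFrame(
        {
            "group_a": [labels[i] for i, _ in pairs],
            "group_b": [labels[j] for _, j in pairs],
            "p_raw": raw,
            "p_adjusted": adj,
        }
    )
    return AnovaResult(table=table, design="one-way", pairwise=pairwise)


def mann_whitney(sample_a, sample_b) -> RankTestResult:
    """Two-tailed Mann-Whitney U test with midrank tie handling.

    The exact null distribution is used for small untied samples
    (n1*n2 <= 400); otherwise the tie-corrected normal approximation.
    ``u`` reports min(U1, U2).
    """
    a = np.asarray(sample_a, dtype=float).reshape(-1)
    b = np.asarray(sample_b, dtype=float).reshape(-1)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u2 = len(a) * len(b) - u1
    return RankTestResult(
        u=min(u1, u2), n1=len(a), n2=len(b), p=float(min(res.pvalue, 1.0))
    )


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p -> min(1, p * m); order-preserving."""
    p = np.asarray(pvals, dtype=float).reshape(-1)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)
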