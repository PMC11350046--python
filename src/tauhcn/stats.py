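"""Group statistics: Student t tests, two-way ANOVA + Tukey HSD, SEM summaries.

The conventions mirror common practice in cellular neurophysiology reports:
unpaired two-tailed pooled-variance t tests for two-group comparisons,
two-way ANOVA (Type II sums of squares, robust to mild unbalance) with
Tukey's HSD post hoc test for factorial designs, means ± SEM everywhere,
and significance stars at 0.05 / 0.01 / 0.001 / 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "significance_stars", "t_test", "anova2_tukey",
           "percent_change", "group_summary"]

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Star annotation as a pure function of the p value."""
    if not np.isfinite(p):
        return ""
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p: float
    stars: str = ""
    effect: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stars:
            self.stars = significance_stars(self.p)


def t_test(a, b, name: str = "t") -> TestResult:
    """Unpaired two-tailed pooled-variance Student t test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        stat, p = 0.0, 1.0  # degenerate: identical constant groups
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    ma, sa = float(a.mean()), float(a.std(ddof=1) / np.sqrt(a.size))
    mb, sb = float(b.mean()), float(b.std(ddof=1) / np.sqrt(b.size))
    return TestResult(name=name, statistic=float(stat), df=df, p=float(p),
                      effect={"mean_a": ma, "sem_a": sa,
                              "mean_b": mb, "sem_b": sb})


def anova2_tukey(table: pd.DataFrame, factors: tuple[str, str],
                 metric: str) -> dict[str, TestResult]:
    """Two-way ANOVA (Type II SS) with Tukey HSD on the factor-cell means.

    Returns a dict with keys ``factors[0]``, ``factors[1]``,
    ``"interaction"`` and ``"tukey"`` (the last carrying the pairwise table
    in ``effect["pairwise"]``).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    f1, f2 = factors
    df = table[[f1, f2, metric]].dropna().copy()
    df.columns = ["f1", "f2", "y"]
    counts = df.groupby(["f1", "f2"], observed=True).size()
    full = [(a, b) for a in df["f1"].unique() for b in df["f2"].unique()]
    for cell in full:
        if cell not in counts.index:
            raise ValueError(f"empty design cell {cell!r}")
    if df["f1"].nunique() < 2 or df["f2"].nunique() < 2:
        raise ValueError("each factor needs at least two levels")

    model = ols("y ~ C(f1) * C(f2)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)

    out: dict[str, TestResult] = {}
    for row, key in (("C(f1)", f1), ("C(f2)", f2), ("C(f1):C(f2)", "interaction")):
        out[key] = TestResult(
            name=f"{metric}:{key}",
            statistic=float(aov.loc[row, "F"]),
            df=float(aov.loc[row, "df"]),
            p=float(aov.loc[row, "PR(>F)"]),
        )

    cell_labels = df["f1"].astype(str) + ":" + df["f2"].astype(str)
    tk = pairwise_tukeyhsd(df["y"].to_numpy(), cell_labels.to_numpy())
    pairs = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    out["tukey"] = TestResult(
        name=f"{metric}:tukey", statistic=np.nan, df=np.nan, p=np.nan,
        stars="", effect={"pairwise": pairs.to_dict(orient="records")},
    )
    return out


def percent_change(reference_mean: float, other_mean: float) -> float:
    """Signed percent change of ``other`` relative to ``reference``."""
    return 100.0 * (other_mean - reference_mean) / reference_mean


def group_summary(table: pd.DataFrame, by: list[str],
                  metrics: list[str]) -> pd.DataFrame:
    """Mean ± SEM table per group for the requested metric columns."""
    rows = []
    for keys, sub in table.groupby(by, observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(by, keys))
        for mcol in metrics:
            x = sub[mcol].dropna().to_numpy(dtype=float)
            row[f"{mcol}_mean"] = x.mean() if x.size else np.nan
            row[f"{mcol}_sem"] = (x.std(ddof=1) / np.sqrt(x.size)
                                  if x.size > 1 else np.nan)
            row[f"{mcol}_n"] = x.size
        rows.append(row)
    return pd.DataFrame(rows)
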