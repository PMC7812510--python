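"""Group summary tables and non-parametric statistics.

Per-subject outcome rows (one per animal: SD counts, latencies, seizure
burden, permeability summaries, lesion volume, stereological totals) are
summarized as median and IQR (25th/75th percentile, linear interpolation)
and compared with the non-parametric battery: Mann–Whitney U for two
groups, Kruskal–Wallis for more, Wilcoxon signed-rank for paired variables,
and Spearman rank correlation with average-rank tie handling.  p values are
reported raw, without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    effect: dict
    flag: str | None = None


def summarize(table: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Median and IQR per group and numeric variable."""
    if table.empty:
        raise ValueError("empty table")
    num = table.select_dtypes("number")
    g = table.groupby(by, observed=True)[num.columns]
    out = pd.concat(
        {
            "median": g.median(),
            "q25": g.quantile(0.25),
            "q75": g.quantile(0.75),
        },
        axis=1,
    )
    return out.swaplevel(axis=1).sort_index(axis=1)


def _effect(groups: dict[str, np.ndarray]) -> dict:
    return {
        name: {
            "median": float(np.median(v)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
        }
        for name, v in groups.items()
    }


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    groups: list[str],
    group_col: str = "group",
    paired: bool = False,
    exact_max_n: int = 20,
) -> TestResult:
    """Two-group Mann–Whitney U (exact null for small samples), Kruskal–Wallis
    for more than two groups, or Wilcoxon signed-rank when ``paired``."""
    data = {
        g: table.loc[table[group_col] == g, variable].dropna().to_numpy(dtype=float)
        for g in groups
    }
    ns = tuple(len(v) for v in data.values())
    if len(groups) < 2 or any(n < 3 for n in ns):
        raise ValueError("need >= 2 groups with >= 3 subjects each")
    if paired:
        if len(groups) != 2 or ns[0] != ns[1]:
            raise ValueError("paired comparison requires two equal-size groups")
        a, b = data.values()
        res = stats.wilcoxon(a, b)
        return TestResult("wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), ns, _effect(data))
    if len(groups) == 2:
        a, b = data.values()
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (max(ns) <= exact_max_n and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue), ns, _effect(data))
    res = stats.kruskal(*data.values())
    return TestResult("kruskal_wallis", float(res.statistic), float(res.pvalue), ns, _effect(data))


def correlate(table: pd.DataFrame, var_x: str, var_y: str) -> TestResult:
    """Spearman rank correlation (average ranks for ties)."""
    sub = table[[var_x, var_y]].dropna()
    if len(sub) < 4:
        raise ValueError("need >= 4 complete pairs")
    x = sub[var_x].to_numpy(dtype=float)
    y = sub[var_y].to_numpy(dtype=float)
    flag = None
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(
            "spearman", float("nan"), float("nan"), (len(sub),) * 2,
            {"rho": float("nan")}, flag="constant input: rho undefined",
        )
    rho, p = stats.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p), (len(sub),) * 2, {"rho": float(rho)}, flag)
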