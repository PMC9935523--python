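"""Between-town comparison of metal concentrations.

The test choice is gated on normality: every town's series is checked with
the Shapiro–Wilk test at alpha = 0.01; if all groups pass (P > 0.01) a
one-way ANOVA compares the towns, otherwise the nonparametric
Kruskal–Wallis test is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

NORMALITY_ALPHA = 0.01


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one between-group comparison for one metal."""

    metal: str
    groups: dict[str, int]               # town -> n
    normality_p: dict[str, float]        # town -> Shapiro-Wilk p-value
    all_normal: bool
    test_used: str                       # one_way_anova | kruskal_wallis
    statistic: float
    p_value: float


def compare_towns(samples: pd.DataFrame, metal: str,
                  group_col: str = "town",
                  alpha_normality: float = NORMALITY_ALPHA
                  ) -> ComparisonResult:
    """Compare a metal's concentrations between towns.

    Requires >= 2 groups with >= 3 non-missing values each.  Shapiro–Wilk
    is applied per group; one-way ANOVA is used iff every group passes
    (p > ``alpha_normality``), Kruskal–Wallis otherwise.
    """
    if metal not in samples.columns:
        raise ValueError(f"samples lack a {metal} column")
    if group_col not in samples.columns:
        raise ValueError(f"samples lack a {group_col} column")
    series = {}
    for town, sub in samples.groupby(group_col, sort=False):
        vals = sub[metal].dropna().to_numpy(dtype=float)
        if len(vals) < 3:
            raise ValueError(
                f"group {town!r} has only {len(vals)} values for {metal}; "
                f"need >= 3")
        series[str(town)] = vals
    if len(series) < 2:
        raise ValueError("need at least 2 groups to compare")

    normality_p = {t: float(sps.shapiro(v).pvalue) for t, v in series.items()}
    all_normal = all(p > alpha_normality for p in normality_p.values())
    groups = list(series.values())
    if all_normal:
        stat, p = sps.f_oneway(*groups)
        test = "one_way_anova"
    else:
        stat, p = sps.kruskal(*groups)
        test = "kruskal_wallis"
    return ComparisonResult(
        metal=metal,
        groups={t: len(v) for t, v in series.items()},
        normality_p=normality_p,
        all_normal=all_normal,
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
    )


def compare_all(samples: pd.DataFrame, metals, group_col: str = "town"
                ) -> pd.DataFrame:
    """Run :func:`compare_towns` for several metals; one row per metal."""
    rows = []
    for metal in metals:
        r = compare_towns(samples, metal, group_col)
        rows.append({"metal": r.metal, "test_used": r.test_used,
                     "statistic": r.statistic, "p_value": r.p_value,
                     "all_normal": r.all_normal,
                     **{f"shapiro_p_{t}": p for t, p in r.normality_p.items()}})
    return pd.DataFrame(rows)
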