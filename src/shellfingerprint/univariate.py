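"""One-way ANOVA and Tukey HSD comparisons of single element ratios.

Run on log-transformed (but not standardized) signatures, one element at a
time, to ask which ratios differ among regions.  Unequal group sizes use the
Tukey–Kramer variant of the studentized-range test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_preprocess import SignatureSet

__all__ = ["AnovaResult", "TukeyResult", "one_way_anova", "tukey_hsd",
           "elementwise_anova_table"]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    group_means: pd.Series

    def __post_init__(self) -> None:
        assert self.F >= 0 and 0 <= self.p_value <= 1


@dataclass
class TukeyResult:
    table: pd.DataFrame  # index (group_a, group_b): diff, p_adj, ci_low, ci_high
    alpha: float


def _groups_from(values, groups):
    v = np.asarray(values, dtype=float)
    glab = np.asarray(groups)
    names = list(pd.unique(glab))
    blocks = [v[glab == c] for c in names]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(b) < 2 for b in blocks):
        raise ValueError("each group needs n >= 2")
    return names, blocks


def one_way_anova(values, groups) -> AnovaResult:
    """F = MS_between / MS_within with (g−1, n−g) degrees of freedom."""
    names, blocks = _groups_from(values, groups)
    n = sum(len(b) for b in blocks)
    g = len(blocks)
    if all(np.allclose(b, b[0]) for b in blocks):
        raise ValueError("zero within-group variance; F undefined")
    F, p = stats.f_oneway(*blocks)
    means = pd.Series({c: float(np.mean(b)) for c, b in zip(names, blocks)})
    return AnovaResult(float(F), g - 1, n - g, float(p), means)


def tukey_hsd(values, groups, alpha: float = 0.05) -> TukeyResult:
    """All-pairs Tukey–Kramer comparisons (studentized-range adjusted)."""
    names, blocks = _groups_from(values, groups)
    if all(np.allclose(b, b[0]) for b in blocks):
        raise ValueError("zero within-group variance")
    res = stats.tukey_hsd(*blocks)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    rows = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows[(names[i], names[j])] = {
                "diff": float(res.statistic[i, j]),
                "p_adj": float(res.pvalue[i, j]),
                "ci_low": float(ci.low[i, j]),
                "ci_high": float(ci.high[i, j]),
            }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["group_a", "group_b"])
    return TukeyResult(table, alpha)


def elementwise_anova_table(sig: SignatureSet, group_by: str = "region",
                            alpha: float = 0.05) -> pd.DataFrame:
    """ANOVA + Tukey summary, one row per element of a log-scale set."""
    if sig.transform_state != "log":
        raise ValueError("univariate tests use log-transformed, unstandardized data")
    groups = sig.meta[group_by].to_numpy()
    rows = []
    for el in sig.elements:
        a = one_way_anova(sig.values[el].to_numpy(), groups)
        t = tukey_hsd(sig.values[el].to_numpy(), groups, alpha=alpha)
        sig_pairs = [f"{i[0]}-{i[1]}" for i, r in t.table.iterrows()
                     if r["p_adj"] < alpha]
        rows.append({"element": el, "F": a.F, "df_between": a.df_between,
                     "df_within": a.df_within, "p": a.p_value,
                     "significant_pairs": ";".join(sig_pairs)})
    return pd.DataFrame(rows).set_index("element")
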