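"""One-way ANOVA with Tukey HSD post hoc comparisons.

Adjusted pairwise p-values use the studentized-range distribution with the
pooled within-group mean square.  The one-sided convention halves the
studentized-range tail when the observed difference is in the alternative's
direction (and reports 1 − tail/2 otherwise); two-sided is the plain tail.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range


def anova_oneway(groups: dict) -> dict:
    """One-way fixed-effects ANOVA over a dict name → 1-D array."""
    names = list(groups)
    arrs = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([len(a) for a in arrs])
    if np.any(ns < 2):
        raise ValueError("each group needs at least two observations")
    grand = np.concatenate(arrs).mean()
    means = np.array([a.mean() for a in arrs])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_b = len(arrs) - 1
    df_w = int(ns.sum()) - len(arrs)
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        F = np.inf
        p = 0.0
    else:
        F = ms_b / ms_w
        p = float(f_dist.sf(F, df_b, df_w))
    return {"F": F, "p": p, "df_between": df_b, "df_within": df_w,
            "ms_within": ms_w, "n_groups": len(arrs)}


def tukey_pairwise(
    groups: dict,
    one_sided: bool = False,
    ms_within: float | None = None,
    df_within: int | None = None,
    n_family: int | None = None,
) -> pd.DataFrame:
    """Tukey HSD adjusted p for every pair of groups.

    ``ms_within``/``df_within``/``n_family`` may be supplied to run the
    comparisons inside a larger ANOVA family (e.g. contrasts from a model
    with more cells than the pair under test)."""
    names = list(groups)
    arrs = {g: np.asarray(groups[g], dtype=float) for g in names}
    if ms_within is None or df_within is None:
        a = anova_oneway(groups)
        ms_within, df_within = a["ms_within"], a["df_within"]
    k = n_family if n_family is not None else len(names)
    rows = []
    for g1, g2 in combinations(names, 2):
        x1, x2 = arrs[g1], arrs[g2]
        diff = x2.mean() - x1.mean()
        se = np.sqrt(ms_within / 2.0 * (1.0 / len(x1) + 1.0 / len(x2)))
        if se == 0:
            q = np.inf
        else:
            q = abs(diff) / se
        p_two = float(studentized_range.sf(q, k, df_within)) if np.isfinite(q) else 0.0
        p_two = min(max(p_two, 0.0), 1.0)
        if one_sided:
            # alternative: mean(g2) > mean(g1)
            p = p_two / 2.0 if diff > 0 else 1.0 - p_two / 2.0
        else:
            p = p_two
        rows.append({"group1": g1, "group2": g2, "diff": diff, "q": q, "p_adj": p})
    return pd.DataFrame(rows)
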