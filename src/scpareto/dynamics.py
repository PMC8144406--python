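"""Specialist-proportion bookkeeping over samples and time, comparative
statistics between cohorts/mutation groups, and tabular WGS filters.

Proportions are per-sample fractions of each archetype specialist label plus
non-specialists (they sum to 1, the substrate of fishplot-style displays).
Cohort shifts use the pooled-variance two-sample Student's t test; mutation
group contrasts use Tukey HSD within the archetype × status ANOVA family;
copy-number z-scores classify gains (rounded z ≥ 2) and losses (≤ −2); and
variant consensus keeps variants seen by at least two callers with a maximum
VAF ≥ 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, ttest_ind

from .posthoc import tukey_pairwise
from .scores import NON_SPECIALIST, ArchetypeScoreTable

VARIANT_KEY = ["sample", "chrom", "pos", "ref", "alt"]


def specialist_proportions(
    table: ArchetypeScoreTable, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample fractions of each archetype specialist and non-specialists.

    ``metadata`` is indexed by cell id with columns sample, patient, time
    (cohort optional).  Returns one row per sample ordered by time, columns
    ``archetype_<a>``, ``non_specialist``, ``n_cells`` plus the metadata keys.
    """
    if table.specialist_label is None:
        raise ValueError("run classify_specialists first")
    meta = metadata.reindex(table.cell_ids)
    if meta["sample"].isna().any():
        raise ValueError("every cell needs sample metadata")
    labels = table.specialist_label
    rows = []
    for sample, idx in labels.groupby(meta["sample"]).groups.items():
        sub = labels.loc[idx]
        n = len(sub)
        if n == 0:
            continue
        msub = meta.loc[idx].iloc[0]
        row = {"sample": sample,
               "patient": msub.get("patient"),
               "time": msub.get("time"),
               "cohort": msub.get("cohort"),
               "n_cells": n}
        for a in range(table.k):
            row[f"archetype_{a + 1}"] = float((sub == a).mean())
        row["non_specialist"] = float((sub == NON_SPECIALIST).mean())
        rows.append(row)
    props = pd.DataFrame(rows).sort_values(["time", "sample"], kind="stable")
    return props.reset_index(drop=True)


def fishplot_long(props: pd.DataFrame) -> pd.DataFrame:
    """Long-format (sample, time, archetype, fraction) export ordered by
    time, ready for fishplot-style visualization."""
    frac_cols = [c for c in props.columns if c.startswith("archetype_")] + ["non_specialist"]
    long = props.melt(
        id_vars=[c for c in ("sample", "patient", "time") if c in props.columns],
        value_vars=frac_cols, var_name="archetype", value_name="fraction",
    )
    return long.sort_values(["time", "sample", "archetype"], kind="stable").reset_index(drop=True)


def cohort_shift_test(
    props: pd.DataFrame, group_column: str = "cohort", groups: tuple | None = None
) -> pd.DataFrame:
    """Equal-variance two-sample Student's t test per archetype on
    sample-level specialist fractions between two groups."""
    levels = groups or tuple(pd.unique(props[group_column]))
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    g1 = props[props[group_column] == levels[0]]
    g2 = props[props[group_column] == levels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need at least two samples")
    frac_cols = [c for c in props.columns if c.startswith("archetype_")] + ["non_specialist"]
    rows = []
    for col in frac_cols:
        t, p = ttest_ind(g1[col], g2[col], equal_var=True)
        rows.append({"archetype": col,
                     "mean_early": float(g1[col].mean()),
                     "mean_late": float(g2[col].mean()),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def proportion_correlation(props: pd.DataFrame, archetype_a: str, archetype_b: str):
    """Pearson correlation (and R²) between two archetypes' specialist
    fractions across samples."""
    if len(props) < 3:
        raise ValueError("need at least 3 samples")
    x = props[archetype_a].to_numpy(dtype=float)
    y = props[archetype_b].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a proportion series")
    r = float(pearsonr(x, y).statistic)
    return r, r * r


def survival_correlation(final_props: pd.DataFrame, survival_days, proportion_column: str):
    """Pearson correlation between final-time specialist proportion and
    overall survival, with the two-sided t-based p; one row per patient."""
    if final_props["patient"].duplicated().any():
        raise ValueError("duplicated patient in final-time table")
    if len(final_props) < 3:
        raise ValueError("need at least 3 patients")
    surv = pd.Series(survival_days)
    y = surv.reindex(final_props["patient"]).to_numpy(dtype=float)
    x = final_props[proportion_column].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in proportions or survival")
    res = pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def mutation_group_test(
    props: pd.DataFrame,
    mutation_status: pd.Series | dict,
    one_sided: bool = True,
) -> pd.DataFrame:
    """Per-archetype wild-type vs mutated contrast of specialist proportions.

    The ANOVA family is the full set of archetype × status cells (the model
    of proportion with mutation status as an interaction term); each
    archetype's wt-vs-m comparison is Tukey-adjusted within that family
    using the pooled within-cell mean square.  ``one_sided`` tests the
    alternative mean(m) > mean(wt) by the single-sided studentized-range
    convention.
    """
    status = pd.Series(mutation_status)
    st = status.reindex(props["sample"]).to_numpy()
    if pd.isna(st).any():
        raise ValueError("every sample needs a mutation status")
    levels = sorted(pd.unique(st))
    if len(levels) < 2:
        raise ValueError("need both mutation status levels")
    if "wt" in levels:  # wild-type is the baseline group
        levels = ["wt"] + [lv for lv in levels if lv != "wt"]
    frac_cols = [c for c in props.columns if c.startswith("archetype_")] + ["non_specialist"]
    # pooled within-cell variance over the full interaction family
    cells = {}
    for col in frac_cols:
        for lv in levels:
            cells[(col, lv)] = props.loc[st == lv, col].to_numpy(dtype=float)
    ss_w = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    df_w = sum(len(v) - 1 for v in cells.values())
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_w = ss_w / df_w
    out = []
    for col in frac_cols:
        groups = {"wt": cells[(col, levels[0])], "m": cells[(col, levels[1])]}
        pw = tukey_pairwise(
            groups, one_sided=one_sided, ms_within=ms_w, df_within=df_w,
            n_family=len(cells),
        )
        pw.insert(0, "archetype", col)
        out.append(pw)
    return pd.concat(out, ignore_index=True)


def cnv_z_classify(z_values) -> pd.Series:
    """Classify per-gene z-transformed copy numbers: round half away from
    zero, then ≥ 2 → gain, ≤ −2 → loss, else neutral."""
    z = pd.Series(z_values, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z values")
    rounded = np.sign(z) * np.floor(np.abs(z) + 0.5)
    out = pd.Series("neutral", index=z.index, dtype=object)
    out[rounded >= 2] = "gain"
    out[rounded <= -2] = "loss"
    return out


def variant_consensus_filter(
    tables: list[pd.DataFrame], min_callers: int = 2, min_vaf: float = 0.05
) -> pd.DataFrame:
    """Keep variants present in at least ``min_callers`` caller tables whose
    maximum VAF across callers is ≥ ``min_vaf``.

    Each table needs columns sample, chrom, pos, ref, alt, vaf and may carry
    a ``caller`` column (defaulting to its position in the list).
    """
    frames = []
    for i, t in enumerate(tables):
        missing = [c for c in VARIANT_KEY + ["vaf"] if c not in t.columns]
        if missing:
            raise ValueError(f"caller table {i} is missing columns {missing}")
        f = t.copy()
        if "caller" not in f.columns:
            f["caller"] = f"caller{i + 1}"
        frames.append(f)
    allv = pd.concat(frames, ignore_index=True)
    grouped = allv.groupby(VARIANT_KEY, sort=True).agg(
        n_callers=("caller", "nunique"), vaf=("vaf", "max"),
        callers=("caller", lambda s: ",".join(sorted(set(s)))),
    )
    kept = grouped[(grouped["n_callers"] >= min_callers) & (grouped["vaf"] >= min_vaf)]
    return kept.reset_index()
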