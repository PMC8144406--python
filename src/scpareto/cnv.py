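"""Expression-inferred copy-number profiles and subclone clustering.

Copy-number-like profiles are inferred from log expression by centering on a
reference cell population, clipping extremes, smoothing with a moving
average along each chromosome's gene order, and re-centering each cell on
its median — a surrogate for dosage effects of contiguous chromosomal gains
and losses.  Cells are then grouped into subclones by Ward hierarchical
clustering of the profiles, and archetype–subclone association is tested by
one-way ANOVA with Tukey HSD post hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, ward

from .posthoc import anova_oneway, tukey_pairwise
from .scores import ArchetypeScoreTable


@dataclass
class GenomicTrack:
    """Per-gene genomic coordinates (1-based inclusive) with a deterministic
    per-chromosome gene order (by start, ties by gene id)."""

    table: pd.DataFrame  # columns gene, chrom, start, end

    def __post_init__(self):
        t = self.table
        required = {"gene", "chrom", "start", "end"}
        if not required.issubset(t.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        if (t["end"] < t["start"]).any():
            raise ValueError("gene end < start in track")
        self.table = t.sort_values(["chrom", "start", "gene"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t"))

    def chromosome_order(self, genes_present) -> dict[str, list[str]]:
        present = set(genes_present)
        out = {}
        for chrom, sub in self.table.groupby("chrom", sort=True):
            genes = [g for g in sub["gene"] if g in present]
            if genes:
                out[chrom] = genes
        return out


@dataclass
class SubcloneAssignment:
    labels: pd.Series  # cell id → cluster id (1..m), ids ordered by size desc
    m: int
    linkage: str = "ward"


def _truncated_moving_average(M: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with the window truncated at the
    ends (each position averages over its available neighbours)."""
    h = window // 2
    n = M.shape[1]
    cs = np.cumsum(np.pad(M, ((0, 0), (1, 0))), axis=1)
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h, n - 1)
    return (cs[:, hi + 1] - cs[:, lo]) / (hi - lo + 1)


def infer_cnv_profile(
    expression: np.ndarray,
    gene_ids: list[str],
    cell_ids: list[str],
    track: GenomicTrack,
    reference_cells: list[str],
    window: int = 101,
    cap: float = 3.0,
) -> pd.DataFrame:
    """Smoothed copy-number surrogate per cell.

    ``expression`` is genes × cells normalized log expression.  Per gene the
    mean over reference cells is subtracted; values are clipped to ±cap;
    per chromosome a centered moving average over ``window`` genes is taken
    (truncated at chromosome ends); finally each cell's median smoothed value
    is subtracted.  Returns a cell × gene DataFrame over genes present in
    the track, in genome order.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    refs = [c for c in reference_cells if c in set(cell_ids)]
    if not refs:
        raise ValueError("no reference cells present in the matrix")
    E = np.asarray(expression, dtype=float)
    cell_pos = {c: i for i, c in enumerate(cell_ids)}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    ref_idx = [cell_pos[c] for c in refs]

    order = track.chromosome_order(gene_ids)
    if not order:
        raise ValueError("no annotated genes overlap the expression matrix")
    missing = set(track.table["chrom"]) - set(order)
    for chrom in sorted(missing):
        warnings.warn(f"chromosome {chrom} has no genes in the matrix; skipped")

    blocks, ordered_genes = [], []
    for chrom, genes in order.items():
        gi = [gene_pos[g] for g in genes]
        centered = E[gi, :] - E[np.ix_(gi, ref_idx)].mean(axis=1, keepdims=True)
        centered = np.clip(centered, -cap, cap)
        smoothed = _truncated_moving_average(centered.T, window)  # cells × genes
        blocks.append(smoothed)
        ordered_genes.extend(genes)
    P = np.hstack(blocks)
    P = P - np.median(P, axis=1, keepdims=True)
    return pd.DataFrame(P, index=pd.Index(cell_ids, name="cell_id"), columns=ordered_genes)


def cluster_subclones(profiles: pd.DataFrame, m: int = 3) -> SubcloneAssignment:
    """Ward hierarchical clustering of CNV profiles cut to m clusters;
    cluster ids are relabeled 1..m by decreasing size."""
    if m < 1:
        raise ValueError("m must be >= 1")
    n = profiles.shape[0]
    if m > n:
        raise ValueError("m exceeds the number of cells")
    if m == n:
        raw = np.arange(1, n + 1)
    elif m == 1:
        raw = np.ones(n, dtype=int)
    else:
        Z = ward(profiles.to_numpy())
        raw = fcluster(Z, t=m, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    remap = {old: new + 1 for new, old in enumerate(sizes.index)}
    labels = pd.Series([remap[r] for r in raw], index=profiles.index, name="subclone")
    return SubcloneAssignment(labels=labels, m=int(labels.nunique()))


def archetype_subclone_association(
    scores: ArchetypeScoreTable,
    assignment: SubcloneAssignment,
    one_sided: bool = False,
):
    """Per archetype: one-way ANOVA of archetype score by subclone cluster
    plus Tukey HSD pairwise adjusted p-values.

    Returns (anova DataFrame with one row per archetype, pairwise DataFrame
    with columns archetype, group1, group2, diff, q, p_adj).
    """
    labels = assignment.labels.reindex(scores.cell_ids)
    if labels.isna().any():
        raise ValueError("every scored cell needs a subclone assignment")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least two subclone clusters")
    anova_rows, pair_rows = [], []
    for a in range(scores.k):
        groups = {c: scores.scores[(labels == c).to_numpy(), a] for c in clusters}
        if any(len(v) < 2 for v in groups.values()):
            raise ValueError("each cluster needs at least two cells")
        res = anova_oneway(groups)
        anova_rows.append({"archetype": a, **{k: res[k] for k in ("F", "p")}})
        pw = tukey_pairwise(groups, one_sided=one_sided)
        pw.insert(0, "archetype", a)
        pair_rows.append(pw)
    return pd.DataFrame(anova_rows), pd.concat(pair_rows, ignore_index=True)
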