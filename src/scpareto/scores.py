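"""Archetype scores and specialist classification.

The score of cell i for archetype a is the per-archetype min–max
standardized, inverted Euclidean distance from the cell to that vertex:
score = 1 at the vertex-nearest cell, 0 at the farthest.  Specialists are
cells whose score for some archetype exceeds that archetype's percentile
threshold (default the 80th percentile); a cell qualifying for several
archetypes is labeled with its highest-scoring one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pcha import ArchetypeFit, _coords

NON_SPECIALIST = "non-specialist"


@dataclass
class ArchetypeScoreTable:
    cell_ids: list[str]
    distances: np.ndarray  # cells × k
    scores: np.ndarray  # cells × k, in [0, 1]
    specialist_label: pd.Series | None = None  # cell id → archetype index or "non-specialist"
    percentile_used: float | None = None

    @property
    def k(self):
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            index=pd.Index(self.cell_ids, name="cell_id"),
            columns=[f"archetype_{a + 1}" for a in range(self.k)],
        )
        if self.specialist_label is not None:
            df["label"] = self.specialist_label.values
        return df


def score_cells(X, fit: ArchetypeFit, cell_ids=None) -> ArchetypeScoreTable:
    """Distances and min–max standardized, inverted scores per archetype."""
    Xm = _coords(X)
    if cell_ids is None:
        cell_ids = getattr(X, "cell_ids", None) or [f"cell{i}" for i in range(Xm.shape[1])]
    D = np.linalg.norm(Xm[:, :, None] - fit.Z[:, None, :], axis=0)  # n × k
    dmin, dmax = D.min(axis=0), D.max(axis=0)
    spread = dmax - dmin
    if np.any(spread <= 1e-12 * np.maximum(dmax, 1.0)):
        bad = int(np.argmin(spread))
        raise ValueError(
            f"distances to archetype {bad} are constant across cells; "
            "scores are undefined"
        )
    scores = 1.0 - (D - dmin[None, :]) / spread[None, :]
    return ArchetypeScoreTable(cell_ids=list(cell_ids), distances=D, scores=scores)


def classify_specialists(
    table: ArchetypeScoreTable, percentile: float = 80.0
) -> ArchetypeScoreTable:
    """Label cells whose score strictly exceeds the per-archetype percentile
    threshold; multi-archetype candidates get their highest-scoring archetype
    (ties → lowest archetype index); others are non-specialists."""
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    S = table.scores
    thresholds = np.percentile(S, percentile, axis=0)
    candidate = S > thresholds[None, :]
    labels = []
    for i in range(S.shape[0]):
        if candidate[i].any():
            masked = np.where(candidate[i], S[i], -np.inf)
            labels.append(int(np.argmax(masked)))  # argmax → lowest index on ties
        else:
            labels.append(NON_SPECIALIST)
    return replace(
        table,
        specialist_label=pd.Series(labels, index=pd.Index(table.cell_ids, name="cell_id")),
        percentile_used=percentile,
    )


def enriched_fraction(
    table: ArchetypeScoreTable, groups, threshold: float = 0.8
):
    """Per-group, per-archetype fraction of cells with score > threshold,
    plus each group's empirical CDF of scores.

    ``groups`` maps cell id → group label and must partition the cells.
    Returns (DataFrame group × archetype fractions,
    dict (group, archetype) → (sorted scores, ECDF values)).
    """
    groups = pd.Series(groups).reindex(table.cell_ids)
    if groups.isna().any():
        raise ValueError("groups must cover every cell")
    S = table.scores
    frac_rows, ecdf = {}, {}
    for g, idx in pd.Series(range(len(table.cell_ids)), index=groups.values).groupby(level=0):
        ii = idx.values
        if len(ii) == 0:
            raise ValueError(f"empty group {g!r}")
        frac_rows[g] = (S[ii] > threshold).mean(axis=0)
        for a in range(table.k):
            x = np.sort(S[ii, a])
            ecdf[(g, a)] = (x, np.arange(1, len(x) + 1) / len(x))
    fractions = pd.DataFrame.from_dict(
        frac_rows, orient="index",
        columns=[f"archetype_{a + 1}" for a in range(table.k)],
    ).sort_index()
    return fractions, ecdf
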