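"""Single-sample gene-set enrichment (ssGSEA-style running sum).

Per cell, genes are ranked by descending expression; with rank weight
r_g = (N − position + 1)^alpha, the enrichment score of a set S is

    ES(S) = Σ_{i=1..N} [ Pin(i) − Pout(i) ]

where Pin(i) is the weighted fraction of in-set mass at or above position i
and Pout(i) the unweighted fraction of out-of-set genes at or above i.  The
statistic is rank-based, hence invariant under any strictly monotone
transform of a cell's expression vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class GMTError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]  # name → gene ids (deduplicated, order kept)
    source: str = ""

    def __len__(self):
        return len(self.sets)

    def restrict(self, universe) -> "GeneSetCollection":
        uni = set(universe)
        return GeneSetCollection(
            {name: [g for g in genes if g in uni] for name, genes in self.sets.items()},
            source=self.source,
        )


@dataclass
class EnrichmentMatrix:
    values: pd.DataFrame  # gene-set × cell
    normalization: str = "none"  # none | zscore


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then gene ids,
    tab-separated.  Duplicate genes within a set are deduplicated; empty
    lines skipped; duplicate set names are an error."""
    sets = {}
    with open(path) as fh:
        for ln_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTError(f"line {ln_no}: expected name, description and >=1 gene")
            name = fields[0]
            if name in sets:
                raise GMTError(f"line {ln_no}: duplicate set name {name!r}")
            seen, genes = set(), []
            for g in fields[2:]:
                if g and g not in seen:
                    seen.add(g)
                    genes.append(g)
            sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


def ssgsea_scores(
    expression: np.ndarray,
    gene_ids: list[str],
    collection: GeneSetCollection,
    cell_ids: list[str] | None = None,
    alpha: float = 0.25,
    normalization: str = "none",
) -> EnrichmentMatrix:
    """Per-cell enrichment scores for every set in the collection.

    ``expression`` is genes × cells (normalized values; only ranks matter).
    Ties in expression get average ranks for the weights; the running-sum
    position order breaks ties stably by gene id.
    """
    E = np.asarray(expression, dtype=float)
    N = E.shape[0]
    if N != len(gene_ids):
        raise ValueError("gene_ids length must match the expression rows")
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(E.shape[1])]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    memberships = {}
    for name, genes in collection.sets.items():
        idx = np.array([gene_index[g] for g in genes if g in gene_index], dtype=int)
        if idx.size == 0:
            raise ValueError(f"gene set {name!r} shares no genes with the expression matrix")
        if idx.size == N:
            raise ValueError(f"gene set {name!r} covers the entire gene universe")
        mask = np.zeros(N, dtype=bool)
        mask[idx] = True
        memberships[name] = mask

    id_order = np.argsort(np.array(gene_ids))  # lexicographic tiebreak helper
    id_rank = np.empty(N)
    id_rank[id_order] = np.arange(N)

    ES = np.zeros((len(memberships), E.shape[1]))
    for c in range(E.shape[1]):
        x = E[:, c]
        ranks = rankdata(-x, method="average")  # 1 = highest expression
        weights = (N - ranks + 1.0) ** alpha
        order = np.lexsort((id_rank, -x))  # descending expression, stable by gene id
        w_ord = weights[order]
        for s, mask in enumerate(memberships.values()):
            in_ord = mask[order]
            w_in = np.where(in_ord, w_ord, 0.0)
            pin = np.cumsum(w_in) / w_in.sum()
            pout = np.cumsum(~in_ord) / (N - in_ord.sum())
            ES[s, c] = float(np.sum(pin - pout))

    values = pd.DataFrame(ES, index=list(memberships.keys()), columns=cell_ids)
    if normalization == "zscore":
        mu = values.mean(axis=1)
        sd = values.std(axis=1, ddof=0)
        if (sd == 0).any():
            raise ValueError("cannot z-score a constant enrichment row")
        values = values.sub(mu, axis=0).div(sd, axis=0)
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return EnrichmentMatrix(values=values, normalization=normalization)
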