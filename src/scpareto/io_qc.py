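"""Reading count matrices, quality-control filtering, normalization,
variable-gene selection, and PCA projection.

Orientation is genes × cells everywhere.  QC keeps cells with at least
``min_genes`` expressed genes, at least ``min_umis`` total UMIs, and a
mitochondrial fraction strictly below ``max_mito_pct`` percent (mitochondrial
genes identified by a configurable gene-id prefix, default ``MT-``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread
from sklearn.decomposition import PCA


class FormatError(ValueError):
    """Inconsistent or malformed input files."""


@dataclass
class CountMatrix:
    """Raw gene × cell UMI counts with identifiers and per-cell metadata."""

    values: sp.spmatrix | np.ndarray  # genes × cells, nonnegative integers
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame | None = None  # indexed by cell id

    def __post_init__(self):
        g, c = self.values.shape
        if g != len(self.gene_ids) or c != len(self.cell_ids):
            raise FormatError(
                f"matrix is {g}x{c} but got {len(self.gene_ids)} gene ids "
                f"and {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell ids")
        if self.dense().min() < 0:
            raise ValueError("counts must be nonnegative")

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class QCParams:
    min_genes: int = 1000
    min_umis: int = 2000
    max_mito_pct: float = 25.0
    mito_prefix: str = "MT-"

    def __post_init__(self):
        if self.min_genes <= 0 or self.min_umis <= 0 or self.max_mito_pct <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.max_mito_pct > 100:
            raise ValueError("max_mito_pct cannot exceed 100")


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed_low_genes: int
    removed_low_umis: int
    removed_high_mito: int
    params: dict = field(default_factory=dict)

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class PCSpace:
    """Cells projected onto the leading principal components.

    ``coords`` is cells × d with columns ordered by decreasing variance and
    each column mean ≈ 0.  ``components`` (d × genes) and ``centering`` allow
    projecting new points into the same space via :meth:`transform`.
    """

    coords: np.ndarray
    explained_variance_ratio: np.ndarray
    centering: np.ndarray | None = None  # per-gene means
    components: np.ndarray | None = None  # d × genes
    gene_ids: list[str] | None = None
    cell_ids: list[str] | None = None

    @property
    def n_cells(self):
        return self.coords.shape[0]

    @property
    def d(self):
        return self.coords.shape[1]

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        """Project a genes × m matrix into this PC space (m × d)."""
        if self.components is None or self.centering is None:
            raise ValueError("this PCSpace does not carry a projection")
        M = np.asarray(matrix, dtype=float)
        return (M - self.centering[:, None]).T @ self.components.T


def read_counts(path, format: str = "mtx", meta_path=None) -> CountMatrix:
    """Read a gene × cell count matrix.

    ``mtx``: a directory with matrix.mtx (genes × cells), genes.tsv and
    barcodes.tsv, and optionally meta.csv (indexed by cell id).
    ``csv``: genes as rows (first column gene id), header row of cell ids.
    """
    path = Path(path)
    if format == "mtx":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        barcodes_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, barcodes_f):
            if not f.exists():
                raise FormatError(f"missing input file: {f}")
        values = sp.csr_matrix(mmread(str(mtx)))
        gene_ids = [ln.split("\t")[0] for ln in genes_f.read_text().splitlines() if ln]
        cell_ids = [ln.strip() for ln in barcodes_f.read_text().splitlines() if ln]
        meta_f = meta_path or (path / "meta.csv")
        meta = None
        if Path(meta_f).exists():
            meta = pd.read_csv(meta_f, index_col=0)
            meta.index = meta.index.astype(str)
        return CountMatrix(values, gene_ids, cell_ids, meta)
    elif format == "csv":
        df = pd.read_csv(path, index_col=0)
        meta = None
        if meta_path is not None and Path(meta_path).exists():
            meta = pd.read_csv(meta_path, index_col=0)
            meta.index = meta.index.astype(str)
        return CountMatrix(
            df.to_numpy(), [str(g) for g in df.index], [str(c) for c in df.columns], meta
        )
    raise ValueError(f"unknown format: {format!r}")


def qc_filter(counts: CountMatrix, params: QCParams | None = None):
    """Apply the per-cell QC criteria; returns (filtered CountMatrix, QCReport).

    A cell is kept iff expressed-gene count ≥ min_genes AND total UMIs ≥
    min_umis AND mitochondrial percentage < max_mito_pct (strict).
    """
    params = params or QCParams()
    V = counts.dense()
    n_genes = (V > 0).sum(axis=0)
    n_umis = V.sum(axis=0)
    mito_mask = np.array([g.startswith(params.mito_prefix) for g in counts.gene_ids])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(n_umis > 0, 100.0 * V[mito_mask].sum(axis=0) / np.maximum(n_umis, 1), 100.0)
    pass_genes = n_genes >= params.min_genes
    pass_umis = n_umis >= params.min_umis
    pass_mito = mito_pct < params.max_mito_pct
    keep = pass_genes & pass_umis & pass_mito
    if not keep.any():
        raise ValueError("no cells survive QC filtering")
    report = QCReport(
        n_input=len(counts.cell_ids),
        n_kept=int(keep.sum()),
        removed_low_genes=int((~pass_genes).sum()),
        removed_low_umis=int((~pass_umis).sum()),
        removed_high_mito=int((~pass_mito).sum()),
        params={
            "min_genes": params.min_genes,
            "min_umis": params.min_umis,
            "max_mito_pct": params.max_mito_pct,
            "mito_prefix": params.mito_prefix,
        },
    )
    idx = np.where(keep)[0]
    meta = counts.cell_meta.iloc[idx] if counts.cell_meta is not None else None
    filtered = CountMatrix(
        counts.values[:, idx] if sp.issparse(counts.values) else V[:, idx],
        counts.gene_ids,
        [counts.cell_ids[i] for i in idx],
        meta,
    )
    return filtered, report


def normalize_log(counts: CountMatrix, method: str = "median") -> np.ndarray:
    """Depth-normalize and log-transform: per-cell counts are scaled to the
    median library size across cells (or to 10,000 for ``cpm10k``), then
    log(1+x).  Returns a dense genes × cells float matrix."""
    V = counts.dense().astype(float)
    lib = V.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("all-zero cell encountered; run qc_filter first")
    if method == "median":
        target = float(np.median(lib))
    elif method == "cpm10k":
        target = 1e4
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return np.log1p(V * (target / lib)[None, :])


def select_hvg(normalized: np.ndarray, gene_ids: list[str], n_top: int = 2000) -> list[str]:
    """The n_top genes with highest variance of normalized expression,
    ordered by descending variance with ties broken by lexicographically
    smaller gene id."""
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > len(gene_ids):
        raise ValueError("n_top exceeds the number of genes")
    var = np.asarray(normalized).var(axis=1)
    order = sorted(range(len(gene_ids)), key=lambda i: (-var[i], gene_ids[i]))
    return [gene_ids[i] for i in order[:n_top]]


def pca_project(
    normalized: np.ndarray,
    d: int = 5,
    gene_ids: list[str] | None = None,
    cell_ids: list[str] | None = None,
) -> PCSpace:
    """Gene-centered PCA of cells; component signs are fixed so the
    largest-magnitude loading of each component is positive."""
    M = np.asarray(normalized, dtype=float)
    n_genes, n_cells = M.shape
    if d > min(n_genes, n_cells):
        raise ValueError("d exceeds min(genes, cells)")
    centering = M.mean(axis=1)
    Xc = (M - centering[:, None]).T  # cells × genes
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(Xc)
    sv = pca.singular_values_
    if sv[d - 1] <= max(1e-12 * max(sv[0], 1.0), 1e-300):
        raise ValueError(f"requested d={d} exceeds the numerical rank of the data")
    comps = pca.components_
    # reproducible sign convention
    flip = np.sign(comps[np.arange(d), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    coords = coords * flip[None, :]
    return PCSpace(
        coords=coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
        centering=centering,
        components=comps,
        gene_ids=list(gene_ids) if gene_ids is not None else None,
        cell_ids=list(cell_ids) if cell_ids is not None else None,
    )
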