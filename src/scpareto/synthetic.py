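"""Synthetic single-cell data with known archetype ground truth.

The generator emulates the inputs of a Pareto task inference analysis: UMI
count matrices whose latent structure is a convex mixture of k archetypal
expression programs (Dirichlet mixture weights, negative-binomial counts,
log-normal library-size variation, independent dropout), disjoint signature
gene sets aligned to the programs, longitudinal samples with drifting
specialist proportions, and planted contiguous CNV blocks defining
subclones.

The negative binomial is parameterized by mean and inverse-dispersion
(``dispersion``): var = μ + μ²/dispersion, with the Poisson limit as
dispersion → ∞.  Library-size factors are log-normal(0, 0.3²).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from .io_qc import CountMatrix

#: log-normal sigma of per-cell library-size factors
LIBRARY_SIGMA = 0.3


@dataclass
class ArchetypeTruth:
    """Ground-truth archetype structure behind a simulated dataset."""

    k: int
    programs: np.ndarray  # k × G per-gene mean expression (nonnegative)
    vertex_coords: np.ndarray  # k × d latent vertex positions
    dirichlet_alpha: float
    gene_set_map: dict[int, list[str]]  # archetype → signature gene ids
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if np.any(self.programs < 0):
            raise ValueError("programs must be nonnegative")
        sig = [g for genes in self.gene_set_map.values() for g in genes]
        if len(sig) != len(set(sig)):
            raise ValueError("signature gene sets must be disjoint")
        V = self.vertex_coords
        if np.linalg.matrix_rank(V[1:] - V[0]) < self.k - 1:
            raise ValueError("vertex_coords must be affinely independent")


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    weights: np.ndarray  # cells × k convex mixture weights
    sample_labels: pd.DataFrame  # index cell id; columns sample, patient, time, cohort
    seed: int
    subclone_labels: pd.Series | None = None  # cell id → subclone id
    cnv_segments: list | None = None  # (chrom, start gene idx, end gene idx, fold change)

    def __post_init__(self):
        W = self.weights
        if np.any(W < 0) or np.any(np.abs(W.sum(axis=1) - 1) > 1e-9):
            raise ValueError("weight rows must be nonnegative and sum to 1")
        if set(self.sample_labels.index) != set(self.counts.cell_ids):
            raise ValueError("every cell needs a sample label")


def make_truth(
    k: int,
    n_genes: int,
    d: int,
    alpha: float,
    seed: int,
    n_signature: int = 50,
    signature_fold: float = 4.0,
    n_mito: int = 5,
) -> ArchetypeTruth:
    """Construct k archetypal expression programs over n_genes genes with
    disjoint signature sets (default 50 genes each) elevated
    ``signature_fold``-fold in their archetype's program, plus k affinely
    independent latent vertices in d dimensions.

    A few genes are named with the ``MT-`` prefix so QC's mitochondrial
    criterion is exercised; their expression is baseline in every program.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_genes < 10 * k:
        raise ValueError("need n_genes >= 10*k")
    if d < k - 1:
        raise ValueError(f"k={k} vertices cannot be affinely independent in d={d} dimensions")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)

    if k * n_signature + n_mito > n_genes:
        raise ValueError(
            f"{k} signatures of {n_signature} genes (+{n_mito} mitochondrial) "
            f"do not fit in {n_genes} genes"
        )
    gene_ids = [f"MT-{i + 1}" for i in range(n_mito)]
    gene_ids += [f"G{i + 1:05d}" for i in range(n_genes - n_mito)]

    base = rng.gamma(shape=2.0, scale=1.0, size=n_genes) + 0.05
    programs = np.tile(base, (k, 1))
    non_mito = np.arange(n_mito, n_genes)
    sig_genes = rng.choice(non_mito, size=k * n_signature, replace=False)
    gene_set_map = {}
    for a in range(k):
        idx = sig_genes[a * n_signature : (a + 1) * n_signature]
        programs[a, idx] *= signature_fold
        gene_set_map[a] = [gene_ids[i] for i in sorted(idx)]

    # scaled simplex embedded in d dims, randomly rotated: affinely independent
    V = np.zeros((k, d))
    V[1:, : k - 1] = 10.0 * np.eye(k - 1)
    Q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    vertex_coords = V @ Q.T
    return ArchetypeTruth(
        k=k,
        programs=programs,
        vertex_coords=vertex_coords,
        dirichlet_alpha=alpha,
        gene_set_map=gene_set_map,
        gene_ids=gene_ids,
    )


def _nb_counts(rng, mean, dispersion):
    """Negative binomial via gamma-Poisson; dispersion = inverse-dispersion
    (size); var = μ + μ²/dispersion."""
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-300) / dispersion)
    return rng.poisson(lam)


def _counts_from_weights(
    truth, W, depth, dispersion, dropout, rng, cell_ids
) -> CountMatrix:
    n_cells = W.shape[0]
    mix = W @ truth.programs  # cells × G
    mix = mix / mix.sum(axis=1, keepdims=True)
    lib = np.exp(rng.normal(0.0, LIBRARY_SIGMA, size=n_cells))
    mean = (depth * lib)[:, None] * mix
    counts = _nb_counts(rng, mean, dispersion)
    if dropout > 0:
        counts = counts * (rng.random(counts.shape) >= dropout)
    return CountMatrix(
        sp.csr_matrix(counts.T.astype(np.int64)), list(truth.gene_ids), list(cell_ids)
    )


def simulate_counts(
    truth: ArchetypeTruth,
    n_cells: int,
    depth: float = 5000.0,
    dispersion: float = 2.0,
    dropout: float = 0.1,
    seed: int = 0,
) -> SimulatedDataset:
    """Draw cells as Dirichlet(alpha·1) mixtures of the archetype programs
    and sample negative-binomial UMI counts with dropout."""
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    if not (0 <= dropout < 1):
        raise ValueError("dropout must be in [0, 1)")
    if depth <= 0 or dispersion <= 0:
        raise ValueError("depth and dispersion must be positive")
    rng = np.random.default_rng(seed)
    W = rng.dirichlet(np.full(truth.k, truth.dirichlet_alpha), size=n_cells)
    cell_ids = [f"C{i + 1:06d}" for i in range(n_cells)]
    counts = _counts_from_weights(truth, W, depth, dispersion, dropout, rng, cell_ids)
    labels = pd.DataFrame(
        {"sample": "S0", "patient": "P0", "time": 0, "cohort": "cohort0"},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return SimulatedDataset(counts=counts, weights=W, sample_labels=labels, seed=seed)


def _specialist_weights(rng, k, alpha, archetype, min_max_weight=0.8, max_tries=10000):
    """Dirichlet draw conditioned on max weight > min_max_weight, permuted so
    the dominant entry is the requested archetype."""
    for _ in range(max_tries):
        w = rng.dirichlet(np.full(k, alpha))
        if w.max() > min_max_weight:
            j = int(np.argmax(w))
            w[j], w[archetype] = w[archetype], w[j]
            return w
    raise RuntimeError("rejection sampling for specialist weights did not converge")


def simulate_longitudinal(
    truth: ArchetypeTruth,
    proportions_by_time: list,
    cells_per_time: int,
    seed: int = 0,
    interior_fraction: float = 0.2,
    depth: float = 5000.0,
    dispersion: float = 2.0,
    dropout: float = 0.1,
) -> SimulatedDataset:
    """Per time point, draw specialist cells near the vertices with the
    stated archetype frequencies plus an ``interior_fraction`` of
    unconditioned interior cells."""
    props = [np.asarray(p, dtype=float) for p in proportions_by_time]
    for p in props:
        if len(p) != truth.k:
            raise ValueError("each proportion vector must have length k")
        if np.any(p < 0):
            raise ValueError("proportions must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("each proportion vector must sum to 1")
    rng = np.random.default_rng(seed)
    rows_W, cell_ids, meta = [], [], []
    for t, p in enumerate(props):
        n_int = int(round(interior_fraction * cells_per_time))
        n_spec = cells_per_time - n_int
        assign = rng.choice(truth.k, size=n_spec, p=p)
        for i in range(cells_per_time):
            if i < n_spec:
                w = _specialist_weights(rng, truth.k, truth.dirichlet_alpha, int(assign[i]))
            else:
                w = rng.dirichlet(np.full(truth.k, truth.dirichlet_alpha))
            rows_W.append(w)
            cid = f"T{t}_C{i + 1:06d}"
            cell_ids.append(cid)
            meta.append({"sample": f"S{t}", "patient": "P0", "time": t, "cohort": "cohort0"})
    W = np.vstack(rows_W)
    counts = _counts_from_weights(truth, W, depth, dispersion, dropout, rng, cell_ids)
    labels = pd.DataFrame(meta, index=pd.Index(cell_ids, name="cell_id"))
    return SimulatedDataset(counts=counts, weights=W, sample_labels=labels, seed=seed)


def simulate_latent(
    vertices: np.ndarray,
    n_cells: int,
    alpha: float = 0.3,
    noise_frac: float = 0.02,
    seed: int = 0,
):
    """Cells as Dirichlet(alpha) convex mixtures of latent vertices plus
    isotropic Gaussian noise with SD = ``noise_frac`` × the mean pairwise
    vertex spacing.  Returns (coords cells × d, weights cells × k)."""
    V = np.asarray(vertices, dtype=float)
    k = V.shape[0]
    rng = np.random.default_rng(seed)
    W = rng.dirichlet(np.full(k, alpha), size=n_cells)
    D = np.linalg.norm(V[:, None, :] - V[None, :, :], axis=2)
    spacing = D[np.triu_indices(k, 1)].mean()
    X = W @ V + rng.normal(0.0, noise_frac * spacing, size=(n_cells, V.shape[1]))
    return X, W


def plant_cnv_subclones(
    dataset: SimulatedDataset,
    segments: list,
    assignment: pd.Series | dict,
    fold_changes: list,
    seed: int | None = None,
) -> SimulatedDataset:
    """Rescale counts of genes inside each segment for cells of the carrier
    subclone by the segment's fold-change.

    ``segments`` is a list of (chrom, start_gene_index, end_gene_index,
    subclone_id) with inclusive 0-based gene index ranges; fold change i
    applies to segment i.  Gains (fc > 1) add Poisson((fc−1)·count) extra
    counts; losses (fc < 1) binomially thin — either way the mean scales
    exactly by fc.
    """
    if len(segments) != len(fold_changes):
        raise ValueError("one fold change per segment is required")
    assignment = pd.Series(assignment)
    by_clone_chrom = {}
    for (chrom, start, end, clone), fc in zip(segments, fold_changes):
        if end < start:
            raise ValueError(f"segment end {end} < start {start}")
        if fc <= 0:
            raise ValueError("fold changes must be positive")
        key = (clone, chrom)
        for s, e in by_clone_chrom.get(key, []):
            if start <= e and s <= end:
                raise ValueError(f"overlapping segments on {chrom} for subclone {clone}")
        by_clone_chrom.setdefault(key, []).append((start, end))

    rng = np.random.default_rng(dataset.seed + 7919 if seed is None else seed)
    V = dataset.counts.dense().astype(np.int64).copy()
    cell_clone = assignment.reindex(dataset.counts.cell_ids)
    seg_records = []
    for (chrom, start, end, clone), fc in zip(segments, fold_changes):
        carriers = np.where(cell_clone.values == clone)[0]
        seg_records.append((chrom, start, end, fc))
        if fc == 1.0 or carriers.size == 0:
            continue
        view = V[start : end + 1]
        block = view[:, carriers]
        if fc > 1.0:
            block = block + rng.poisson((fc - 1.0) * block)
        else:
            block = rng.binomial(block, fc)
        view[:, carriers] = block
    counts = CountMatrix(
        sp.csr_matrix(V), list(dataset.counts.gene_ids), list(dataset.counts.cell_ids)
    )
    return replace(
        dataset,
        counts=counts,
        subclone_labels=cell_clone,
        cnv_segments=(dataset.cnv_segments or []) + seg_records,
    )


def make_gene_track(gene_ids: list[str], n_chromosomes: int = 5) -> pd.DataFrame:
    """Assign genes to chromosomes in contiguous index blocks with 1-based
    inclusive coordinates (10 kb per gene); columns gene, chrom, start, end."""
    n = len(gene_ids)
    per = int(np.ceil(n / n_chromosomes))
    rows = []
    for i, g in enumerate(gene_ids):
        c = i // per
        j = i % per
        rows.append({"gene": g, "chrom": f"chr{c + 1}", "start": j * 10000 + 1, "end": j * 10000 + 5000})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers (MTX triplet, GMT, gene track TSV, metadata CSV)

def write_mtx(dataset: SimulatedDataset, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    M = dataset.counts.values
    mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(M))
    (outdir / "genes.tsv").write_text(
        "".join(f"{g}\t{g}\n" for g in dataset.counts.gene_ids)
    )
    (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in dataset.counts.cell_ids))
    dataset.sample_labels.loc[dataset.counts.cell_ids].to_csv(outdir / "meta.csv")
    if dataset.subclone_labels is not None:
        dataset.subclone_labels.rename("subclone").to_csv(outdir / "subclones.csv")
    return outdir


def write_gmt(gene_sets: dict, path, description: str = "synthetic"):
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([str(name), description, *genes]) + "\n")
    return path


def write_gene_track(track: pd.DataFrame, path):
    track.to_csv(path, sep="\t", index=False)
    return path


def truth_gene_sets(truth: ArchetypeTruth) -> dict:
    """Signature gene sets named after their archetype."""
    return {f"ARCHETYPE_{a + 1}_SIGNATURE": genes for a, genes in truth.gene_set_map.items()}
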