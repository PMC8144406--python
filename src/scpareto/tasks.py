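"""Biological task annotation of archetypes.

A multitask (multi-response Gaussian) group-lasso regresses all k archetype
score columns jointly on standardized pathway enrichment scores:

    (1/2n) ‖Y − 1bᵀ − X B‖²_F  +  λ Σ_j ‖B_j·‖₂

so each pathway is either active in all responses jointly or zero in all.
Solved by block coordinate descent with the group soft-threshold
B_j· ← (1 − λ/‖z_j‖₂)₊ z_j on standardized columns, warm-started along a
log-spaced λ path from λ_max (the smallest λ with an all-zero solution).
λ is chosen by 10-fold cross-validation with the one-standard-error rule.
Active-coefficient rows are then hierarchically clustered (correlation
distance, average linkage) into task groups, each mapped to the archetype
with the largest mean coefficient.  A univariate pass (per pathway–archetype
simple regression with Benjamini–Hochberg FDR) provides the orthogonal
association table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from statsmodels.stats.multitest import multipletests


@dataclass
class TaskModel:
    B: np.ndarray  # p × k coefficients at the chosen λ
    intercepts: np.ndarray  # length k
    lambda_path: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    folds: int
    seed: int
    pathway_names: list[str] = field(default_factory=list)

    def active_pathways(self):
        mask = np.linalg.norm(self.B, axis=1) > 0
        return [self.pathway_names[j] for j in np.where(mask)[0]]


@dataclass
class ArchetypeTaskLabels:
    pathway_clusters: dict[str, int]  # active pathway → cluster id (1..n_clusters)
    cluster_to_archetype: dict[int, int]  # cluster id → archetype index
    archetype_names: dict[int, str] = field(default_factory=dict)


def _check_standardized(Xp):
    mu = Xp.mean(axis=0)
    sd = Xp.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant pathway column; standardize (and drop constants) first")
    if np.max(np.abs(mu)) > 1e-6 or np.max(np.abs(sd - 1)) > 1e-6:
        raise ValueError("predictor columns must be standardized (mean 0, SD 1)")


def standardize(Xp: np.ndarray):
    """Z-score columns; raises on constant columns."""
    Xp = np.asarray(Xp, dtype=float)
    sd = Xp.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant pathway column cannot be standardized")
    return (Xp - Xp.mean(axis=0)) / sd


def _bcd_grouplasso(X, Y, lam, B0, max_sweeps=2000, tol=1e-7):
    """Block coordinate descent at one λ (columns of X standardized)."""
    n, p = X.shape
    B = B0.copy()
    R = Y - X @ B
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            xj = X[:, j]
            Bj_old = B[j].copy()
            z = xj @ (R + np.outer(xj, Bj_old)) / n  # x_j'x_j/n = 1
            nz = np.linalg.norm(z)
            Bj_new = np.zeros_like(Bj_old) if nz <= lam else (1.0 - lam / nz) * z
            delta = Bj_new - Bj_old
            if np.any(delta):
                R -= np.outer(xj, delta)
                B[j] = Bj_new
                max_delta = max(max_delta, float(np.max(np.abs(delta))))
        if max_delta < tol:
            break
    return B


def fit_grouplasso_path(
    Xp: np.ndarray,
    Y: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    lambdas: np.ndarray | None = None,
    tol: float = 1e-7,
):
    """Coefficient path over a decreasing λ grid with warm starts.

    Returns (lambdas, list of p × k coefficient matrices, length-k
    intercepts).  λ_max = max_j ‖x_jᵀ Y / n‖₂ yields the all-zero solution.
    """
    Xp = np.asarray(Xp, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    _check_standardized(Xp)
    n, p = Xp.shape
    k = Y.shape[1]
    intercepts = Y.mean(axis=0)
    Yc = Y - intercepts
    if lambdas is None:
        lam_max = float(np.max(np.linalg.norm(Xp.T @ Yc / n, axis=1)))
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    lambdas = np.asarray(lambdas, dtype=float)
    B = np.zeros((p, k))
    path = []
    for lam in lambdas:
        B = _bcd_grouplasso(Xp, Yc, lam, B, tol=tol)
        path.append(B.copy())
    return lambdas, path, intercepts


def cv_grouplasso(
    Xp: np.ndarray,
    Y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    pathway_names: list[str] | None = None,
) -> TaskModel:
    """K-fold cross-validated group lasso with the one-SE rule.

    cv_mean is the mean held-out Frobenius MSE per λ; λ_1se is the largest λ
    whose cv_mean is within one standard error of the minimum; the reported
    B is the full-data fit at λ_1se.
    """
    Xp = np.asarray(Xp, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Xp.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("need at least one sample per fold")
    _check_standardized(Xp)
    lambdas, full_path, intercepts = fit_grouplasso_path(
        Xp, Y, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio
    )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_id = np.empty(n, dtype=int)
    fold_id[perm] = np.arange(n) % folds
    errs = np.zeros((folds, len(lambdas)))
    for f in range(folds):
        tr, te = fold_id != f, fold_id == f
        _, path, b = fit_grouplasso_path(
            standardize(Xp[tr]), Y[tr], lambdas=lambdas
        )
        Xte = standardize_like(Xp[te], Xp[tr])
        for li, B in enumerate(path):
            pred = b + Xte @ B
            errs[f, li] = float(np.mean((Y[te] - pred) ** 2))
    cv_mean = errs.mean(axis=0)
    cv_se = errs.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(cv_mean))
    bound = cv_mean[i_min] + cv_se[i_min]
    ok = np.where(cv_mean <= bound)[0]
    i_1se = int(ok.min())  # lambdas are decreasing, so smallest index = largest λ
    if pathway_names is None:
        pathway_names = [f"pathway_{j + 1}" for j in range(Xp.shape[1])]
    return TaskModel(
        B=full_path[i_1se],
        intercepts=intercepts,
        lambda_path=lambdas,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_min=float(lambdas[i_min]),
        lambda_1se=float(lambdas[i_1se]),
        folds=folds,
        seed=seed,
        pathway_names=list(pathway_names),
    )


def standardize_like(X, ref):
    """Z-score columns of X using the mean/SD of ref (for held-out folds)."""
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _correlation_distance(rows: np.ndarray) -> np.ndarray:
    """Condensed 1−r distance; constant rows get r = 0 against everything."""
    p = rows.shape[0]
    sd = rows.std(axis=1)
    Z = rows - rows.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * rows.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(denom > 0, (Z @ Z.T) / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(R, 1.0)
    D = np.clip(1.0 - R, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return squareform(D, checks=False)


def cluster_coefficients(
    model: TaskModel | np.ndarray,
    n_clusters: int = 3,
    pathway_names: list[str] | None = None,
) -> ArchetypeTaskLabels:
    """Hierarchically cluster active coefficient rows (correlation distance,
    average linkage) into task groups; map each cluster to the archetype with
    the largest mean coefficient."""
    if isinstance(model, TaskModel):
        B = model.B
        names = model.pathway_names
    else:
        B = np.asarray(model, dtype=float)
        names = pathway_names or [f"pathway_{j + 1}" for j in range(B.shape[0])]
    active = np.where(np.linalg.norm(B, axis=1) > 0)[0]
    if len(active) < n_clusters:
        raise ValueError(
            f"only {len(active)} active pathways; cannot form {n_clusters} clusters"
        )
    rows = B[active]
    if len(active) == n_clusters:
        labels = np.arange(1, n_clusters + 1)
    else:
        Zl = average(_correlation_distance(rows))
        labels = fcluster(Zl, t=n_clusters, criterion="maxclust")
    pathway_clusters = {names[j]: int(c) for j, c in zip(active, labels)}
    cluster_to_archetype = {}
    for c in sorted(set(labels.tolist())):
        mean_coef = rows[labels == c].mean(axis=0)
        cluster_to_archetype[int(c)] = int(np.argmax(mean_coef))
    return ArchetypeTaskLabels(
        pathway_clusters=pathway_clusters, cluster_to_archetype=cluster_to_archetype
    )


def univariate_associations(enrichment, scores: np.ndarray) -> pd.DataFrame:
    """Per pathway–archetype simple linear regression with BH FDR.

    ``enrichment`` is an EnrichmentMatrix or a pathway × cell DataFrame;
    ``scores`` is cells × k.  Zero-variance pathways are skipped and flagged
    in the ``skipped`` attribute-column of the result.
    """
    if isinstance(enrichment, pd.DataFrame):
        values = enrichment
    elif hasattr(enrichment, "values") and isinstance(enrichment.values, pd.DataFrame):
        values = enrichment.values
    else:
        values = pd.DataFrame(enrichment)
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    rows, skipped = [], []
    for name, x in values.iterrows():
        xv = x.to_numpy(dtype=float)
        if np.std(xv) == 0:
            skipped.append(name)
            continue
        for a in range(scores.shape[1]):
            res = linregress(xv, scores[:, a])
            rows.append({"pathway": name, "archetype": a, "slope": res.slope,
                         "p": res.pvalue})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = multipletests(table["p"].fillna(1.0), method="fdr_bh")[1]
        table = table.sort_values("fdr", kind="stable").reset_index(drop=True)
    table.attrs["skipped"] = skipped
    return table
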