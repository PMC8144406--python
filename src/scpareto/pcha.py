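"""Archetypal analysis by the principal convex hull algorithm (PCHA).

Cells (as points in PC space) are factored as convex mixtures of archetypes
that are themselves convex mixtures of cells:

    X  ≈  X · C · S

with X the d × n data matrix, C (n × k) and S (k × n) column-stochastic and
nonnegative.  The archetypes Z = X·C therefore lie inside the convex hull of
the data; they are the vertices of the fitted polytope.  The factorization is
found by alternating projected-gradient descent with adaptive step halving,
so the residual sum of squares is non-increasing across iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class ArchetypeFit:
    """Fitted polytope for one vertex count k.

    Z is d × k (archetype coordinates), C is n × k (cell-to-archetype
    generator weights), S is k × n (archetype-to-cell mixture weights).
    ``ev`` is 1 − sse/SST with SST the mean-centered total variation, so the
    trivial k=1 model has ev = 0.
    """

    k: int
    Z: np.ndarray
    C: np.ndarray
    S: np.ndarray
    sse: float
    ev: float
    n_iter: int
    restarts_used: int
    seed: int | None = None
    converged: bool = True
    sse_history: list = field(default_factory=list, repr=False)


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex
    {w : w ≥ 0, Σw = 1}."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("project_to_simplex expects a non-empty 1-D vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite entries in input vector")
    return _project_columns(v[:, None])[:, 0]


def _project_columns(V: np.ndarray) -> np.ndarray:
    """Project each column of V onto the probability simplex (sort-based)."""
    m, n = V.shape
    U = -np.sort(-V, axis=0)
    cssv = np.cumsum(U, axis=0) - 1.0
    ind = np.arange(1, m + 1, dtype=float)[:, None]
    cond = U - cssv / ind > 0
    # rho = largest index where cond holds (cond always holds at index 0)
    rho = m - 1 - np.argmax(cond[::-1], axis=0)
    theta = cssv[rho, np.arange(n)] / (rho + 1.0)
    return np.maximum(V - theta[None, :], 0.0)


def _furthest_sum(Xm: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """FurthestSum greedy anchor selection (ties broken by lowest index).

    Starts from a random cell, greedily adds the cell maximizing the summed
    distance to the current anchors, then discards the random start and
    selects one replacement.
    """
    n = Xm.shape[1]
    sq = np.einsum("ij,ij->j", Xm, Xm)

    def dist_to(i):
        d2 = sq + sq[i] - 2.0 * (Xm.T @ Xm[:, i])
        return np.sqrt(np.maximum(d2, 0.0))

    if k >= n:
        return np.arange(n, dtype=int)
    start = int(rng.integers(n))
    selected = [start]
    sumd = dist_to(start)
    n_extra = k if k + 1 <= n else n - 1
    for _ in range(n_extra):
        sumd_masked = sumd.copy()
        sumd_masked[selected] = -np.inf
        nxt = int(np.argmax(sumd_masked))  # argmax → first (lowest) index on ties
        selected.append(nxt)
        sumd = sumd + dist_to(nxt)
    # drop the random start (classic FurthestSum correction)
    selected = selected[1:]
    if len(selected) < k:
        selected.append(start)
    return np.asarray(selected[:k], dtype=int)


def _coords(X) -> np.ndarray:
    """Accept a PCSpace-like object (``.coords`` cells × d) or a raw
    cells × d array; return the d × n internal matrix."""
    coords = getattr(X, "coords", X)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("expected a 2-D cells × d coordinate matrix")
    return coords.T


def _sse(Xm, C, S):
    R = Xm - (Xm @ C) @ S
    return float(np.einsum("ij,ij->", R, R))


def _fit_single(Xm, k, C0, S0, max_iter, tol, delta):
    """Alternating projected-gradient PCHA from one initialization."""
    C, S = C0.copy(), S0.copy()
    alpha = np.ones(k)  # per-column scale for delta-relaxed hull
    sse = _sse(Xm, C * alpha, S)
    mu_c, mu_s = 1.0, 1.0
    history = [sse]
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        sse_prev = sse
        Ca = C * alpha
        # --- S update ---
        Z = Xm @ Ca
        ZtZ = Z.T @ Z
        ZtX = Z.T @ Xm
        G = ZtZ @ S - ZtX
        for _ in range(30):
            S_new = _project_columns(S - mu_s * G)
            sse_new = _sse(Xm, Ca, S_new)
            if sse_new <= sse:
                S, sse = S_new, sse_new
                mu_s *= 1.2
                break
            mu_s /= 2.0
        # --- C update ---
        SSt = S @ S.T
        XSt = Xm @ S.T
        G = Xm.T @ ((Xm @ (C * alpha)) @ SSt - XSt) * alpha[None, :]
        for _ in range(30):
            C_new = _project_columns(C - mu_c * G)
            sse_new = _sse(Xm, C_new * alpha, S)
            if sse_new <= sse:
                C, sse = C_new, sse_new
                mu_c *= 1.2
                break
            mu_c /= 2.0
        if delta > 0:
            # exact per-column scale solve, clipped to [1-delta, 1+delta]
            Z = Xm @ C
            M = (Z.T @ Z) * (S @ S.T)
            b = np.einsum("dk,dk->k", Z, Xm @ S.T)
            try:
                a = np.linalg.solve(M + 1e-12 * np.eye(k), b)
            except np.linalg.LinAlgError:
                a = alpha
            a = np.clip(a, 1.0 - delta, 1.0 + delta)
            sse_a = _sse(Xm, C * a, S)
            if sse_a <= sse:
                alpha, sse = a, sse_a
        history.append(sse)
        denom = max(sse_prev, 1e-300)
        if (sse_prev - sse) / denom < tol:
            converged = True
            break
    return C * alpha, S, sse, n_iter, converged, history


def fit_pcha(
    X,
    k: int,
    restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = 0,
    delta: float = 0.0,
    extra_inits: list | None = None,
) -> ArchetypeFit:
    """Fit a k-vertex principal convex hull to the cells in X.

    Parameters
    ----------
    X : PCSpace or cells × d array
    k : number of archetypes (vertices); k=1 is allowed with a warning and
        returns the data centroid with ev = 0.
    restarts : number of FurthestSum-seeded starts; the best final SSE wins.
    delta : relaxation allowing archetypes slightly outside the data hull
        (column sums of C in [1−δ, 1+δ]); 0 keeps them strictly inside.
    extra_inits : optional list of (C0, S0) pairs tried in addition to the
        seeded restarts (used for nested initialization across k).
    """
    Xm = _coords(X)
    d, n = Xm.shape
    if not np.all(np.isfinite(Xm)):
        raise ValueError("non-finite values in input data")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells n={n}")
    if k == 1:
        warnings.warn("k=1 is degenerate: the single archetype is the data centroid")
    rng = np.random.default_rng(seed)

    inits = []
    for _ in range(max(restarts, 1)):
        anchors = _furthest_sum(Xm, k, rng) if k <= n else np.arange(k)
        C0 = np.zeros((n, k))
        C0[anchors, np.arange(k)] = 1.0
        S0 = np.full((k, n), 1.0 / k)
        inits.append((C0, S0))
    if extra_inits:
        inits.extend((C0.copy(), S0.copy()) for C0, S0 in extra_inits)

    best = None
    for C0, S0 in inits:
        C, S, sse, n_iter, converged, history = _fit_single(
            Xm, k, C0, S0, max_iter, tol, delta
        )
        if best is None or sse < best[2]:
            best = (C, S, sse, n_iter, converged, history)
    C, S, sse, n_iter, converged, history = best
    if not converged:
        warnings.warn("PCHA hit max_iter without meeting the SSE tolerance")

    mu = Xm.mean(axis=1, keepdims=True)
    sst = float(np.einsum("ij,ij->", Xm - mu, Xm - mu))
    ev = 1.0 - sse / sst if sst > 0 else 1.0
    return ArchetypeFit(
        k=k,
        Z=Xm @ C,
        C=C,
        S=S,
        sse=sse,
        ev=ev,
        n_iter=n_iter,
        restarts_used=len(inits),
        seed=seed,
        converged=converged,
        sse_history=history,
    )


def match_archetypes(fitA: ArchetypeFit, fitB: ArchetypeFit) -> np.ndarray:
    """Permutation p such that vertex j of fitA pairs with vertex p[j] of
    fitB, minimizing the total Euclidean distance between paired vertices."""
    ZA = fitA.Z if isinstance(fitA, ArchetypeFit) else np.asarray(fitA)
    ZB = fitB.Z if isinstance(fitB, ArchetypeFit) else np.asarray(fitB)
    if ZA.shape != ZB.shape:
        raise ValueError("fits must share k and the embedding space")
    D = np.linalg.norm(ZA[:, :, None] - ZB[:, None, :], axis=0)
    rows, cols = linear_sum_assignment(D)
    perm = np.empty(ZA.shape[1], dtype=int)
    perm[rows] = cols
    return perm
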