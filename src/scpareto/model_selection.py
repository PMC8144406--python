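"""Choosing the number of archetypes.

The vertex count k is scanned over a range (default 3–8), each k fitted with
a shared restart protocol plus a nested initialization carried over from the
previous k (which guarantees the explained-variance curve is non-decreasing).
The elbow rule picks the smallest k whose next increment gains less than an
absolute explained-variance threshold.  Polytope tightness is quantified by
the t-ratio — the volume of the fitted polytope divided by the volume of the
data's convex hull, both in the first (k−1) coordinates — and its
significance by a randomization test that independently permutes each
coordinate column across cells (destroying the joint simplex structure while
preserving the marginals).  With vertices constrained inside the data hull
(δ = 0) a tight simplex fit has t-ratio near 1, while a shuffled elliptical
cloud can only inscribe a relatively small polytope; the null therefore
counts shuffled t-ratios ≥ the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import factorial

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .pcha import ArchetypeFit, fit_pcha, match_archetypes, _coords


@dataclass
class KScanResult:
    records: list  # per-k dicts: k, ev, sse, t_ratio, t_ratio_pvalue, vertex_uncertainty
    fits: dict = field(repr=False, default_factory=dict)  # k → ArchetypeFit
    chosen_k: int | None = None
    gain_threshold: float | None = None
    chose_k_max: bool = False

    def ev(self, k):
        return next(r["ev"] for r in self.records if r["k"] == k)


def _nested_init(fit: ArchetypeFit, Xm: np.ndarray):
    """Extend a k-vertex solution to k+1 by adding the cell farthest from its
    nearest archetype as a fresh vertex; SSE is unchanged at the start."""
    n = Xm.shape[1]
    D = np.linalg.norm(Xm[:, :, None] - fit.Z[:, None, :], axis=0)  # n × k
    j = int(np.argmax(D.min(axis=1)))
    C = np.hstack([fit.C, np.zeros((n, 1))])
    C[j, -1] = 1.0
    S = np.vstack([fit.S, np.zeros((1, n))])
    return C, S


def scan_k(
    X,
    k_min: int = 3,
    k_max: int = 8,
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    with_t_ratio: bool = False,
) -> KScanResult:
    """Fit each k in [k_min, k_max] with a shared restart protocol; record
    explained variance and SSE (and optionally the t-ratio)."""
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    Xm = _coords(X)
    if k_max > Xm.shape[1]:
        raise ValueError("k_max exceeds the number of cells")
    records, fits = [], {}
    prev = None
    for k in range(k_min, k_max + 1):
        extra = [_nested_init(prev, Xm)] if prev is not None else None
        fit = fit_pcha(
            X, k, restarts=restarts, max_iter=max_iter, tol=tol,
            seed=seed + k, extra_inits=extra,
        )
        rec = {"k": k, "ev": fit.ev, "sse": fit.sse,
               "t_ratio": None, "t_ratio_pvalue": None, "vertex_uncertainty": None}
        if with_t_ratio and k >= 3:
            try:
                rec["t_ratio"] = t_ratio(fit, X)
            except ValueError:
                pass
        records.append(rec)
        fits[k] = fit
        prev = fit
    return KScanResult(records=records, fits=fits)


def select_k_elbow(scan: KScanResult, gain_threshold: float = 0.02) -> int:
    """Smallest k whose gain in explained variance at k+1 falls below
    ``gain_threshold`` (absolute EV); if every gain is large, returns k_max
    with ``chose_k_max`` flagged."""
    if len(scan.records) < 2:
        raise ValueError("need at least two k values to locate an elbow")
    evs = [(r["k"], r["ev"]) for r in scan.records]
    scan.gain_threshold = gain_threshold
    for (k, ev), (_, ev_next) in zip(evs, evs[1:]):
        if ev_next - ev < gain_threshold:
            scan.chosen_k = k
            scan.chose_k_max = False
            return k
    scan.chosen_k = evs[-1][0]
    scan.chose_k_max = True
    return scan.chosen_k


def _simplex_volume(P: np.ndarray) -> float:
    """Volume of the simplex with rows of P as vertices (k points in k−1
    dims); 0 for degenerate configurations."""
    k = P.shape[0]
    return abs(float(np.linalg.det(P[1:] - P[0]))) / factorial(k - 1)


def t_ratio(fit: ArchetypeFit, X) -> float:
    """volume(polytope of archetypes) / volume(convex hull of cells), both
    computed in the first (k−1) coordinates."""
    if fit.k < 3:
        raise ValueError("t-ratio requires k >= 3")
    m = fit.k - 1
    Xm = _coords(X)
    if Xm.shape[0] < m:
        raise ValueError("data has fewer coordinates than k-1")
    pts = Xm[:m].T
    try:
        data_vol = ConvexHull(pts).volume
    except QhullError as e:
        raise ValueError("degenerate (zero-volume) data hull") from e
    if data_vol <= 0:
        raise ValueError("degenerate (zero-volume) data hull")
    poly_vol = _simplex_volume(fit.Z[:m].T)
    return poly_vol / data_vol


def t_ratio_test(
    X,
    k: int,
    n_shuffles: int = 200,
    seed: int = 0,
    restarts: int = 3,
    max_iter: int = 300,
    tol: float = 1e-6,
):
    """Randomization test of polytope tightness.

    Null datasets are made by independently permuting each coordinate column
    across cells; each null is refit at k and its t-ratio computed.  A tight
    (simplex-like) dataset has a larger t-ratio than its shuffled nulls, so
    the add-one empirical p is
    (1 + #{null t-ratio ≥ observed}) / (1 + n_shuffles).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    Xm = _coords(X)
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs_fit = fit_pcha(Xm.T, k, restarts=restarts, max_iter=max_iter, tol=tol,
                           seed=int(rng.integers(2**31)))
    observed = t_ratio(obs_fit, Xm.T)
    count = 0
    for _ in range(n_shuffles):
        null = np.column_stack([rng.permutation(col) for col in Xm])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_fit = fit_pcha(null, k, restarts=restarts, max_iter=max_iter, tol=tol,
                                seed=int(rng.integers(2**31)))
        try:
            tr = t_ratio(null_fit, null)
        except ValueError:
            tr = 0.0
        if tr >= observed:
            count += 1
    p = (1 + count) / (1 + n_shuffles)
    return observed, p


def bootstrap_vertex_uncertainty(
    X,
    k: int,
    n_boot: int = 50,
    seed: int = 0,
    restarts: int = 3,
    max_iter: int = 300,
    force_include: np.ndarray | None = None,
    reference: ArchetypeFit | None = None,
) -> np.ndarray:
    """Per-vertex mean displacement across bootstrap resamples (units of PC
    space).  Cells are resampled with replacement, refit, and vertices
    matched to the reference fit by optimal assignment.  ``force_include``
    (cell indices always kept) provides the stratified option for data whose
    vertices are actual cells."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    Xm = _coords(X)
    n = Xm.shape[1]
    rng = np.random.default_rng(seed)
    ref = reference or fit_pcha(Xm.T, k, restarts=max(restarts, 5), max_iter=max_iter,
                                seed=int(rng.integers(2**31)))
    disp = np.zeros(k)
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        if force_include is not None:
            idx = np.concatenate([np.asarray(force_include, dtype=int), idx])
        fit = fit_pcha(Xm[:, idx].T, k, restarts=restarts, max_iter=max_iter,
                       seed=int(rng.integers(2**31)))
        perm = match_archetypes(ref, fit)
        disp += np.linalg.norm(ref.Z - fit.Z[:, perm], axis=0)
    return disp / n_boot
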