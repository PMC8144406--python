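"""Multitask group lasso: path correctness, CV/one-SE selection, coefficient
clustering, and univariate associations."""

import numpy as np
import pandas as pd
import pytest

from scpareto.tasks import (
    cluster_coefficients, cv_grouplasso, fit_grouplasso_path, standardize,
    univariate_associations,
)


@pytest.fixture
def small_instance():
    rng = np.random.default_rng(7)
    Xp = standardize(rng.normal(size=(50, 10)))
    Y = rng.normal(size=(50, 2))
    return Xp, Y


def test_lambda_max_gives_exact_zero(small_instance):
    Xp, Y = small_instance
    n = Xp.shape[0]
    Yc = Y - Y.mean(axis=0)
    lam_max = float(np.max(np.linalg.norm(Xp.T @ Yc / n, axis=1)))
    _, path, _ = fit_grouplasso_path(Xp, Y, lambdas=np.array([lam_max * (1 + 1e-10)]))
    assert np.all(path[0] == 0.0)


def test_lambda_zero_matches_normal_equations(small_instance):
    Xp, Y = small_instance
    _, path, _ = fit_grouplasso_path(Xp, Y, lambdas=np.array([0.0]))
    Bls = np.linalg.lstsq(Xp, Y - Y.mean(axis=0), rcond=None)[0]
    np.testing.assert_allclose(path[0], Bls, atol=1e-5)


def test_duplicated_responses_scale_lambda_by_sqrt2(small_instance):
    """With Y duplicated to [Y, Y], each group norm doubles in squared terms,
    so the active set at λ√2 matches the original active set at λ."""
    Xp, Y = small_instance
    n = Xp.shape[0]
    Yc = Y - Y.mean(axis=0)
    lam_max = float(np.max(np.linalg.norm(Xp.T @ Yc / n, axis=1)))
    lams = lam_max * np.array([0.5, 0.2, 0.05])
    _, path1, _ = fit_grouplasso_path(Xp, Y, lambdas=lams)
    _, path2, _ = fit_grouplasso_path(Xp, np.hstack([Y, Y]),
                                      lambdas=lams * np.sqrt(2))
    for B1, B2 in zip(path1, path2):
        act1 = np.linalg.norm(B1, axis=1) > 1e-10
        act2 = np.linalg.norm(B2, axis=1) > 1e-10
        np.testing.assert_array_equal(act1, act2)
        np.testing.assert_allclose(B2[:, :2], B1, atol=1e-5)


def test_kkt_conditions_at_solution(small_instance):
    Xp, Y = small_instance
    n = Xp.shape[0]
    Yc = Y - Y.mean(axis=0)
    lam = 0.2 * float(np.max(np.linalg.norm(Xp.T @ Yc / n, axis=1)))
    _, path, _ = fit_grouplasso_path(Xp, Y, lambdas=np.array([lam]))
    B = path[0]
    R = Yc - Xp @ B
    grad_norms = np.linalg.norm(Xp.T @ R / n, axis=1)
    inactive = np.linalg.norm(B, axis=1) == 0
    assert np.all(grad_norms[inactive] <= lam + 1e-6)


def test_constant_column_rejected():
    rng = np.random.default_rng(1)
    Xp = rng.normal(size=(20, 3))
    Xp[:, 1] = 2.0
    with pytest.raises(ValueError):
        fit_grouplasso_path(Xp, rng.normal(size=(20, 2)))
    with pytest.raises(ValueError):
        standardize(Xp)


def test_cv_determinism_and_1se_ordering(small_instance):
    Xp, Y = small_instance
    m1 = cv_grouplasso(Xp, Y, folds=5, seed=3, n_lambda=30)
    m2 = cv_grouplasso(Xp, Y, folds=5, seed=3, n_lambda=30)
    assert m1.lambda_1se == m2.lambda_1se
    np.testing.assert_array_equal(m1.B, m2.B)
    assert m1.lambda_1se >= m1.lambda_min
    assert m1.cv_mean.min() == m1.cv_mean[list(m1.lambda_path).index(m1.lambda_min)]
    with pytest.raises(ValueError):
        cv_grouplasso(Xp, Y, folds=1)


def test_support_recovery_on_planted_pathways():
    """3 active pathways of 60 are recovered at λ_1se with a small active
    set in most replicates."""
    hits = 0
    for s in range(4):
        rng = np.random.default_rng(500 + s)
        Xp = standardize(rng.normal(size=(200, 60)))
        B = np.zeros((60, 3))
        B[:3] = rng.normal(0, 1, size=(3, 3)) + np.sign(rng.normal(size=(3, 3)))
        Y = Xp @ B + rng.normal(0, 0.5, size=(200, 3))
        m = cv_grouplasso(Xp, Y, folds=10, seed=s, n_lambda=40)
        act = set(np.where(np.linalg.norm(m.B, axis=1) > 0)[0])
        hits += ({0, 1, 2} <= act) and (len(act) <= 15)
    assert hits >= 3


def test_cluster_block_diagonal_coefficients():
    B = np.zeros((9, 3))
    for a in range(3):
        B[3 * a:3 * a + 3, a] = [2.0, 2.5, 1.8]
    labels = cluster_coefficients(B, n_clusters=3)
    parts = {}
    for name, c in labels.pathway_clusters.items():
        parts.setdefault(c, set()).add(name)
    expected = [{f"pathway_{j + 1}" for j in range(3 * a, 3 * a + 3)} for a in range(3)]
    assert sorted(map(frozenset, parts.values())) == sorted(map(frozenset, expected))
    archetypes = {labels.cluster_to_archetype[c] for c in parts}
    assert archetypes == {0, 1, 2}


def test_cluster_singletons_and_order_invariance():
    rng = np.random.default_rng(2)
    B = rng.normal(size=(3, 3)) + np.eye(3) * 5
    labels = cluster_coefficients(B, n_clusters=3)
    assert len(set(labels.pathway_clusters.values())) == 3
    B8 = np.abs(rng.normal(size=(8, 3))) + 0.1
    l1 = cluster_coefficients(B8, n_clusters=3)
    perm = rng.permutation(8)
    l2 = cluster_coefficients(B8[perm], n_clusters=3,
                              pathway_names=[f"pathway_{j + 1}" for j in perm])
    def partition(labels):
        parts = {}
        for name, c in labels.pathway_clusters.items():
            parts.setdefault(c, set()).add(name)
        return {frozenset(s) for s in parts.values()}

    assert partition(l1) == partition(l2)


def test_cluster_requires_enough_active_rows():
    with pytest.raises(ValueError):
        cluster_coefficients(np.zeros((5, 3)), n_clusters=3)


def test_univariate_slope_oracle_and_leader():
    rng = np.random.default_rng(11)
    scores = rng.random((10, 2))
    enrich = pd.DataFrame(
        [scores[:, 0], rng.random(10)], index=["mirror", "noise"])
    table = univariate_associations(enrich, scores)
    lead = table.iloc[0]
    assert lead["pathway"] == "mirror" and lead["archetype"] == 0
    assert lead["slope"] == pytest.approx(1.0, abs=1e-12)
    x = enrich.loc["noise"].to_numpy()
    y = scores[:, 1]
    slope_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    row = table[(table.pathway == "noise") & (table.archetype == 1)].iloc[0]
    assert row["slope"] == pytest.approx(slope_oracle, abs=1e-12)


def test_univariate_bh_fixed_point_and_skips():
    # orthogonal designs give r = 0 hence p = 1 for every pair
    enrich = pd.DataFrame([[-1.0, 0.0, 1.0], [5.0, 5.0, 5.0]], index=["orth", "flat"])
    scores = np.array([[1.0], [0.0], [1.0]])
    table = univariate_associations(enrich, scores)
    np.testing.assert_allclose(table["fdr"], 1.0)
    assert table.attrs["skipped"] == ["flat"]
    with pytest.raises(ValueError):
        univariate_associations(enrich.iloc[:, :2], scores[:2])
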