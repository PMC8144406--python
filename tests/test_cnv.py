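"""Expression-inferred CNV profiles, subclone clustering, and
archetype–subclone association statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind
from sklearn.metrics import adjusted_rand_score

from scpareto.cnv import (
    GenomicTrack, _truncated_moving_average, archetype_subclone_association,
    cluster_subclones, infer_cnv_profile,
)
from scpareto.io_qc import normalize_log
from scpareto.scores import ArchetypeScoreTable
from scpareto.synthetic import make_gene_track, make_truth, plant_cnv_subclones, simulate_counts


@pytest.fixture(scope="module")
def planted_cnv():
    """600 tumor cells in two subclones (one carrying a 2-fold gain over a
    150-gene block) plus 100 CNV-neutral reference cells."""
    truth = make_truth(3, 800, 5, 0.3, seed=2)
    ds = simulate_counts(truth, 700, depth=5000, dispersion=2.0, dropout=0.1, seed=3)
    cells = ds.counts.cell_ids
    clone = pd.Series(["c1"] * 300 + ["c2"] * 300 + ["ref"] * 100, index=cells)
    ds2 = plant_cnv_subclones(ds, [("chr1", 10, 159, "c2")], clone, [2.0], seed=9)
    norm = normalize_log(ds2.counts)
    track = GenomicTrack(make_gene_track(ds2.counts.gene_ids))
    return ds2, norm, track, clone


def test_track_validation_and_ordering():
    t = pd.DataFrame({"gene": ["b", "a"], "chrom": ["chr1", "chr1"],
                      "start": [5, 1], "end": [6, 2]})
    track = GenomicTrack(t)
    assert list(track.table["gene"]) == ["a", "b"]
    bad = t.copy()
    bad.loc[0, "end"] = 1
    with pytest.raises(ValueError):
        GenomicTrack(bad)


def test_profile_zero_when_cells_match_reference():
    genes = [f"g{i}" for i in range(20)]
    cells = [f"c{i}" for i in range(6)]
    E = np.tile(np.linspace(0, 2, 20)[:, None], (1, 6))
    track = GenomicTrack(make_gene_track(genes, n_chromosomes=2))
    prof = infer_cnv_profile(E, genes, cells, track, cells[:2], window=5)
    assert np.abs(prof.to_numpy()).max() < 1e-10


def test_window_one_is_identity_after_centering():
    rng = np.random.default_rng(4)
    genes = [f"g{i}" for i in range(15)]
    cells = [f"c{i}" for i in range(8)]
    E = rng.normal(0, 0.5, size=(15, 8))
    track = GenomicTrack(make_gene_track(genes, n_chromosomes=1))
    prof = infer_cnv_profile(E, genes, cells, track, cells[:3], window=1, cap=3)
    centered = np.clip(E - E[:, :3].mean(axis=1, keepdims=True), -3, 3).T
    expected = centered - np.median(centered, axis=1, keepdims=True)
    np.testing.assert_allclose(prof.to_numpy(), expected, atol=1e-12)


def test_moving_average_is_linear():
    rng = np.random.default_rng(5)
    A, B = rng.normal(size=(2, 4, 30))
    alpha = 0.3
    left = _truncated_moving_average(alpha * A + (1 - alpha) * B, 7)
    right = (alpha * _truncated_moving_average(A, 7)
             + (1 - alpha) * _truncated_moving_average(B, 7))
    np.testing.assert_allclose(left, right, atol=1e-12)


def test_planted_gain_visible_in_carrier_profiles(planted_cnv):
    ds2, norm, track, clone = planted_cnv
    cells = ds2.counts.cell_ids
    prof = infer_cnv_profile(norm, ds2.counts.gene_ids, cells, track,
                             cells[600:], window=101)
    carrier = (clone == "c2").to_numpy()
    noncar = (clone == "c1").to_numpy()
    genes = ds2.counts.gene_ids
    in_block = [g for g in prof.columns if 10 <= genes.index(g) <= 159]
    out_block = [g for g in prof.columns if genes.index(g) >= 300]
    diff_in = prof.loc[carrier, in_block].mean().mean() - prof.loc[noncar, in_block].mean().mean()
    diff_out = abs(prof.loc[carrier, out_block].mean().mean()
                   - prof.loc[noncar, out_block].mean().mean())
    assert diff_in > 3 * diff_out


def test_subclone_recovery_ari(planted_cnv):
    ds2, norm, track, clone = planted_cnv
    cells = ds2.counts.cell_ids
    prof = infer_cnv_profile(norm, ds2.counts.gene_ids, cells, track,
                             cells[600:], window=101)
    assign = cluster_subclones(prof.iloc[:600], m=2)
    assert adjusted_rand_score(clone.iloc[:600], assign.labels) > 0.9


def test_cluster_edge_cases():
    rng = np.random.default_rng(6)
    prof = pd.DataFrame(rng.normal(size=(10, 5)),
                        index=[f"c{i}" for i in range(10)])
    assert cluster_subclones(prof, m=10).labels.nunique() == 10
    dup = pd.concat([prof, prof.set_axis([f"d{i}" for i in range(10)])])
    assign = cluster_subclones(dup, m=3)
    for i in range(10):
        assert assign.labels[f"c{i}"] == assign.labels[f"d{i}"]
    with pytest.raises(ValueError):
        cluster_subclones(prof, m=0)


def test_cluster_order_invariance():
    rng = np.random.default_rng(7)
    prof = pd.DataFrame(np.vstack([rng.normal(0, 1, (20, 6)),
                                   rng.normal(5, 1, (20, 6))]),
                        index=[f"c{i}" for i in range(40)])
    a1 = cluster_subclones(prof, m=2).labels
    perm = rng.permutation(40)
    a2 = cluster_subclones(prof.iloc[perm], m=2).labels
    assert (a2.reindex(a1.index) == a1).all()


def _score_table(scores, cells):
    return ArchetypeScoreTable(cell_ids=cells, distances=1 - scores, scores=scores)


def test_association_extreme_separation():
    rng = np.random.default_rng(8)
    cells = [f"c{i}" for i in range(60)]
    scores = np.empty((60, 2))
    scores[:30, 0] = rng.normal(0.0, 0.01, 30)
    scores[30:, 0] = rng.normal(0.5, 0.01, 30)  # 50 SDs apart
    scores[:, 1] = rng.normal(0.5, 0.01, 60)
    from scpareto.cnv import SubcloneAssignment
    assign = SubcloneAssignment(
        labels=pd.Series([1] * 30 + [2] * 30, index=cells), m=2)
    anova, pairs = archetype_subclone_association(_score_table(scores, cells), assign)
    assert pairs.loc[pairs.archetype == 0, "p_adj"].iloc[0] < 1e-6
    assert anova.loc[anova.archetype == 0, "p"].iloc[0] < 1e-10


def test_association_null_calibration():
    """ANOVA p on permuted scores rejects at <= 10% of 40 runs (alpha 0.05)."""
    rng = np.random.default_rng(9)
    cells = [f"c{i}" for i in range(90)]
    from scpareto.cnv import SubcloneAssignment
    assign = SubcloneAssignment(
        labels=pd.Series([1] * 30 + [2] * 30 + [3] * 30, index=cells), m=3)
    base = rng.normal(0.5, 0.1, size=(90, 1))
    rejections = 0
    for _ in range(40):
        perm = rng.permutation(90)
        anova, _ = archetype_subclone_association(
            _score_table(base[perm], cells), assign)
        rejections += anova["p"].iloc[0] < 0.05
    assert rejections <= 4


def test_tukey_two_groups_matches_t_test():
    rng = np.random.default_rng(10)
    cells = [f"c{i}" for i in range(50)]
    scores = rng.normal(0.5, 0.1, size=(50, 1))
    from scpareto.cnv import SubcloneAssignment
    assign = SubcloneAssignment(
        labels=pd.Series([1] * 25 + [2] * 25, index=cells), m=2)
    anova, pairs = archetype_subclone_association(_score_table(scores, cells), assign)
    t, p = ttest_ind(scores[:25, 0], scores[25:, 0], equal_var=True)
    assert pairs["p_adj"].iloc[0] == pytest.approx(p, abs=1e-8)
    assert anova["p"].iloc[0] == pytest.approx(p, abs=1e-8)


def test_association_requires_two_clusters():
    cells = ["a", "b", "c"]
    from scpareto.cnv import SubcloneAssignment
    assign = SubcloneAssignment(labels=pd.Series([1, 1, 1], index=cells), m=1)
    with pytest.raises(ValueError):
        archetype_subclone_association(
            _score_table(np.random.default_rng(0).random((3, 1)), cells), assign)
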