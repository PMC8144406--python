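"""Specialist-proportion bookkeeping, cohort statistics, and WGS table
filters."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import studentized_range

from scpareto.dynamics import (
    cnv_z_classify, cohort_shift_test, fishplot_long, mutation_group_test,
    proportion_correlation, specialist_proportions, survival_correlation,
    variant_consensus_filter,
)
from scpareto.scores import NON_SPECIALIST, ArchetypeScoreTable
from scpareto.synthetic import make_truth, simulate_longitudinal


def _labeled_table(labels, k=3):
    cells = [f"c{i}" for i in range(len(labels))]
    scores = np.random.default_rng(0).random((len(labels), k))
    return ArchetypeScoreTable(
        cell_ids=cells, distances=1 - scores, scores=scores,
        specialist_label=pd.Series(labels, index=cells), percentile_used=80)


def _meta(cells, sample="S0", time=0, cohort="early"):
    return pd.DataFrame({"sample": sample, "patient": "P1", "time": time,
                         "cohort": cohort}, index=cells)


def test_proportions_simple_counts():
    labels = [0] * 4 + [1] * 3 + [2] * 2 + [NON_SPECIALIST]
    t = _labeled_table(labels)
    props = specialist_proportions(t, _meta(t.cell_ids))
    row = props.iloc[0]
    assert (row["archetype_1"], row["archetype_2"], row["archetype_3"],
            row["non_specialist"]) == (0.4, 0.3, 0.2, 0.1)
    assert row["n_cells"] == 10


def test_proportions_sum_to_one_and_fishplot_long():
    rng = np.random.default_rng(1)
    choices = [0, 1, 2, NON_SPECIALIST]
    labels = [choices[i] for i in rng.integers(0, 4, size=60)]
    t = _labeled_table(labels)
    meta = _meta(t.cell_ids)
    meta.iloc[30:, meta.columns.get_loc("sample")] = "S1"
    meta.iloc[30:, meta.columns.get_loc("time")] = 1
    props = specialist_proportions(t, meta)
    frac_cols = ["archetype_1", "archetype_2", "archetype_3", "non_specialist"]
    np.testing.assert_allclose(props[frac_cols].sum(axis=1), 1.0, atol=1e-9)
    long = fishplot_long(props)
    assert set(long.columns) >= {"sample", "time", "archetype", "fraction"}
    assert list(long["time"]) == sorted(long["time"])


def test_longitudinal_planted_proportions_recovered():
    """Specialist labels derived from the planted weights reproduce the
    drifting archetype frequencies within sampling error."""
    truth = make_truth(3, 60, 3, 0.3, seed=20, n_signature=5)
    planted = [(0.6, 0.2, 0.2), (0.2, 0.2, 0.6)]
    ds = simulate_longitudinal(truth, planted, cells_per_time=2000, seed=21,
                               interior_fraction=0.2, dropout=0.0)
    W = ds.weights
    labels = [int(np.argmax(w)) if w.max() > 0.8 else NON_SPECIALIST for w in W]
    cells = ds.counts.cell_ids
    scores = np.random.default_rng(2).random((len(cells), 3))
    t = ArchetypeScoreTable(cells, 1 - scores, scores,
                            pd.Series(labels, index=cells), 80)
    props = specialist_proportions(t, ds.sample_labels)
    for ti, p in enumerate(planted):
        row = props[props["time"] == ti].iloc[0]
        # planted specialists are 80% of cells; interior cells add a few more
        for a in range(3):
            assert row[f"archetype_{a + 1}"] == pytest.approx(0.8 * p[a], abs=0.06)


def test_cohort_shift_identical_groups():
    props = pd.DataFrame({
        "sample": list("abcd"), "cohort": ["e", "e", "l", "l"],
        "archetype_1": [0.3, 0.4, 0.3, 0.4], "non_specialist": [0.7, 0.6, 0.7, 0.6]})
    res = cohort_shift_test(props, "cohort")
    row = res[res.archetype == "archetype_1"].iloc[0]
    assert row["t"] == pytest.approx(0.0, abs=1e-12)
    assert row["p"] == pytest.approx(1.0, abs=1e-12)


def test_cohort_shift_matches_pooled_t_formula():
    x, y = np.array([0.1, 0.2, 0.3]), np.array([0.5, 0.6, 0.7])
    props = pd.DataFrame({
        "sample": list("abcdef"), "cohort": ["e"] * 3 + ["l"] * 3,
        "archetype_1": np.concatenate([x, y]),
        "non_specialist": 1 - np.concatenate([x, y])})
    res = cohort_shift_test(props, "cohort")
    row = res[res.archetype == "archetype_1"].iloc[0]
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / 4
    t_oracle = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    assert row["t"] == pytest.approx(t_oracle, abs=1e-12)
    swapped = cohort_shift_test(props, "cohort", groups=("l", "e"))
    srow = swapped[swapped.archetype == "archetype_1"].iloc[0]
    assert srow["t"] == pytest.approx(-row["t"], abs=1e-12)
    assert srow["p"] == pytest.approx(row["p"], abs=1e-12)


def test_cohort_shift_requires_two_per_group():
    props = pd.DataFrame({"sample": list("abc"), "cohort": ["e", "l", "l"],
                          "archetype_1": [0.1, 0.2, 0.3],
                          "non_specialist": [0.9, 0.8, 0.7]})
    with pytest.raises(ValueError):
        cohort_shift_test(props, "cohort")


def test_proportion_correlation_identities():
    a = np.array([0.2, 0.4, 0.1, 0.6, 0.3])
    props = pd.DataFrame({"archetype_1": a, "archetype_2": 1 - a})
    r, r2 = proportion_correlation(props, "archetype_1", "archetype_2")
    assert r == pytest.approx(-1.0, abs=1e-12)
    b = np.array([0.3, 0.1, 0.5, 0.2, 0.4])
    props2 = pd.DataFrame({"archetype_1": a, "archetype_2": b})
    r, r2 = proportion_correlation(props2, "archetype_1", "archetype_2")
    num = np.sum((a - a.mean()) * (b - b.mean()))
    den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
    assert r == pytest.approx(num / den, abs=1e-12)
    assert r2 == pytest.approx(r * r, abs=1e-15)


def test_survival_correlation_oracles():
    props = pd.DataFrame({"patient": list("ABCDE"),
                          "archetype_1": [0.1, 0.25, 0.4, 0.55, 0.7]})
    surv = pd.Series([900, 800, 600, 500, 300], index=list("ABCDE"))
    r, r2, p = survival_correlation(props, surv, "archetype_1")
    assert r < -0.98
    n = 5
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    from scipy.stats import t as t_dist
    p_oracle = 2 * t_dist.sf(abs(t), n - 2)
    assert p == pytest.approx(p_oracle, rel=1e-9)
    with pytest.raises(ValueError):
        survival_correlation(props, pd.Series(100, index=list("ABCDE")), "archetype_1")
    dup = pd.concat([props, props.iloc[[0]]])
    with pytest.raises(ValueError):
        survival_correlation(dup, surv, "archetype_1")


def _mutation_props(rng, n=12):
    samples = [f"s{i}" for i in range(n)]
    a = rng.uniform(0.1, 0.4, n)
    b = rng.uniform(0.1, 0.4, n)
    rest = 1 - a - b
    return pd.DataFrame({"sample": samples, "archetype_1": a, "archetype_2": b,
                         "non_specialist": rest})


def test_mutation_group_null_calibration():
    rng = np.random.default_rng(30)
    props = _mutation_props(rng)
    rejections = 0
    for _ in range(40):
        status = pd.Series(rng.permutation(["wt"] * 6 + ["m"] * 6),
                           index=props["sample"])
        res = mutation_group_test(props, status, one_sided=True)
        rejections += (res["p_adj"] < 0.05).any()
    assert rejections <= 4


def test_mutation_group_extreme_separation_and_shape():
    samples = [f"s{i}" for i in range(12)]
    a = np.array([0.1] * 6 + [0.9] * 6) + np.linspace(0, 1e-3, 12)
    props = pd.DataFrame({"sample": samples, "archetype_1": a,
                          "non_specialist": 1 - a})
    status = pd.Series(["wt"] * 6 + ["m"] * 6, index=samples)
    res = mutation_group_test(props, status, one_sided=True)
    assert res.loc[res.archetype == "archetype_1", "p_adj"].iloc[0] < 1e-6
    # one row per archetype column per wt-vs-m contrast
    assert len(res) == 2
    with pytest.raises(ValueError):
        mutation_group_test(props, pd.Series("wt", index=samples))


@pytest.mark.parametrize("z, expected", [
    (1.5, "gain"), (-1.4, "neutral"), (-2.0, "loss"),
    (1.49, "neutral"), (-1.5, "loss"), (0.0, "neutral"), (2.6, "gain"),
])
def test_cnv_z_classification(z, expected):
    assert cnv_z_classify([z]).iloc[0] == expected


def _caller(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt", "vaf"])


def test_variant_consensus_rules():
    v1 = ("s1", "chr1", 100, "A", "T")
    v2 = ("s1", "chr2", 200, "G", "C")
    v3 = ("s1", "chr3", 300, "T", "A")
    c1 = _caller([v1 + (0.06,), v2 + (0.04,), v3 + (0.9,)])
    c2 = _caller([v1 + (0.05,), v2 + (0.04,)])
    c3 = _caller([v2 + (0.04,)])
    kept = variant_consensus_filter([c1, c2, c3])
    keys = set(map(tuple, kept[["sample", "chrom", "pos", "ref", "alt"]].to_numpy()))
    assert ("s1", "chr1", 100, "A", "T") in keys     # 2 callers, VAF 0.06
    assert ("s1", "chr2", 200, "G", "C") not in keys  # VAF 0.04 everywhere
    assert ("s1", "chr3", 300, "T", "A") not in keys  # single caller
    with pytest.raises(ValueError, match="missing"):
        variant_consensus_filter([c1.drop(columns=["pos"])])


def test_tukey_one_sided_halves_the_tail():
    """Sanity-check the single-sided convention against the studentized
    range tail itself."""
    from scpareto.posthoc import tukey_pairwise
    rng = np.random.default_rng(31)
    g = {"wt": rng.normal(0, 1, 10), "m": rng.normal(2, 1, 10)}
    two = tukey_pairwise(g, one_sided=False)["p_adj"].iloc[0]
    one = tukey_pairwise(g, one_sided=True)["p_adj"].iloc[0]
    assert one == pytest.approx(two / 2, abs=1e-12)
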