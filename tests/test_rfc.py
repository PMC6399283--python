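"""Clustering core: linkage vs a brute-force agglomeration oracle,
tree cutting, the chi-square heterogeneity test and k selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

import rfclust as rc
from rfclust.gower import DistanceMatrix
from rfclust.rfc import _chi2_logsf
from rfclust.tables import contingency_counts


def dist_from_square(m):
    m = np.asarray(m, dtype=float)
    return DistanceMatrix(n=len(m), condensed=squareform(m, checks=False))


def brute_force_complete(square):
    """Naive agglomeration: repeatedly merge the closest pair of clusters
    under maximum linkage; returns merge heights and final 2-partition."""
    clusters = [{i} for i in range(len(square))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(square[a][b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
        if len(clusters) == 2:
            two_partition = [frozenset(c) for c in clusters]
    return heights, two_partition


FIVE_POINT = [
    [0.0, 0.10, 0.60, 0.70, 0.90],
    [0.10, 0.0, 0.65, 0.75, 0.95],
    [0.60, 0.65, 0.0, 0.15, 0.80],
    [0.70, 0.75, 0.15, 0.0, 0.85],
    [0.90, 0.95, 0.80, 0.85, 0.0],
]


def test_two_points_single_merge():
    tree = rc.complete_linkage(dist_from_square([[0, 0.3], [0.3, 0]]))
    assert tree.merges.shape == (1, 4)
    assert tree.merges[0, 2] == pytest.approx(0.3)


def test_linkage_matches_bruteforce_oracle():
    tree = rc.complete_linkage(dist_from_square(FIVE_POINT))
    heights, two_partition = brute_force_complete(FIVE_POINT)
    assert np.allclose(sorted(tree.merges[:, 2]), sorted(heights))
    cut = rc.cut_tree(tree, 2)
    got = {frozenset(np.flatnonzero(cut.labels == c)) for c in (1, 2)}
    assert got == set(two_partition)


def test_duplicate_point_merges_first_at_zero():
    m = np.array(FIVE_POINT)
    m6 = np.zeros((6, 6))
    m6[:5, :5] = m
    m6[5, :5] = m6[:5, 5] = m[0, :5]  # duplicate of point 0
    tree = rc.complete_linkage(dist_from_square(m6))
    assert tree.merges[0, 2] == 0.0
    assert {int(tree.merges[0, 0]), int(tree.merges[0, 1])} == {0, 5}


def test_cut_tree_extremes_and_refinement(rng):
    df = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, 30),
            "age": rng.uniform(40, 70, 30),
            "bmi": rng.uniform(20, 30, 30),
            "htn": rng.integers(0, 2, 30),
            "fhdm": rng.integers(0, 2, 30),
        }
    )
    tree = rc.complete_linkage(rc.gower_matrix(df))
    assert rc.cut_tree(tree, 1).labels.max() == 1
    assert rc.cut_tree(tree, 30).k == 30
    for k in range(1, 12):
        coarse = rc.cut_tree(tree, k).labels
        fine = rc.cut_tree(tree, k + 1).labels
        # each finer cluster lies inside exactly one coarser cluster
        for c in np.unique(fine):
            assert len(np.unique(coarse[fine == c])) == 1
    with pytest.raises(ValueError):
        rc.cut_tree(tree, 0)
    with pytest.raises(ValueError):
        rc.cut_tree(tree, 31)


def test_prevalence_table_counts_and_trivia():
    a = rc.ClusterAssignment(labels=np.array([1, 1, 2, 2, 2]), k=2)
    t = rc.prevalence_table(a, [0, 1, 0, 0, 1])
    assert list(t.ndm) == [1, 2] and list(t.dm) == [1, 1]
    assert t.prevalence() == pytest.approx([0.5, 1 / 3])
    t0 = rc.prevalence_table(a, [0, 0, 0, 0, 0])
    assert list(t0.dm) == [0, 0] and np.all(t0.prevalence() == 0)
    one = rc.ClusterAssignment(labels=np.ones(5, dtype=int), k=1)
    assert rc.prevalence_table(one, [0, 1, 0, 0, 1]).prevalence()[0] == 0.4


def test_published_table_prevalences():
    counts = contingency_counts("discovery")
    t = rc.ContingencyTable(ndm=counts[0], dm=counts[1])
    prev = t.prevalence()
    assert round(prev.max(), 2) == 0.44  # 121/277 in the highest cluster
    assert list(np.round(prev, 2)) == [0.09, 0.09, 0.20, 0.20, 0.22, 0.44]


def test_chi_square_homogeneous_is_zero():
    stat, df, log_p = rc.chi_square_heterogeneity(
        rc.ContingencyTable(ndm=[10, 10], dm=[10, 10])
    )
    assert stat == pytest.approx(0.0)
    assert df == 1
    assert math.exp(log_p) == pytest.approx(1.0)


def test_chi_square_closed_form_2x2():
    # N(ad-bc)^2 / (r1 r2 c1 c2) = 200*3000^2 / (100*100*150*50) = 24
    stat, df, _ = rc.chi_square_heterogeneity(
        rc.ContingencyTable(ndm=[90, 60], dm=[10, 40])
    )
    assert stat == pytest.approx(24.0)
    assert df == 1


def test_chi_square_permutation_and_split_invariance(rng):
    ndm = 2 * rng.integers(50, 200, 5)
    dm = 2 * rng.integers(5, 60, 5)
    t = rc.ContingencyTable(ndm=ndm, dm=dm)
    stat, df, _ = rc.chi_square_heterogeneity(t)
    perm = rng.permutation(5)
    stat_p, df_p, _ = rc.chi_square_heterogeneity(
        rc.ContingencyTable(ndm=ndm[perm], dm=dm[perm])
    )
    assert stat_p == pytest.approx(stat)
    assert df_p == df
    # splitting a column into two halves with identical prevalence keeps
    # the statistic and adds one degree of freedom
    split = rc.ContingencyTable(
        ndm=np.r_[ndm[:4], ndm[4] // 2, ndm[4] // 2],
        dm=np.r_[dm[:4], dm[4] // 2, dm[4] // 2],
    )
    stat_s, df_s, _ = rc.chi_square_heterogeneity(split)
    assert stat_s == pytest.approx(stat)
    assert df_s == df + 1


def test_chi_square_zero_expected_raises():
    with pytest.raises(ValueError, match="zero expected"):
        rc.chi_square_heterogeneity(rc.ContingencyTable(ndm=[10, 20], dm=[0, 0]))


def test_log_survival_stable_in_extreme_regime():
    # the validation-scale statistic (~1.4e4) underflows naive p-values
    counts = contingency_counts("validation")
    stat, df, log_p = rc.chi_square_heterogeneity(
        rc.ContingencyTable(ndm=counts[0], dm=counts[1])
    )
    assert np.isfinite(log_p) and log_p < math.log(2.2e-16)
    # expansion agrees with scipy where scipy is still finite
    from scipy.stats import chi2

    for s, d in [(450.0, 5), (1200.0, 5), (80.0, 1)]:
        assert _chi2_logsf(s, d) == pytest.approx(chi2.logsf(s, d), rel=1e-10)


def _cloud_cohort(offsets, prevalences, n_per, rng, sd=1.0):
    frames = []
    for i, (off, prev) in enumerate(zip(offsets, prevalences), start=1):
        frames.append(
            pd.DataFrame(
                {
                    "sex": i % 2,  # cluster-constant, like the study clusters
                    "age": np.clip(rng.normal(off, sd, n_per), 40, 70),
                    "bmi": 25.0 + rng.normal(0, 0.5, n_per),
                    "htn": 1 if i >= 2 else 0,
                    "fhdm": 1 if i >= 3 else 0,
                    "dm": (rng.random(n_per) < prev).astype(int),
                    "true": i,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def test_select_k_homogeneous_split_picks_two(rng):
    # two fully separated clouds with prevalences 0 and 1: any further
    # split preserves the statistic but raises df, so k=2 under both
    # policies
    df = _cloud_cohort([45.0, 65.0], [0.0, 1.0], 20, rng, sd=0.5)
    tree = rc.complete_linkage(rc.gower_matrix(df))
    for policy in ("global", "local"):
        res = rc.select_k(tree, df["dm"], k_min=2, k_max=8, policy=policy)
        assert res.selected_k == 2
        assert set(res.trace) >= {2, 3}


def test_select_k_recovers_three_planted_clusters():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        df = _cloud_cohort([45.0, 55.0, 65.0], [0.05, 0.25, 0.60], 200, rng, sd=2.0)
        tree = rc.complete_linkage(rc.gower_matrix(df))
        res = rc.select_k(tree, df["dm"], k_min=2, k_max=10)
        hits += res.selected_k == 3
    assert hits >= 9


def test_select_k_scan_exhausted_reason(rng):
    df = _cloud_cohort([45.0, 65.0], [0.0, 1.0], 10, rng, sd=0.5)
    tree = rc.complete_linkage(rc.gower_matrix(df))
    res = rc.select_k(tree, np.r_[np.zeros(10), np.ones(10)].astype(int),
                      k_min=2, k_max=4, policy="local")
    assert res.selected_k in (2, 3, 4)
    assert len(res.trace) == 3 or "more significant" in res.stopping_reason


def test_label_by_prevalence_sorting_and_ties():
    labels = np.r_[np.ones(10), 2 * np.ones(10), 3 * np.ones(10)].astype(int)
    dm = np.zeros(30, dtype=int)
    dm[:3] = 1  # cluster 1 prevalence 0.3
    dm[10] = 1  # cluster 2 prevalence 0.1
    dm[20:22] = 1  # cluster 3 prevalence 0.2
    a = rc.ClusterAssignment(labels=labels, k=3)
    relabeled = rc.label_by_prevalence(a, dm)
    # old clusters (1, 2, 3) -> new labels (3, 1, 2)
    assert list(relabeled.labels[[0, 10, 20]]) == [3, 1, 2]
    # tie on prevalence: the larger cluster gets the smaller label
    labels2 = np.r_[np.ones(50), 2 * np.ones(100)].astype(int)
    a2 = rc.ClusterAssignment(labels=labels2, k=2)
    tied = rc.label_by_prevalence(a2, np.zeros(150, dtype=int))
    assert tied.labels[0] == 2 and tied.labels[-1] == 1


def test_model_results_interface(fitted_small, small_cohort):
    res = fitted_small
    assert res.selected_k == res.assignment.k
    assert len(res.prevalences) == res.selected_k
    # labels ascend in prevalence by construction
    assert np.all(np.diff(res.prevalences) >= 0)
    summary = res.summary()
    assert len(summary) == res.selected_k
    assert summary["n"].sum() == len(small_cohort)
    assert "selected k" in str(res)
    # newick export parses back to the right leaf count
    newick = res.dendrogram.to_newick()
    assert newick.count("L") == len(small_cohort)
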