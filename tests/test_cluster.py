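import itertools

import numpy as np
import pytest

from gazestrat.cluster import (
    ANSWER_ENTRY_FEATURES,
    CLUSTER_AOIS,
    OFFDIAG_PAIRS,
    ScanpathKMeans,
    build_transition_features,
    compare_clusters_bf,
    features_to_matrix,
    fit_two_cluster_model,
    percent_cluster1,
    percent_cluster2,
    pool_answers,
)


def brute_force_features(seq):
    """Independent count-and-normalize oracle for transition features."""
    idx = {a: i for i, a in enumerate(CLUSTER_AOIS)}
    pooled = []
    for el in seq:
        lab = "ANS" if el.startswith("A") else el
        if not pooled or pooled[-1] != lab:
            pooled.append(lab)
    counts = np.zeros((10, 10))
    for a, b in zip(pooled, pooled[1:]):
        counts[idx[a], idx[b]] += 1
    mat = np.zeros((10, 10))
    for i in range(10):
        if counts[i].sum():
            mat[i] = counts[i] / counts[i].sum()
    return np.array([mat[i, j] for i, j in OFFDIAG_PAIRS])


def test_row_wise_walk_gives_unit_rows():
    vec = build_transition_features(["M00", "M01", "M02", "A0"])
    mat = features_to_matrix(vec)
    assert mat.loc["M00", "M01"] == 1.0
    assert mat.loc["M01", "M02"] == 1.0
    assert mat.loc["M02", "ANS"] == 1.0
    assert mat.to_numpy().sum() == 3.0


def test_back_and_forth_probabilities():
    vec = build_transition_features(["M00", "A0", "M00", "A3"])
    mat = features_to_matrix(vec)
    assert mat.loc["M00", "ANS"] == 1.0
    assert mat.loc["ANS", "M00"] == 1.0


def test_short_sequence_gives_zero_vector():
    assert build_transition_features(["M00"]).sum() == 0.0
    assert build_transition_features([]).sum() == 0.0


def test_answer_choices_pool_and_recollapse():
    assert pool_answers(["M00", "A0", "A5", "A0", "M01"]) == ["M00", "ANS", "M01"]


def test_features_match_brute_force_oracle():
    rng = np.random.default_rng(12)
    labels = [f"M{r}{c}" for r in range(3) for c in range(3)] + [f"A{k}" for k in range(8)]
    for _ in range(1000):
        seq = list(rng.choice(labels, size=rng.integers(0, 40)))
        mine = build_transition_features(seq)
        np.testing.assert_allclose(mine, brute_force_features(seq), atol=1e-15)
        mat = features_to_matrix(mine).to_numpy()
        sums = mat.sum(axis=1)
        assert np.all((np.abs(sums - 1.0) < 1e-12) | (sums == 0.0))


def exhaustive_best_sse(X):
    """Global optimum of 2-cluster SSE by enumerating all 2-partitions."""
    n = len(X)
    best = np.inf
    for mask_bits in range(1, 2 ** (n - 1)):
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        sse = 0.0
        for part in (X[mask], X[~mask]):
            if len(part):
                sse += ((part - part.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


def two_group_fixture(rng, n=8):
    a = rng.normal(0.0, 0.02, size=(n // 2, 90)) + 0.0
    b = rng.normal(0.0, 0.02, size=(n - n // 2, 90))
    b[:, list(ANSWER_ENTRY_FEATURES)] += 0.5
    X = np.vstack([a, b])
    truth = np.array([1] * (n // 2) + [2] * (n - n // 2))
    return X, truth


def test_two_cluster_fit_reaches_global_optimum():
    rng = np.random.default_rng(0)
    for _ in range(5):
        X, truth = two_group_fixture(rng)
        model = fit_two_cluster_model(X, seed=0)
        assert model.inertia_ == pytest.approx(exhaustive_best_sse(X), abs=1e-9)
        assert list(model.labels_) == list(truth)


def test_duplicated_data_keeps_centroids():
    rng = np.random.default_rng(1)
    X, _ = two_group_fixture(rng)
    m1 = fit_two_cluster_model(X, seed=3)
    m2 = fit_two_cluster_model(np.vstack([X, X]), seed=3)
    np.testing.assert_allclose(
        np.sort(m1.cluster_centers_, axis=0), np.sort(m2.cluster_centers_, axis=0), atol=1e-9
    )


def test_same_seed_same_result():
    rng = np.random.default_rng(2)
    X = rng.random((40, 90))
    a = fit_two_cluster_model(X, seed=11)
    b = fit_two_cluster_model(X, seed=11)
    assert list(a.labels_) == list(b.labels_)
    assert a.inertia_ == b.inertia_


def test_identical_vectors_degenerate_model():
    X = np.ones((5, 90)) * 0.3
    with pytest.warns(UserWarning, match="degenerate"):
        model = ScanpathKMeans(random_state=0).fit(X)
    assert model.degenerate_
    assert list(model.labels_) == [1] * 5
    assert model.inertia_ == 0.0


def test_cluster2_has_larger_answer_entry_mass():
    rng = np.random.default_rng(4)
    X, truth = two_group_fixture(rng, n=8)
    model = fit_two_cluster_model(X, seed=0)
    mass = model.cluster_centers_[:, list(ANSWER_ENTRY_FEATURES)].sum(axis=1)
    assert mass[1] > mass[0]
    # and predict() agrees with fit labels
    assert list(model.predict(X)) == list(model.labels_)


def test_percent_cluster2_examples_and_complement():
    assert percent_cluster2([2, 2, 1, 1]) == 50.0
    assert percent_cluster2([1, 1, 1]) == 0.0
    rng = np.random.default_rng(5)
    for _ in range(100):
        labels = rng.choice([1, 2], size=rng.integers(1, 30))
        assert percent_cluster1(labels) + percent_cluster2(labels) == 100.0


def test_bf_contrast_identical_groups_supports_null():
    rng = np.random.default_rng(6)
    values = rng.normal(0.0, 1.0, 1000)
    labels = np.array([1] * 500 + [2] * 500)
    res = compare_clusters_bf(values, labels, "n_ma_transitions")
    assert res.bf10 < 1 / 3
    assert "H0" in res.category


def test_bf_contrast_large_effect_is_extreme():
    rng = np.random.default_rng(7)
    values = np.concatenate([rng.normal(0, 1, 200), rng.normal(1.5, 1, 200)])
    labels = np.array([1] * 200 + [2] * 200)
    res = compare_clusters_bf(values, labels, "mean_fixdur_matrix_ms")
    assert res.bf10 > 100
    assert res.bf10 * res.bf01 == pytest.approx(1.0)


def test_bf_contrast_needs_both_groups():
    with pytest.raises(ValueError, match=">= 2"):
        compare_clusters_bf([1.0, 2.0, 3.0], [1, 1, 1], "x")
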