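"""Embedding, 2D-histogram log-ratio contrast and adaptive k-means niches."""

import numpy as np
import pytest

from spatialniche import sumap


def blobs(rng, centers, n_per, sigma):
    return np.vstack([c + rng.normal(0, sigma, (n_per, 2)) for c in centers])


# ---------------------------------------------------------------- embedding

def test_embedding_shape_and_determinism():
    rng = np.random.default_rng(0)
    X = rng.random((150, 40))
    a = sumap.embed_profiles(X, n_neighbors=10, seed=5)
    b = sumap.embed_profiles(X, n_neighbors=10, seed=5)
    assert a.coords.shape == (150, 2)
    assert np.array_equal(a.coords, b.coords)


def test_embedding_separates_disjoint_profile_populations():
    rng = np.random.default_rng(1)
    a = np.zeros((100, 40)); a[:, :5] = rng.uniform(900, 1100, (100, 5))
    b = np.zeros((100, 40)); b[:, 30:35] = rng.uniform(900, 1100, (100, 5))
    emb = sumap.embed_profiles(np.vstack([a, b]), n_neighbors=15, seed=2)
    c = emb.coords
    intra = np.linalg.norm(c[:100] - c[:100].mean(0), axis=1).mean()
    inter = np.linalg.norm(c[:100].mean(0) - c[100:].mean(0))
    assert inter > intra


def test_embedding_input_validation():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="n_neighbors"):
        sumap.embed_profiles(rng.random((20, 40)), n_neighbors=30)
    bad = rng.random((50, 40)); bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        sumap.embed_profiles(bad, n_neighbors=10)


# ---------------------------------------------------------------- histograms

def test_group_histograms_normalized_and_scale_invariant():
    rng = np.random.default_rng(3)
    coords = rng.random((300, 2))
    groups = np.array(["deceased"] * 100 + ["alive"] * 200)
    h = sumap.group_histograms(coords, groups, n_bins=10)
    assert h.freq_deceased.sum() == pytest.approx(1.0)
    assert h.freq_alive.sum() == pytest.approx(1.0)
    # duplicating every deceased cell leaves its frequencies unchanged
    coords2 = np.vstack([coords, coords[:100]])
    groups2 = np.concatenate([groups, ["deceased"] * 100])
    h2 = sumap.group_histograms(coords2, groups2, n_bins=10)
    assert np.allclose(h2.freq_deceased, h.freq_deceased)


def test_single_occupied_bin_has_frequency_one():
    coords = np.vstack([np.full((50, 2), 0.5), [[10, 10]]])
    groups = np.array(["deceased"] * 50 + ["alive"])
    h = sumap.group_histograms(coords, groups, n_bins=5)
    assert h.freq_deceased.max() == 1.0


def test_histogram_requires_both_groups():
    with pytest.raises(ValueError, match="alive"):
        sumap.group_histograms(
            np.zeros((5, 2)), np.array(["deceased"] * 5)
        )


# ---------------------------------------------------------------- log-ratio

def _hist(fd, fa):
    e = np.arange(fd.shape[0] + 1, dtype=float)
    return sumap.GroupHistogram(e, e, fd, fa)


def test_log_ratio_identity_and_antisymmetry():
    rng = np.random.default_rng(4)
    f = rng.random((6, 6)); f /= f.sum()
    assert not sumap.log_ratio_field(_hist(f, f)).field.any()
    g = rng.random((6, 6)); g /= g.sum()
    fwd = sumap.log_ratio_field(_hist(f, g), epsilon=1e-4).field
    rev = sumap.log_ratio_field(_hist(g, f), epsilon=1e-4).field
    assert np.allclose(fwd, -rev)


def test_log_ratio_value_log10_two():
    fd = np.array([[0.02]]); fa = np.array([[0.01]])
    out = sumap.log_ratio_field(_hist(fd, fa), epsilon=1e-12).field[0, 0]
    assert out == pytest.approx(np.log10(2), abs=1e-6)
    assert out == pytest.approx(0.30103, abs=1e-5)


def test_prevalence_cells_thresholds_and_disjointness():
    fd = np.array([[0.02, 0.0], [0.005, 0.0]])
    fa = np.array([[0.01, 0.0], [0.02, 0.0]])
    fld = sumap.log_ratio_field(_hist(fd, fa), epsilon=1e-12)
    # 5 deceased cells in the enriched bin (0,0); 3 alive in depleted (1,0)
    coords = np.vstack([np.full((5, 2), [0.5, 0.5]),
                        np.full((3, 2), [1.5, 0.5])])
    groups = np.array(["deceased"] * 5 + ["alive"] * 3)
    dec, alv = sumap.prevalence_cells(fld, coords, groups)
    assert len(dec) == 5 and len(alv) == 3
    # bin sets with field > +tau and < -tau can never overlap
    assert not (set(dec) & set(alv))
    # a zero field selects nothing
    zero = sumap.log_ratio_field(_hist(fa, fa))
    dec, alv = sumap.prevalence_cells(zero, coords, groups)
    assert len(dec) == 0 and len(alv) == 0


# ---------------------------------------------------------------- clustering

def test_davies_bouldin_hand_computed():
    pts = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], float)
    assert sumap.davies_bouldin(pts, np.array([0, 0, 1, 1])) == pytest.approx(
        0.1, abs=1e-12
    )


@pytest.mark.parametrize("k_true", [2, 3, 4])
def test_adaptive_kmeans_recovers_planted_k(k_true):
    """Separation/sigma = 20 blobs: the DB-selected k matches the planted k
    in >= 90% of seeds."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        centers = 10.0 * np.array(
            [[np.cos(2 * np.pi * i / k_true), np.sin(2 * np.pi * i / k_true)]
             for i in range(k_true)]
        )
        pts = blobs(rng, centers, 150, 0.5)
        cs = sumap.adaptive_kmeans(pts, range(2, 11), seed=seed)
        hits += cs.k == k_true
    assert hits >= 9


def test_adaptive_kmeans_labels_partition_and_name_by_size():
    rng = np.random.default_rng(8)
    pts = np.vstack([blobs(rng, [[0, 0]], 300, 0.5),
                     blobs(rng, [[15, 0]], 100, 0.5)])
    cs = sumap.adaptive_kmeans(pts, range(2, 5), seed=0, group="alive")
    assert cs.k == 2 and cs.names == ["A1", "A2"]
    sizes = np.bincount(cs.labels)
    assert sizes[0] >= sizes[1] and sizes.sum() == 400


def test_adaptive_kmeans_order_invariance_up_to_relabeling():
    rng = np.random.default_rng(2)
    pts = blobs(rng, [[0, 0], [20, 0]], 100, 0.5)
    cs1 = sumap.adaptive_kmeans(pts, range(2, 4), seed=1)
    perm = rng.permutation(len(pts))
    cs2 = sumap.adaptive_kmeans(pts[perm], range(2, 4), seed=1)
    from sklearn.metrics import adjusted_rand_score

    # identical partition up to label permutation
    assert adjusted_rand_score(cs1.labels[perm], cs2.labels) == 1.0


def test_adaptive_kmeans_degenerate_inputs_raise():
    with pytest.raises(ValueError):
        sumap.adaptive_kmeans(np.zeros((5, 2)), range(2, 11))
    with pytest.raises(ValueError, match="distinct"):
        sumap.adaptive_kmeans(np.tile([[1.0, 1.0]], (50, 1)), range(2, 4))


# ------------------------------------------------------- cluster summaries

def test_cluster_mean_profile_closed_forms():
    prof = np.vstack([np.zeros(40), np.full(40, 2.0)])
    means, sems = sumap.cluster_mean_profile(np.array([0, 0]), prof)
    assert np.allclose(means[0], 1.0) and np.allclose(sems[0], 1.0)
    same = np.tile([[3.0] * 40], (5, 1))
    means, sems = sumap.cluster_mean_profile(np.zeros(5, int), same)
    assert np.allclose(means[0], 3.0) and not sems.any()
    with pytest.warns(UserWarning, match="single cell"):
        _, sems = sumap.cluster_mean_profile(np.array([0]), np.ones((1, 40)))
    assert not sems.any()


def test_cluster_ratio_profile_values_and_floor():
    ten = np.full(40, 10.0)
    one = np.ones(40)
    assert np.allclose(sumap.cluster_ratio_profile(ten, ten, floor=0), 1.0)
    assert np.allclose(sumap.cluster_ratio_profile(ten, one, floor=0), 10.0)
    with pytest.raises(ValueError, match="zero denominator"):
        sumap.cluster_ratio_profile(ten, np.zeros(40), floor=0)
    assert np.allclose(
        sumap.cluster_ratio_profile(ten, np.zeros(40), floor=2.0), 5.0
    )


def test_cluster_prevalence_bounds():
    labels = np.array([0] * 30 + [1] * 10)
    cs = sumap.ClusterSet(
        group="deceased", k=2, davies_bouldin=0.0, db_per_k={},
        labels=labels, names=["D1", "D2"], cell_index=np.arange(40),
    )
    prev = sumap.cluster_prevalence(cs, group_total=100)
    assert np.allclose(prev, [0.3, 0.1])
    assert prev.sum() <= 1.0
    with pytest.raises(ValueError):
        sumap.cluster_prevalence(cs, group_total=30)
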