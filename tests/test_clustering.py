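"""K-means, k selection, composition and condition-shift summaries."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from symbiolipo import (
    assign_to_model,
    cluster_shift,
    composition,
    generate_cell_table,
    kmeans_fit,
    normalise_to_endosymbiont_mean,
    select_k,
    TableGroundTruth,
)
from conftest import three_blob_points


def brute_force_wss(points: np.ndarray, k: int) -> float:
    """Exhaustive optimum over all k-partitions (n small)."""
    n = len(points)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) < k:
            continue
        labels = np.asarray(labels)
        wss = 0.0
        for c in range(k):
            pts = points[labels == c]
            wss += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, wss)
    return best


class TestKMeans:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 2))
        model = kmeans_fit(pts, k=1, n_init=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], pts.mean(axis=0))
        assert model.wss == pytest.approx(((pts - pts.mean(axis=0)) ** 2).sum())

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_optimum(self, k):
        for seed in range(10):
            pts = np.random.default_rng(seed).uniform(0, 1, size=(8, 2))
            model = kmeans_fit(pts, k=k, n_init=50, seed=0)
            assert model.wss == pytest.approx(brute_force_wss(pts, k), rel=1e-7)

    def test_recovers_separated_components_exactly(self):
        pts = three_blob_points(seed=1)
        truth = np.repeat([0, 1, 2], 40)
        model = kmeans_fit(pts, k=3, seed=0)
        assert adjusted_rand_score(truth, model.assignments) == 1.0

    def test_clusters_ordered_by_descending_lpo(self):
        model = kmeans_fit(three_blob_points(seed=2), k=3, seed=0)
        lpo = model.centroids[:, 1]
        assert np.all(np.diff(lpo) < 0)
        # cluster 1 = high-LPO/low-volume (endosymbiotic-like) profile
        assert model.centroids[0, 0] == min(model.centroids[:, 0])

    def test_deterministic_under_seed(self):
        pts = np.random.default_rng(3).uniform(size=(50, 2))
        a = kmeans_fit(pts, k=3, seed=9)
        b = kmeans_fit(pts, k=3, seed=9)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        assert a.wss == b.wss

    def test_duplicate_points_warn(self):
        pts = np.tile([[1.0, 1.0], [2.0, 2.0]], (3, 1))
        with pytest.warns(UserWarning, match="distinct"):
            kmeans_fit(pts, k=3, n_init=2, seed=0)


class TestAssign:
    def test_point_at_centroid_gets_its_label(self):
        model = kmeans_fit(three_blob_points(seed=4), k=3, seed=0)
        labels = assign_to_model(model, model.centroids)
        np.testing.assert_array_equal(labels, [1, 2, 3])

    def test_training_points_reproduce_training_assignments(self):
        pts = three_blob_points(seed=5)
        model = kmeans_fit(pts, k=3, seed=0)
        np.testing.assert_array_equal(assign_to_model(model, pts), model.assignments)

    def test_tie_broken_toward_lowest_index(self):
        model = kmeans_fit(np.array([[0.0, 0.0], [2.0, 0.0]] * 3), k=2, seed=0)
        midpoint = model.centroids.mean(axis=0, keepdims=True)
        assert assign_to_model(model, midpoint)[0] == 1

    def test_dimension_mismatch(self):
        model = kmeans_fit(three_blob_points(seed=6), k=2, seed=0)
        with pytest.raises(ValueError, match="features"):
            assign_to_model(model, np.ones((3, 5)))


class TestSelectK:
    def test_wss_curve_non_increasing(self):
        pts = np.random.default_rng(7).uniform(size=(60, 2))
        report = select_k(pts, range(1, 6), B=2, seed=0)
        assert all(a >= b - 1e-9 for a, b in zip(report.wss_curve, report.wss_curve[1:]))

    def test_silhouette_in_range_and_picks_three_blobs(self):
        report = select_k(three_blob_points(seed=8), range(1, 6), B=2, seed=0)
        assert all(-1 <= v <= 1 for v in report.silhouette.values())
        assert report.recommended["silhouette"] == 3

    def test_gap_prefers_one_cluster_for_single_blob(self):
        pts = np.random.default_rng(9).normal(0, 1, size=(120, 2))
        report = select_k(pts, range(1, 5), B=50, seed=0)
        assert report.recommended["gap"] == 1

    def test_bootstrap_count_guard(self):
        with pytest.raises(ValueError, match="B >= 2"):
            select_k(three_blob_points(seed=10), range(1, 4), B=1, seed=0)


class TestComposition:
    def test_counting(self):
        labels = np.array([1] * 10 + [2] * 4)
        types = np.array(
            ["endosymbiotic"] * 9 + ["ex-symbiotic"] + ["ex-symbiotic"] * 4
        )
        comp = composition(labels, types)
        assert comp.endo_ex(1) == (90.0, 10.0)
        assert comp.percentages.loc[1].sum() == pytest.approx(100.0)

    def test_empty_cluster_zero_counts_nan_percent(self):
        labels = np.array([1, 1, 3])
        types = np.array(["endosymbiotic", "endosymbiotic", "ex-symbiotic"])
        comp = composition(labels, types)
        assert comp.counts.loc[2].sum() == 0
        assert comp.percentages.loc[2].isna().all()

    def test_unknown_cell_type_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            composition(np.array([1, 1]), np.array(["endosymbiotic", "mystery"]))

    def test_recovers_planted_mixes(self, default_table_truth):
        table = generate_cell_table(default_table_truth)
        normed = normalise_to_endosymbiont_mean(table)
        pts = normed[["rel_lipid_volume_um3", "rel_lpo_ratio"]].to_numpy()
        model = kmeans_fit(pts, k=3, seed=0)
        comp = composition(model, normed["cell_type"])
        for cluster, mix in zip((1, 2, 3), default_table_truth.celltype_mix_per_component):
            n = comp.counts.loc[cluster].sum()
            observed = comp.counts.loc[cluster, "endosymbiotic"] / n
            half_width = 1.96 * np.sqrt(mix * (1 - mix) / n)
            assert abs(observed - mix) <= max(half_width, 1.0 / n)


class TestClusterShift:
    def test_identical_conditions_zero_difference(self):
        labels = np.array([1, 1, 2, 3, 3])
        types = np.array(["endosymbiotic"] * 4 + ["ex-symbiotic"])
        shift = cluster_shift(labels, types, labels, types)
        np.testing.assert_allclose(shift["difference"], 0.0)

    def test_constructed_shift_quantified_exactly(self):
        control = np.array([1] * 10 + [2] * 5)
        types = np.array(["endosymbiotic"] * 15)
        treated = control.copy()
        treated[:3] = 2  # move 30% of cluster-1 endosymbionts to cluster 2
        shift = cluster_shift(control, types, treated, types).set_index("cluster")
        assert shift.loc[1, "difference"] == pytest.approx(-3 / 15)
        assert shift.loc[2, "difference"] == pytest.approx(3 / 15)

    def test_proportions_sum_to_one_per_condition(self):
        rng = np.random.default_rng(11)
        labels_c = rng.integers(1, 4, 200)
        labels_t = rng.integers(1, 4, 150)
        types_c = rng.choice(["endosymbiotic", "ex-symbiotic"], 200)
        types_t = rng.choice(["endosymbiotic", "ex-symbiotic"], 150)
        shift = cluster_shift(labels_c, types_c, labels_t, types_t)
        pooled = shift[shift.colony == "(pooled)"]
        assert pooled["proportion_control"].sum() == pytest.approx(1.0)
        assert pooled["proportion_treated"].sum() == pytest.approx(1.0)

    def test_no_endosymbionts_flagged_nan(self):
        labels = np.array([1, 2])
        types = np.array(["ex-symbiotic", "ex-symbiotic"])
        shift = cluster_shift(labels, types, labels, types)
        assert shift["proportion_control"].isna().all()
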