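import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rcseg.errors import ValidationError
from rcseg.io import RasterImage
from rcseg.preseg import (
    DistanceClustering,
    cluster_distance_image,
    cluster_zscores,
    compute_color_distance_map,
    equidistant_kmeans_1d,
    preseg_mask,
)


def _img(arr):
    return RasterImage(np.asarray(arr, dtype=float))


class TestDistanceMap:
    def test_identical_images_give_zero_map(self, rng):
        px = rng.random((6, 5, 3))
        dm = compute_color_distance_map(_img(px), _img(px.copy()))
        assert np.all(dm.values == 0.0)

    def test_unit_vector_distance(self):
        img = _img(np.full((1, 1, 3), [1.0, 0.0, 0.0]))
        ref = _img(np.zeros((1, 1, 3)))
        assert compute_color_distance_map(img, ref).values[0, 0] == 1.0

    def test_three_four_five_triangle(self):
        img = _img(np.full((1, 1, 3), [0.3, 0.4, 0.5]))
        ref = _img(np.full((1, 1, 3), [0.0, 0.0, 0.5]))
        assert compute_color_distance_map(img, ref).values[0, 0] == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_color_distance_map(_img(np.zeros((2, 2, 3))),
                                       _img(np.zeros((3, 2, 3))))

    @given(arrays(np.uint8, (4, 4, 3), elements=st.integers(0, 255)),
           arrays(np.uint8, (4, 4, 3), elements=st.integers(0, 255)))
    def test_symmetric_and_zero_iff_equal(self, a8, b8):
        a, b = a8 / 255.0, b8 / 255.0
        d_ab = compute_color_distance_map(_img(a), _img(b)).values
        d_ba = compute_color_distance_map(_img(b), _img(a)).values
        assert np.allclose(d_ab, d_ba)
        assert np.array_equal(d_ab == 0.0, np.all(a == b, axis=2))


def _lloyd_oracle(values, n_clusters, max_iter=100, tol=1e-4):
    """Brute-force scalar Lloyd from the equidistant init (independent path)."""
    values = np.asarray(values, dtype=float)
    centroids = np.linspace(values.min(), values.max(), n_clusters)
    span = max(values.max() - values.min(), 1e-300)
    for _ in range(max_iter):
        d = np.abs(values[:, None] - centroids[None, :])
        labels = np.argmin(d, axis=1)
        new = centroids.copy()
        for k in range(n_clusters):
            members = values[labels == k]
            if members.size:
                new[k] = members.mean()
        if np.max(np.abs(new - centroids)) / span < tol:
            centroids = new
            break
        centroids = new
    d = np.abs(values[:, None] - centroids[None, :])
    labels = np.argmin(d, axis=1)
    return centroids, labels


def _wcss(values, centroids, labels):
    return float(np.sum((values - centroids[labels]) ** 2))


class TestEquidistantKMeans:
    def test_constant_values_collapse_to_one_cluster(self):
        centroids, labels = equidistant_kmeans_1d(np.full(40, 0.7), 25)
        assert centroids.shape == (1,)
        assert np.all(labels == 0)

    def test_two_point_masses_split_exactly(self):
        values = np.array([0.0] * 50 + [1.0] * 50)
        centroids, labels = equidistant_kmeans_1d(values, 2)
        assert np.allclose(centroids, [0.0, 1.0])
        assert np.all(labels[:50] == 0) and np.all(labels[50:] == 1)

    def test_matches_bruteforce_lloyd_wcss(self, rng):
        values = rng.random(100)
        centroids, labels = equidistant_kmeans_1d(values, 5)
        oc, ol = _lloyd_oracle(values, 5)
        assert _wcss(values, centroids, labels) == pytest.approx(
            _wcss(values, oc, ol), rel=1e-9
        )

    def test_centroids_sorted_and_labels_complete(self, rng):
        values = rng.random(500)
        centroids, labels = equidistant_kmeans_1d(values, 12)
        assert np.all(np.diff(centroids) > 0)
        assert labels.min() >= 0 and labels.max() == centroids.size - 1

    def test_invalid_cluster_count_rejected(self):
        with pytest.raises(ValidationError):
            equidistant_kmeans_1d(np.array([1.0, 2.0]), 0)

    def test_histogram_path_close_to_exact(self, rng):
        # above the histogram threshold the accelerated path is used
        values = rng.normal(0.3, 0.1, size=150_000).clip(0, 1)
        centroids, labels = equidistant_kmeans_1d(values, 8)
        exact = _lloyd_oracle(values, 8)
        assert _wcss(values, centroids, labels) <= 1.02 * _wcss(values, *exact)


class TestClusterZScores:
    def test_identical_images_give_zero_z(self, rng):
        px = rng.random((8, 8, 3))
        img, ref = _img(px), _img(px.copy())
        clustering = cluster_distance_image(
            compute_color_distance_map(img, ref), 5
        )
        z = cluster_zscores(img, ref, clustering)
        assert np.all(z.z == 0.0)

    def test_ten_sigma_shift_by_construction(self):
        # one cluster; reference red channel alternates 0.48/0.52 (sd 0.02),
        # the image is shifted by exactly 10 reference sd in that channel
        ref_px = np.zeros((1, 100, 3))
        ref_px[0, :, 0] = np.tile([0.48, 0.52], 50)
        img_px = ref_px.copy()
        img_px[0, :, 0] = 0.5 + 10 * 0.02
        clustering = DistanceClustering(
            labels=np.zeros((1, 100), dtype=np.intp),
            centroids=np.array([0.0]),
            n_pre=1,
        )
        z = cluster_zscores(_img(img_px), _img(ref_px), clustering)
        assert z.z[0] == pytest.approx(10.0)

    def test_matches_direct_recomputation(self, rng):
        img_px, ref_px = rng.random((10, 10, 3)), rng.random((10, 10, 3))
        img, ref = _img(img_px), _img(ref_px)
        clustering = cluster_distance_image(
            compute_color_distance_map(img, ref), 4
        )
        z = cluster_zscores(img, ref, clustering)
        for k in range(clustering.centroids.size):
            sel = clustering.labels == k
            zk = 0.0
            for c in range(3):
                mean_diff = abs(img_px[sel, c].mean() - ref_px[sel, c].mean())
                sd = max(ref_px[sel, c].std(), 1.0 / 255.0)
                zk = max(zk, mean_diff / sd)
            assert z.z[k] == pytest.approx(zk, rel=1e-12)


class TestPresegMask:
    def test_no_plant_gives_empty_mask(self, rng):
        px = rng.random((16, 16, 3))
        mask = preseg_mask(_img(px), _img(px.copy()))
        assert mask.count() == 0

    def test_raising_threshold_shrinks_mask(self, rosette_pair):
        pair = rosette_pair.pair
        masks = [preseg_mask(pair.vis, pair.vis_ref, tsh=t) for t in (2, 5, 10, 50)]
        for lo, hi in zip(masks, masks[1:]):
            assert np.all(hi.pixels <= lo.pixels)

    def test_noise_free_flu_is_almost_ideal(self, clean_pair):
        mask = preseg_mask(clean_pair.pair.flu, clean_pair.pair.flu_ref)
        truth = clean_pair.truth_flu
        wrong = np.logical_xor(mask.pixels, truth.pixels).sum()
        assert wrong <= 0.01 * truth.count()

    def test_default_noise_flu_accuracy(self, rosette_pair):
        mask = preseg_mask(rosette_pair.pair.flu, rosette_pair.pair.flu_ref)
        acc = (mask.pixels == rosette_pair.truth_flu.pixels).mean()
        assert acc >= 0.99
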