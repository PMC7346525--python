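import colorsys

import numpy as np
import pytest

from rcseg.colorspace import (
    fit_eigen_basis,
    multicolor_image,
    reduce_to_regions,
    rgb_to_multicolor,
)
from rcseg.errors import ValidationError
from rcseg.io import BinaryMask, RasterImage

# ---------------------------------------------------------------------------
# Independent reference conversions (classic published constants)

_XYZ_FROM_LINEAR_RGB = np.array(
    [[0.412453, 0.357580, 0.180423],
     [0.212671, 0.715160, 0.072169],
     [0.019334, 0.119193, 0.950227]]
)
_D65_WHITE = np.array([0.95047, 1.0, 1.08883])


def _reference_multicolor(rgb):
    """Hand-coded HSV/Lab/CMYK conversion used as the cross-check oracle."""
    r, g, b = rgb
    h, s, v = colorsys.rgb_to_hsv(r, g, b)

    u = np.array(rgb)
    lin = np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)
    t = (_XYZ_FROM_LINEAR_RGB @ lin) / _D65_WHITE
    f = np.where(t > 0.008856, np.cbrt(t), 7.787 * t + 16.0 / 116.0)
    lab = np.array([116 * f[1] - 16, 500 * (f[0] - f[1]), 200 * (f[1] - f[2])])

    k = 1.0 - max(r, g, b)
    if k >= 1.0:
        c = m = y = 0.0
    else:
        c = (1 - r - k) / (1 - k)
        m = (1 - g - k) / (1 - k)
        y = (1 - b - k) / (1 - k)
    return np.array([
        h, s, v,
        lab[0] / 100.0, (lab[1] + 128) / 255.0, (lab[2] + 128) / 255.0,
        c, m, y, k,
    ]).clip(0, 1)


class TestMulticolor:
    def test_black_conventions(self):
        v = rgb_to_multicolor(np.array([0.0, 0.0, 0.0]))
        assert np.allclose(v[:3], 0.0)          # hue/sat/value zero at black
        assert v[3] == pytest.approx(0.0)       # L = 0
        assert v[4] == pytest.approx(128 / 255, abs=1e-6)
        assert v[5] == pytest.approx(128 / 255, abs=1e-6)
        assert np.allclose(v[6:9], 0.0) and v[9] == 1.0

    def test_white_achromatic_extreme(self):
        v = rgb_to_multicolor(np.array([1.0, 1.0, 1.0]))
        assert v[1] == 0.0 and v[2] == 1.0       # S = 0, V = 1
        assert v[3] == pytest.approx(1.0)        # L = 100 rescaled
        assert np.allclose(v[6:], 0.0)           # C = M = Y = K = 0

    def test_mid_gray_neutral(self):
        v = rgb_to_multicolor(np.array([0.5, 0.5, 0.5]))
        assert v[9] == pytest.approx(0.5)
        assert v[4] == pytest.approx(0.502, abs=0.001)
        assert v[5] == pytest.approx(0.502, abs=0.001)

    def test_matches_reference_conversion_sweep(self, rng):
        rgb = rng.random((200, 3))
        ours = rgb_to_multicolor(rgb)
        theirs = np.stack([_reference_multicolor(c) for c in rgb])
        assert np.abs(ours - theirs).max() < 1e-6

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            rgb_to_multicolor(np.array([1.2, 0.0, 0.0]))


class TestEigenBasis:
    def test_rank_one_data_has_one_nonzero_component(self, rng):
        direction = rng.random(10)
        x = np.outer(rng.random(50), direction)
        basis = fit_eigen_basis(x)
        assert basis.explained_variance[0] > 1e-10
        assert np.all(basis.explained_variance[1:] < 1e-10)

    def test_variance_conservation(self, rng):
        x = rng.random((200, 10))
        basis = fit_eigen_basis(x)
        total = np.trace(np.cov(x, rowvar=False))
        assert basis.explained_variance.sum() == pytest.approx(total, abs=1e-8)

    def test_components_orthonormal_and_sorted(self, rng):
        x = rng.random((100, 10))
        basis = fit_eigen_basis(x)
        gram = basis.components @ basis.components.T
        assert np.abs(gram - np.eye(10)).max() < 1e-8
        assert np.all(np.diff(basis.explained_variance) <= 1e-12)

    def test_matches_svd_oracle(self, rng):
        x = rng.random((500, 10))
        basis = fit_eigen_basis(x)
        centered = x - x.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        for i in range(10):
            v = vt[i]
            j = int(np.argmax(np.abs(v)))
            if v[j] < 0:
                v = -v
            assert np.abs(basis.components[i] - v).max() < 1e-8
        assert np.allclose(basis.explained_variance, s**2 / (x.shape[0] - 1),
                           atol=1e-8)

    def test_projection_roundtrip_reconstructs(self, rng):
        x = rng.random((50, 10))
        basis = fit_eigen_basis(x)
        back = basis.inverse_transform(basis.transform(x))
        assert np.abs(back - x).max() < 1e-8

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            fit_eigen_basis(np.ones((1, 10)))


class TestRegionReduction:
    def _features(self, rgb_image):
        return multicolor_image(RasterImage(rgb_image))

    def test_uniform_region_yields_single_cluster(self):
        img = np.full((8, 8, 3), [0.2, 0.6, 0.3])
        mask = BinaryMask(np.ones((8, 8), dtype=bool))
        part = reduce_to_regions(self._features(img), mask, n_reg=10, seed=0)
        assert part.n_reg == 1
        assert np.allclose(part.ackmr[0], rgb_to_multicolor(np.array([0.2, 0.6, 0.3])))

    def test_two_separated_colors_recovered_exactly(self):
        img = np.zeros((4, 10, 3))
        img[:, 5:] = [0.9, 0.1, 0.1]
        mask = BinaryMask(np.ones((4, 10), dtype=bool))
        part = reduce_to_regions(self._features(img), mask, n_reg=2, seed=0)
        got = sorted(map(tuple, np.round(part.ackmr, 12)))
        want = sorted([
            tuple(np.round(rgb_to_multicolor(np.zeros(3)), 12)),
            tuple(np.round(rgb_to_multicolor(np.array([0.9, 0.1, 0.1])), 12)),
        ])
        assert got == want

    def test_palette_recovery(self, rng):
        palette = rng.random((5, 3))
        idx = rng.integers(0, 5, size=(20, 20))
        img = palette[idx]
        mask = BinaryMask(np.ones((20, 20), dtype=bool))
        part = reduce_to_regions(self._features(img), mask, n_reg=5, seed=0)
        assert part.n_reg == 5
        expected = {tuple(np.round(rgb_to_multicolor(p), 10)) for p in palette}
        got = {tuple(np.round(a, 10)) for a in part.ackmr}
        assert got == expected

    def test_labels_partition_the_mask(self, rng):
        img = rng.random((16, 16, 3))
        mask = BinaryMask(rng.random((16, 16)) > 0.4)
        part = reduce_to_regions(self._features(img), mask, n_reg=6, seed=1)
        assert np.all((part.labels >= 0) == mask.pixels)
        assert part.n_reg <= 6
        assert part.region_pixel_counts().sum() == mask.count()

    def test_ackmr_rows_are_region_means(self, rng):
        img = rng.random((12, 12, 3))
        mask = BinaryMask(np.ones((12, 12), dtype=bool))
        feats = self._features(img)
        part = reduce_to_regions(feats, mask, n_reg=4, seed=2)
        for k in range(part.n_reg):
            sel = part.labels == k
            assert np.allclose(part.ackmr[k], feats[sel].mean(axis=0), atol=1e-10)

    def test_inertia_not_worse_than_single_lloyd_run(self, rng):
        from scipy.cluster.vq import kmeans2

        x = rng.random((1000, 10))
        img = x.reshape(10, 100, 10)
        mask = BinaryMask(np.ones((10, 100), dtype=bool))
        part = reduce_to_regions(img, mask, n_reg=10, seed=3, use_eigen=False)
        ours = sum(
            np.sum((x[part.labels.ravel() == k] - part.ackmr[k]) ** 2)
            for k in range(part.n_reg)
        )
        centroids, labels = kmeans2(x, 10, minit="++", seed=3)
        theirs = np.sum((x - centroids[labels]) ** 2)
        assert ours <= theirs * 1.0001

    def test_empty_mask_rejected(self):
        mask = BinaryMask(np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValidationError):
            reduce_to_regions(np.zeros((4, 4, 10)), mask, n_reg=2)
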