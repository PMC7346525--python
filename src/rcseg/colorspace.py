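"""Extended color spaces, Eigen-colors and k-means region reduction.

Every RGB pixel is lifted to a 10-dimensional "multi-color" vector by
concatenating HSV (3), CIE Lab (3, D65/2 degree) and naive CMYK (4), with
each channel rescaled to [0, 1] so that no space dominates by unit scale
(L is divided by 100, the signed a/b channels are mapped by
``(x + 128) / 255``).  A principal-component analysis of these vectors
yields the "Eigen-color" representation, which improves the topological
separability of color clusters and is the space in which pixel k-means
runs.  A masked image is finally reduced to ``N`` regions described by
their average multi-color vectors - the AC-KMR table that the region
classifiers consume.  Juvenile, homogeneously colored plants need fewer
regions (default 10) than color-rich adult plants (default 30).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv, rgb2lab
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ValidationError
from .io import BinaryMask, RasterImage
from .register import SimilarityTransform

#: Channel order of the multi-color vector.
CHANNEL_NAMES = ("H", "S", "V", "L", "a", "b", "C", "M", "Y", "K")

#: Default region counts per developmental stage (juvenile / mid / adult).
DEFAULT_N_REG = {"I": 10, "II": 20, "III": 30}


def rgb_to_multicolor(rgb: np.ndarray) -> np.ndarray:
    """Lift RGB values in [0, 1] to the 10-D multi-color representation.

    Accepts any leading shape ``(..., 3)`` and returns ``(..., 10)`` in the
    order H, S, V, L, a, b, C, M, Y, K.  Conventions: hue is a fraction of
    a turn in [0, 1); at pure black hue, saturation and C=M=Y are 0 and
    K is 1; Lab neutral gray maps a and b to about 0.502.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValidationError("expected trailing dimension of 3 (RGB)")
    if rgb.min() < 0.0 or rgb.max() > 1.0:
        raise ValidationError("RGB values must lie in [0, 1]")
    lead = rgb.shape[:-1]
    flat = rgb.reshape(-1, 1, 3)

    hsv = rgb2hsv(flat).reshape(-1, 3)
    lab = rgb2lab(flat).reshape(-1, 3)
    lab_scaled = np.empty_like(lab)
    lab_scaled[:, 0] = lab[:, 0] / 100.0
    lab_scaled[:, 1] = (lab[:, 1] + 128.0) / 255.0
    lab_scaled[:, 2] = (lab[:, 2] + 128.0) / 255.0

    r, g, b = (flat[:, 0, i] for i in range(3))
    k = 1.0 - np.maximum(np.maximum(r, g), b)
    denom = np.where(k < 1.0, 1.0 - k, 1.0)
    cmy = np.stack([(1.0 - r - k), (1.0 - g - k), (1.0 - b - k)], axis=1) / denom[:, None]
    cmy[k >= 1.0] = 0.0

    out = np.concatenate([hsv, lab_scaled, cmy, k[:, None]], axis=1)
    return np.clip(out, 0.0, 1.0).reshape(*lead, 10)


def multicolor_image(image: RasterImage) -> np.ndarray:
    """Multi-color representation of a whole image, shape ``(H, W, 10)``."""
    return rgb_to_multicolor(image.pixels)


@dataclass
class EigenColorBasis:
    """Mean-centered orthonormal principal components of multi-color pixels."""

    mean: np.ndarray
    components: np.ndarray  # (k, D) rows orthonormal
    explained_variance: np.ndarray  # non-increasing

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x) - self.mean) @ self.components.T

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z) @ self.components + self.mean


def _fix_component_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading positive."""
    comps = components.copy()
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return comps


def fit_eigen_basis(pixel_features: np.ndarray) -> EigenColorBasis:
    """Fit the Eigen-color basis (full PCA) on an ``(n, D)`` feature matrix."""
    x = np.asarray(pixel_features, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("PCA needs a 2-D matrix with at least 2 rows")
    pca = PCA(n_components=min(x.shape), svd_solver="full")
    pca.fit(x)
    return EigenColorBasis(
        mean=pca.mean_,
        components=_fix_component_signs(pca.components_),
        explained_variance=pca.explained_variance_,
    )


@dataclass
class RegionPartition:
    """A masked image reduced to ``n_reg`` color regions.

    ``labels`` is an ``(H, W)`` integer map with -1 outside the mask;
    ``ackmr`` holds one average multi-color vector per region (the
    classification features), in the raw pre-PCA space.
    """

    labels: np.ndarray
    ackmr: np.ndarray
    n_reg: int

    @property
    def mask(self) -> np.ndarray:
        return self.labels >= 0

    def region_pixel_counts(self) -> np.ndarray:
        lab = self.labels[self.labels >= 0]
        return np.bincount(lab, minlength=self.n_reg)


def reduce_to_regions(
    features: np.ndarray,
    mask: BinaryMask,
    n_reg: int,
    seed: int = 0,
    use_eigen: bool = True,
    n_init: int = 5,
) -> RegionPartition:
    """Reduce the masked pixels of a feature image to k-means color regions.

    ``features`` is ``(H, W, D)``; clustering runs in the Eigen-color
    projection of the masked pixels (k-means++ init, ``n_init`` restarts,
    fixed seed), while the reported AC-KMR vectors are averages of the
    original features.  The effective cluster count is capped by the
    number of distinct feature vectors, so a uniform region always yields
    a single cluster.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 3:
        raise ValidationError("features must be (H, W, D)")
    if features.shape[:2] != mask.shape:
        raise ValidationError("features and mask shapes differ")
    if n_reg < 1:
        raise ValidationError("n_reg must be >= 1")
    sel = mask.pixels
    x = features[sel]
    if x.shape[0] == 0:
        raise ValidationError("empty mask: no plant candidate pixels to cluster")

    n_distinct = np.unique(x, axis=0).shape[0]
    k = int(min(n_reg, n_distinct))
    if k == 1:
        flat_labels = np.zeros(x.shape[0], dtype=np.intp)
    else:
        z = x
        if use_eigen and x.shape[0] > 1:
            z = fit_eigen_basis(x).transform(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
            flat_labels = km.fit_predict(z)
        # Drop empty clusters (rare) and re-index compactly.
        counts = np.bincount(flat_labels, minlength=k)
        keep = np.flatnonzero(counts > 0)
        remap = np.full(k, -1, dtype=np.intp)
        remap[keep] = np.arange(keep.size)
        flat_labels = remap[flat_labels]
        k = keep.size

    ackmr = np.zeros((k, x.shape[1]))
    counts = np.bincount(flat_labels, minlength=k).astype(np.float64)
    for d in range(x.shape[1]):
        ackmr[:, d] = np.bincount(flat_labels, weights=x[:, d], minlength=k) / counts

    labels = np.full(mask.shape, -1, dtype=np.intp)
    labels[sel] = flat_labels
    return RegionPartition(labels=labels, ackmr=ackmr, n_reg=k)


def paired_multicolor(
    vis: RasterImage,
    flu: RasterImage,
    flu_ref: RasterImage,
    transform: SimilarityTransform,
    mask: BinaryMask,
) -> np.ndarray:
    """20-D FLU+VIS features on the VIS grid (VIS channels first).

    Each VIS pixel inside the transferred mask is paired with the FLU
    pixel found by inverse-transform nearest-neighbour lookup; lookups
    falling outside the FLU frame receive the mean FLU reference
    (background) color.  Pixels outside ``mask`` carry the same pairing
    but are not meant to be used.
    """
    h, w = vis.shape
    vis_mc = multicolor_image(vis)
    minv = np.linalg.inv(transform.matrix())
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    src_c = np.rint(minv[0, 0] * cols + minv[0, 1] * rows + minv[0, 2]).astype(np.intp)
    src_r = np.rint(minv[1, 0] * cols + minv[1, 1] * rows + minv[1, 2]).astype(np.intp)
    fh, fw = flu.shape
    valid = (src_r >= 0) & (src_r < fh) & (src_c >= 0) & (src_c < fw)
    flu_rgb = np.empty((h, w, 3))
    flu_rgb[:] = flu_ref.pixels.reshape(-1, 3).mean(axis=0)
    flu_rgb[valid] = flu.pixels[src_r[valid], src_c[valid]]
    flu_mc = rgb_to_multicolor(flu_rgb)
    return np.concatenate([vis_mc, flu_mc], axis=2)
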