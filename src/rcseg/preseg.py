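"""Distance-based pre-segmentation of plant images.

A rough plant/background split is obtained in three steps:

1. a per-pixel Euclidean RGB distance map between the plant-containing
   image and the empty-background reference of the same photochamber;
2. 1-D k-means clustering of the distance values with equidistantly
   initialized centroids (default ``N_pre = 25``);
3. selection of clusters whose plant-vs-reference color distributions
   differ by a standardized z-score above a threshold (default
   ``tsh = 5``).

The union of the selected clusters is the pre-segmentation mask.  On
high-contrast FLU images this already segments the plant almost ideally;
on VIS images it merely removes the bulk of the background so that the
co-registration step sees comparable shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import BinaryMask, RasterImage

#: Default number of distance clusters.
DEFAULT_N_PRE = 25
#: Default z-score selection threshold.
DEFAULT_TSH = 5.0
#: Floor on the reference standard deviation (8-bit quantization step).
SIGMA_FLOOR = 1.0 / 255.0
#: Sample size above which the histogram-accelerated k-means path is used.
_HISTOGRAM_THRESHOLD = 100_000
_HISTOGRAM_BINS = 1024


@dataclass
class DistanceMap:
    """Per-pixel Euclidean RGB distance to the reference (range [0, sqrt(3)])."""

    values: np.ndarray


@dataclass
class DistanceClustering:
    """1-D k-means clustering of a distance map.

    ``centroids`` are sorted ascending with empty clusters removed;
    ``labels`` index into the surviving centroids for every pixel.
    """

    labels: np.ndarray
    centroids: np.ndarray
    n_pre: int


@dataclass
class ClusterZScores:
    """Per-cluster standardized plant-vs-reference color differences."""

    z: np.ndarray
    tsh: float


def compute_color_distance_map(
    image: RasterImage, reference: RasterImage
) -> DistanceMap:
    """Euclidean RGB distance between an image and its reference, per pixel."""
    if image.shape != reference.shape:
        raise ValidationError(
            f"image {image.shape} and reference {reference.shape} differ in size"
        )
    diff = image.pixels - reference.pixels
    return DistanceMap(np.sqrt(np.sum(diff * diff, axis=2)))


def _lloyd_exact(
    values: np.ndarray, centroids: np.ndarray, max_iter: int, tol: float
) -> np.ndarray:
    """Plain Lloyd iterations on scalars; empty clusters keep their centroid."""
    span = max(values.max() - values.min(), np.finfo(float).eps)
    for _ in range(max_iter):
        edges = (centroids[:-1] + centroids[1:]) / 2.0
        labels = np.searchsorted(edges, values, side="right")
        sums = np.bincount(labels, weights=values, minlength=centroids.size)
        counts = np.bincount(labels, minlength=centroids.size)
        new = np.where(counts > 0, sums / np.maximum(counts, 1), centroids)
        if np.max(np.abs(new - centroids)) / span < tol:
            centroids = new
            break
        centroids = new
    return centroids


def _lloyd_histogram(
    values: np.ndarray, centroids: np.ndarray, max_iter: int, tol: float
) -> np.ndarray:
    """Histogram-accelerated Lloyd: iterate on 1024 bin centers with counts."""
    counts, edges = np.histogram(values, bins=_HISTOGRAM_BINS)
    mids = (edges[:-1] + edges[1:]) / 2.0
    span = max(values.max() - values.min(), np.finfo(float).eps)
    for _ in range(max_iter):
        bounds = (centroids[:-1] + centroids[1:]) / 2.0
        labels = np.searchsorted(bounds, mids, side="right")
        sums = np.bincount(labels, weights=counts * mids, minlength=centroids.size)
        wsum = np.bincount(labels, weights=counts, minlength=centroids.size)
        new = np.where(wsum > 0, sums / np.maximum(wsum, 1e-300), centroids)
        if np.max(np.abs(new - centroids)) / span < tol:
            centroids = new
            break
        centroids = new
    return centroids


def equidistant_kmeans_1d(
    values, n_pre: int, max_iter: int = 100, tol: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster scalars with Lloyd's algorithm from an equidistant init.

    Centroids start on a uniform grid over ``[min(values), max(values)]``.
    For large samples (>= 1e5 values) the update runs on a 1024-bin
    histogram of the data instead of the raw values.  Empty clusters are
    dropped afterwards and labels re-indexed against the surviving,
    ascending centroids.

    Returns
    -------
    centroids, labels
        Sorted surviving centroids and a flat label array.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValidationError("cannot cluster an empty value set")
    if n_pre < 1:
        raise ValidationError("n_pre must be >= 1")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax or n_pre == 1:
        return np.array([values.mean()]), np.zeros(values.size, dtype=np.intp)

    centroids = np.linspace(vmin, vmax, n_pre)
    if values.size >= _HISTOGRAM_THRESHOLD:
        centroids = _lloyd_histogram(values, centroids, max_iter, tol)
    else:
        centroids = _lloyd_exact(values, centroids, max_iter, tol)

    # Final assignment, then drop empty / duplicate clusters and re-index.
    centroids = np.unique(centroids)
    edges = (centroids[:-1] + centroids[1:]) / 2.0
    labels = np.searchsorted(edges, values, side="right")
    counts = np.bincount(labels, minlength=centroids.size)
    keep = np.flatnonzero(counts > 0)
    remap = np.full(centroids.size, -1, dtype=np.intp)
    remap[keep] = np.arange(keep.size)
    return centroids[keep], remap[labels]


def cluster_distance_image(
    dmap: DistanceMap, n_pre: int = DEFAULT_N_PRE, max_iter: int = 100,
    tol: float = 1e-4,
) -> DistanceClustering:
    """Apply :func:`equidistant_kmeans_1d` to a distance map."""
    centroids, labels = equidistant_kmeans_1d(
        dmap.values, n_pre, max_iter=max_iter, tol=tol
    )
    return DistanceClustering(
        labels=labels.reshape(dmap.values.shape), centroids=centroids, n_pre=n_pre
    )


def cluster_zscores(
    image: RasterImage,
    reference: RasterImage,
    clustering: DistanceClustering,
    sigma_floor: float = SIGMA_FLOOR,
) -> ClusterZScores:
    """Standardized color difference between image and reference per cluster.

    For cluster ``k`` with pixel set ``P_k`` (the same spatial support in
    both images) and channel ``c``::

        z_{k,c} = |mean_c(image, P_k) - mean_c(ref, P_k)| / max(sd_c(ref, P_k), floor)

    and ``z_k = max_c z_{k,c}``.  The reference-only standard deviation is
    used (the reference is the noise model of the empty chamber); the
    floor guards against exactly constant references.
    """
    if image.shape != reference.shape or image.shape != clustering.labels.shape:
        raise ValidationError("image, reference and clustering shapes differ")
    labels = clustering.labels.ravel()
    n_clusters = clustering.centroids.size
    counts = np.bincount(labels, minlength=n_clusters).astype(np.float64)
    z = np.zeros(n_clusters)
    img = image.pixels.reshape(-1, 3)
    ref = reference.pixels.reshape(-1, 3)
    for c in range(3):
        mean_img = np.bincount(labels, weights=img[:, c], minlength=n_clusters)
        mean_ref = np.bincount(labels, weights=ref[:, c], minlength=n_clusters)
        sq_ref = np.bincount(labels, weights=ref[:, c] ** 2, minlength=n_clusters)
        mean_img /= counts
        mean_ref /= counts
        var_ref = np.maximum(sq_ref / counts - mean_ref**2, 0.0)
        sd_ref = np.maximum(np.sqrt(var_ref), sigma_floor)
        z = np.maximum(z, np.abs(mean_img - mean_ref) / sd_ref)
    return ClusterZScores(z=z, tsh=DEFAULT_TSH)


def preseg_mask(
    image: RasterImage,
    reference: RasterImage,
    n_pre: int = DEFAULT_N_PRE,
    tsh: float = DEFAULT_TSH,
) -> BinaryMask:
    """Pre-segmentation: union of distance clusters with z-score > ``tsh``."""
    dmap = compute_color_distance_map(image, reference)
    clustering = cluster_distance_image(dmap, n_pre=n_pre)
    zscores = cluster_zscores(image, reference, clustering)
    selected = zscores.z > tsh
    return BinaryMask(selected[clustering.labels], frame=image.modality)
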