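"""Small-object (artefact) removal from segmented plant masks.

A segmented mask may still contain small solitary non-plant objects
(e.g. fluorescing algae or moss on the soil).  Because separately
segmented leaf tips of small shoots can be the same size as such
artefacts, no fixed size threshold works; instead every connected
component except the largest is classified from five per-object
features - mean color ratios R/B, R/G, G/B over the VIS image, pixel
size, and vicinity (minimum Euclidean distance-transform value to the
largest component) - by the same eight-classifier family used for
regions, deciding by the median vote (ties keep the object).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.measure import label as cc_label

from .classify import EnsembleModel, combine_predictions, train_ensemble
from .errors import ValidationError
from .io import BinaryMask, RasterImage

#: Feature order of the object-filter table.
OBJECT_FEATURE_NAMES = ("size", "r_over_b", "r_over_g", "g_over_b", "vicinity")
#: Denominator clamp for color ratios (8-bit quantization step).
RATIO_FLOOR = 1.0 / 255.0


@dataclass
class ObjectFeatures:
    """Per-component descriptors used by the artefact filter."""

    component_id: int
    size: int
    r_over_b: float
    r_over_g: float
    g_over_b: float
    vicinity: float
    is_largest: bool

    def vector(self) -> np.ndarray:
        return np.array(
            [self.size, self.r_over_b, self.r_over_g, self.g_over_b, self.vicinity]
        )


def extract_object_features(
    mask: BinaryMask, vis: RasterImage
) -> list[ObjectFeatures]:
    """Describe every 8-connected component of ``mask``.

    Vicinity is the minimum Euclidean distance of the component's pixels
    to the largest component (0 for the largest itself; size ties are
    broken toward the smallest label index).  Ratios use mean channel
    values over the component with the denominator clamped at 1/255.
    """
    if mask.shape != vis.shape:
        raise ValidationError("mask and VIS image shapes differ")
    if mask.count() == 0:
        return []
    labels = cc_label(mask.pixels, connectivity=2)
    n = labels.max()
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=n + 1)
    largest = int(np.argmax(sizes[1:])) + 1  # argmax takes the first (smallest) tie

    edt = distance_transform_edt(labels != largest)
    rgb = vis.pixels.reshape(-1, 3)
    means = np.stack(
        [np.bincount(flat, weights=rgb[:, c], minlength=n + 1) for c in range(3)],
        axis=1,
    ) / np.maximum(sizes, 1)[:, None]

    vicinity = np.full(n + 1, np.inf)
    np.minimum.at(vicinity, flat, edt.ravel())

    out = []
    for comp in range(1, n + 1):
        r, g, b = means[comp]
        out.append(
            ObjectFeatures(
                component_id=comp,
                size=int(sizes[comp]),
                r_over_b=float(r / max(b, RATIO_FLOOR)),
                r_over_g=float(r / max(g, RATIO_FLOOR)),
                g_over_b=float(g / max(b, RATIO_FLOOR)),
                vicinity=float(vicinity[comp]) if comp != largest else 0.0,
                is_largest=comp == largest,
            )
        )
    return out


def features_matrix(objects: list[ObjectFeatures]) -> np.ndarray:
    """Stack object feature vectors into an ``(n, 5)`` table."""
    if not objects:
        return np.empty((0, 5))
    return np.stack([o.vector() for o in objects])


@dataclass
class ObjectFilterModel:
    """Eight object classifiers deciding keep/remove by median vote."""

    ensemble: EnsembleModel

    def decide(self, features: np.ndarray) -> np.ndarray:
        """Median keep(1)/remove(0) decision per object row."""
        votes = self.ensemble.predict_members(features)
        return combine_predictions(votes)["median"]


def train_object_filter(
    features: np.ndarray, labels: np.ndarray, seed: int = 0, net_hidden: int = 10
) -> ObjectFilterModel:
    """Train the artefact filter on labeled object features (1 = plant)."""
    ens = train_ensemble(features, labels, net_hidden=net_hidden, seed=seed)
    return ObjectFilterModel(ensemble=ens)


def filter_small_objects(
    mask: BinaryMask, vis: RasterImage, filter_model: ObjectFilterModel | None
) -> BinaryMask:
    """Remove components voted non-plant; the largest component always stays.

    With no trained filter (``None``) the mask passes through unchanged
    (permissive fallback).
    """
    if filter_model is None or mask.count() == 0:
        return BinaryMask(mask.pixels.copy(), frame=mask.frame)
    objs = extract_object_features(mask, vis)
    candidates = [o for o in objs if not o.is_largest]
    if not candidates:
        return BinaryMask(mask.pixels.copy(), frame=mask.frame)
    keep = filter_model.decide(features_matrix(candidates))
    labels = cc_label(mask.pixels, connectivity=2)
    out = mask.pixels.copy()
    for obj, k in zip(candidates, keep):
        if k == 0:
            out[labels == obj.component_id] = False
    return BinaryMask(out, frame=mask.frame)
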