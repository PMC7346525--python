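"""End-to-end composition of the registration-classification pipeline.

One segmentation run chains: distance-based pre-segmentation of both
modalities -> FLU-to-VIS co-registration of the pre-segmentations ->
transfer of the FLU mask onto the VIS frame -> k-means color-region
reduction of the masked VIS (or FLU+VIS) pixels -> ensemble region
classification -> small-object filtering.  Training assembles the same
region tables but labels them from ground-truth masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import (
    CaseScenarioModel,
    EnsembleModel,
    segment_regions,
    train_ensemble,
)
from .colorspace import (
    DEFAULT_N_REG,
    RegionPartition,
    multicolor_image,
    paired_multicolor,
    reduce_to_regions,
)
from .errors import TrainingError
from .evaluate import RegionSample, region_truth_labels
from .io import BinaryMask, MultimodalPair, RasterImage
from .objects import (
    ObjectFilterModel,
    extract_object_features,
    features_matrix,
    filter_small_objects,
    train_object_filter,
)
from .preseg import DEFAULT_N_PRE, DEFAULT_TSH, preseg_mask
from .register import SimilarityTransform, estimate_similarity_transform, transfer_mask
from .synth import FixturePair

logger = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    """Everything one pipeline run produces."""

    vis_mask: BinaryMask
    flu_mask_registered: BinaryMask
    transform: SimilarityTransform | None
    partition: RegionPartition | None
    support: BinaryMask
    empty: bool = False  # no plant found in the FLU pre-segmentation


def _partition_for(
    pair: MultimodalPair,
    support: BinaryMask,
    transform: SimilarityTransform,
    modality: str,
    n_reg: int,
    seed: int,
) -> RegionPartition:
    if modality == "FLU+VIS":
        features = paired_multicolor(
            pair.vis, pair.flu, pair.flu_ref, transform, support
        )
    else:
        features = multicolor_image(pair.vis)
    return reduce_to_regions(features, support, n_reg=n_reg, seed=seed)


def registered_support(
    pair: MultimodalPair,
    n_pre: int = DEFAULT_N_PRE,
    tsh: float = DEFAULT_TSH,
) -> tuple[BinaryMask, SimilarityTransform | None, BinaryMask]:
    """Pre-segment both modalities and transfer the FLU mask to the VIS frame.

    Returns ``(support, transform, flu_preseg)``; the support is empty
    (and the transform ``None``) when no plant shows in the FLU frame.
    """
    flu_pre = preseg_mask(pair.flu, pair.flu_ref, n_pre=n_pre, tsh=tsh)
    if flu_pre.count() == 0:
        empty = BinaryMask(np.zeros(pair.vis.shape, dtype=bool), frame="VIS")
        return empty, None, flu_pre
    vis_pre = preseg_mask(pair.vis, pair.vis_ref, n_pre=n_pre, tsh=tsh)
    if vis_pre.count() == 0:
        empty = BinaryMask(np.zeros(pair.vis.shape, dtype=bool), frame="VIS")
        return empty, None, flu_pre
    transform = estimate_similarity_transform(flu_pre, vis_pre)
    support = transfer_mask(flu_pre, transform, pair.vis.shape)
    return support, transform, flu_pre


def segment_pair(
    pair: MultimodalPair,
    model: CaseScenarioModel,
    combine: str = "median",
    n_pre: int = DEFAULT_N_PRE,
    tsh: float = DEFAULT_TSH,
    seed: int = 0,
) -> SegmentationResult:
    """Run the full registration-classification segmentation of one pair."""
    support, transform, _ = registered_support(pair, n_pre=n_pre, tsh=tsh)
    empty_vis = BinaryMask(np.zeros(pair.vis.shape, dtype=bool), frame="VIS")
    if transform is None or support.count() == 0:
        logger.warning("empty pre-segmentation: writing an empty mask")
        return SegmentationResult(
            vis_mask=empty_vis,
            flu_mask_registered=empty_vis,
            transform=transform,
            partition=None,
            support=support,
            empty=True,
        )
    modality = model.meta.get("modality", "VIS")
    n_reg = int(model.meta.get("n_reg", 20))
    partition = _partition_for(pair, support, transform, modality, n_reg, seed)
    mask = segment_regions(partition, model.ensemble, combine=combine)
    mask = filter_small_objects(mask, pair.vis, model.object_filter)
    return SegmentationResult(
        vis_mask=mask,
        flu_mask_registered=support,
        transform=transform,
        partition=partition,
        support=support,
    )


def region_sample_for_fixture(
    fixture: FixturePair,
    modality: str = "VIS",
    n_reg: int = 20,
    n_pre: int = DEFAULT_N_PRE,
    tsh: float = DEFAULT_TSH,
    seed: int = 0,
) -> tuple[RegionSample, RegionPartition, SimilarityTransform | None]:
    """Build the labeled region table of one ground-truth fixture.

    Runs the pipeline up to region reduction and labels every region from
    the fixture's pixel ground truth (majority rule, ties plant).
    """
    support, transform, _ = registered_support(fixture.pair, n_pre=n_pre, tsh=tsh)
    if transform is None or support.count() == 0:
        raise TrainingError("fixture yields an empty pre-segmentation")
    partition = _partition_for(
        fixture.pair, support, transform, modality, n_reg, seed
    )
    y = region_truth_labels(partition, fixture.truth_vis)
    return RegionSample(x=partition.ackmr, y=y), partition, transform


def build_suite_samples(
    suite,
    modality: str = "VIS",
    n_reg: dict | int | None = None,
    seed: int = 0,
) -> dict:
    """Region tables for every suite cell, keyed ``(archetype, stage)``.

    ``n_reg`` may be a single count or a per-stage mapping; the default
    follows the stage-dependent region counts (juvenile plants need fewer
    color regions than adult ones).
    """
    if n_reg is None:
        n_reg = DEFAULT_N_REG
    samples = {}
    for (arch, stage), _lst in suite.pairs.items():
        k = n_reg[stage] if isinstance(n_reg, dict) else int(n_reg)
        split = suite.split(arch, stage)
        cell = {}
        for part in ("train", "test"):
            cell[part] = [
                region_sample_for_fixture(
                    fx, modality=modality, n_reg=k, seed=seed
                )[0]
                for fx in split[part]
            ]
        samples[(arch, stage)] = cell
    return samples


def train_case_scenario(
    fixtures: list[FixturePair],
    meta: dict,
    n_reg: int = 20,
    seed: int = 0,
    net_hidden: int = 10,
) -> CaseScenarioModel:
    """Train a full case-scenario model (region ensemble + object filter).

    The region ensemble is trained on the pooled labeled region tables of
    the fixtures.  The object filter is then trained on the connected
    components of the median-combined segmentations, labeled by majority
    overlap with the pixel ground truth; if only one object class occurs
    the permissive fallback (no filter) is stored.
    """
    modality = meta.get("modality", "VIS")
    tables = []
    cached = []
    for fx in fixtures:
        sample, partition, transform = region_sample_for_fixture(
            fx, modality=modality, n_reg=n_reg, seed=seed
        )
        tables.append(sample)
        cached.append((fx, partition))
    x = np.concatenate([t.x for t in tables])
    y = np.concatenate([t.y for t in tables])
    ensemble = train_ensemble(x, y, net_hidden=net_hidden, seed=seed)

    feats, labels = [], []
    for fx, partition in cached:
        mask = segment_regions(partition, ensemble, combine="median")
        for obj in extract_object_features(mask, fx.pair.vis):
            if obj.is_largest:
                continue
            comp_sel = _component_pixels(mask, obj.component_id)
            frac_plant = fx.truth_vis.pixels[comp_sel].mean() if comp_sel.any() else 0
            feats.append(obj.vector())
            labels.append(1 if frac_plant >= 0.5 else 0)
    object_filter: ObjectFilterModel | None = None
    if feats:
        labels_arr = np.asarray(labels, dtype=np.intp)
        if np.unique(labels_arr).size == 2 and labels_arr.size >= 8:
            object_filter = train_object_filter(
                np.stack(feats), labels_arr, seed=seed, net_hidden=net_hidden
            )
        else:
            logger.warning(
                "object filter not trained (single class or too few objects); "
                "using the permissive fallback"
            )
    full_meta = dict(meta)
    full_meta.setdefault("n_reg", n_reg)
    full_meta.setdefault("seed", seed)
    return CaseScenarioModel(ensemble=ensemble, object_filter=object_filter,
                             meta=full_meta)


def _component_pixels(mask: BinaryMask, component_id: int) -> np.ndarray:
    from skimage.measure import label as cc_label

    return cc_label(mask.pixels, connectivity=2) == component_id
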