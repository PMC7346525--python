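"""Synthetic multimodal FLU/VIS fixtures with known ground truth.

The generator emulates the imaging conditions of a greenhouse
phenotyping chamber closely enough that every pipeline stage can be
exercised and verified without real data:

* a dark-background, high-contrast FLU frame versus a light-background,
  low-contrast VIS frame of a *different* size (the two cameras do not
  share a sensor);
* a known FLU-to-VIS similarity misalignment (the motion artefact caused
  by relocating plants between photochambers), recorded exactly as
  applied;
* inhomogeneous illumination (a linear gradient), a blurred offset
  shadow of the plant, Gaussian sensor noise;
* background clutter: fluorescing moss-colored specks that survive the
  FLU mask (the artefacts the small-object filter must remove),
  non-fluorescing soil specks, and detached green leaf tips near the
  plant that must be *kept*;
* three species archetypes (rosette top view, grass side view, broadleaf
  side view) at three developmental stages whose color palettes shift
  from light juvenile green to dark/yellowish adult tones.

All randomness flows from the spec seed; the same spec yields
byte-identical images.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from . import io as rio
from .errors import ValidationError
from .io import BinaryMask, MultimodalPair, RasterImage
from .register import SimilarityTransform

ARCHETYPES = ("rosette-top", "grass-side", "broadleaf-side")
STAGES = ("I", "II", "III")

#: VIS plant color palettes per stage: (base color, secondary color).
STAGE_PALETTES = {
    "I": ((0.55, 0.80, 0.45), (0.62, 0.85, 0.50)),
    "II": ((0.38, 0.62, 0.30), (0.45, 0.68, 0.33)),
    "III": ((0.22, 0.42, 0.18), (0.58, 0.55, 0.20)),
}
#: Plant silhouette size (px in the VIS frame) per stage.
STAGE_SIZES = {"I": 40.0, "II": 75.0, "III": 110.0}

MOSS_COLOR = (0.36, 0.44, 0.30)
SOIL_COLOR = (0.45, 0.33, 0.22)
FLU_PLANT_COLOR = (0.62, 0.08, 0.10)
FLU_MOSS_COLOR = (0.35, 0.06, 0.08)
FLU_BACKGROUND = 0.03
VIS_BACKGROUND = 0.78


@dataclass
class FixtureSpec:
    """Parameters of one synthetic FLU/VIS pair (defaults = study conditions)."""

    seed: int = 0
    vis_shape: tuple[int, int] = (512, 512)
    flu_shape: tuple[int, int] = (400, 400)
    archetype: str = "rosette-top"
    stage: str = "I"
    #: None -> randomized around the frame-size ratio; otherwise a dict
    #: with keys scale, rotation_deg, dx, dy (center is the FLU center).
    misalignment: dict | None = None
    noise_sd: float = 0.01
    illumination_amplitude: float = 0.08
    shadow_opacity: float = 0.25
    shadow_offset: tuple[int, int] = (10, 14)
    shadow_blur: float = 5.0
    n_moss: int = 4
    n_leaftips: int = 3
    n_soil: int = 3
    clutter_radius: tuple[int, int] = (2, 5)

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValidationError(f"unknown archetype {self.archetype!r}")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")


@dataclass
class FixturePair:
    """A generated pair with complete ground truth."""

    pair: MultimodalPair
    truth_vis: BinaryMask
    truth_flu: BinaryMask
    applied_transform: SimilarityTransform
    #: Per clutter/leaf-tip object: center (row, col) in the VIS frame,
    #: radius, label (1 = plant, 0 = artefact) and kind.
    object_labels: list = field(default_factory=list)
    #: Fluorescing clutter (moss) mask in the VIS frame.
    clutter_mask_vis: BinaryMask | None = None
    spec: FixtureSpec | None = None


def _smooth_noise(shape, rng, sigma=4.0) -> np.ndarray:
    """Smooth zero-mean, unit-amplitude noise field (for color texture)."""
    n = gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.abs(n).max()
    return n / peak if peak > 0 else n


def _rosette(shape, center, radius, rng) -> np.ndarray:
    n_lobes = int(rng.integers(6, 11))
    phase = rng.uniform(0, 2 * np.pi)
    rows, cols = np.indices(shape)
    dy, dx = rows - center[0], cols - center[1]
    r = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    rmax = radius * (0.30 + 0.70 * np.abs(np.cos(n_lobes * (phi - phase) / 2)) ** 0.8)
    return r <= rmax


def _stamp_disks(mask, points, radii) -> None:
    for (r, c), rad in zip(points, radii):
        rr, cc = draw_disk((r, c), rad, shape=mask.shape)
        mask[rr, cc] = True


def _grass(shape, base, height, rng) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    n_blades = int(rng.integers(4, 8))
    for _ in range(n_blades):
        tip_dx = rng.uniform(-0.7, 0.7) * height
        ctrl_dx = rng.uniform(-0.3, 0.3) * height
        t = np.linspace(0, 1, 140)
        # quadratic Bezier from the base to a curved tip
        row = base[0] - height * (t**1.1)
        col = base[1] + 2 * t * (1 - t) * ctrl_dx + t**2 * tip_dx
        width = np.maximum(1.0, (1 - t) * max(2.5, height / 40.0))
        _stamp_disks(mask, np.stack([row, col], axis=1), width)
    return mask


def _broadleaf(shape, base, height, rng) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    t = np.linspace(0, 1, 120)
    stem_w = max(1.5, height / 45.0)
    row = base[0] - height * t
    col = base[1] + rng.uniform(-0.08, 0.08) * height * t
    _stamp_disks(mask, np.stack([row, col], axis=1), np.full(t.size, stem_w))
    n_leaves = int(rng.integers(3, 7))
    for i in range(n_leaves):
        at = rng.uniform(0.3, 1.0)
        side = 1 if i % 2 == 0 else -1
        lr = height * rng.uniform(0.18, 0.30)
        cr, cc = base[0] - height * at, base[1] + side * lr * 0.9
        rot = side * rng.uniform(0.4, 1.0)
        rr, cc_ = draw_ellipse(cr, cc, lr * 0.45, lr, rotation=rot, shape=shape)
        mask[rr, cc_] = True
    return mask


def _silhouette(spec: FixtureSpec, rng) -> np.ndarray:
    h, w = spec.vis_shape
    size = STAGE_SIZES[spec.stage]
    jitter = rng.uniform(-15, 15, size=2)
    if spec.archetype == "rosette-top":
        center = (h / 2 + jitter[0], w / 2 + jitter[1])
        return _rosette(spec.vis_shape, center, size, rng)
    if spec.archetype == "grass-side":
        base = (h - 60 + jitter[0] * 0.3, w / 2 + jitter[1])
        return _grass(spec.vis_shape, base, size * 2.1, rng)
    base = (h - 60 + jitter[0] * 0.3, w / 2 + jitter[1])
    return _broadleaf(spec.vis_shape, base, size * 2.1, rng)


def _place_blobs(
    rng, allowed: np.ndarray, n: int, radii_range, occupied: np.ndarray
) -> tuple[np.ndarray, list]:
    """Stamp ``n`` disks at random allowed positions; returns (mask, records)."""
    mask = np.zeros(allowed.shape, dtype=bool)
    records = []
    cand_r, cand_c = np.nonzero(allowed)
    if cand_r.size == 0:
        return mask, records
    for _ in range(n):
        for _attempt in range(30):
            i = int(rng.integers(cand_r.size))
            r, c = int(cand_r[i]), int(cand_c[i])
            rad = int(rng.integers(radii_range[0], radii_range[1] + 1))
            rr, cc = draw_disk((r, c), rad, shape=allowed.shape)
            if occupied[rr, cc].any() or mask[rr, cc].any():
                continue
            mask[rr, cc] = True
            records.append({"center": (r, c), "radius": rad})
            break
    return mask, records


def _default_misalignment(spec: FixtureSpec, rng) -> dict:
    base_scale = min(spec.vis_shape) / min(spec.flu_shape)
    c_vis = np.array([spec.vis_shape[1] / 2, spec.vis_shape[0] / 2])  # (col, row)
    c_flu = np.array([spec.flu_shape[1] / 2, spec.flu_shape[0] / 2])
    t = c_vis - c_flu
    return {
        "scale": base_scale * (1 + rng.uniform(-0.04, 0.04)),
        "rotation_deg": rng.uniform(-3.0, 3.0),
        "dx": float(t[0] + rng.uniform(-8, 8)),
        "dy": float(t[1] + rng.uniform(-8, 8)),
    }


def _sample_vis_frame(masks: dict, transform: SimilarityTransform, flu_shape):
    """Sample VIS-frame boolean maps onto the FLU grid via the forward map."""
    h, w = flu_shape
    m = transform.matrix()
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    vc = np.rint(m[0, 0] * cols + m[0, 1] * rows + m[0, 2]).astype(np.intp)
    vr = np.rint(m[1, 0] * cols + m[1, 1] * rows + m[1, 2]).astype(np.intp)
    vh, vw = next(iter(masks.values())).shape
    valid = (vr >= 0) & (vr < vh) & (vc >= 0) & (vc < vw)
    out = {}
    for name, mask in masks.items():
        s = np.zeros((h, w), dtype=bool)
        s[valid] = mask[vr[valid], vc[valid]]
        out[name] = s
    return out


def generate_pair(spec: FixtureSpec) -> FixturePair:
    """Render one synthetic FLU/VIS pair with ground truth.

    Raises a validation error when the plant silhouette would exceed
    either camera frame.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.vis_shape

    sil = _silhouette(spec, rng)
    if sil.sum() == 0:
        raise ValidationError("degenerate spec: empty silhouette")

    # Distance from the silhouette, for placing near/far clutter.
    edt = distance_transform_edt(~sil)
    tip_zone = (edt >= 4) & (edt <= 15)
    far_zone = edt >= 40
    margin = np.zeros_like(sil)
    margin[20:-20, 20:-20] = True

    rmin, rmax = spec.clutter_radius
    occupied = sil | (edt <= 2)
    tips, tip_rec = _place_blobs(
        rng, tip_zone & margin, spec.n_leaftips, (rmin, max(rmin, rmax - 1)), occupied
    )
    occupied |= tips
    moss, moss_rec = _place_blobs(
        rng, far_zone & margin, spec.n_moss, (rmin, rmax), occupied
    )
    occupied |= moss
    soil, _ = _place_blobs(rng, far_zone & margin, spec.n_soil, (rmin, rmax), occupied)

    objects = [
        {"center": r["center"], "radius": r["radius"], "label": 1, "kind": "leaftip"}
        for r in tip_rec
    ] + [
        {"center": r["center"], "radius": r["radius"], "label": 0, "kind": "moss"}
        for r in moss_rec
    ]

    plant_vis = sil | tips
    if plant_vis[:3].any() or plant_vis[-3:].any() or plant_vis[:, :3].any() or plant_vis[:, -3:].any():
        raise ValidationError("plant silhouette exceeds the VIS frame")

    mis = spec.misalignment or _default_misalignment(spec, rng)
    transform = SimilarityTransform(
        scale=mis["scale"],
        rotation_deg=mis["rotation_deg"],
        translation=(mis["dx"], mis["dy"]),
        center=(spec.flu_shape[1] / 2, spec.flu_shape[0] / 2),
    )

    # ------------------------------------------------------------------ VIS
    angle = rng.uniform(0, 2 * np.pi)
    rows, cols = np.indices((h, w))
    ramp = (np.cos(angle) * (cols / w - 0.5) + np.sin(angle) * (rows / h - 0.5)) * 2
    bg = VIS_BACKGROUND + spec.illumination_amplitude * ramp

    shadow_src = np.roll(sil, spec.shadow_offset, axis=(0, 1)).astype(float)
    shadow = gaussian_filter(shadow_src, spec.shadow_blur)
    shadow /= max(shadow.max(), 1e-9)

    vis = np.repeat((bg * (1 - spec.shadow_opacity * shadow))[..., None], 3, axis=2)
    mix = (_smooth_noise((h, w), rng) + 1) / 2  # smooth field in [0, 1]
    c0, c1 = (np.array(c) for c in STAGE_PALETTES[spec.stage])
    plant_rgb = c0[None, None] * (1 - mix[..., None]) + c1[None, None] * mix[..., None]
    vis[plant_vis] = plant_rgb[plant_vis]
    vis[moss] = np.array(MOSS_COLOR) * rng.uniform(0.9, 1.1)
    vis[soil] = np.array(SOIL_COLOR) * rng.uniform(0.9, 1.1)
    vis_ref_px = np.repeat(bg[..., None], 3, axis=2).copy()
    if spec.noise_sd > 0:
        vis = vis + rng.normal(0, spec.noise_sd, vis.shape)
        vis_ref_px = vis_ref_px + rng.normal(0, spec.noise_sd, vis_ref_px.shape)
    vis = np.clip(vis, 0, 1)
    vis_ref_px = np.clip(vis_ref_px, 0, 1)

    # ------------------------------------------------------------------ FLU
    flu_maps = _sample_vis_frame(
        {"plant": plant_vis, "moss": moss}, transform, spec.flu_shape
    )
    flu_plant, flu_moss = flu_maps["plant"], flu_maps["moss"]
    if flu_plant[:3].any() or flu_plant[-3:].any() or flu_plant[:, :3].any() or flu_plant[:, -3:].any():
        raise ValidationError("plant silhouette exceeds the FLU frame")

    fh, fw = spec.flu_shape
    flu = np.full((fh, fw, 3), FLU_BACKGROUND)
    glow = (_smooth_noise((fh, fw), rng) + 1) / 2
    flu_rgb = np.array(FLU_PLANT_COLOR)[None, None] * (0.85 + 0.3 * glow[..., None])
    flu[flu_plant] = flu_rgb[flu_plant]
    flu[flu_moss] = FLU_MOSS_COLOR
    flu_ref_px = np.full((fh, fw, 3), FLU_BACKGROUND)
    if spec.noise_sd > 0:
        flu = flu + rng.normal(0, spec.noise_sd, flu.shape)
        flu_ref_px = flu_ref_px + rng.normal(0, spec.noise_sd, flu_ref_px.shape)
    flu = np.clip(flu, 0, 1)
    flu_ref_px = np.clip(flu_ref_px, 0, 1)

    pair = MultimodalPair(
        flu=RasterImage(flu, modality="FLU"),
        vis=RasterImage(vis, modality="VIS"),
        flu_ref=RasterImage(flu_ref_px, modality="FLU"),
        vis_ref=RasterImage(vis_ref_px, modality="VIS"),
        meta={"archetype": spec.archetype, "stage": spec.stage, "seed": spec.seed},
    )
    return FixturePair(
        pair=pair,
        truth_vis=BinaryMask(plant_vis, frame="VIS"),
        truth_flu=BinaryMask(flu_plant, frame="FLU"),
        applied_transform=transform,
        object_labels=objects,
        clutter_mask_vis=BinaryMask(moss, frame="VIS"),
        spec=spec,
    )


@dataclass
class SuiteDataset:
    """Per-(archetype, stage) fixture pairs with train/test splits."""

    pairs: dict  # (archetype, stage) -> list[FixturePair]
    n_train: int

    def split(self, archetype: str, stage: str) -> dict:
        lst = self.pairs[(archetype, stage)]
        return {"train": lst[: self.n_train], "test": lst[self.n_train:]}

    def all_pairs(self) -> list[FixturePair]:
        return [p for lst in self.pairs.values() for p in lst]


def generate_scenario_suite(
    seed: int,
    n_pairs: int = 10,
    archetypes=ARCHETYPES,
    stages=STAGES,
    train_fraction: float = 0.5,
    **spec_overrides,
) -> SuiteDataset:
    """Generate the labeled fixture suite: archetypes x stages x ``n_pairs``.

    The first ``train_fraction`` of each cell is the training split.
    Stage palettes follow the juvenile-to-adult color shift, so stage-I
    and stage-III plants differ strongly in mean green level.
    """
    root = np.random.default_rng(seed)
    pairs = {}
    for arch in archetypes:
        for stage in stages:
            cell = []
            for _ in range(n_pairs):
                child = int(root.integers(0, 2**31 - 1))
                cell.append(
                    generate_pair(
                        FixtureSpec(seed=child, archetype=arch, stage=stage,
                                    **spec_overrides)
                    )
                )
            pairs[(arch, stage)] = cell
    return SuiteDataset(pairs=pairs, n_train=max(1, int(n_pairs * train_fraction)))


def object_training_set(fixtures: list[FixturePair]):
    """Build a labeled object table for the artefact filter.

    For every fixture the pre-filter mask (truth plant plus fluorescing
    moss clutter, i.e. what survives FLU masking and color
    classification) is decomposed into components whose features are
    labeled by matching against the generator's object records.
    """
    from .objects import extract_object_features, features_matrix

    feats, labels = [], []
    for fx in fixtures:
        mask = BinaryMask(fx.truth_vis.pixels | fx.clutter_mask_vis.pixels)
        objs = extract_object_features(mask, fx.pair.vis)
        for o in objs:
            if o.is_largest:
                continue
            lab = _match_object_label(o, mask, fx.object_labels)
            if lab is None:
                continue
            feats.append(o.vector())
            labels.append(lab)
    if not feats:
        return np.empty((0, 5)), np.empty(0, dtype=np.intp)
    return np.stack(feats), np.asarray(labels, dtype=np.intp)


def _match_object_label(obj, mask: BinaryMask, records: list) -> int | None:
    from skimage.measure import label as cc_label

    labels = cc_label(mask.pixels, connectivity=2)
    comp = labels == obj.component_id
    for rec in records:
        r, c = rec["center"]
        if comp[int(r), int(c)]:
            return int(rec["label"])
    return None


# --------------------------------------------------------------------------
# Disk layout

def write_suite(suite: SuiteDataset, outdir: str | Path) -> Path:
    """Write the suite in the standard dataset layout plus a manifest."""
    outdir = Path(outdir)
    manifest = {"n_train": suite.n_train, "cells": []}
    for (arch, stage), lst in suite.pairs.items():
        for i, fx in enumerate(lst):
            d = outdir / arch / f"stage_{stage}" / f"pair_{i:03d}"
            d.mkdir(parents=True, exist_ok=True)
            rio.save_image(fx.pair.flu, d / "flu.png")
            rio.save_image(fx.pair.vis, d / "vis.png")
            rio.save_image(fx.pair.flu_ref, d / "flu_ref.png")
            rio.save_image(fx.pair.vis_ref, d / "vis_ref.png")
            rio.save_mask(fx.truth_vis, d / "truth_vis.png")
            rio.save_mask(fx.truth_flu, d / "truth_flu.png")
            fx.applied_transform.to_json(d / "transform.json")
            meta = {
                "archetype": arch,
                "stage": stage,
                "seed": fx.spec.seed if fx.spec else None,
                "objects": [
                    {"center": list(o["center"]), "radius": o["radius"],
                     "label": o["label"], "kind": o["kind"]}
                    for o in fx.object_labels
                ],
            }
            (d / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
            checksum = hashlib.sha256((d / "vis.png").read_bytes()).hexdigest()
            manifest["cells"].append(
                {"archetype": arch, "stage": stage, "index": i,
                 "path": str(d.relative_to(outdir)), "vis_sha256": checksum}
            )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def read_suite(outdir: str | Path) -> SuiteDataset:
    """Reload a suite written by :func:`write_suite`."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    pairs: dict = {}
    for cell in manifest["cells"]:
        d = outdir / cell["path"]
        pair = rio.load_pair(
            d / "flu.png", d / "vis.png", d / "flu_ref.png", d / "vis_ref.png"
        )
        meta = json.loads((d / "meta.json").read_text())
        objects = [
            {"center": tuple(o["center"]), "radius": o["radius"],
             "label": o["label"], "kind": o["kind"]}
            for o in meta["objects"]
        ]
        truth_vis = rio.load_mask(d / "truth_vis.png", frame="VIS")
        clutter = np.zeros(truth_vis.shape, dtype=bool)
        for o in objects:
            if o["kind"] == "moss":
                rr, cc = draw_disk(o["center"], o["radius"], shape=clutter.shape)
                clutter[rr, cc] = True
        fx = FixturePair(
            pair=pair,
            truth_vis=truth_vis,
            truth_flu=rio.load_mask(d / "truth_flu.png", frame="FLU"),
            applied_transform=SimilarityTransform.from_json(d / "transform.json"),
            object_labels=objects,
            clutter_mask_vis=BinaryMask(clutter, frame="VIS"),
        )
        pairs.setdefault((cell["archetype"], cell["stage"]), []).append(fx)
    return SuiteDataset(pairs=pairs, n_train=manifest["n_train"])
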